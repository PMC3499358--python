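"""Genotype panels of homozygous inbred lines.

A :class:`LinePanel` holds a lines-by-sites matrix of genotype codes for a
panel of (near-)fully homozygous lines such as the DGRP.  Because the lines
are inbred, each line carries a single allele at each site and genotypes are
coded as allele dosages:

====================  =====
homozygous reference      0
homozygous alternate      2
missing                  -1
segregating in line      -2
====================  =====

Sites still segregating *within* a line (residual heterozygosity) get their
own code so that downstream analyses can treat them as missing while the
fact remains visible in the stored data.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

HOM_REF = 0
HOM_ALT = 2
MISSING = -1
SEGREGATING = -2

VALID_CODES = frozenset({HOM_REF, HOM_ALT, MISSING, SEGREGATING})

_SITE_RE = re.compile(r"^([^:]+):(\d+)$")


@dataclass(frozen=True, order=True)
class SiteId:
    """A SNP locus named by chromosome arm and 1-based position, e.g. ``3L:7350895``."""

    chrom: str
    pos: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1 (got {self.pos}); coordinates are 1-based")

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}"

    @classmethod
    def parse(cls, text: str) -> "SiteId":
        m = _SITE_RE.match(text)
        if not m:
            raise ValueError(f"malformed site id {text!r}; expected 'chrom:pos'")
        return cls(m.group(1), int(m.group(2)))


class LinePanel:
    """Line-by-site genotype matrix for a homozygous inbred-line panel.

    Parameters
    ----------
    genotypes : pandas.DataFrame
        Integer matrix, index = line ids, columns = site ids ("chrom:pos"
        strings or :class:`SiteId`), values in the panel code set.
    """

    def __init__(self, genotypes: pd.DataFrame):
        cols = [str(c) for c in genotypes.columns]
        if len(set(cols)) != len(cols):
            dupes = pd.Index(cols)[pd.Index(cols).duplicated()].unique().tolist()
            raise ValueError(f"duplicate site ids: {dupes}")
        sites = [SiteId.parse(c) for c in cols]
        values = genotypes.to_numpy()
        bad = ~np.isin(values, list(VALID_CODES))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype code {values[i, j]} at line {genotypes.index[i]!r}, site {cols[j]}"
            )
        self.genotypes = pd.DataFrame(
            values.astype(np.int8), index=genotypes.index.astype(str), columns=cols
        )
        self.sites = sites

    # -- basic queries ---------------------------------------------------

    @property
    def n_lines(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    @property
    def line_ids(self) -> list[str]:
        return list(self.genotypes.index)

    @property
    def site_ids(self) -> list[str]:
        return list(self.genotypes.columns)

    def dosage(self, treat_segregating_as_missing: bool = True) -> pd.DataFrame:
        """Return genotypes as float dosages with NaN for unusable calls.

        Segregating-within-line calls are mapped to NaN by default, the rule
        applied throughout the association analyses.
        """
        x = self.genotypes.to_numpy().astype(float)
        x[x == MISSING] = np.nan
        if treat_segregating_as_missing:
            x[x == SEGREGATING] = np.nan
        return pd.DataFrame(x, index=self.genotypes.index, columns=self.genotypes.columns)

    def signed(self) -> pd.DataFrame:
        """Dosages recoded to -1 (hom ref) / +1 (hom alt) with NaN elsewhere.

        Under this coding the regression slope in a line-mean scan equals
        ``a``, half the difference between homozygote phenotypes.
        """
        return self.dosage() - 1.0

    # -- I/O -------------------------------------------------------------

    def to_tsv(self, path) -> None:
        """Write as TSV: first column ``line_id``, one column per "chrom:pos" site."""
        out = self.genotypes.copy()
        out.index.name = "line_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "LinePanel":
        try:
            df = pd.read_csv(path, sep="\t", index_col="line_id", dtype=str)
        except ValueError as exc:
            raise ValueError(f"malformed genotype TSV header in {path}: {exc}") from exc
        try:
            df = df.astype(np.int8)
        except ValueError as exc:
            raise ValueError(f"non-integer genotype code in {path}: {exc}") from exc
        df.index.name = None
        return cls(df)

    def to_vcf(self, path, ref: str = "A", alt: str = "T") -> None:
        """Write a minimal VCF 4.2 with GT-only FORMAT, one sample per line.

        Homozygous codes map to ``0/0`` and ``1/1``; missing to ``./.``;
        within-line segregating calls to ``0/1``.
        """
        gt_map = {HOM_REF: "0/0", HOM_ALT: "1/1", MISSING: "./.", SEGREGATING: "0/1"}
        buf = io.StringIO()
        buf.write("##fileformat=VCFv4.2\n")
        buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(s.chrom for s in self.sites):
            buf.write(f"##contig=<ID={chrom}>\n")
        buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        buf.write("\t".join(self.line_ids) + "\n")
        codes = self.genotypes.to_numpy()
        for j, site in enumerate(self.sites):
            gts = "\t".join(gt_map[int(c)] for c in codes[:, j])
            buf.write(f"{site.chrom}\t{site.pos}\t{site}\t{ref}\t{alt}\t.\t.\t.\tGT\t{gts}\n")
        with open(path, "w") as fh:
            fh.write(buf.getvalue())

    @classmethod
    def from_vcf(cls, path) -> "LinePanel":
        """Read a GT-only VCF subset.

        ``0/0``→0, ``1/1``→2, ``0/1``/``1/0``→segregating, anything containing
        ``.`` (including half-calls) →missing.
        """
        from cyvcf2 import VCF

        vcf = VCF(str(path), gts012=False)
        samples = list(vcf.samples)
        rows: list[np.ndarray] = []
        sites: list[str] = []
        for var in vcf:
            if var.POS < 1:
                raise ValueError(f"position {var.POS} on {var.CHROM}: coordinates must be 1-based")
            sid = f"{var.CHROM}:{var.POS}"
            if sid in sites:
                raise ValueError(f"duplicate site id {sid}")
            sites.append(sid)
            col = np.full(len(samples), MISSING, dtype=np.int8)
            for i, g in enumerate(var.genotypes):
                alleles = [a for a in g[:-1] if a >= 0]
                if len(alleles) < 2:
                    col[i] = MISSING
                elif alleles[0] != alleles[1]:
                    col[i] = SEGREGATING
                else:
                    col[i] = HOM_ALT if alleles[0] == 1 else HOM_REF
            rows.append(col)
        geno = pd.DataFrame(np.column_stack(rows), index=samples, columns=sites)
        return cls(geno)


def read_genotypes(path, format: str = "tsv") -> LinePanel:
    """Load a genotype panel from ``tsv`` or ``vcf``."""
    if format == "tsv":
        return LinePanel.from_tsv(path)
    if format == "vcf":
        return LinePanel.from_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}; expected 'tsv' or 'vcf'")
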