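"""Synthetic inbred-line panels and phenotypes.

Generates genotype and phenotype data with exactly the statistical structure
the analysis models assume: a panel of homozygous lines genotyped at biallelic
SNPs with tunable linkage disequilibrium and missingness, and vial-structured
phenotypes — per-fly survival times (Gaussian on the observed scale) or
per-vial infected counts (binomial with a logit link and vial-level
overdispersion).  A few planted major-effect loci plus a polygenic line
deviation provide known truth for recovery tests; every simulation returns a
:class:`TruthManifest` recording the realized per-line genetic values.

The defaults emulate a DGRP-like design: ~185 lines, 4 vials per line
(the assay set up 4 vials whenever possible), 15 flies per vial.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .panel import HOM_ALT, HOM_REF, MISSING, SEGREGATING, LinePanel

GAUSSIAN = "observed-survival"
BINOMIAL = "logit-infection"


@dataclass
class PanelSpec:
    """Parameters of a synthetic genotype panel.

    ``maf_law`` gives the two shape parameters of a beta distribution; a draw
    u ~ Beta(a, b) is scaled to a minor-allele frequency u/2 in (0, 0.5).
    ``ld_copy_prob`` is the probability that a site copies the previous
    site's line-assignment pattern (first-order Markov copying), giving
    monotone LD decay r²(d) ≈ ld_copy_prob**d with inter-site distance d.
    """

    n_lines: int = 185
    n_sites: int = 2000
    chrom_lengths: dict[str, int] | None = None
    maf_law: tuple[float, float] = (0.7, 0.7)
    ld_copy_prob: float = 0.7
    missing_rate: float = 0.03
    het_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 2:
            raise ValueError("n_lines must be >= 2: between-line variance is not estimable from one line")
        if self.chrom_lengths is None:
            self.chrom_lengths = {"2L": self.n_sites}
        if sum(self.chrom_lengths.values()) != self.n_sites:
            raise ValueError("chrom_lengths must sum to n_sites")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        for name, rate in [
            ("ld_copy_prob", self.ld_copy_prob),
            ("missing_rate", self.missing_rate),
            ("het_rate", self.het_rate),
        ]:
            if not (0.0 <= rate <= 1.0) or (name != "ld_copy_prob" and rate >= 1.0):
                raise ValueError(f"{name}={rate} out of range")


@dataclass
class TraitDef:
    """Generative parameters of one trait.

    scale ``observed-survival``: per-fly value = β + genetic + vial + residual.
    scale ``logit-infection``: per-vial logit(p) = β + genetic + overdispersion;
    ``v_resid`` is then the overdispersion variance and ``v_vial`` unused.
    """

    scale: str
    beta: float
    v_line_poly: float = 0.0
    v_vial: float = 0.0
    v_resid: float = 0.0

    def __post_init__(self) -> None:
        if self.scale not in (GAUSSIAN, BINOMIAL):
            raise ValueError(f"unknown trait scale {self.scale!r}")
        if min(self.v_line_poly, self.v_vial, self.v_resid) < 0:
            raise ValueError("variances must be >= 0")


@dataclass
class CausalLocus:
    """A planted major-effect locus.

    ``a`` is half the difference between homozygote genotypic values in trait
    units; ``d_ratio`` (dominance deviation as a multiple of a) only matters
    for projecting to outbred populations — inbred lines carry no heterozygotes.
    """

    site: str
    trait: str
    a: float
    d_ratio: float = 0.0


@dataclass
class GeneticModel:
    causal_loci: list[CausalLocus] = field(default_factory=list)
    traits: dict[str, TraitDef] = field(default_factory=dict)

    def loci_for(self, trait: str) -> list[CausalLocus]:
        return [c for c in self.causal_loci if c.trait == trait]


@dataclass
class TruthManifest:
    """Everything needed to score an analysis against the simulation truth."""

    trait: str
    trait_def: TraitDef
    causal_loci: list[CausalLocus]
    seed: int
    line_genetic_values: dict[str, float]

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"trait\t{self.trait}\n")
            fh.write(f"seed\t{self.seed}\n")
            for k, v in asdict(self.trait_def).items():
                fh.write(f"trait.{k}\t{v}\n")
            for c in self.causal_loci:
                fh.write(f"locus\t{c.site}\t{c.trait}\t{float(c.a)!r}\t{float(c.d_ratio)!r}\n")
            for line, g in self.line_genetic_values.items():
                fh.write(f"g\t{line}\t{float(g)!r}\n")

    @classmethod
    def from_file(cls, path) -> "TruthManifest":
        trait = ""
        seed = 0
        td: dict[str, object] = {}
        loci: list[CausalLocus] = []
        gvals: dict[str, float] = {}
        with open(path) as fh:
            for raw in fh:
                parts = raw.rstrip("\n").split("\t")
                key = parts[0]
                if key == "trait":
                    trait = parts[1]
                elif key == "seed":
                    seed = int(parts[1])
                elif key.startswith("trait."):
                    name = key.split(".", 1)[1]
                    td[name] = parts[1] if name == "scale" else float(parts[1])
                elif key == "locus":
                    loci.append(CausalLocus(parts[1], parts[2], float(parts[3]), float(parts[4])))
                elif key == "g":
                    gvals[parts[1]] = float(parts[2])
        return cls(trait, TraitDef(**td), loci, seed, gvals)


def generate_panel(spec: PanelSpec) -> LinePanel:
    """Simulate a homozygous-line genotype panel.

    Each site's alternate allele is assigned to lines as Bernoulli(maf)
    draws; with probability ``ld_copy_prob`` a site instead copies the
    previous site's assignment pattern within the chromosome, creating
    blocks of perfectly correlated sites whose correlation decays
    geometrically with distance.  Missing and within-line-segregating
    calls are overlaid independently at the stated rates.
    """
    rng = np.random.default_rng(spec.seed)
    a, b = spec.maf_law
    cols: list[np.ndarray] = []
    site_ids: list[str] = []
    for chrom, length in spec.chrom_lengths.items():
        prev: np.ndarray | None = None
        for i in range(length):
            if prev is not None and rng.random() < spec.ld_copy_prob:
                pattern = prev
            else:
                maf = 0.5 * rng.beta(a, b)
                pattern = (rng.random(spec.n_lines) < maf).astype(np.int8) * HOM_ALT
            cols.append(pattern)
            prev = pattern
            site_ids.append(f"{chrom}:{i + 1}")
    geno = np.column_stack(cols)
    u = rng.random(geno.shape)
    geno = geno.copy()
    geno[u < spec.missing_rate + spec.het_rate] = SEGREGATING
    geno[u < spec.missing_rate] = MISSING
    lines = [f"line_{i:04d}" for i in range(spec.n_lines)]
    return LinePanel(pd.DataFrame(geno, index=lines, columns=site_ids))


def _line_genetic_values(
    panel: LinePanel, model: GeneticModel, trait: str, rng: np.random.Generator
) -> np.ndarray:
    """Realized genetic value of each line: planted loci plus polygenic deviation.

    Missing genotype at a causal site is resolved by a fresh allele draw at
    that site's observed alternate-allele frequency, so every line has a
    defined genetic value.
    """
    td = model.traits[trait]
    g = np.zeros(panel.n_lines)
    signed = panel.signed()
    for locus in model.loci_for(trait):
        if locus.site not in signed.columns:
            raise ValueError(f"causal site {locus.site} not in panel")
        x = signed[locus.site].to_numpy()
        miss = np.isnan(x)
        if miss.any():
            p_alt = np.nanmean(x + 1) / 2 if (~miss).any() else 0.5
            x = x.copy()
            x[miss] = np.where(rng.random(miss.sum()) < p_alt, 1.0, -1.0)
        g += locus.a * x
    if td.v_line_poly > 0:
        g += rng.normal(0.0, np.sqrt(td.v_line_poly), panel.n_lines)
    return g


def simulate_gaussian_trait(
    panel: LinePanel,
    model: GeneticModel,
    trait: str,
    n_vials: int = 4,
    flies_per_vial: int = 15,
    seed: int = 0,
    round_to_days: bool = False,
) -> tuple[pd.DataFrame, TruthManifest]:
    """Simulate per-fly survival times for each line.

    Returns a long-format phenotype table (line_id, trait, vial_id, fly_id,
    value) and the truth manifest.  Values are continuous by default; with
    ``round_to_days`` they are rounded to whole non-negative days, matching
    an assay that records survival every 24 hours.
    """
    td = model.traits[trait]
    if td.scale != GAUSSIAN:
        raise ValueError(f"trait {trait!r} is not on the observed-survival scale")
    rng = np.random.default_rng(seed)
    g = _line_genetic_values(panel, model, trait, rng)
    lines = panel.line_ids
    n_l, n_v, n_f = len(lines), n_vials, flies_per_vial
    vial_dev = rng.normal(0.0, np.sqrt(td.v_vial), (n_l, n_v)) if td.v_vial > 0 else np.zeros((n_l, n_v))
    resid = rng.normal(0.0, np.sqrt(td.v_resid), (n_l, n_v, n_f)) if td.v_resid > 0 else np.zeros((n_l, n_v, n_f))
    values = td.beta + g[:, None, None] + vial_dev[:, :, None] + resid
    if round_to_days:
        values = np.maximum(np.rint(values), 0.0)
    df = pd.DataFrame(
        {
            "line_id": np.repeat(lines, n_v * n_f),
            "trait": trait,
            "vial_id": [f"{l}_v{v}" for l in lines for v in range(n_v) for _ in range(n_f)],
            "fly_id": [f for _ in range(n_l * n_v) for f in range(n_f)],
            "value": values.ravel(),
        }
    )
    manifest = TruthManifest(trait, td, model.loci_for(trait), seed, dict(zip(lines, g)))
    return df, manifest


def simulate_binomial_trait(
    panel: LinePanel,
    model: GeneticModel,
    trait: str,
    n_vials: int = 4,
    flies_per_vial: int = 15,
    seed: int = 0,
) -> tuple[pd.DataFrame, TruthManifest]:
    """Simulate per-vial infected counts on the logit scale.

    Each vial's infection probability is logit⁻¹(β + line genetic value +
    vial overdispersion deviation); the infected count is binomial in the
    flies of that vial.
    """
    td = model.traits[trait]
    if td.scale != BINOMIAL:
        raise ValueError(f"trait {trait!r} is not on the logit-infection scale")
    rng = np.random.default_rng(seed)
    g = _line_genetic_values(panel, model, trait, rng)
    lines = panel.line_ids
    n_l, n_v = len(lines), n_vials
    od = rng.normal(0.0, np.sqrt(td.v_resid), (n_l, n_v)) if td.v_resid > 0 else np.zeros((n_l, n_v))
    eta = td.beta + g[:, None] + od
    p = 1.0 / (1.0 + np.exp(-eta))
    counts = rng.binomial(flies_per_vial, p)
    df = pd.DataFrame(
        {
            "line_id": np.repeat(lines, n_v),
            "trait": trait,
            "vial_id": [f"{l}_v{v}" for l in lines for v in range(n_v)],
            "n_flies": flies_per_vial,
            "n_infected": counts.ravel(),
        }
    )
    manifest = TruthManifest(trait, td, model.loci_for(trait), seed, dict(zip(lines, g)))
    return df, manifest


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path)
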