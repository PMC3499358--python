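"""End-to-end pipeline driver: simulate -> variance components -> GWAS -> explain.

A :class:`RunConfig` (round-trippable through YAML) names the inputs, trait
definitions and stage settings; :func:`run_pipeline` executes the stages in
order, writing every intermediate artifact plus a machine-readable run log
with the seeds, config hash and line/site/vial counts of each stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import syndata, varcomp, varexplained
from .gwas import (
    INFECTION,
    SURVIVAL,
    LineMeanScan,
    PermutationThreshold,
    collapse_to_line_values,
    qq_curve,
)
from .panel import LinePanel, read_genotypes

log = logging.getLogger("viroquant")


@dataclass
class TraitConfig:
    name: str
    kind: str = SURVIVAL  # survival | infection
    arcsine: bool = False
    covariate_sites: list[str] = field(default_factory=list)


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    out_dir: str
    genotypes: str | None = None  # path; None => simulate
    genotype_format: str = "tsv"
    phenotypes: str | None = None
    traits: list[TraitConfig] = field(default_factory=list)
    # simulation settings (used when genotypes is None)
    simulate: dict = field(default_factory=dict)
    min_minor_lines: int = 4
    n_perm: int = 400
    alpha: float = 0.05
    mcmc: dict = field(default_factory=dict)
    seed: int = 0

    def to_yaml(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["traits"] = [TraitConfig(**t) for t in d.get("traits", [])]
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


def _setup_logging(out: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers.clear()
    for h in (logging.StreamHandler(sys.stderr), logging.FileHandler(out / "run.log")):
        h.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(h)


def _simulate_inputs(cfg: RunConfig, out: Path) -> tuple[LinePanel, pd.DataFrame, dict]:
    sim = dict(cfg.simulate)
    causal = sim.pop("causal_loci", [])
    trait_defs = sim.pop("traits", {})
    design = {k: sim.pop(k, v) for k, v in (("n_vials", 4), ("flies_per_vial", 15))}
    spec = syndata.PanelSpec(seed=cfg.seed, **sim)
    panel = syndata.generate_panel(spec)
    model = syndata.GeneticModel(
        causal_loci=[syndata.CausalLocus(**c) for c in causal],
        traits={k: syndata.TraitDef(**v) for k, v in trait_defs.items()},
    )
    frames = []
    truths = {}
    for i, (name, td) in enumerate(model.traits.items()):
        seed = cfg.seed * 1000 + i + 1
        if td.scale == syndata.GAUSSIAN:
            df, truth = syndata.simulate_gaussian_trait(panel, model, name, seed=seed, **design)
        else:
            df, truth = syndata.simulate_binomial_trait(panel, model, name, seed=seed, **design)
        truth.to_file(out / f"truth_{name}.txt")
        frames.append(df)
        truths[name] = truth
    pheno = pd.concat(frames, ignore_index=True)
    return panel, pheno, truths


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage; returns a bundle of in-memory results.

    Artifacts written under ``cfg.out_dir``: genotypes.tsv, phenotypes.csv,
    per-trait components/scan/null/qq/loci TSVs, run_log.json.  Any stage
    failure aborts with the stage name; artifacts written so far remain.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    runlog: dict = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stages": {},
    }
    bundle: dict = {}
    stage = "inputs"
    try:
        if cfg.genotypes is None:
            panel, pheno, truths = _simulate_inputs(cfg, out)
            bundle["truths"] = truths
        else:
            panel = read_genotypes(cfg.genotypes, cfg.genotype_format)
            pheno = pd.read_csv(cfg.phenotypes)
        panel.to_tsv(out / "genotypes.tsv")
        pheno.to_csv(out / "phenotypes.csv", index=False)
        bundle["panel"], bundle["pheno"] = panel, pheno
        runlog["stages"][stage] = {
            "n_lines": panel.n_lines,
            "n_sites": panel.n_sites,
            "n_vials": int(pheno["vial_id"].nunique()),
        }
        log.info("inputs: %d lines x %d sites", panel.n_lines, panel.n_sites)

        mcmc = dict(cfg.mcmc)
        bundle["components"] = {}
        bundle["scans"] = {}
        bundle["nulls"] = {}
        bundle["loci"] = {}
        for tc in cfg.traits:
            tdf = pheno[pheno["trait"] == tc.name]
            stage = f"varcomp[{tc.name}]"
            if tc.kind == SURVIVAL:
                vc = varcomp.fit_gaussian_nested(tdf, seed=cfg.seed, **mcmc)
            else:
                vc = varcomp.fit_binomial_logit(tdf, seed=cfg.seed, **mcmc)
            vc.to_tsv(out / f"components_{tc.name}.tsv")
            bundle["components"][tc.name] = vc
            h2 = varcomp.heritability(vc)
            log.info("%s: V_g=%.3f h2=%.3f", tc.name, vc.component("v_g").mean, h2.mean)

            stage = f"gwas[{tc.name}]"
            lv = collapse_to_line_values(
                tdf, SURVIVAL if tc.kind == SURVIVAL else INFECTION, arcsine=tc.arcsine
            )
            lv.attrs["trait"] = tc.name
            scan_est = LineMeanScan(cfg.min_minor_lines, tuple(tc.covariate_sites))
            scan_est.fit(panel, lv)
            res = scan_est.scan_
            res.to_tsv(out / f"scan_{tc.name}.tsv")
            perm = PermutationThreshold(
                cfg.n_perm, cfg.min_minor_lines, tuple(tc.covariate_sites), keep_full=True,
                seed=cfg.seed + 17,
            ).fit(panel, lv)
            perm.null_.to_tsv(out / f"null_{tc.name}.tsv")
            qq = qq_curve(res, perm.null_)
            qq.to_csv(out / f"qq_{tc.name}.tsv", sep="\t", index=False)
            bundle["scans"][tc.name] = res
            bundle["nulls"][tc.name] = perm.null_
            thr = perm.null_.threshold(cfg.alpha)
            n_sig = int((res.table["p"] <= thr).sum())
            runlog["stages"][stage] = {
                "sites_retained": len(scan_est.retained_sites_),
                "lines_used": scan_est.n_lines_,
                "threshold": thr,
                "n_significant": n_sig,
            }
            log.info("%s scan: %d sites, threshold(%.2f)=%.2e, %d significant",
                     tc.name, len(scan_est.retained_sites_), cfg.alpha, thr, n_sig)

            stage = f"explain[{tc.name}]"
            top = res.top_hit()
            effects = []
            if top["p"] <= thr:
                eff = varexplained.effect_summary(top, panel, higher_is_resistant=tc.kind == SURVIVAL)
                effects.append(eff)
            v_g = vc.component("v_g").mean
            report = varexplained.locus_report(effects, v_g)
            report.to_csv(out / f"loci_{tc.name}.tsv", sep="\t", index=False)
            bundle["loci"][tc.name] = report
    except Exception as exc:
        log.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    runlog["outputs"] = sorted(p.name for p in out.iterdir())
    with open(out / "run_log.json", "w") as fh:
        json.dump(runlog, fh, indent=2)
    bundle["run_log"] = runlog
    return bundle
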