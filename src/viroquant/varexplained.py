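"""Variance explained by major-effect loci and outbred-population projections.

Under additivity a biallelic locus with allele frequencies p, q and
genotypic values +a / -a for the two homozygotes contributes 2pqa² of
additive genetic variance in a random-mating population.  The slope of the
line-mean regression estimates a, but its square overestimates a²; the
bias-corrected estimate is â² - SE(â)².

Inbred panels carry no heterozygotes, so dominance is invisible to the
panel itself.  To project a locus's share of additive variance into an
outcrossed population under a dominance scenario, the average effect
α = a + d(q - p) replaces a: the locus's outbred additive variance is
2pqα² = 2pqa²·(1 + (d/a)(q - p))².  The remaining (non-focal) genetic
variance is scaled by the fraction of it assumed additive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import LinePanel
from .varcomp import VarianceComponents


@dataclass
class DominanceScenario:
    """Dominance assumption for the outbred projection.

    ``d_ratio`` is the dominance deviation d expressed as a multiple of a:
    +1 means the resistant allele is fully dominant (equivalently the
    susceptible allele recessive), -1 the resistant allele fully recessive,
    0 purely additive.  ``frac_remaining_additive`` is the fraction of the
    non-focal genetic variance assumed additive in the outbred population.
    """

    d_ratio: float = 0.0
    frac_remaining_additive: float = 1.0

    def __post_init__(self) -> None:
        if not -1.0 <= self.d_ratio <= 1.0:
            raise ValueError(f"d_ratio must be in [-1, 1] (got {self.d_ratio})")
        if not 0.0 <= self.frac_remaining_additive <= 1.0:
            raise ValueError("frac_remaining_additive must be in [0, 1]")


@dataclass
class LocusEffect:
    """Effect-size bookkeeping for one associated site."""

    site: str
    p: float  # resistant-allele frequency among genotyped lines
    q: float
    a_hat: float
    se: float
    a2_unbiased: float
    va_locus: float
    n_lines: int
    flags: tuple[str, ...] = ()


def unbiased_a2(a_hat: float, se: float) -> tuple[float, bool]:
    """Bias-corrected squared effect, â² - SE², floored at zero.

    Returns (value, floored): the floor triggers for effects too small to
    distinguish from noise.
    """
    if se < 0:
        raise ValueError("standard error must be >= 0")
    raw = a_hat**2 - se**2
    return (max(raw, 0.0), raw < 0.0)


def locus_additive_variance(p: float, q: float, a2: float) -> float:
    """Additive genetic variance contributed by the locus: 2pqa²."""
    if abs(p + q - 1.0) > 1e-9:
        raise ValueError("allele frequencies must satisfy p + q = 1")
    if a2 < 0:
        raise ValueError("a2 must be >= 0")
    return 2.0 * p * q * a2


def hwe_additive_variance(p: float, a: float, d: float) -> float:
    """Additive variance of a biallelic locus by genotype enumeration.

    Enumerates Hardy-Weinberg genotype frequencies (p², 2pq, q²) with
    genotypic values (a, d, -a) and takes the variance of the least-squares
    regression of value on allele count.  Equals 2pq(a + d(q-p))² and acts
    as the independent cross-check for the projection formula.
    """
    q = 1.0 - p
    freqs = np.array([p**2, 2 * p * q, q**2])
    counts = np.array([2.0, 1.0, 0.0])  # copies of the p allele
    values = np.array([a, d, -a])
    mean_c = freqs @ counts
    mean_v = freqs @ values
    cov = freqs @ ((counts - mean_c) * (values - mean_v))
    var_c = freqs @ (counts - mean_c) ** 2
    alpha = cov / var_c
    fitted = mean_v + alpha * (counts - mean_c)
    return float(freqs @ (fitted - mean_v) ** 2)


def proportion_heritability(
    va_loci: list[float],
    vc: VarianceComponents | float,
    panel: LinePanel | None = None,
    sites: list[str] | None = None,
    ld_warn_r2: float = 0.1,
) -> float:
    """Fraction of the genetic variance explained by the listed loci.

    Σ2pqa²/V_g; since the environmental terms in the heritability
    numerator and denominator cancel, this equals the ratio of the
    adjusted h² to the full h².  Summing locus contributions assumes
    linkage equilibrium between them; when a panel and site list are
    supplied, pairwise genotype correlations above ``ld_warn_r2`` trigger
    a warning.
    """
    import warnings

    v_g = vc.component("v_g").mean if isinstance(vc, VarianceComponents) else float(vc)
    if v_g <= 0:
        raise ValueError("V_g must be positive")
    if panel is not None and sites is not None and len(sites) > 1:
        x = panel.signed()[sites]
        r2 = x.corr().to_numpy() ** 2
        iu = np.triu_indices(len(sites), k=1)
        worst = np.nanmax(r2[iu])
        if worst > ld_warn_r2:
            warnings.warn(
                f"loci in LD (max pairwise r²={worst:.2f}); summed variance contributions overlap"
            )
    return float(np.sum(va_loci) / v_g)


def outbred_va_projection(
    p: float,
    twopqa2: float,
    vg_total: float,
    scenario: DominanceScenario,
) -> float:
    """Locus share of outbred additive variance under a dominance scenario.

    The locus's additive variance becomes 2pqa²·(1 + d_ratio·(q-p))² via
    the average effect α = a(1 + d_ratio(q-p)); the rest of the genetic
    variance contributes frac_remaining_additive·(V_g - 2pqa²).  Dominance
    variance itself is excluded — the projection concerns V_a only.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be a frequency")
    if twopqa2 > vg_total:
        raise ValueError("locus variance cannot exceed total genetic variance")
    q = 1.0 - p
    locus_va = twopqa2 * (1.0 + scenario.d_ratio * (q - p)) ** 2
    remaining = scenario.frac_remaining_additive * (vg_total - twopqa2)
    return locus_va / (locus_va + remaining)


def effect_summary(
    assoc: pd.Series,
    panel: LinePanel,
    higher_is_resistant: bool = True,
) -> LocusEffect:
    """Assemble a :class:`LocusEffect` from one scan row.

    The resistant allele is oriented by the sign of â: for survival traits
    the allele increasing the line mean is resistant
    (``higher_is_resistant``); for infection proportions pass False.
    Frequencies are computed over genotyped (non-missing, non-segregating)
    lines only.
    """
    site = str(assoc["site"])
    x = panel.signed()[site].to_numpy()
    x = x[~np.isnan(x)]
    n = x.size
    if n == 0:
        raise ValueError(f"no genotyped lines at {site}")
    a_hat = float(assoc["a_hat"])
    se = float(assoc["se"])
    flags: list[str] = []
    # +1-coded (alt) allele raises the value iff a_hat > 0
    alt_freq = float(np.mean(x == 1))
    alt_is_resistant = (a_hat > 0) == higher_is_resistant
    if a_hat == 0:
        flags.append("allele orientation ambiguous (a_hat = 0)")
    p = alt_freq if alt_is_resistant else 1.0 - alt_freq
    a2, floored = unbiased_a2(a_hat, se)
    if floored:
        flags.append("a2 floored at 0 (se exceeds |a_hat|)")
    va = locus_additive_variance(p, 1.0 - p, a2)
    return LocusEffect(site, p, 1.0 - p, a_hat, se, a2, va, n, tuple(flags))


def locus_report(effects: list[LocusEffect], v_g: float) -> pd.DataFrame:
    """Tabular per-locus report with each locus's heritability share."""
    rows = [
        (
            e.site,
            e.p,
            e.a_hat,
            e.se,
            e.a2_unbiased,
            e.va_locus,
            e.va_locus / v_g,
            ";".join(e.flags),
        )
        for e in effects
    ]
    return pd.DataFrame(
        rows, columns=["site", "p", "a_hat", "se", "a2_unbiased", "va", "frac_h2", "flags"]
    )
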