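"""Line-mean association scans with permutation-derived significance.

Phenotypes are collapsed to one susceptibility value per line (fly-weighted
mean survival, or pooled proportion infected, optionally arcsine-square-root
transformed) and each retained SNP is tested by least squares regression of
the line values on genotype.  Genotypes are coded -1/+1 for the two
homozygous classes so the slope equals ``a``, half the difference between
homozygote phenotypes.  Because inbred panels carry extensive LD and many
correlated tests, the genome-wide significance threshold comes from
permutation: line values are shuffled across lines, the full scan is rerun,
and the minimum p-value per permutation builds the null distribution of the
best hit.

Multi-SNP helpers (joint marginal and sequential ANOVA p-values) serve to
disentangle clusters of associated SNPs in linkage disequilibrium.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .panel import SEGREGATING, LinePanel

SURVIVAL = "survival"
INFECTION = "infection"


# ---------------------------------------------------------------------------
# line values


def collapse_to_line_values(
    pheno: pd.DataFrame, trait_kind: str = SURVIVAL, arcsine: bool = False
) -> pd.DataFrame:
    """Collapse vial-structured phenotypes to one value per line.

    Survival: mean survival across flies (equivalently the vial means
    weighted by flies per vial).  Infection: pooled proportion infected,
    with an optional arcsin√ transform to remove the mean-variance
    dependence of proportions.  Returns columns line_id, value, weight
    (total flies), n_vials.  Lines with zero flies are dropped with a
    logged warning.
    """
    if trait_kind == SURVIVAL:
        g = pheno.groupby("line_id", sort=False)
        out = pd.DataFrame(
            {
                "value": g["value"].mean(),
                "weight": g["value"].size(),
                "n_vials": g["vial_id"].nunique(),
            }
        )
    elif trait_kind == INFECTION:
        g = pheno.groupby("line_id", sort=False)
        tot = g["n_flies"].sum()
        inf = g["n_infected"].sum()
        zero = tot == 0
        if zero.any():
            warnings.warn(f"dropping lines with zero flies: {list(tot.index[zero])}")
            tot, inf = tot[~zero], inf[~zero]
        prop = inf / tot
        if arcsine:
            prop = np.arcsin(np.sqrt(prop))
        out = pd.DataFrame(
            {"value": prop, "weight": tot, "n_vials": g["vial_id"].nunique()[tot.index]}
        )
    else:
        raise ValueError(f"unknown trait kind {trait_kind!r}")
    out = out[out["weight"] > 0]
    out.index.name = "line_id"
    return out.reset_index()


# ---------------------------------------------------------------------------
# site filtering


def filter_sites(panel: LinePanel, min_minor_lines: int = 4) -> list[str]:
    """Retain biallelic sites whose minor allele occurs in >= ``min_minor_lines`` lines.

    Within-line segregating calls are treated as missing first, so a site
    can drop out if its only minor-allele carriers are segregating.
    """
    x = panel.genotypes.to_numpy()
    usable = (x == 0) | (x == 2)
    n_alt = ((x == 2) & usable).sum(axis=0)
    n_ref = ((x == 0) & usable).sum(axis=0)
    minor = np.minimum(n_alt, n_ref)
    keep = (n_alt > 0) & (n_ref > 0) & (minor >= min_minor_lines)
    return [s for s, k in zip(panel.site_ids, keep) if k]


# ---------------------------------------------------------------------------
# scanning


@dataclass
class ScanResult:
    """Per-SNP association statistics for one trait."""

    trait: str
    table: pd.DataFrame  # site, chrom, pos, n_lines, a_hat, se, F, p, note
    covariates: list[str] = field(default_factory=list)

    def top_hit(self) -> pd.Series:
        ok = self.table.dropna(subset=["p"])
        return ok.loc[ok["p"].idxmin()]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _scan_matrix(X: np.ndarray, y: np.ndarray):
    """Vectorized per-site simple regression of y on ±1 genotype with NaN handling.

    Returns (n, slope, se, F, p) arrays across sites.
    """
    M = ~np.isnan(X)
    Xz = np.where(M, X, 0.0)
    n = M.sum(axis=0).astype(float)
    sx = Xz.sum(axis=0)
    sxx = (Xz**2).sum(axis=0)
    sy = M.T @ y
    syy = M.T @ (y**2)
    sxy = (Xz * y[:, None]).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        sxx_c = sxx - sx**2 / n
        sxy_c = sxy - sx * sy / n
        syy_c = syy - sy**2 / n
        slope = sxy_c / sxx_c
        sse = syy_c - slope * sxy_c
        df = n - 2
        mse = sse / df
        se = np.sqrt(mse / sxx_c)
        F = slope**2 / se**2
    bad = (sxx_c <= 0) | (df <= 0) | (mse <= 0)
    F = np.where(bad, np.nan, F)
    p = np.where(np.isnan(F), np.nan, stats.f.sf(np.where(np.isnan(F), 1.0, F), 1, np.maximum(df, 1)))
    # perfect fits: mse underflows to 0 while the slope is defined
    perfect = (mse <= 0) & (sxx_c > 0) & (df > 0)
    p = np.where(perfect, np.nextafter(0, 1), p)
    F = np.where(perfect, np.inf, F)
    se = np.where(perfect, 0.0, se)
    return n, slope, se, F, p


def _conditional_site_fit(x: np.ndarray, C: np.ndarray, y: np.ndarray):
    """F-test of one site given covariate genotypes, complete cases per site."""
    keep = ~np.isnan(x)
    x, Ck, yk = x[keep], C[keep], y[keep]
    n = x.size
    full = np.column_stack([np.ones(n), Ck, x])
    if n <= full.shape[1]:
        return n, np.nan, np.nan, np.nan, np.nan, "insufficient lines"
    rank_red = np.linalg.matrix_rank(full[:, :-1])
    if np.linalg.matrix_rank(full) <= rank_red:
        return n, np.nan, np.nan, np.nan, np.nan, "collinear with covariates"
    coef, _, _, _ = np.linalg.lstsq(full, yk, rcond=None)
    resid = yk - full @ coef
    df = n - full.shape[1]
    sse_full = float(resid @ resid)
    coef_r, _, _, _ = np.linalg.lstsq(full[:, :-1], yk, rcond=None)
    sse_red = float(((yk - full[:, :-1] @ coef_r) ** 2).sum())
    slope = float(coef[-1])
    if sse_full <= 1e-12 * max(sse_red, 1.0):
        return n, slope, 0.0, np.inf, np.nextafter(0, 1), ""
    F = (sse_red - sse_full) / (sse_full / df)
    p = float(stats.f.sf(F, 1, df))
    se = float(abs(slope) / np.sqrt(F)) if F > 0 else np.nan
    return n, slope, se, float(F), p, ""


class LineMeanScan(BaseEstimator):
    """Genome scan regressing line susceptibility values on SNP genotype.

    Sites are filtered to biallelic SNPs with the minor allele in at least
    ``min_minor_lines`` lines.  ``covariate_sites`` adds known major-effect
    genotypes as explanatory variables (the conditional scan); lines
    missing any covariate genotype are excluded, and per focal site the
    remaining missing genotypes are dropped casewise.
    """

    def __init__(self, min_minor_lines: int = 4, covariate_sites: tuple[str, ...] = ()):
        self.min_minor_lines = min_minor_lines
        self.covariate_sites = covariate_sites

    def fit(self, panel: LinePanel, line_values: pd.DataFrame) -> "LineMeanScan":
        trait = str(line_values.attrs.get("trait", "trait"))
        lv = line_values.set_index("line_id")["value"]
        common = [l for l in panel.line_ids if l in lv.index]
        if len(common) < 3:
            raise ValueError("need >= 3 lines shared between panel and phenotypes")
        retained = filter_sites(panel, self.min_minor_lines)
        signed = panel.signed().loc[common]
        y = lv.loc[common].to_numpy(dtype=float)
        covs = list(self.covariate_sites)
        self.retained_sites_ = retained
        self.n_lines_ = len(common)
        focal = [s for s in retained if s not in covs]
        if covs:
            missing_cov = [c for c in covs if c not in signed.columns]
            if missing_cov:
                raise KeyError(f"covariate sites not in panel: {missing_cov}")
            C = signed[covs].to_numpy()
            keep = ~np.isnan(C).any(axis=1)
            C, y = C[keep], y[keep]
            X = signed[focal].to_numpy()[keep]
            rows = []
            for k, site in enumerate(focal):
                n, slope, se, F, p, note = _conditional_site_fit(X[:, k], C, y)
                rows.append((site, n, slope, se, F, p, note))
            tab = pd.DataFrame(rows, columns=["site", "n_lines", "a_hat", "se", "F", "p", "note"])
        else:
            X = signed[focal].to_numpy()
            n, slope, se, F, p = _scan_matrix(X, y)
            tab = pd.DataFrame(
                {"site": focal, "n_lines": n.astype(int), "a_hat": slope, "se": se, "F": F, "p": p, "note": ""}
            )
        parts = tab["site"].str.split(":", expand=True)
        tab.insert(1, "chrom", parts[0])
        tab.insert(2, "pos", parts[1].astype(int))
        self.scan_ = ScanResult(trait, tab, covs)
        # cached design for the permutation engine; y and C already share the
        # same (covariate-complete) line set
        self._X = X
        self._y = y
        self._C = C if covs else None
        self._focal = focal
        return self

    # internal fast path reused by the permutation engine
    def _scan_pvalues(self, y: np.ndarray) -> np.ndarray:
        if self._C is None:
            return _scan_matrix(self._X, y)[4]
        return np.array(
            [_conditional_site_fit(self._X[:, k], self._C, y)[4] for k in range(self._X.shape[1])]
        )


def scan(
    panel: LinePanel,
    line_values: pd.DataFrame,
    covariate_sites: tuple[str, ...] = (),
    min_minor_lines: int = 4,
) -> ScanResult:
    est = LineMeanScan(min_minor_lines=min_minor_lines, covariate_sites=tuple(covariate_sites))
    return est.fit(panel, line_values).scan_


# ---------------------------------------------------------------------------
# permutation null


@dataclass
class PermutationNull:
    """Null distribution of the genome-wide minimum p-value.

    Built by shuffling line values across lines and rescanning; the
    α-threshold is the empirical α-quantile of the minimum p-values.
    """

    min_p: np.ndarray
    n_perm: int
    seed: int
    perm_pvalues: np.ndarray | None = None  # (n_perm, n_sites) if retained

    def threshold(self, alpha: float = 0.05) -> float:
        return float(np.quantile(self.min_p, alpha))

    def genomewide_p(self, p_obs: float) -> float:
        """Permutation p-value of an observed best hit."""
        return float((np.sum(self.min_p <= p_obs) + 1) / (self.n_perm + 1))

    def to_tsv(self, path) -> None:
        pd.DataFrame({"min_p": self.min_p}).to_csv(path, sep="\t", index=False)


class PermutationThreshold(BaseEstimator):
    """Permutation engine for genome-wide significance thresholds.

    ``keep_full=True`` additionally stores every permutation scan's full
    p-value vector, which the QQ expectation needs.
    """

    def __init__(
        self,
        n_perm: int = 400,
        min_minor_lines: int = 4,
        covariate_sites: tuple[str, ...] = (),
        keep_full: bool = False,
        seed: int = 0,
    ):
        self.n_perm = n_perm
        self.min_minor_lines = min_minor_lines
        self.covariate_sites = covariate_sites
        self.keep_full = keep_full
        self.seed = seed

    def fit(self, panel: LinePanel, line_values: pd.DataFrame) -> "PermutationThreshold":
        if self.n_perm < 20:
            warnings.warn(f"n_perm={self.n_perm} < 20: threshold quantile will be unstable")
        base = LineMeanScan(self.min_minor_lines, tuple(self.covariate_sites))
        base.fit(panel, line_values)
        rng = np.random.default_rng(self.seed)
        y = base._y
        mins = np.empty(self.n_perm)
        full = np.empty((self.n_perm, len(base._focal))) if self.keep_full else None
        for i in range(self.n_perm):
            p = base._scan_pvalues(rng.permutation(y))
            mins[i] = np.nanmin(p)
            if full is not None:
                full[i] = p
        self.null_ = PermutationNull(mins, self.n_perm, self.seed, full)
        self.scan_ = base.scan_
        return self


def permute_threshold(
    panel: LinePanel,
    line_values: pd.DataFrame,
    covariate_sites: tuple[str, ...] = (),
    n_perm: int = 400,
    seed: int = 0,
    keep_full: bool = False,
    min_minor_lines: int = 4,
) -> PermutationNull:
    est = PermutationThreshold(n_perm, min_minor_lines, tuple(covariate_sites), keep_full, seed)
    return est.fit(panel, line_values).null_


def qq_curve(observed: ScanResult, null: PermutationNull) -> pd.DataFrame:
    """Observed vs permutation-expected -log10 p order statistics.

    The k-th smallest observed p is paired with the mean k-th smallest p
    across the stored permutation scans (requires ``keep_full``).
    """
    if null.perm_pvalues is None:
        raise ValueError("permutation null was built without keep_full=True")
    obs = np.sort(observed.table["p"].dropna().to_numpy())
    perm = np.sort(null.perm_pvalues, axis=1)
    k = min(obs.size, perm.shape[1])
    expected = np.nanmean(perm[:, :k], axis=0)
    return pd.DataFrame(
        {"expected_nlog10p": -np.log10(expected[:k]), "observed_nlog10p": -np.log10(obs[:k])}
    )


# ---------------------------------------------------------------------------
# multi-SNP models


def _design_for_sites(panel: LinePanel, line_values: pd.DataFrame, sites: list[str]):
    lv = line_values.set_index("line_id")["value"]
    common = [l for l in panel.line_ids if l in lv.index]
    signed = panel.signed().loc[common, sites]
    keep = ~signed.isna().any(axis=1)  # listwise deletion inside joint fits
    X = signed.loc[keep].to_numpy()
    y = lv.loc[signed.index[keep]].to_numpy(dtype=float)
    return X, y


def _rss(A: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return float(resid @ resid), int(rank)


def joint_fit(panel: LinePanel, line_values: pd.DataFrame, sites: list[str]) -> pd.DataFrame:
    """Marginal p-value of each site with all others as covariates.

    Each site's F-test compares the full joint model against the model
    dropping that site; perfectly collinear sites are reported as aliased
    instead of receiving p-values.
    """
    X, y = _design_for_sites(panel, line_values, sites)
    n, k = X.shape
    if k > n - 2:
        raise ValueError(f"{k} sites but only {n} complete-case lines; need k <= n-2")
    full = np.column_stack([np.ones(n), X])
    sse_full, rank_full = _rss(full, y)
    df_full = n - rank_full
    rows = []
    aliased = rank_full < full.shape[1]
    for j, site in enumerate(sites):
        sub = np.delete(full, j + 1, axis=1)
        sse_red, rank_red = _rss(sub, y)
        if aliased and rank_red == rank_full:
            rows.append((site, np.nan, np.nan, "aliased (collinear with another site)"))
            continue
        F = (sse_red - sse_full) / max(sse_full / df_full, 1e-300)
        p = float(stats.f.sf(F, 1, df_full))
        rows.append((site, float(F), p, ""))
    return pd.DataFrame(rows, columns=["site", "F", "p", "note"])


def sequential_fit(panel: LinePanel, line_values: pd.DataFrame, site_order: list[str]) -> pd.DataFrame:
    """Sequential (type-I ANOVA) p-values adding sites in the given order."""
    X, y = _design_for_sites(panel, line_values, site_order)
    n = X.shape[0]
    full = np.column_stack([np.ones(n), X])
    sse_full, rank_full = _rss(full, y)
    df_full = n - rank_full
    rows = []
    prev_sse, prev_rank = _rss(full[:, :1], y)
    for j, site in enumerate(site_order):
        sse_j, rank_j = _rss(full[:, : j + 2], y)
        if rank_j == prev_rank:
            rows.append((site, np.nan, np.nan, "aliased (no new information)"))
        else:
            F = (prev_sse - sse_j) / max(sse_full / df_full, 1e-300)
            p = float(stats.f.sf(F, 1, df_full))
            rows.append((site, float(F), p, ""))
        prev_sse, prev_rank = sse_j, rank_j
    return pd.DataFrame(rows, columns=["site", "F", "p", "note"])
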