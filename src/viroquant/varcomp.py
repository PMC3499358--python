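"""Variance components, heritability and genetic correlations.

Vial-structured phenotypes from an inbred-line panel are decomposed into
between-line, between-vial and residual variance by Bayesian MCMC:

* Gaussian nested model for per-fly survival times,
  ``y_ijk = β + b_i + c_j + ε_ijk`` with ``b ~ N(0, V_line)``,
  ``c ~ N(0, V_vial)``, ``ε ~ N(0, V_r)`` — fitted by conjugate Gibbs.
* Binomial logit model for per-vial infected counts,
  ``logit(p_ij) = β + b_i + ε_ij`` where the vial-level ``ε`` captures
  overdispersion — fitted by adaptive Metropolis-within-Gibbs.
* Multivariate binary model across traits with a line-effect covariance
  matrix (inverse-Wishart updates), for genetic correlations.

Because the lines are homozygous, the additive genetic variance of the base
population is half the between-line variance: ``V_g = V_line / 2``.
Heritability is ``V_g/(V_g + V_vial + V_r)`` on the observed scale and
``V_g/(V_g + V_r + π²/3)`` on the logit scale, the π²/3 term being the
variance of the standard logistic distribution implied by the link.

Point summaries are posterior means with 95% highest-posterior-density
intervals; nonlinear transforms (h², correlations, CV_g) are computed per
draw and then summarized, never from averaged components.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

LOGIT_RESID = np.pi**2 / 3

OBSERVED = "observed"
LOGIT = "logit"


# ---------------------------------------------------------------------------
# posterior containers


def hpd_interval(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``prob`` of the draws."""
    lo, hi = az.hdi(np.asarray(draws, dtype=float).ravel(), hdi_prob=prob)
    return float(lo), float(hi)


@dataclass
class PosteriorSummary:
    """Posterior mean and 95% HPD interval of a scalar quantity."""

    name: str
    draws: np.ndarray
    n_excluded: int = 0

    @property
    def mean(self) -> float:
        return float(np.mean(self.draws))

    @property
    def hpd(self) -> tuple[float, float]:
        return hpd_interval(self.draws)

    def __repr__(self) -> str:
        lo, hi = self.hpd
        return f"{self.name}: {self.mean:.4g} (95% HPD {lo:.4g}-{hi:.4g})"


@dataclass
class VarianceComponents:
    """Posterior draws and summaries of a single-trait variance decomposition.

    ``draws`` has one row per retained MCMC draw with columns ``chain``,
    ``beta``, ``v_line``, ``v_vial`` (0 for logit-scale fits) and ``v_r``
    (residual, or overdispersion on the logit scale).
    """

    trait: str
    scale: str
    draws: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    @property
    def v_g_draws(self) -> np.ndarray:
        # inbred panel: genetic variance is half the between-line variance
        return self.draws["v_line"].to_numpy() / 2.0

    @property
    def v_e_draws(self) -> np.ndarray:
        if self.scale == OBSERVED:
            return (self.draws["v_vial"] + self.draws["v_r"]).to_numpy()
        return self.draws["v_r"].to_numpy() + LOGIT_RESID

    def component(self, name: str) -> PosteriorSummary:
        mapping = {
            "beta": self.draws["beta"].to_numpy(),
            "v_line": self.draws["v_line"].to_numpy(),
            "v_vial": self.draws["v_vial"].to_numpy(),
            "v_r": self.draws["v_r"].to_numpy(),
            "v_g": self.v_g_draws,
            "v_e": self.v_e_draws,
        }
        return PosteriorSummary(name, mapping[name])

    def diagnostics(self) -> pd.DataFrame:
        """Effective sample size and split scale-reduction per component."""
        rows = []
        chains = sorted(self.draws["chain"].unique())
        for name in ("beta", "v_line", "v_vial", "v_r"):
            arr = np.stack([self.draws.loc[self.draws.chain == c, name].to_numpy() for c in chains])
            if np.allclose(arr, arr.ravel()[0]):
                rows.append((name, float(arr.size), 1.0))
                continue
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                ess = float(az.ess(arr))
                rhat = float(az.rhat(arr)) if len(chains) > 1 else float("nan")
            rows.append((name, ess, rhat))
        return pd.DataFrame(rows, columns=["component", "ess", "rhat"]).set_index("component")

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in ("beta", "v_line", "v_vial", "v_r", "v_g", "v_e"):
            s = self.component(name)
            lo, hi = s.hpd
            rows.append((name, s.mean, lo, hi))
        return pd.DataFrame(rows, columns=["component", "mean", "hpd_lo", "hpd_hi"]).set_index(
            "component"
        )

    def to_tsv(self, path) -> None:
        out = self.summary().join(self.diagnostics(), how="left")
        out.to_csv(path, sep="\t")


@dataclass
class GeneticCovMatrix:
    """Posterior of the between-line covariance matrix across traits."""

    traits: list[str]
    cov_draws: np.ndarray  # (n_draws, T, T)
    resid_draws: np.ndarray  # (n_draws, T)
    beta_draws: np.ndarray  # (n_draws, T)
    chain: np.ndarray  # (n_draws,)
    warnings: list[str] = field(default_factory=list)

    def index_of(self, trait: str) -> int:
        try:
            return self.traits.index(trait)
        except ValueError:
            raise KeyError(f"trait {trait!r} not in covariance matrix ({self.traits})") from None


# ---------------------------------------------------------------------------
# design extraction


def _gaussian_design(pheno: pd.DataFrame):
    df = pheno
    required = {"line_id", "vial_id", "value"}
    if not required <= set(df.columns):
        raise ValueError(f"Gaussian phenotype table needs columns {sorted(required)}")
    y = df["value"].to_numpy(dtype=float)
    line_codes, line_ids = pd.factorize(df["line_id"])
    vial_codes, vial_ids = pd.factorize(df["vial_id"])
    # each vial must belong to exactly one line
    vial_line = np.full(len(vial_ids), -1, dtype=int)
    vial_line[vial_codes] = line_codes
    check = pd.DataFrame({"v": vial_codes, "l": line_codes}).groupby("v")["l"].nunique()
    if (check > 1).any():
        raise ValueError("a vial id maps to more than one line")
    return y, line_codes, vial_codes, vial_line, list(line_ids)


def _inv_gamma_draw(rng, shape: float, rate: float) -> float:
    return rate / rng.gamma(shape)


# ---------------------------------------------------------------------------
# Gaussian nested model


class GaussianNestedVC(BaseEstimator):
    """Gibbs sampler for the nested Gaussian survival model.

    Parameters
    ----------
    n_iter, burn_in, thin : int
        Total iterations per chain, burn-in discarded, thinning interval.
    n_chains : int
        Independent chains (used for the scale-reduction diagnostic).
    prior_shape, prior_rate : float
        Inverse-gamma prior on each variance; the default (0.01, 0.01) is
        weakly informative but proper.  ``improper=True`` switches to the
        scale prior p(σ²) ∝ 1/σ², which can yield an improper posterior
        with few levels.
    """

    def __init__(
        self,
        n_iter: int = 20000,
        burn_in: int = 5000,
        thin: int = 10,
        n_chains: int = 2,
        prior_shape: float = 0.01,
        prior_rate: float = 0.01,
        improper: bool = False,
        seed: int = 0,
    ):
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.n_chains = n_chains
        self.prior_shape = prior_shape
        self.prior_rate = prior_rate
        self.improper = improper
        self.seed = seed

    def fit(self, pheno: pd.DataFrame, trait: str | None = None) -> "GaussianNestedVC":
        df = pheno if trait is None else pheno[pheno["trait"] == trait]
        trait_name = trait or (str(df["trait"].iloc[0]) if "trait" in df.columns else "trait")
        y, line, vial, vial_line, line_ids = _gaussian_design(df)
        n_l = line.max() + 1
        if n_l < 2:
            raise ValueError("need >= 2 lines to estimate between-line variance")
        warns: list[str] = []
        vials_per_line = np.bincount(vial_line, minlength=n_l)
        vial_estimable = bool((vials_per_line >= 2).any())
        if not vial_estimable:
            warns.append("one vial per line everywhere: V_vial inestimable, fixed at 0")
        a0, b0 = (0.0, 0.0) if self.improper else (self.prior_shape, self.prior_rate)
        all_draws = []
        for chain in range(self.n_chains):
            rng = np.random.default_rng((self.seed, chain))
            all_draws.append(self._run_chain(rng, y, line, vial, vial_estimable, a0, b0, chain))
        draws = pd.concat(all_draws, ignore_index=True)
        self.components_ = VarianceComponents(trait_name, OBSERVED, draws, warns)
        self.line_ids_ = line_ids
        for w in warns:
            _warnings.warn(w)
        return self

    def _run_chain(self, rng, y, line, vial, vial_estimable, a0, b0, chain):
        N = y.size
        n_l = line.max() + 1
        n_v = vial.max() + 1
        n_per_line = np.bincount(line, minlength=n_l).astype(float)
        n_per_vial = np.bincount(vial, minlength=n_v).astype(float)
        beta = float(np.mean(y))
        b = np.zeros(n_l)
        c = np.zeros(n_v)
        v_line = max(np.var(y) / 2, 1e-3)
        v_vial = max(np.var(y) / 4, 1e-3) if vial_estimable else 0.0
        v_r = max(np.var(y) / 2, 1e-3)
        out = []
        for it in range(self.n_iter):
            # line effects
            resid = y - beta - c[vial]
            s = np.bincount(line, weights=resid, minlength=n_l)
            prec = n_per_line / v_r + 1.0 / v_line
            b = s / v_r / prec + rng.standard_normal(n_l) / np.sqrt(prec)
            # vial effects
            if vial_estimable:
                resid = y - beta - b[line]
                s = np.bincount(vial, weights=resid, minlength=n_v)
                prec = n_per_vial / v_r + 1.0 / v_vial
                c = s / v_r / prec + rng.standard_normal(n_v) / np.sqrt(prec)
            # grand mean (flat prior)
            resid = y - b[line] - c[vial]
            beta = float(np.mean(resid) + rng.standard_normal() * np.sqrt(v_r / N))
            # variances
            v_line = _inv_gamma_draw(rng, a0 + n_l / 2, b0 + 0.5 * np.sum(b**2))
            if vial_estimable:
                v_vial = _inv_gamma_draw(rng, a0 + n_v / 2, b0 + 0.5 * np.sum(c**2))
            sse = np.sum((y - beta - b[line] - c[vial]) ** 2)
            v_r = _inv_gamma_draw(rng, a0 + N / 2, b0 + 0.5 * sse)
            if it >= self.burn_in and (it - self.burn_in) % self.thin == 0:
                out.append((chain, beta, v_line, v_vial, v_r))
        return pd.DataFrame(out, columns=["chain", "beta", "v_line", "v_vial", "v_r"])


# ---------------------------------------------------------------------------
# binomial logit model


def _binom_loglik(eta: np.ndarray, y: np.ndarray, n: np.ndarray) -> np.ndarray:
    # per-vial binomial log-likelihood up to a constant; stable for large |eta|
    return y * eta - n * np.logaddexp(0.0, eta)


class BinomialLogitVC(BaseEstimator):
    """Adaptive Metropolis-within-Gibbs sampler for the logit infection model.

    Per-vial infected counts are binomial with
    ``logit(p) = β + b_line + ε_vial``; the vial-level Gaussian ``ε`` absorbs
    extra-binomial (overdispersion) variance.  Effects are updated with
    coordinate random-walk Metropolis steps whose scales adapt during
    burn-in toward ~44% acceptance; variances use conjugate inverse-gamma
    updates given the effects.
    """

    def __init__(
        self,
        n_iter: int = 20000,
        burn_in: int = 5000,
        thin: int = 10,
        n_chains: int = 2,
        prior_shape: float = 0.01,
        prior_rate: float = 0.01,
        improper: bool = False,
        seed: int = 0,
    ):
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.n_chains = n_chains
        self.prior_shape = prior_shape
        self.prior_rate = prior_rate
        self.improper = improper
        self.seed = seed

    def fit(self, pheno: pd.DataFrame, trait: str | None = None) -> "BinomialLogitVC":
        df = pheno if trait is None else pheno[pheno["trait"] == trait]
        trait_name = trait or (str(df["trait"].iloc[0]) if "trait" in df.columns else "trait")
        required = {"line_id", "vial_id", "n_flies", "n_infected"}
        if not required <= set(df.columns):
            raise ValueError(f"binomial phenotype table needs columns {sorted(required)}")
        y = df["n_infected"].to_numpy(dtype=float)
        n = df["n_flies"].to_numpy(dtype=float)
        if (y < 0).any() or (y > n).any():
            raise ValueError("infected counts must lie in [0, n_flies]")
        line, line_ids = pd.factorize(df["line_id"])
        n_l = line.max() + 1
        if n_l < 2:
            raise ValueError("V_line inestimable: need >= 2 lines for a between-line contrast")
        warns: list[str] = []
        if y.sum() == 0 or y.sum() == n.sum():
            warns.append("all vials entirely infected or entirely uninfected: beta poorly identified")
        a0, b0 = (0.0, 0.0) if self.improper else (self.prior_shape, self.prior_rate)
        all_draws = []
        for chain in range(self.n_chains):
            rng = np.random.default_rng((self.seed, chain))
            all_draws.append(self._run_chain(rng, y, n, line, a0, b0, chain))
        draws = pd.concat(all_draws, ignore_index=True)
        draws["v_vial"] = 0.0
        self.components_ = VarianceComponents(trait_name, LOGIT, draws, warns)
        self.line_ids_ = list(line_ids)
        for w in warns:
            _warnings.warn(w)
        return self

    def _run_chain(self, rng, y, n, line, a0, b0, chain):
        n_vials = y.size
        n_l = line.max() + 1
        p0 = np.clip((y.sum() + 0.5) / (n.sum() + 1.0), 1e-6, 1 - 1e-6)
        beta = float(np.log(p0 / (1 - p0)))
        b = np.zeros(n_l)
        e = np.zeros(n_vials)
        v_line, v_od = 1.0, 1.0
        s_b = np.full(n_l, 0.5)
        s_e = np.full(n_vials, 0.8)
        s_beta = 0.3
        acc_b = np.zeros(n_l)
        acc_e = np.zeros(n_vials)
        acc_beta = 0.0
        out = []
        adapt_every = 50
        for it in range(self.n_iter):
            eta = beta + b[line] + e
            ll_vial = _binom_loglik(eta, y, n)
            # line effects, independent blocks given beta and e
            prop = b + s_b * rng.standard_normal(n_l)
            eta_p = beta + prop[line] + e
            d_ll = np.bincount(line, weights=_binom_loglik(eta_p, y, n) - ll_vial, minlength=n_l)
            d_ll += (b**2 - prop**2) / (2 * v_line)
            accept = np.log(rng.random(n_l)) < d_ll
            b = np.where(accept, prop, b)
            acc_b += accept
            # vial overdispersion deviations, independent per vial
            eta = beta + b[line] + e
            ll_vial = _binom_loglik(eta, y, n)
            prop = e + s_e * rng.standard_normal(n_vials)
            d_ll = _binom_loglik(eta - e + prop, y, n) - ll_vial
            d_ll += (e**2 - prop**2) / (2 * v_od)
            accept = np.log(rng.random(n_vials)) < d_ll
            e = np.where(accept, prop, e)
            acc_e += accept
            # grand mean, flat prior
            eta = beta + b[line] + e
            prop_beta = beta + s_beta * rng.standard_normal()
            d = _binom_loglik(eta - beta + prop_beta, y, n).sum() - _binom_loglik(eta, y, n).sum()
            if np.log(rng.random()) < d:
                beta = float(prop_beta)
                acc_beta += 1
            # conjugate variance updates
            v_line = _inv_gamma_draw(rng, a0 + n_l / 2, b0 + 0.5 * np.sum(b**2))
            v_od = _inv_gamma_draw(rng, a0 + n_vials / 2, b0 + 0.5 * np.sum(e**2))
            if it < self.burn_in and (it + 1) % adapt_every == 0:
                step = min(0.1, 1.0 / np.sqrt((it + 1) / adapt_every))
                s_b *= np.exp(step * np.where(acc_b / adapt_every > 0.44, 1.0, -1.0))
                s_e *= np.exp(step * np.where(acc_e / adapt_every > 0.44, 1.0, -1.0))
                s_beta *= np.exp(step * (1.0 if acc_beta / adapt_every > 0.44 else -1.0))
                acc_b[:] = 0
                acc_e[:] = 0
                acc_beta = 0.0
            if it >= self.burn_in and (it - self.burn_in) % self.thin == 0:
                out.append((chain, beta, v_line, v_od))
        return pd.DataFrame(out, columns=["chain", "beta", "v_line", "v_r"])


# ---------------------------------------------------------------------------
# multivariate binary model


class MultiTraitBinaryVC(BaseEstimator):
    """Multivariate logit model for genetic covariances across traits.

    All traits are reduced to per-vial infected (or dead-by-day) counts;
    each line carries a vector of effects, one per trait, drawn from a
    multivariate normal whose covariance matrix gets an inverse-Wishart
    update.  Trait-specific vial-level deviations capture overdispersion.
    Survival traits must be binarized (dead/alive at a single day) before
    fitting; see :func:`binarize_survival`.
    """

    def __init__(
        self,
        n_iter: int = 20000,
        burn_in: int = 5000,
        thin: int = 10,
        n_chains: int = 2,
        prior_df: float | None = None,
        prior_scale: float = 0.1,
        prior_shape: float = 0.01,
        prior_rate: float = 0.01,
        seed: int = 0,
    ):
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.n_chains = n_chains
        self.prior_df = prior_df
        self.prior_scale = prior_scale
        self.prior_shape = prior_shape
        self.prior_rate = prior_rate
        self.seed = seed

    def fit(self, pheno: pd.DataFrame) -> "MultiTraitBinaryVC":
        required = {"line_id", "trait", "vial_id", "n_flies", "n_infected"}
        if not required <= set(pheno.columns):
            raise ValueError(f"multivariate fit needs columns {sorted(required)}")
        traits = sorted(pheno["trait"].unique())
        T = len(traits)
        if T < 2:
            raise ValueError("need >= 2 traits for a covariance matrix")
        line_sets = {t: set(pheno.loc[pheno.trait == t, "line_id"]) for t in traits}
        for i in range(T):
            for j in range(i + 1, T):
                if not (line_sets[traits[i]] & line_sets[traits[j]]):
                    raise ValueError(
                        f"traits {traits[i]!r} and {traits[j]!r} share no lines; covariance inestimable"
                    )
        df = pheno.reset_index(drop=True)
        y = df["n_infected"].to_numpy(dtype=float)
        n = df["n_flies"].to_numpy(dtype=float)
        line, line_ids = pd.factorize(df["line_id"])
        trait_idx = df["trait"].map({t: i for i, t in enumerate(traits)}).to_numpy()
        all_cov, all_resid, all_beta, all_chain = [], [], [], []
        for chain in range(self.n_chains):
            rng = np.random.default_rng((self.seed, chain))
            cov_d, res_d, beta_d = self._run_chain(rng, y, n, line, trait_idx, T)
            all_cov.append(cov_d)
            all_resid.append(res_d)
            all_beta.append(beta_d)
            all_chain.append(np.full(len(cov_d), chain))
        self.cov_ = GeneticCovMatrix(
            traits,
            np.concatenate(all_cov),
            np.concatenate(all_resid),
            np.concatenate(all_beta),
            np.concatenate(all_chain),
        )
        self.line_ids_ = list(line_ids)
        return self

    def _run_chain(self, rng, y, n, line, trait_idx, T):
        n_vials = y.size
        n_l = line.max() + 1
        nu0 = self.prior_df if self.prior_df is not None else T + 1.0
        S0 = np.eye(T) * self.prior_scale
        a0, b0 = self.prior_shape, self.prior_rate
        # cell index for (line, trait) blocks
        cell = line * T + trait_idx
        beta = np.zeros(T)
        for t in range(T):
            m = trait_idx == t
            p0 = np.clip((y[m].sum() + 0.5) / (n[m].sum() + 1.0), 1e-6, 1 - 1e-6)
            beta[t] = np.log(p0 / (1 - p0))
        B = np.zeros((n_l, T))
        e = np.zeros(n_vials)
        Sigma = np.eye(T)
        sig2 = np.ones(T)
        s_B = np.full((n_l, T), 0.5)
        s_e = np.full(n_vials, 0.8)
        s_beta = np.full(T, 0.2)
        acc_B = np.zeros((n_l, T))
        acc_e = np.zeros(n_vials)
        acc_beta = np.zeros(T)
        n_per_trait_vials = np.bincount(trait_idx, minlength=T).astype(float)
        cov_out, resid_out, beta_out = [], [], []
        adapt_every = 50
        for it in range(self.n_iter):
            Lam = np.linalg.inv(Sigma)
            # line-effect matrix, one trait column at a time (conditional MVN prior)
            for t in range(T):
                idx = np.delete(np.arange(T), t)
                cond_var = 1.0 / Lam[t, t]
                cond_mean = -(B[:, idx] @ Lam[idx, t]) * cond_var
                m = trait_idx == t
                eta_m = beta[t] + B[line[m], t] + e[m]
                ll = _binom_loglik(eta_m, y[m], n[m])
                prop = B[:, t] + s_B[:, t] * rng.standard_normal(n_l)
                eta_p = eta_m - B[line[m], t] + prop[line[m]]
                d_ll = np.bincount(line[m], weights=_binom_loglik(eta_p, y[m], n[m]) - ll, minlength=n_l)
                d_ll += ((B[:, t] - cond_mean) ** 2 - (prop - cond_mean) ** 2) / (2 * cond_var)
                accept = np.log(rng.random(n_l)) < d_ll
                B[:, t] = np.where(accept, prop, B[:, t])
                acc_B[:, t] += accept
            # vial deviations
            eta = beta[trait_idx] + B[line, trait_idx] + e
            ll = _binom_loglik(eta, y, n)
            prop = e + s_e * rng.standard_normal(n_vials)
            d_ll = _binom_loglik(eta - e + prop, y, n) - ll
            d_ll += (e**2 - prop**2) / (2 * sig2[trait_idx])
            accept = np.log(rng.random(n_vials)) < d_ll
            e = np.where(accept, prop, e)
            acc_e += accept
            # trait means
            eta = beta[trait_idx] + B[line, trait_idx] + e
            prop_beta = beta + s_beta * rng.standard_normal(T)
            eta_p = eta - beta[trait_idx] + prop_beta[trait_idx]
            d_ll_t = np.bincount(trait_idx, weights=_binom_loglik(eta_p, y, n) - _binom_loglik(eta, y, n), minlength=T)
            accept_t = np.log(rng.random(T)) < d_ll_t
            beta = np.where(accept_t, prop_beta, beta)
            acc_beta += accept_t
            # covariance matrix (conjugate inverse-Wishart) and overdispersion variances
            Sigma = stats.invwishart.rvs(df=nu0 + n_l, scale=S0 + B.T @ B, random_state=rng)
            Sigma = np.atleast_2d(Sigma)
            ssq = np.bincount(trait_idx, weights=e**2, minlength=T)
            for t in range(T):
                sig2[t] = _inv_gamma_draw(rng, a0 + n_per_trait_vials[t] / 2, b0 + 0.5 * ssq[t])
            if it < self.burn_in and (it + 1) % adapt_every == 0:
                step = min(0.1, 1.0 / np.sqrt((it + 1) / adapt_every))
                s_B *= np.exp(step * np.where(acc_B / adapt_every > 0.44, 1.0, -1.0))
                s_e *= np.exp(step * np.where(acc_e / adapt_every > 0.44, 1.0, -1.0))
                s_beta *= np.exp(step * np.where(acc_beta / adapt_every > 0.44, 1.0, -1.0))
                acc_B[:] = 0
                acc_e[:] = 0
                acc_beta[:] = 0
            if it >= self.burn_in and (it - self.burn_in) % self.thin == 0:
                cov_out.append(Sigma.copy())
                resid_out.append(sig2.copy())
                beta_out.append(beta.copy())
        return np.array(cov_out), np.array(resid_out), np.array(beta_out)


def binarize_survival(pheno: pd.DataFrame, day: float | None = None) -> pd.DataFrame:
    """Collapse per-fly survival times to per-vial dead/alive counts at one day.

    ``day=None`` picks the observation day at which pooled mortality is
    nearest 50%, maximizing the information in the binary split.
    """
    values = pheno["value"].to_numpy(dtype=float)
    if day is None:
        days = np.unique(np.ceil(values))
        frac_dead = [(values <= d).mean() for d in days]
        day = float(days[int(np.argmin(np.abs(np.asarray(frac_dead) - 0.5)))])
    grouped = pheno.groupby(["line_id", "trait", "vial_id"], sort=False)["value"]
    out = grouped.agg(n_flies="size", n_infected=lambda v: int((v <= day).sum())).reset_index()
    out.attrs["binarization_day"] = day
    return out


# ---------------------------------------------------------------------------
# derived quantities


def heritability(vc: VarianceComponents) -> PosteriorSummary:
    """Per-draw heritability on the fit's scale.

    Observed scale: h² = V_g/(V_g + V_vial + V_r).  Logit scale:
    h² = V_g/(V_g + V_r + π²/3) with π²/3 the logistic-link residual.
    """
    vg = vc.v_g_draws
    if vc.scale == OBSERVED:
        denom = vg + vc.draws["v_vial"].to_numpy() + vc.draws["v_r"].to_numpy()
    else:
        denom = vg + vc.draws["v_r"].to_numpy() + LOGIT_RESID
    with np.errstate(invalid="ignore"):
        h2 = np.where(denom > 0, vg / np.where(denom > 0, denom, 1.0), 0.0)
    return PosteriorSummary("h2", h2)


def cvg(vc: VarianceComponents) -> PosteriorSummary:
    """Coefficient of genetic variation, 100·√V_g/β, observed scale only."""
    if vc.scale != OBSERVED:
        raise ValueError("CV_g is not defined for traits analysed on a logit scale")
    beta = vc.draws["beta"].to_numpy()
    if np.mean(beta) <= 0:
        raise ValueError("CV_g requires a positive trait mean")
    return PosteriorSummary("cvg", 100.0 * np.sqrt(vc.v_g_draws) / beta)


def genetic_correlation(cov: GeneticCovMatrix, trait_i: str, trait_j: str) -> PosteriorSummary:
    """Posterior of r = cov_ij/√(cov_ii·cov_jj) with an MCMC p-value.

    The p-value is 2·min(P(r>0), P(r<0)) over the draws, floored at one
    over the number of draws; draws with a zero variance are excluded and
    counted in ``n_excluded``.
    """
    i, j = cov.index_of(trait_i), cov.index_of(trait_j)
    vii = cov.cov_draws[:, i, i]
    vjj = cov.cov_draws[:, j, j]
    ok = (vii > 0) & (vjj > 0)
    r = cov.cov_draws[ok, i, j] / np.sqrt(vii[ok] * vjj[ok])
    summ = PosteriorSummary(f"r({trait_i},{trait_j})", r, n_excluded=int((~ok).sum()))
    n = r.size
    p = 2.0 * min((r > 0).mean(), (r < 0).mean())
    summ.mcmc_p = max(p, 1.0 / n)
    return summ


def moments_nested_anova(pheno: pd.DataFrame) -> dict:
    """Expected-mean-squares estimates of (V_line, V_vial, V_r).

    Closed-form method-of-moments decomposition of the two-level nested
    design (flies in vials in lines), valid for balanced and mildly
    unbalanced data; negative solutions are truncated at zero and flagged.
    Serves as a deterministic oracle for the MCMC fit.
    """
    y, line, vial, vial_line, _ = _gaussian_design(pheno)
    N = y.size
    n_l = line.max() + 1
    n_v = vial.max() + 1
    if n_l < 2:
        raise ValueError("nested ANOVA needs >= 2 lines")
    n_ij = np.bincount(vial, minlength=n_v).astype(float)
    N_i = np.bincount(line, minlength=n_l).astype(float)
    grand = y.mean()
    vial_means = np.bincount(vial, weights=y, minlength=n_v) / n_ij
    line_means = np.bincount(line, weights=y, minlength=n_l) / N_i
    ss_among = float(np.sum(N_i * (line_means - grand) ** 2))
    ss_vials = float(np.sum(n_ij * (vial_means - line_means[vial_line]) ** 2))
    ss_within = float(np.sum((y - vial_means[vial]) ** 2))
    df_among = n_l - 1
    df_vials = n_v - n_l
    df_within = N - n_v
    ms_within = ss_within / df_within if df_within > 0 else 0.0
    flags: list[str] = []
    sum_nij2_over_Ni = float(np.sum(np.bincount(vial_line, weights=n_ij**2, minlength=n_l) / N_i))
    if df_vials > 0:
        c1 = (N - sum_nij2_over_Ni) / df_vials
        ms_vials = ss_vials / df_vials
        v_vial = (ms_vials - ms_within) / c1
    else:
        flags.append("V_vial inestimable (one vial per line everywhere); fixed at 0")
        v_vial = 0.0
    c2 = (sum_nij2_over_Ni - float(np.sum(n_ij**2)) / N) / df_among
    c3 = (N - float(np.sum(N_i**2)) / N) / df_among
    ms_among = ss_among / df_among
    v_line = (ms_among - ms_within - c2 * v_vial) / c3
    if v_vial < 0:
        flags.append("V_vial truncated at 0")
        v_vial = 0.0
    if v_line < 0:
        flags.append("V_line truncated at 0")
        v_line = 0.0
    return {"v_line": v_line, "v_vial": v_vial, "v_r": ms_within, "flags": flags}


# ---------------------------------------------------------------------------
# thin functional wrappers


def fit_gaussian_nested(pheno: pd.DataFrame, trait: str | None = None, **config) -> VarianceComponents:
    return GaussianNestedVC(**config).fit(pheno, trait=trait).components_


def fit_binomial_logit(pheno: pd.DataFrame, trait: str | None = None, **config) -> VarianceComponents:
    return BinomialLogitVC(**config).fit(pheno, trait=trait).components_


def fit_multivariate_binary(pheno: pd.DataFrame, day: float | None = None, **config) -> GeneticCovMatrix:
    """Fit the multitrait model; Gaussian survival traits (rows with a
    ``value`` column) are binarized at ``day`` first."""
    if "value" in pheno.columns and pheno["value"].notna().any():
        gaussian = pheno[pheno["value"].notna()]
        counts = pheno.drop(gaussian.index)
        parts = [binarize_survival(gaussian, day=day)]
        if len(counts):
            parts.append(counts[["line_id", "trait", "vial_id", "n_flies", "n_infected"]])
        pheno = pd.concat(parts, ignore_index=True)
    return MultiTraitBinaryVC(**config).fit(pheno).cov_
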