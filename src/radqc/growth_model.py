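"""Hierarchical Bayesian length-at-age model.

Model
-----
For fish n in river j(n), with ``male``, ``south`` and ``contemp`` 0/1
indicators and age in years,

    length_n ~ Normal(mu_n, sigma)
    mu_n = beta0 + u0_j + beta2_j * male_n + (beta1 + u1_j) * age_n
           + beta3 * south_n + beta4 * contemp_n
           + beta5 * south_n * contemp_n

with river-level random intercepts and age slopes
``(u0_j, u1_j) ~ N2(0, Sigma)``, ``Sigma = diag(tau) R(rho) diag(tau)``
(scale x correlation decomposition), and river-level sex effects
``beta2_j ~ Normal(mu_beta2, sigma_beta2)``.

Priors are vague and data-scaled: Normal(0, (10 * SD(length))^2) on the
fixed-effect means (the age slope uses 10 * SD(length)/SD(age)),
half-Cauchy(0, 5 * SD(length)) on sigma, sigma_beta2, tau0 and tau1, and
a uniform prior on the correlation rho (the 2x2 case of a
concentration-1 correlation prior).

Sampling
--------
A blocked Gibbs sampler: all location parameters (fixed effects, river
intercept/slope deviations and river sex effects) are drawn jointly
from their multivariate-normal full conditional — the joint block is
essential because with few rivers the grand mean and slope are nearly
confounded with the river deviations and one-at-a-time updates mix
badly. The variances sigma^2 and sigma_beta2^2 have conjugate
conditionals (half-Cauchy scales via their inverse-gamma
auxiliary-variable representation); the random-effect scales tau0, tau1
and the correlation rho are updated by univariate slice sampling. Multiple chains are run from jittered
starting points and convergence is summarised with R-hat and effective
sample size (via arviz) for every reported quantity.

Derived quantities — predicted length of an age-11 fish per
location x period, the period declines, and the south-minus-north
difference in declines — are deterministic functions of the saved
draws, so they can be recomputed from a saved fit bit-for-bit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GrowthDataset

__all__ = [
    "McmcConfig",
    "GrowthFit",
    "fit",
    "predict_age11",
    "contrast_south_minus_north",
    "summarize_draws",
]


@dataclass
class McmcConfig:
    """MCMC run configuration and prior hyperparameters."""

    n_iter: int = 10_000
    n_warmup: int = 5_000
    thin: int = 10
    chains: int = 4
    seed: int = 0
    # slice-sampling sweeps of (tau0, tau1, rho) per iteration; extra
    # sweeps cut the autocorrelation these scales feed into beta0/beta3
    scale_sweeps: int = 3
    normal_sd_multiplier: float = 10.0  # vague normal prior: N(0, (m*SD(y))^2)
    cauchy_scale_multiplier: float = 5.0  # half-Cauchy(0, m*SD(y)) on scales

    def __post_init__(self) -> None:
        if self.n_warmup >= self.n_iter:
            raise ValueError("warmup must be < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.chains < 2:
            raise ValueError("need >= 2 chains for R-hat")


@dataclass
class GrowthFit:
    """Posterior draws plus the design metadata needed for predictions.

    ``draws`` maps parameter names to arrays of shape (chains, n_draws).
    River-level parameters are ``u0[river]``, ``u1[river]``,
    ``beta2[river]``.
    """

    draws: dict[str, np.ndarray]
    rivers: list[str]
    river_location: dict[str, str]
    config: McmcConfig
    prior_scales: dict[str, float]
    diagnostics: pd.DataFrame = field(default=None)

    def stacked(self, name: str) -> np.ndarray:
        """All chains concatenated, shape (chains * n_draws,)."""
        return self.draws[name].reshape(-1)

    def rivers_in(self, location: str) -> list[str]:
        rs = [r for r in self.rivers if self.river_location[r] == location]
        if not rs:
            raise ValueError(f"no rivers in location {location!r}")
        return rs


# ---------------------------------------------------------------------------
# slice sampler (Neal 2003, stepping out + shrinkage)
# ---------------------------------------------------------------------------

def _slice_update(x0, logf, rng, w=1.0, max_steps=50, lower=-np.inf, upper=np.inf):
    logy = logf(x0) - rng.exponential()
    u = rng.uniform(0.0, w)
    lo, hi = x0 - u, x0 + (w - u)
    steps = rng.integers(0, max_steps)
    j, k = steps, max_steps - 1 - steps
    while j > 0 and lo > lower and logf(lo) > logy:
        lo -= w
        j -= 1
    while k > 0 and hi < upper and logf(hi) > logy:
        hi += w
        k -= 1
    lo, hi = max(lo, lower), min(hi, upper)
    while True:
        x1 = rng.uniform(lo, hi)
        if logf(x1) > logy:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _design(data: GrowthDataset):
    t = data.table
    rivers = data.rivers
    river_idx = np.array([rivers.index(r) for r in t["river"]])
    age = t["age"].to_numpy(dtype=float)
    male = (t["sex"] == "male").to_numpy(dtype=float)
    south = (t["location"] == "south").to_numpy(dtype=float)
    contemp = (t["history"] == "contemporary").to_numpy(dtype=float)
    y = t["length"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(age), age, south, contemp, south * contemp])
    return y, X, age, male, river_idx, rivers


def fit(data: GrowthDataset, config: McmcConfig | None = None) -> GrowthFit:
    """Sample the posterior of the length-at-age model.

    Requires at least two rivers and both locations and periods
    represented. Convergence failures (R-hat or ESS beyond the usual
    gates) produce a warning, never an error.
    """
    config = config or McmcConfig()
    t = data.table
    if len(data.rivers) < 2:
        raise ValueError("need >= 2 rivers")
    for col, levels in (("location", {"north", "south"}),
                        ("history", {"historical", "contemporary"})):
        present = set(t[col])
        if present != levels:
            raise ValueError(f"{col} must have both levels, found {sorted(present)}")

    y, X, age, male, river_idx, rivers = _design(data)
    n = y.size
    J = len(rivers)
    sd_y = float(y.std(ddof=0))
    sd_age = float(age.std(ddof=0)) or 1.0

    s_beta = config.normal_sd_multiplier * sd_y
    prior_sd = np.array([s_beta, s_beta / sd_age, s_beta, s_beta, s_beta])
    A = config.cauchy_scale_multiplier * sd_y
    prior_scales = {
        "normal_sd_intercepts": s_beta,
        "normal_sd_age_slope": s_beta / sd_age,
        "half_cauchy_scale": A,
    }

    # joint design for all location parameters:
    # [beta (5) | u0 (J) | u1 (J) | beta2 (J)]
    ind = np.zeros((n, J))
    ind[np.arange(n), river_idx] = 1.0
    W = np.hstack([X, ind, ind * age[:, None], ind * male[:, None]])

    kept = (config.n_iter - config.n_warmup) // config.thin
    names = (
        ["beta0", "beta1", "beta3", "beta4", "beta5",
         "mu_beta2", "sigma_beta2", "tau0", "tau1", "rho", "sigma"]
        + [f"u0[{r}]" for r in rivers]
        + [f"u1[{r}]" for r in rivers]
        + [f"beta2[{r}]" for r in rivers]
    )
    out = {nm: np.empty((config.chains, kept)) for nm in names}

    for chain in range(config.chains):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, chain]))
        _run_chain(
            rng, chain, out, config,
            y, W, age, rivers,
            prior_sd, A, sd_y,
        )

    fit_obj = GrowthFit(
        draws=out,
        rivers=rivers,
        river_location={
            r: t.loc[t["river"] == r, "location"].iloc[0] for r in rivers
        },
        config=config,
        prior_scales=prior_scales,
    )
    fit_obj.diagnostics = _diagnostics(fit_obj)
    bad = fit_obj.diagnostics.query("rhat > 1.01 or ess < 1000")
    if len(bad):
        warnings.warn(
            "convergence gates not met for: " + ", ".join(bad.index), RuntimeWarning
        )
    return fit_obj


def _run_chain(
    rng, chain, out, config,
    y, W, age, rivers,
    prior_sd, A, sd_y,
):
    n = y.size
    J = len(rivers)
    p = 5 + 3 * J
    WtW = W.T @ W
    Wty = W.T @ y
    sl_u0 = slice(5, 5 + J)
    sl_u1 = slice(5 + J, 5 + 2 * J)
    sl_b2 = slice(5 + 2 * J, p)

    # jittered data-driven start
    theta = np.zeros(p)
    b1_init = float(np.cov(age, y)[0, 1] / np.var(age))
    theta[0] = y.mean() - b1_init * age.mean()
    theta[1] = b1_init
    theta += rng.normal(0, 0.05 * sd_y, size=p)
    mu_b2 = 0.0
    sigma2 = float(np.var(y)) * math.exp(rng.normal(0, 0.2))
    sigma_b2_sq = (0.1 * sd_y) ** 2
    tau0, tau1, rho = 0.1 * sd_y, 0.1 * sd_y / max(age.std(), 1.0), 0.0
    aux_s = aux_b2 = 1.0

    prior_prec_fixed = 1.0 / prior_sd**2
    kept_i = 0
    for it in range(config.n_iter):
        # --- all location parameters, one joint Gaussian block ------------
        # prior precision: diag for fixed effects and beta2, coupled 2x2
        # blocks (Sigma^-1) for each river's (u0, u1)
        det = tau0**2 * tau1**2 * (1 - rho**2)
        Sinv00 = tau1**2 / det
        Sinv11 = tau0**2 / det
        Sinv01 = -rho * tau0 * tau1 / det
        prec = WtW / sigma2
        idx = np.arange(p)
        prec[idx[:5], idx[:5]] += prior_prec_fixed
        prec[idx[sl_u0], idx[sl_u0]] += Sinv00
        prec[idx[sl_u1], idx[sl_u1]] += Sinv11
        prec[idx[sl_u0], idx[sl_u1]] += Sinv01
        prec[idx[sl_u1], idx[sl_u0]] += Sinv01
        prec[idx[sl_b2], idx[sl_b2]] += 1.0 / sigma_b2_sq
        rhs = Wty / sigma2
        rhs[sl_b2] += mu_b2 / sigma_b2_sq
        L = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, rhs)
        theta = mean + np.linalg.solve(L.T, rng.standard_normal(p))
        beta = theta[:5]
        u0 = theta[sl_u0]
        u1 = theta[sl_u1]
        beta2 = theta[sl_b2]

        # --- sex-effect hyperparameters ----------------------------------
        prec_mu = J / sigma_b2_sq + 1.0 / (prior_sd[0] ** 2)
        mean_mu = (beta2.sum() / sigma_b2_sq) / prec_mu
        mu_b2 = mean_mu + rng.standard_normal() / math.sqrt(prec_mu)
        ss_b2 = float(((beta2 - mu_b2) ** 2).sum())
        sigma_b2_sq = 1.0 / rng.gamma((J + 1) / 2.0, 1.0 / (ss_b2 / 2.0 + 1.0 / aux_b2))
        aux_b2 = 1.0 / rng.gamma(1.0, 1.0 / (1.0 / A**2 + 1.0 / sigma_b2_sq))

        # --- residual variance -------------------------------------------
        resid = y - W @ theta
        ssr = float(resid @ resid)
        sigma2 = 1.0 / rng.gamma((n + 1) / 2.0, 1.0 / (ssr / 2.0 + 1.0 / aux_s))
        aux_s = 1.0 / rng.gamma(1.0, 1.0 / (1.0 / A**2 + 1.0 / sigma2))

        # --- random-effect scales and correlation (slice) ----------------
        s00 = float(u0 @ u0)
        s11 = float(u1 @ u1)
        s01 = float(u0 @ u1)

        def log_bvn(t0, t1, rh):
            omr = 1.0 - rh * rh
            if omr <= 0 or t0 <= 0 or t1 <= 0:
                return -np.inf
            quad = s00 / t0**2 - 2 * rh * s01 / (t0 * t1) + s11 / t1**2
            return (
                -J * (math.log(t0) + math.log(t1) + 0.5 * math.log(omr))
                - quad / (2 * omr)
            )

        # tau's sampled on the log scale (Jacobian: +x); half-Cauchy prior
        def logf_t0(x):
            t0 = math.exp(x)
            return log_bvn(t0, tau1, rho) - math.log1p((t0 / A) ** 2) + x

        def logf_t1(x):
            t1 = math.exp(x)
            return log_bvn(tau0, t1, rho) - math.log1p((t1 / A) ** 2) + x

        for _ in range(config.scale_sweeps):
            tau0 = math.exp(_slice_update(math.log(tau0), logf_t0, rng, w=1.0))
            tau1 = math.exp(_slice_update(math.log(tau1), logf_t1, rng, w=1.0))
            rho = _slice_update(
                rho, lambda rh: log_bvn(tau0, tau1, rh), rng,
                w=0.5, lower=-0.999, upper=0.999,
            )

        # --- record -------------------------------------------------------
        if it >= config.n_warmup and (it - config.n_warmup) % config.thin == 0:
            row = kept_i
            kept_i += 1
            out["beta0"][chain, row] = beta[0]
            out["beta1"][chain, row] = beta[1]
            out["beta3"][chain, row] = beta[2]
            out["beta4"][chain, row] = beta[3]
            out["beta5"][chain, row] = beta[4]
            out["mu_beta2"][chain, row] = mu_b2
            out["sigma_beta2"][chain, row] = math.sqrt(sigma_b2_sq)
            out["tau0"][chain, row] = tau0
            out["tau1"][chain, row] = tau1
            out["rho"][chain, row] = rho
            out["sigma"][chain, row] = math.sqrt(sigma2)
            for jj, r in enumerate(rivers):
                out[f"u0[{r}]"][chain, row] = u0[jj]
                out[f"u1[{r}]"][chain, row] = u1[jj]
                out[f"beta2[{r}]"][chain, row] = beta2[jj]


# ---------------------------------------------------------------------------
# diagnostics and summaries
# ---------------------------------------------------------------------------

def _diagnostics(fit_obj: GrowthFit) -> pd.DataFrame:
    import arviz as az

    idata = az.from_dict(posterior={k: v for k, v in fit_obj.draws.items()})
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    rows = {
        k: {"rhat": float(rhat[k].values), "ess": float(ess[k].values)}
        for k in fit_obj.draws
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def summarize_draws(draws: np.ndarray, ci: float = 0.95) -> dict:
    """Posterior mean, central credible interval and P(draw < 0)."""
    flat = np.asarray(draws).reshape(-1)
    lo, hi = np.quantile(flat, [(1 - ci) / 2, 1 - (1 - ci) / 2])
    return {
        "mean": float(flat.mean()),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "p_below_zero": float((flat < 0).mean()),
    }


def posterior_summary(fit_obj: GrowthFit, ci: float = 0.95) -> pd.DataFrame:
    """Summary table (mean, CI, R-hat, ESS) for every sampled parameter."""
    rows = {}
    for name, d in fit_obj.draws.items():
        s = summarize_draws(d, ci)
        rows[name] = {
            "mean": s["mean"],
            "ci_low": s["ci_low"],
            "ci_high": s["ci_high"],
            "rhat": fit_obj.diagnostics.loc[name, "rhat"],
            "ess": fit_obj.diagnostics.loc[name, "ess"],
        }
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

def predict_age11(
    fit_obj: GrowthFit,
    location: str,
    history: str,
    age: float = 11.0,
    sex_mix: float = 0.5,
) -> np.ndarray:
    """Posterior draws of the predicted length (mm) of an age-``age`` fish.

    The prediction averages the random intercepts and slopes over the
    rivers of the location and mixes sexes at ``sex_mix`` (fraction
    male). Returns a flat array of draws.
    """
    south = 1.0 if location == "south" else 0.0
    contemp = 1.0 if history == "contemporary" else 0.0
    rs = fit_obj.rivers_in(location)
    u0 = np.mean([fit_obj.stacked(f"u0[{r}]") for r in rs], axis=0)
    u1 = np.mean([fit_obj.stacked(f"u1[{r}]") for r in rs], axis=0)
    return (
        fit_obj.stacked("beta0")
        + u0
        + (fit_obj.stacked("beta1") + u1) * age
        + fit_obj.stacked("beta3") * south
        + fit_obj.stacked("beta4") * contemp
        + fit_obj.stacked("beta5") * south * contemp
        + fit_obj.stacked("mu_beta2") * sex_mix
    )


def decline(fit_obj: GrowthFit, location: str, **kw) -> np.ndarray:
    """Draws of the historical-minus-contemporary drop in predicted length."""
    return predict_age11(fit_obj, location, "historical", **kw) - predict_age11(
        fit_obj, location, "contemporary", **kw
    )


def contrast_south_minus_north(fit_obj: GrowthFit, **kw) -> dict:
    """South-minus-north difference in period declines (mm).

    Positive values mean the south shrank more than the north. Returns
    the summary dict plus the raw draws under ``"draws"``.
    """
    diff = decline(fit_obj, "south", **kw) - decline(fit_obj, "north", **kw)
    s = summarize_draws(diff)
    s["draws"] = diff
    return s
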