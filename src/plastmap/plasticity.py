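"""Reaction-norm decomposition of multi-environment phenotypes.

The Finlay-Wilkinson regression (FWR)

    y_ij = mu + g_i + (1 + b_i) * h_j + eps_ij

splits each accession's multi-environment record into three heritable
sub-phenotypes: the *mean* (g_i), the *linear plasticity* (the slope
1 + b_i of the accession's regression on the environment effect h_j), and
the *nonlinear plasticity* (the natural log of the accession's residual
variance around its own regression line — departure from a straight-line
environmental response).

Two estimators are provided: a fast two-step least-squares fit and a Gibbs
sampler for the Bayesian FWR with independent (identity-covariance) normal
priors on g and b, i.e. no pedigree or kinship structure in the priors.
Dispersion summaries (coefficient of variation, quartile coefficient of
dispersion) used as population-level plasticity indicators live here too.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "PlasticityDecomposition",
    "fit_fw_ls",
    "fit_fw_gibbs",
    "coefficient_of_variation",
    "quartile_coefficient_of_dispersion",
    "trait_summary",
]


@dataclass
class PlasticityDecomposition:
    """Result of an FWR fit for one trait.

    ``accessions`` indexes all per-accession vectors. Accessions whose slope
    is inestimable (observed in < 2 environments, or all their h values
    coincide) carry NaN and are listed in ``flagged``.
    """

    trait: str
    method: str  # "LS" or "Gibbs"
    mu: float
    accessions: list[str]
    g: np.ndarray                   # accession main effect (mean)
    linear_plasticity: np.ndarray   # slope 1 + b_i
    nonlinear_plasticity: np.ndarray  # ln residual variance
    environments: list[str]
    h: np.ndarray                   # environment effects, sum to 0
    flagged: list[str] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    @property
    def mean_phenotype(self) -> np.ndarray:
        """mu + g_i — the accession mean on the original trait scale."""
        return self.mu + self.g

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "accession": self.accessions,
                "trait": self.trait,
                "mean_effect": self.g,
                "mean_phenotype": self.mean_phenotype,
                "linear_plasticity": self.linear_plasticity,
                "nonlinear_plasticity": self.nonlinear_plasticity,
            }
        )


def _pivot(pheno: pd.DataFrame, trait: str) -> pd.DataFrame:
    sub = pheno[pheno["trait"] == trait]
    if sub.empty:
        raise ValueError(f"no records for trait {trait!r}")
    wide = sub.pivot(index="accession", columns="environment", values="value")
    if wide.shape[1] < 2:
        raise ValueError(
            f"trait {trait!r} observed in {wide.shape[1]} environment(s); "
            "at least 2 are required"
        )
    return wide


def fit_fw_ls(pheno: pd.DataFrame, trait: str) -> PlasticityDecomposition:
    """Two-step least-squares Finlay-Wilkinson fit.

    Step 1 estimates h_j as the environment mean minus the grand mean;
    step 2 regresses each accession's phenotypes on h_j, giving intercept
    mu + g_i and slope 1 + b_i; the accession's residual variance (divisor
    n_i - 2) is log-transformed into nonlinear plasticity. With >= 3
    observed environments the residual variance is well-defined; with
    exactly 2 the line interpolates and it is 0 (log -> -inf), reported
    as NaN.
    """
    wide = _pivot(pheno, trait)
    env_ids = list(wide.columns)
    acc_ids = list(wide.index)
    Y = wide.to_numpy()

    mu = float(np.nanmean(Y))
    h = np.nanmean(Y, axis=0) - mu
    h = h - h.mean()

    n_acc = len(acc_ids)
    g = np.full(n_acc, np.nan)
    slope = np.full(n_acc, np.nan)
    nlp = np.full(n_acc, np.nan)
    flagged: list[str] = []

    for i in range(n_acc):
        obs = ~np.isnan(Y[i])
        if obs.sum() < 2 or np.ptp(h[obs]) == 0:
            flagged.append(acc_ids[i])
            continue
        hi, yi = h[obs], Y[i, obs]
        b1, b0 = np.polyfit(hi, yi, 1)
        g[i] = b0 - mu
        slope[i] = b1
        resid = yi - (b0 + b1 * hi)
        dof = obs.sum() - 2
        if dof > 0:
            s2 = float(resid @ resid) / dof
            nlp[i] = np.log(s2) if s2 > 0 else -np.inf

    return PlasticityDecomposition(
        trait=trait, method="LS", mu=mu, accessions=acc_ids, g=g,
        linear_plasticity=slope, nonlinear_plasticity=nlp,
        environments=env_ids, h=h, flagged=flagged,
    )


def fit_fw_gibbs(
    pheno: pd.DataFrame,
    trait: str,
    n_iter: int = 2000,
    burnin: int = 500,
    seed: int = 0,
    rhat_threshold: float = 1.1,
) -> PlasticityDecomposition:
    """Gibbs sampler for the Bayesian FWR with identity prior covariances.

    Model: y_ij = mu + g_i + (1 + b_i) h_j + eps_ij with eps ~ N(0, s2),
    g ~ N(0, s2_g I), b ~ N(0, s2_b I), h ~ N(0, s2_h I) — the accessions
    and environments exchangeable a priori (no relationship matrices).
    Variance components carry scaled inverse-gamma priors anchored at the
    least-squares fit (see inline note on the b-h scale ridge). Posterior
    means of the fitted parameters are reported;
    per-accession residual variances are averaged over the kept draws and
    log-transformed. A split-chain scale-reduction diagnostic on the
    residual variance is recorded; values above ``rhat_threshold`` add a
    convergence warning to ``diagnostics``.
    """
    if n_iter <= burnin:
        raise ValueError("n_iter must exceed burnin")
    wide = _pivot(pheno, trait)
    env_ids = list(wide.columns)
    acc_ids = list(wide.index)
    Y = wide.to_numpy()
    n, m = Y.shape
    obs = ~np.isnan(Y)
    rng = substream(seed, f"fw-gibbs:{trait}")

    # start at the LS solution
    ls = fit_fw_ls(pheno, trait)
    mu = ls.mu
    g = np.nan_to_num(ls.g)
    b = np.nan_to_num(ls.linear_plasticity - 1.0)
    h = ls.h.copy()
    var_y = float(np.nanvar(Y))
    # scaled inverse-gamma priors anchored at the least-squares fit
    # (empirical Bayes): the multiplicative (1 + b_i) * h_j term leaves a
    # soft scale ridge between b and h that vague priors cannot pin down
    # on small tables, so the effect-variance rates sit at the LS scales
    # and the residual-variance prior at the pooled LS residual variance
    # (which is zero for interpolable data, concentrating the chain on the
    # exact solution).
    resid_ls = []
    for i in range(n):
        oi = obs[i]
        if oi.sum() >= 2 and np.ptp(ls.h[oi]) > 0:
            pred = (ls.mu + ls.g[i]) + ls.linear_plasticity[i] * ls.h[oi]
            resid_ls.append(Y[i, oi] - pred)
    s2_ls = float(np.mean(np.concatenate(resid_ls) ** 2)) if resid_ls else var_y
    a_eff = 2.0
    rate_g = max(float(np.var(g)), 1e-6 * var_y, 1e-10)
    rate_b = max(float(np.var(b)), 1e-4)
    rate_h = max(float(np.var(h)), 1e-6 * var_y, 1e-10)
    s2_g, s2_b, s2_h = rate_g, rate_b, rate_h
    a0 = 2.0
    b0 = a0 * s2_ls + 1e-12 * max(var_y, 1.0)
    s2 = max(s2_ls, 1e-12 * max(var_y, 1.0))

    g_sum = np.zeros(n)
    slope_sum = np.zeros(n)
    h_sum = np.zeros(m)
    mu_sum = 0.0
    resid2_sum = np.zeros(n)
    resid_n = obs.sum(axis=1)
    s2_draws = []

    n_obs_total = int(obs.sum())
    Y0 = np.where(obs, Y, 0.0)

    M = obs.astype(float)

    for it in range(n_iter):
        # joint (g_i, b_i) update: independent 2x2 normal systems, done
        # for all accessions at once via the closed-form 2x2 Cholesky
        H = np.broadcast_to(h, (n, m))
        R = np.where(obs, Y0 - mu - H, 0.0)  # target = g_i + b_i * h_j
        s11 = M.sum(axis=1) / s2 + 1.0 / s2_g
        s12 = (M * H).sum(axis=1) / s2
        s22 = (M * H * H).sum(axis=1) / s2 + 1.0 / s2_b
        t1 = R.sum(axis=1) / s2
        t2 = (R * H).sum(axis=1) / s2
        det = s11 * s22 - s12 * s12
        mg = (s22 * t1 - s12 * t2) / det
        mb = (s11 * t2 - s12 * t1) / det
        # Cholesky of the 2x2 covariance (inverse precision)
        l11 = np.sqrt(s22 / det)
        l21 = -s12 / det / l11
        l22 = np.sqrt(s11 / det - l21**2)
        z1 = rng.standard_normal(n)
        z2 = rng.standard_normal(n)
        g = mg + l11 * z1
        b = mb + l21 * z1 + l22 * z2

        # identifiability: centre g and b; mu absorbs the level shift
        b -= b.mean()
        g -= g.mean()

        # h_j update: independent scalar normals
        W = np.where(obs, (1.0 + b)[:, None], 0.0)
        Rj = np.where(obs, Y0 - mu - g[:, None], 0.0)
        prec = (W * W).sum(axis=0) / s2 + 1.0 / s2_h
        mean = (W * Rj).sum(axis=0) / s2 / prec
        h = mean + rng.standard_normal(m) / np.sqrt(prec)
        h -= h.mean()

        # mu update (flat prior)
        fitted_no_mu = g[:, None] + (1.0 + b)[:, None] * h[None, :]
        mean_mu = float((np.where(obs, Y0 - fitted_no_mu, 0.0)).sum()) / n_obs_total
        mu = mean_mu + rng.standard_normal() * np.sqrt(s2 / n_obs_total)

        # variance updates (conjugate inverse-gamma)
        resid_all = np.where(obs, Y0 - mu - fitted_no_mu, 0.0)
        sse = float((resid_all**2).sum())
        s2 = 1.0 / rng.gamma(a0 + n_obs_total / 2.0, 1.0 / (b0 + sse / 2.0))
        s2_g = 1.0 / rng.gamma(a_eff + n / 2.0,
                               1.0 / (rate_g + (g @ g) / 2.0))
        s2_b = 1.0 / rng.gamma(a_eff + n / 2.0,
                               1.0 / (rate_b + (b @ b) / 2.0))
        s2_h = 1.0 / rng.gamma(a_eff + m / 2.0,
                               1.0 / (rate_h + (h @ h) / 2.0))

        if it >= burnin:
            g_sum += g
            slope_sum += 1.0 + b
            h_sum += h
            mu_sum += mu
            resid2_sum += (resid_all**2).sum(axis=1)
            s2_draws.append(s2)

    kept = n_iter - burnin
    s2_draws = np.asarray(s2_draws)
    half = kept // 2
    rhat = _split_rhat(s2_draws[:half], s2_draws[half: 2 * half])
    diagnostics = {"rhat_residual_variance": rhat, "n_kept": kept}
    if rhat > rhat_threshold:
        msg = (f"Gibbs chain for trait {trait!r} may not have converged "
               f"(split R-hat {rhat:.3f} > {rhat_threshold})")
        warnings.warn(msg)
        diagnostics["convergence_warning"] = msg

    with np.errstate(divide="ignore"):
        mean_res_var = resid2_sum / kept / np.maximum(resid_n - 2, 1)
        nlp = np.where(mean_res_var > 0, np.log(mean_res_var), -np.inf)
    nlp = np.where(resid_n >= 3, nlp, np.nan)

    return PlasticityDecomposition(
        trait=trait, method="Gibbs", mu=mu_sum / kept, accessions=acc_ids,
        g=g_sum / kept, linear_plasticity=slope_sum / kept,
        nonlinear_plasticity=nlp, environments=env_ids, h=h_sum / kept,
        flagged=list(ls.flagged), diagnostics=diagnostics,
    )


def _split_rhat(first: np.ndarray, second: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction on two half-chains."""
    chains = np.stack([first, second])
    mcount, nlen = chains.shape
    if nlen < 2:
        return float("nan")
    means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean()
    B = nlen * means.var(ddof=1)
    if W <= 0:
        return 1.0
    var_plus = (nlen - 1) / nlen * W + B / nlen
    return float(np.sqrt(var_plus / W))


def coefficient_of_variation(values) -> float:
    """CV = sd / mean x 100, with the sample (n-1) standard deviation."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 2:
        raise ValueError("CV requires at least 2 values")
    mean = x.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(x.std(ddof=1) / mean * 100.0)


def quartile_coefficient_of_dispersion(values) -> float:
    """QCD = (Q3 - Q1) / (Q3 + Q1), quartiles by linear interpolation."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 4:
        raise ValueError("QCD requires at least 4 values")
    q1, q3 = np.percentile(x, [25, 75])
    if q1 + q3 == 0:
        raise ValueError("QCD undefined: Q1 + Q3 = 0")
    return float((q3 - q1) / (q3 + q1))


def trait_summary(pheno: pd.DataFrame, trait: str,
                  per_environment: bool = True) -> pd.DataFrame:
    """Mean, SD, CV, quartiles and QCD for one trait, per environment or pooled."""
    sub = pheno[pheno["trait"] == trait]
    if sub.empty:
        raise ValueError(f"no records for trait {trait!r}")
    groups = sub.groupby("environment") if per_environment else [("pooled", sub)]
    rows = []
    for env, grp in groups:
        x = grp["value"].to_numpy(dtype=float)
        x = x[~np.isnan(x)]
        q1, q3 = np.percentile(x, [25, 75]) if len(x) >= 4 else (np.nan, np.nan)
        rows.append(
            {
                "trait": trait,
                "environment": env,
                "n": len(x),
                "mean": x.mean(),
                "sd": x.std(ddof=1) if len(x) > 1 else np.nan,
                "cv": coefficient_of_variation(x)
                if len(x) >= 2 and x.mean() != 0 else np.nan,
                "q1": q1,
                "q3": q3,
                "qcd": (q3 - q1) / (q3 + q1)
                if len(x) >= 4 and (q1 + q3) != 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)
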