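"""Environmental drivers of plasticity.

Quantifies how much of the trait's environmental response is explained by a
measured covariate: DIFF scores (phenotype in a high-temperature reference
environment minus the phenotype elsewhere, per accession), the per-genotype
environment-response regression (phenotype on an environmental index, with
the mean per-accession R^2 summarising the covariate's contribution),
temperature-vs-trait and temperature-vs-CV Pearson correlations across
environments, seeded bootstrap resampling, and the grain-width pleiotropy
regression (simple-model R^2 as percent PVE).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream

__all__ = [
    "diff_score",
    "ppre_fit",
    "env_correlation",
    "bootstrap_resample",
    "width_effect_regression",
]


def diff_score(pheno: pd.DataFrame, trait: str, ref_env: str) -> pd.DataFrame:
    """Per-accession reference-minus-comparison phenotype differences.

    Signed differences: positive values mean the accession expressed more
    of the trait in the (high-temperature) reference environment. Returns
    columns accession, trait, ref_env, environment, diff. Accessions not
    observed in both environments of a pair are skipped.
    """
    sub = pheno[pheno["trait"] == trait]
    wide = sub.pivot(index="accession", columns="environment", values="value")
    if ref_env not in wide.columns:
        raise ValueError(f"reference environment {ref_env!r} not in data")
    rows = []
    for env in wide.columns:
        if env == ref_env:
            continue
        d = wide[ref_env] - wide[env]
        d = d.dropna()
        for acc, val in d.items():
            rows.append(
                {"accession": acc, "trait": trait, "ref_env": ref_env,
                 "environment": env, "diff": float(val)}
            )
    return pd.DataFrame(rows,
                        columns=["accession", "trait", "ref_env",
                                 "environment", "diff"])


def ppre_fit(pheno: pd.DataFrame, trait: str,
             env_index: pd.Series) -> dict:
    """Per-genotype regression of the trait on an environmental index.

    ``env_index`` maps environment id to the covariate (e.g. grain-filling
    tmean). Each accession with >= 3 indexed observations is fit by simple
    linear regression; a zero-variance response gets slope 0 and, by
    convention, R^2 = 0. Returns ``{"per_accession": DataFrame, "mean_r2":
    float}`` where mean_r2 is the arithmetic mean of per-accession R^2 —
    the summary of the covariate's contribution to plasticity.
    """
    env_index = pd.Series(env_index).dropna()
    if env_index.nunique() <= 1:
        raise ValueError("environmental index is constant; slope inestimable")
    sub = pheno[(pheno["trait"] == trait)
                & pheno["environment"].isin(env_index.index)]
    wide = sub.pivot(index="accession", columns="environment", values="value")
    x_full = env_index.loc[wide.columns].to_numpy(dtype=float)

    rows = []
    for acc, yrow in wide.iterrows():
        y = yrow.to_numpy(dtype=float)
        obs = ~np.isnan(y)
        if obs.sum() < 3:
            continue
        x, yy = x_full[obs], y[obs]
        if np.ptp(x) == 0:
            continue
        if np.ptp(yy) == 0:
            rows.append({"accession": acc, "intercept": float(yy[0]),
                         "slope": 0.0, "r2": 0.0, "n": int(obs.sum())})
            continue
        res = stats.linregress(x, yy)
        rows.append(
            {"accession": acc, "intercept": float(res.intercept),
             "slope": float(res.slope), "r2": float(res.rvalue**2),
             "n": int(obs.sum())}
        )
    per_acc = pd.DataFrame(rows,
                           columns=["accession", "intercept", "slope", "r2", "n"])
    if per_acc.empty:
        raise ValueError("no accession has >= 3 observations on the index")
    return {"per_accession": per_acc, "mean_r2": float(per_acc["r2"].mean())}


def env_correlation(
    summary: pd.DataFrame,
    env: pd.DataFrame,
    stat: str = "mean",
    temp: str = "tmax",
) -> tuple[float, float]:
    """Pearson correlation of a per-environment trait statistic vs temperature.

    ``summary`` is a per-environment table from
    :func:`plastmap.plasticity.trait_summary` (columns ``environment`` plus
    the chosen ``stat``, typically ``mean`` or ``cv``); ``temp`` selects
    tmin / tmean / tmax from the environment table. Returns (r, two-tailed
    p). Requires >= 3 environments.
    """
    if stat not in summary.columns:
        raise ValueError(f"statistic {stat!r} not in summary columns")
    if temp not in env.columns:
        raise ValueError(f"temperature series {temp!r} not in environment table")
    merged = summary.merge(env[["environment", temp]], on="environment")
    merged = merged.dropna(subset=[stat, temp])
    if len(merged) < 3:
        raise ValueError("need >= 3 environments for a correlation")
    r, p = stats.pearsonr(merged[stat], merged[temp])
    return float(r), float(p)


_STATISTICS = {
    "mean": np.mean,
    "cv": lambda x: np.std(x, ddof=1) / np.mean(x) * 100.0,
    "median": np.median,
    "sd": lambda x: np.std(x, ddof=1),
}


def bootstrap_resample(values, statistic="mean", n_boot: int = 1000,
                       seed: int = 0) -> np.ndarray:
    """``n_boot`` with-replacement resample statistics of the input.

    ``statistic`` is a name from {mean, cv, median, sd} or any callable on
    a 1-D array. Deterministic under ``seed``.
    """
    x = np.asarray(values, dtype=float)
    if len(x) == 0:
        raise ValueError("empty input")
    fn = _STATISTICS.get(statistic, statistic)
    if not callable(fn):
        raise ValueError(f"unknown statistic {statistic!r}")
    rng = substream(seed, "bootstrap")
    idx = rng.integers(0, len(x), size=(n_boot, len(x)))
    return np.array([fn(x[row]) for row in idx])


def width_effect_regression(width, chalk) -> dict:
    """Pleiotropy of grain width on a chalkiness component.

    Simple regression of the chalkiness values on the width values over
    paired accessions; returns the slope and the model R^2 expressed in
    percent (the PVE of width for that component). Applies equally to
    mean, linear-plasticity or nonlinear-plasticity values.
    """
    w = np.asarray(width, dtype=float)
    c = np.asarray(chalk, dtype=float)
    if w.shape != c.shape:
        raise ValueError("width and chalkiness vectors differ in length")
    obs = ~(np.isnan(w) | np.isnan(c))
    w, c = w[obs], c[obs]
    if len(w) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(w) == 0:
        raise ValueError("zero-variance predictor")
    res = stats.linregress(w, c)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "pve_percent": float(res.rvalue**2 * 100.0),
        "p": float(res.pvalue),
        "n": int(len(w)),
    }
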