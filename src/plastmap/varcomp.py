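"""Crossed random-effects decomposition of multi-environment phenotypes.

Fits the linear mixed model

    y ~ mu + (1|Line) + (1|Env) + (1|Line:Env) + e

by EM-REML on Henderson's mixed-model equations, tests each random term by
a REML likelihood-ratio test against the boundary-corrected null, computes
broad-sense heritability as

    H2 = Vg / (Vg + VE + VGE/m + Ve/(n*m))

with m environments and n individuals, and predicts per-accession BLUPs of
the Line effect for downstream marker selection.

With a single observation per Line x Env cell the interaction and residual
variances are confounded; the model then drops the explicit interaction
term and reports their sum as VGE (with Ve = 0 and ``confounded=True``).
The synthetic generator can produce replicated cells to separate them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "VarianceComponents",
    "fit_gxe_variance_components",
    "lrt_random_effect",
    "broad_sense_heritability",
    "blup_genotype_effects",
    "anova_moments",
]

_FLOOR_FRAC = 1e-8  # variance floor, as a fraction of total phenotype variance


@dataclass
class VarianceComponents:
    Vg: float
    VE: float
    VGE: float
    Ve: float
    m: int                # number of environments
    n: int                # number of accessions
    H2: float
    lrt_p: dict = field(default_factory=dict)
    confounded: bool = False  # True when VGE holds the combined VGE+Ve
    loglik: float = float("nan")
    converged: bool = True
    n_iter: int = 0


class _Design:
    """Dense design matrices and bookkeeping for the crossed model."""

    def __init__(self, pheno: pd.DataFrame, trait: str):
        sub = pheno[pheno["trait"] == trait].dropna(subset=["value"])
        if sub.empty:
            raise ValueError(f"no records for trait {trait!r}")
        self.lines = sorted(sub["accession"].unique())
        self.envs = sorted(sub["environment"].unique())
        if len(self.lines) < 2 or len(self.envs) < 2:
            raise ValueError("need >= 2 accessions and >= 2 environments")
        li = sub["accession"].map({a: i for i, a in enumerate(self.lines)})
        ei = sub["environment"].map({e: j for j, e in enumerate(self.envs)})
        self.y = sub["value"].to_numpy(dtype=float)
        self.line_idx = li.to_numpy()
        self.env_idx = ei.to_numpy()
        nl, ne = len(self.lines), len(self.envs)
        counts = np.zeros((nl, ne), dtype=int)
        np.add.at(counts, (self.line_idx, self.env_idx), 1)
        self.cell_counts = counts
        self.replicated = counts.max() > 1
        self.balanced = counts.min() == counts.max() and counts.min() >= 1

    def z_blocks(self, terms: tuple[str, ...]) -> tuple[np.ndarray, list[int]]:
        nobs = len(self.y)
        cols = []
        sizes = []
        for t in terms:
            if t == "Line":
                q = len(self.lines)
                Z = np.zeros((nobs, q))
                Z[np.arange(nobs), self.line_idx] = 1.0
            elif t == "Env":
                q = len(self.envs)
                Z = np.zeros((nobs, q))
                Z[np.arange(nobs), self.env_idx] = 1.0
            elif t == "Line:Env":
                ne = len(self.envs)
                cell = self.line_idx * ne + self.env_idx
                used = np.unique(cell)
                remap = {c: k for k, c in enumerate(used)}
                q = len(used)
                Z = np.zeros((nobs, q))
                Z[np.arange(nobs), [remap[c] for c in cell]] = 1.0
            else:
                raise ValueError(f"unknown term {t!r}")
            cols.append(Z)
            sizes.append(q)
        return np.hstack(cols) if cols else np.zeros((nobs, 0)), sizes


def _em_reml(y, Z, sizes, start, tol=1e-8, max_iter=5000):
    """EM-REML for y = 1*mu + sum_k Z_k u_k + e via the MME.

    ``start`` is (sigma2_components..., sigma2_e). Variances are floored at
    a small fraction of the phenotype variance rather than removed, so the
    model dimension is stable across iterations. Aitken extrapolation is
    attempted every few sweeps and kept only when it improves the REML
    log-likelihood.
    """
    nobs = len(y)
    q = Z.shape[1]
    p = 1
    X = np.ones((nobs, 1))
    XtX = X.T @ X
    XtZ = X.T @ Z
    ZtZ = Z.T @ Z
    Xty = X.T @ y
    Zty = Z.T @ y
    yty = float(y @ y)
    floor = max(_FLOOR_FRAC * float(np.var(y)), 1e-12)

    offsets = np.concatenate([[0], np.cumsum(sizes)]).astype(int)
    k_comp = len(sizes)
    theta = np.maximum(np.asarray(start, dtype=float), floor)

    def loglik_and_solution(th):
        s2 = th[:-1]
        s2e = th[-1]
        lam = np.concatenate(
            [np.full(sz, s2e / s2[k]) for k, sz in enumerate(sizes)]
        ) if q else np.zeros(0)
        M = np.block([[XtX, XtZ], [XtZ.T, ZtZ + np.diag(lam)]])
        rhs = np.concatenate([Xty.ravel(), Zty])
        cF, low = cho_factor(M, lower=True)
        sol = cho_solve((cF, low), rhs)
        ypy = (yty - sol @ rhs) / s2e
        logdetM = 2.0 * np.sum(np.log(np.diag(cF)))
        ll = -0.5 * (
            (nobs - q - p) * np.log(s2e)
            + sum(sz * np.log(s2[k]) for k, sz in enumerate(sizes))
            + logdetM
            + ypy
            + (nobs - p) * np.log(2.0 * np.pi)
        )
        return ll, sol, (cF, low), ypy

    ll, sol, chol, _ = loglik_and_solution(theta)
    prev_theta = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        s2 = theta[:-1]
        s2e = theta[-1]
        # traces of the u_k blocks of the inverse coefficient matrix
        Minv = cho_solve(chol, np.eye(p + q))
        new = np.empty_like(theta)
        u = sol[p:]
        for k in range(k_comp):
            a, bnd = offsets[k] + p, offsets[k + 1] + p
            uk = sol[a:bnd]
            tr = np.trace(Minv[a:bnd, a:bnd])
            new[k] = (uk @ uk + s2e * tr) / sizes[k]
        resid_quad = yty - sol @ np.concatenate([Xty.ravel(), Zty])
        new[-1] = resid_quad / (nobs - p)
        new = np.maximum(new, floor)

        # Aitken extrapolation every 5 EM sweeps
        if it % 5 == 0 and prev_theta is not None:
            d1 = theta - prev_theta
            d2 = new - theta
            denom = d1 - d2
            with np.errstate(divide="ignore", invalid="ignore"):
                acc = np.where(
                    np.abs(denom) > 1e-12, theta - d1**2 / denom, new
                )
            acc = np.maximum(acc, floor)
            ll_acc, sol_acc, chol_acc, _ = loglik_and_solution(acc)
            ll_new, sol_new, chol_new, _ = loglik_and_solution(new)
            if np.isfinite(ll_acc) and ll_acc > ll_new:
                cand, ll_c, sol_c, chol_c = acc, ll_acc, sol_acc, chol_acc
            else:
                cand, ll_c, sol_c, chol_c = new, ll_new, sol_new, chol_new
        else:
            cand = new
            ll_c, sol_c, chol_c, _ = loglik_and_solution(cand)

        prev_theta = theta
        rel = abs(ll_c - ll) / (abs(ll) + 1.0)
        theta, ll, sol, chol = cand, ll_c, sol_c, chol_c
        if rel < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"EM-REML did not converge in {max_iter} iterations; "
            f"last estimates {dict(zip(range(k_comp), theta[:-1]))}, "
            f"residual {theta[-1]:.6g}"
        )
    # zero out floored components for reporting
    report = theta.copy()
    report[report <= floor * (1 + 1e-9)] = 0.0
    return report, ll, sol, it


def anova_moments(pheno: pd.DataFrame, trait: str) -> dict[str, float]:
    """Method-of-moments (expected-mean-squares) estimates on balanced data.

    Requires a complete design with a constant replicate count r; with
    r >= 2 all four components are estimable. Serves as the closed-form
    starting point (and, on balanced data, the REML solution itself when
    all estimates are interior).
    """
    d = _Design(pheno, trait)
    if not d.balanced:
        raise ValueError("method-of-moments decomposition requires balanced data")
    return _anova_from_design(d)


def _fit(design: _Design, terms: tuple[str, ...], tol=1e-8, max_iter=5000):
    Z, sizes = design.z_blocks(terms)
    vary = float(np.var(design.y))
    start = [vary / (len(terms) + 1)] * len(terms) + [vary / (len(terms) + 1)]
    # balanced complete designs: seed EM at the ANOVA moments, which are the
    # REML solution when interior
    if design.balanced:
        r = int(design.cell_counts[0, 0])
        mom = _anova_from_design(design)
        key = {"Line": "Vg", "Env": "VE", "Line:Env": "VGE"}
        resid0 = mom["Ve"] if r > 1 else mom["VGE"]
        start = [max(mom[key[t]], vary * 1e-4) for t in terms]
        start.append(max(resid0, vary * 1e-4))
    theta, ll, sol, it = _em_reml(design.y, Z, sizes, start, tol, max_iter)
    return theta, ll, sol, sizes, it


def _anova_from_design(d: _Design) -> dict[str, float]:
    nl, ne = len(d.lines), len(d.envs)
    r = int(d.cell_counts[0, 0])
    cell_sum = np.zeros((nl, ne))
    np.add.at(cell_sum, (d.line_idx, d.env_idx), d.y)
    cm = cell_sum / r
    grand = d.y.mean()
    rm = cm.mean(axis=1)
    cmn = cm.mean(axis=0)
    ms_a = ne * r * np.sum((rm - grand) ** 2) / (nl - 1)
    ms_b = nl * r * np.sum((cmn - grand) ** 2) / (ne - 1)
    inter = cm - rm[:, None] - cmn[None, :] + grand
    ms_ab = r * np.sum(inter**2) / ((nl - 1) * (ne - 1))
    if r > 1:
        fitted_cell = cm[d.line_idx, d.env_idx]
        ms_e = np.sum((d.y - fitted_cell) ** 2) / (nl * ne * (r - 1))
        return {"Vg": (ms_a - ms_ab) / (ne * r), "VE": (ms_b - ms_ab) / (nl * r),
                "VGE": (ms_ab - ms_e) / r, "Ve": ms_e}
    return {"Vg": (ms_a - ms_ab) / ne, "VE": (ms_b - ms_ab) / nl,
            "VGE": ms_ab, "Ve": 0.0}


def fit_gxe_variance_components(
    pheno: pd.DataFrame, trait: str, tol: float = 1e-8, max_iter: int = 5000
) -> VarianceComponents:
    """EM-REML estimates of Vg, VE, VGE and Ve for one trait.

    Negative updates are truncated at (effectively) zero. When the data
    carry one observation per Line x Env cell, VGE and Ve cannot be
    separated: the interaction term is dropped, the residual absorbs both,
    and the result reports their sum under VGE with ``confounded=True``.
    """
    d = _Design(pheno, trait)
    if d.replicated:
        terms = ("Line", "Env", "Line:Env")
        theta, ll, _, _, it = _fit(d, terms, tol, max_iter)
        vg, ve_env, vge, ve = theta
        confounded = False
    else:
        terms = ("Line", "Env")
        theta, ll, _, _, it = _fit(d, terms, tol, max_iter)
        vg, ve_env = theta[0], theta[1]
        vge, ve = theta[-1], 0.0  # residual = interaction + error, merged
        confounded = True
    m, n = len(d.envs), len(d.lines)
    vc = VarianceComponents(
        Vg=float(vg), VE=float(ve_env), VGE=float(vge), Ve=float(ve),
        m=m, n=n, H2=float("nan"), confounded=confounded,
        loglik=float(ll), n_iter=it,
    )
    vc.H2 = broad_sense_heritability(vc)
    return vc


def lrt_random_effect(
    pheno: pd.DataFrame, trait: str, term: str, boundary_mixture: bool = True
) -> float:
    """REML likelihood-ratio p-value for dropping one random term.

    The statistic 2*(l_full - l_reduced) is referred to the 50:50 mixture
    of a point mass at zero and chi-square(1) — the null for a variance
    component on its boundary. ``boundary_mixture=False`` uses plain
    chi-square(1).
    """
    if term not in {"Line", "Env", "Line:Env"}:
        raise ValueError(f"unknown term {term!r}")
    d = _Design(pheno, trait)
    if d.replicated:
        full_terms = ("Line", "Env", "Line:Env")
    else:
        if term == "Line:Env":
            raise ValueError(
                "Line:Env is confounded with the residual when cells hold a "
                "single observation; it cannot be tested on these data"
            )
        full_terms = ("Line", "Env")
    reduced_terms = tuple(t for t in full_terms if t != term)
    _, ll_full, _, _, _ = _fit(d, full_terms)
    _, ll_red, _, _, _ = _fit(d, reduced_terms)
    stat = max(0.0, 2.0 * (ll_full - ll_red))
    if stat == 0.0:
        return 1.0
    p = stats.chi2.sf(stat, df=1)
    return float(0.5 * p if boundary_mixture else p)


def broad_sense_heritability(
    vc: VarianceComponents, ve_reading: str = "nm"
) -> float:
    """H2 = Vg / (Vg + VE + VGE/m + Ve/(n*m)).

    ``ve_reading`` selects how the residual is scaled: ``"nm"`` divides by
    n*m (error averages over every observation, shrinking with more data —
    the default); ``"n_times_m"`` reads it as (Ve/n)*m.
    """
    if vc.m < 1 or vc.n < 1:
        raise ValueError("m and n must be >= 1")
    if ve_reading == "nm":
        ve_term = vc.Ve / (vc.n * vc.m)
    elif ve_reading == "n_times_m":
        ve_term = vc.Ve / vc.n * vc.m
    else:
        raise ValueError(f"unknown ve_reading {ve_reading!r}")
    denom = vc.Vg + vc.VE + vc.VGE / vc.m + ve_term
    if denom == 0:
        raise ValueError("all variance components are zero; H2 undefined")
    return float(vc.Vg / denom)


def blup_genotype_effects(
    pheno: pd.DataFrame, trait: str, vc: VarianceComponents
) -> pd.DataFrame:
    """BLUPs of the random Line effects at the supplied variance components.

    Solves Henderson's equations with the variances fixed at ``vc``;
    returns a DataFrame (accession, blup, shrinkage) where ``shrinkage`` is
    the balanced-design factor Vg / (Vg + s2_within / m_i) with s2_within
    the per-observation non-Line variance and m_i the accession's
    observation count. Accessions absent from the data get NaN.
    """
    d = _Design(pheno, trait)
    terms = ("Line", "Env", "Line:Env") if d.replicated and vc.Ve > 0 else ("Line", "Env")
    Z, sizes = d.z_blocks(terms)
    if terms == ("Line", "Env", "Line:Env"):
        comps = [vc.Vg, vc.VE, vc.VGE]
        s2e = vc.Ve
    else:
        comps = [vc.Vg, vc.VE]
        s2e = vc.VGE + vc.Ve  # interaction folds into the residual
    s2e = max(s2e, 1e-12)
    nobs = len(d.y)
    X = np.ones((nobs, 1))
    lam = np.concatenate(
        [np.full(sz, s2e / max(c, 1e-12)) for c, sz in zip(comps, sizes)]
    )
    M = np.block([[X.T @ X, X.T @ Z], [Z.T @ X, Z.T @ Z + np.diag(lam)]])
    rhs = np.concatenate([(X.T @ d.y).ravel(), Z.T @ d.y])
    sol = np.linalg.solve(M, rhs)
    u_line = sol[1: 1 + len(d.lines)]

    counts = d.cell_counts.sum(axis=1).astype(float)
    s2_within = vc.VGE + vc.Ve
    with np.errstate(divide="ignore", invalid="ignore"):
        shrink = vc.Vg / (vc.Vg + s2_within / np.maximum(counts, 1))
    return pd.DataFrame(
        {"accession": d.lines, "blup": u_line, "shrinkage": shrink}
    )
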