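"""Single-marker mixed-model association with kinship control.

The scan follows the standard two-stage ("population parameters previously
determined") strategy used by the fast LMM family of tools: the ratio of
residual to genetic variance, delta, is estimated once by REML on the null
model through the spectral decomposition of the kinship matrix; each SNP is
then tested by generalized least squares in the rotated space with a Wald
t-test. An exact mode re-profiles delta per SNP. With K = I the machinery
reduces algebraically to ordinary least squares.

Also here: LD pruning to count effective independent tests for the
Bonferroni threshold, the per-SNP proportion of variance explained

    PVE = beta^2 / (beta^2 + N * se^2)

(the standardized 2*MAF*(1-MAF) factors cancel between numerator and
denominator), and a two-population Weir-Cockerham Fst scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import GenotypeMatrix

__all__ = [
    "GwasResult",
    "compute_kinship",
    "lmm_scan",
    "ld_prune_effective_tests",
    "bonferroni_threshold",
    "snp_pve",
    "fst_scan",
]

logger = logging.getLogger(__name__)

#: Recognised scan categories — metadata tags on identical machinery.
CATEGORIES = (
    "mean", "LP", "NLP", "environment-specific", "condition-specific",
    "grain-width",
)


@dataclass
class GwasResult:
    """Association scan output.

    ``table`` columns: snp_id, chrom, pos, beta, se, p, maf, n_eff, pve.
    """

    table: pd.DataFrame
    trait: str = ""
    category: str = ""
    condition: str = ""
    delta: float = float("nan")  # REML residual/genetic variance ratio
    n_dropped: int = 0           # accessions dropped for missing phenotype


def compute_kinship(geno: GenotypeMatrix, method: str = "standardized") -> np.ndarray:
    """Genetic relatedness matrix from mean-imputed dosages.

    ``standardized`` scales each SNP to unit variance before the
    cross-product (diagonal mean ~ 1 under HWE); ``centered`` only removes
    the mean (VanRaden-style numerator relationship). Monomorphic SNPs are
    excluded.
    """
    X = geno.imputed()
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    n_mono = int((~poly).sum())
    if n_mono:
        logger.info("kinship: excluding %d monomorphic SNP(s)", n_mono)
    X = X[:, poly]
    p = p[poly]
    if X.shape[1] == 0:
        raise ValueError("no polymorphic SNPs available for kinship")
    Z = X - 2.0 * p
    if method == "standardized":
        Z = Z / np.sqrt(2.0 * p * (1.0 - p))
        K = Z @ Z.T / Z.shape[1]
    elif method == "centered":
        K = Z @ Z.T / (2.0 * np.sum(p * (1.0 - p)))
    else:
        raise ValueError(f"unknown kinship method {method!r}")
    return (K + K.T) / 2.0


def _null_reml_delta(yr: np.ndarray, Xr: np.ndarray, lam: np.ndarray) -> float:
    """REML estimate of delta = sigma2_e / sigma2_g on the rotated null model.

    The covariance in the rotated basis is sigma2_g * diag(lam + delta);
    the REML criterion is profiled over sigma2_g and minimised over
    log10(delta) on [-6, 6] by grid + Brent refinement.
    """
    n, p = Xr.shape

    def neg_reml(log_delta: float) -> float:
        d = 10.0**log_delta
        w = 1.0 / (lam + d)
        XtWX = Xr.T @ (Xr * w[:, None])
        XtWy = Xr.T @ (yr * w)
        try:
            beta = np.linalg.solve(XtWX, XtWy)
        except np.linalg.LinAlgError:
            return np.inf
        r = yr - Xr @ beta
        rss = float(r @ (r * w))
        if rss <= 0:
            return np.inf
        sign, logdet_XtWX = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return np.inf
        return (
            (n - p) * np.log(rss / (n - p))
            + np.sum(np.log(lam + d))
            + logdet_XtWX
        )

    grid = np.linspace(-6, 6, 25)
    vals = [neg_reml(g) for g in grid]
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(neg_reml, bounds=(lo, hi), method="bounded")
    return float(10.0**res.x)


def lmm_scan(
    pheno_vector: pd.Series,
    geno: GenotypeMatrix,
    K: np.ndarray,
    covariates: np.ndarray | None = None,
    trait: str = "",
    category: str = "",
    condition: str = "",
    exact_delta: bool = False,
) -> GwasResult:
    """Per-SNP mixed-model Wald test.

    ``pheno_vector`` is indexed by accession id; accessions with missing
    phenotype are dropped (count recorded on the result). ``covariates``
    excludes the intercept, which is always included. ``exact_delta``
    re-estimates the variance ratio under each SNP's model instead of
    reusing the null-model value.
    """
    pheno_vector = pheno_vector.dropna()
    n_dropped = geno.n_accessions - len(pheno_vector)
    if n_dropped:
        logger.info("lmm_scan: dropped %d accession(s) with missing phenotype",
                    n_dropped)
        keep_ids = [a for a in geno.accession_ids if a in set(pheno_vector.index)]
        idx = [geno.accession_ids.index(a) for a in keep_ids]
        geno = geno.subset_accessions(keep_ids)
        K = K[np.ix_(idx, idx)]
        if covariates is not None:
            covariates = np.asarray(covariates)[idx]
        pheno_vector = pheno_vector.loc[keep_ids]
    y = pheno_vector.to_numpy(dtype=float)
    n = len(y)

    X0 = np.ones((n, 1))
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        X0 = np.hstack([X0, C])
    if np.linalg.matrix_rank(X0) < X0.shape[1]:
        raise ValueError("covariate matrix is singular (collinear columns)")

    lam, U = np.linalg.eigh((K + K.T) / 2.0)
    lam = np.maximum(lam, 0.0)
    yr = U.T @ y
    X0r = U.T @ X0

    G = geno.imputed()
    n_missing = np.isnan(geno.dosages).sum(axis=0)
    Gr = U.T @ G

    delta = _null_reml_delta(yr, X0r, lam)

    m = geno.n_snps
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    pval = np.full(m, np.nan)
    p_cov = X0.shape[1]
    dof = n - p_cov - 1

    def _test_block(w: np.ndarray, cols: np.ndarray):
        sw = np.sqrt(w)
        Xw = X0r * sw[:, None]
        yw = yr * sw
        Q, _ = np.linalg.qr(Xw)
        y_t = yw - Q @ (Q.T @ yw)
        Gw = Gr[:, cols] * sw[:, None]
        G_t = Gw - Q @ (Q.T @ Gw)
        gg = np.einsum("ij,ij->j", G_t, G_t)
        gy = G_t.T @ y_t
        yy = float(y_t @ y_t)
        ok = gg > 1e-12
        b = np.where(ok, gy / np.where(ok, gg, 1.0), np.nan)
        rss = np.maximum(yy - np.where(ok, b * gy, 0.0), 0.0)
        s2 = rss / dof
        s = np.sqrt(np.where(ok, s2 / np.where(ok, gg, 1.0), np.nan))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = b / s
        p = 2.0 * stats.t.sf(np.abs(t), df=dof)
        return b, s, p, ok

    if not exact_delta:
        w = 1.0 / (lam + delta)
        b, s, p, ok = _test_block(w, np.arange(m))
        beta, se, pval = b, s, p
    else:
        for j in range(m):
            dj = _null_reml_delta(yr, np.hstack([X0r, Gr[:, [j]]]), lam)
            w = 1.0 / (lam + dj)
            b, s, p, ok = _test_block(w, np.array([j]))
            beta[j], se[j], pval[j] = b[0], s[0], p[0]

    maf = geno.maf
    n_eff = (n - n_missing).astype(int)  # N_total - N_missing per SNP
    with np.errstate(invalid="ignore", divide="ignore"):
        pve = np.where(
            np.isfinite(beta) & np.isfinite(se),
            beta**2 / (beta**2 + n_eff * se**2),
            np.nan,
        )
    table = pd.DataFrame(
        {
            "snp_id": geno.snps["snp_id"].to_numpy(),
            "chrom": geno.snps["chrom"].to_numpy(),
            "pos": geno.snps["pos"].to_numpy(),
            "beta": beta,
            "se": se,
            "p": np.clip(pval, np.finfo(float).tiny, 1.0),
            "maf": maf,
            "n_eff": n_eff,
            "pve": pve,
        }
    )
    return GwasResult(table=table, trait=trait, category=category,
                      condition=condition, delta=delta, n_dropped=n_dropped)


def _r2_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise squared Pearson correlation between dosage columns."""
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    sd[sd == 0] = np.nan
    C = (Xc.T @ Xc) / len(X)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = C / np.outer(sd, sd)
    return np.nan_to_num(r**2)


def ld_prune_effective_tests(
    geno: GenotypeMatrix,
    window_kb: float = 1000.0,
    step: int = 10,
    r2_threshold: float = 0.3,
    return_mask: bool = False,
):
    """Greedy windowed pairwise-r^2 pruning; returns the retained count.

    Mirrors PLINK's ``--indep-pairwise <window kb> <step> <r^2>``: within a
    sliding window of ``window_kb`` the SNP with the lower MAF of any pair
    exceeding ``r2_threshold`` is removed (ties broken by keeping the
    earlier position), then the window advances by ``step`` SNPs.
    """
    if geno.n_snps == 0:
        raise ValueError("empty genotype set")
    X = geno.imputed()
    maf = geno.maf
    pos = geno.snps["pos"].to_numpy()
    chrom = geno.snps["chrom"].to_numpy()
    keep = np.ones(geno.n_snps, dtype=bool)
    span = window_kb * 1000.0

    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        start = 0
        while start < len(idx):
            anchor = idx[start]
            in_win = idx[(pos[idx] >= pos[anchor]) & (pos[idx] <= pos[anchor] + span)]
            active = [i for i in in_win if keep[i]]
            if len(active) > 1:
                r2 = _r2_matrix(X[:, active])
                for a in range(len(active)):
                    if not keep[active[a]]:
                        continue
                    for b in range(a + 1, len(active)):
                        if not keep[active[b]]:
                            continue
                        if r2[a, b] > r2_threshold:
                            ia, ib = active[a], active[b]
                            # drop the lower-MAF SNP; tie -> drop the later
                            drop = ia if maf[ia] < maf[ib] else ib
                            keep[drop] = False
                            if drop == ia:
                                break
            start += step
    n_kept = int(keep.sum())
    if return_mask:
        return n_kept, keep
    return n_kept


def bonferroni_threshold(alpha: float, n_independent: int) -> float:
    """Genome-wide p-value threshold alpha / n at n effective tests."""
    if alpha <= 0 or n_independent < 1:
        raise ValueError("alpha must be > 0 and n_independent >= 1")
    return alpha / n_independent


def snp_pve(beta: float, se: float, maf: float, n_effective: int,
            simplified: bool = True) -> float:
    """Proportion of phenotypic variance explained by one SNP.

    Full form: 2*MAF*(1-MAF)*beta^2 / (2*MAF*(1-MAF)*beta^2 +
    2*MAF*(1-MAF)*N*se^2); the frequency factor cancels, leaving
    beta^2 / (beta^2 + N*se^2). Both forms are implemented and agree to
    machine precision.
    """
    if not (0.0 < maf <= 0.5):
        raise ValueError(f"maf must be in (0, 0.5], got {maf}")
    if se < 0 or n_effective < 1:
        raise ValueError("se must be >= 0 and n_effective >= 1")
    if se == 0 and beta == 0:
        raise ValueError("PVE undefined for beta = se = 0")
    if se == 0:
        return 1.0
    if simplified:
        return beta**2 / (beta**2 + n_effective * se**2)
    v = 2.0 * maf * (1.0 - maf)
    return (v * beta**2) / (v * beta**2 + v * n_effective * se**2)


def fst_scan(geno: GenotypeMatrix, group_labels: dict[str, str]) -> pd.DataFrame:
    """Per-SNP Weir-Cockerham (1984) two-population Fst.

    ``group_labels`` maps accession id to one of two group names. SNPs
    monomorphic across both groups get NaN. Returns a DataFrame with
    columns snp_id, chrom, pos, fst, p_a, p_b, n_a, n_b. Slightly negative
    estimates are reported as computed (the estimator is unbiased, not
    range-restricted); floor at zero downstream if needed.
    """
    groups = sorted(set(group_labels.values()))
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    rows_a = [i for i, a in enumerate(geno.accession_ids)
              if group_labels.get(a) == groups[0]]
    rows_b = [i for i, a in enumerate(geno.accession_ids)
              if group_labels.get(a) == groups[1]]
    if not rows_a or not rows_b:
        raise ValueError("both groups must be non-empty")

    out = []
    X = geno.dosages
    r = 2
    for j in range(geno.n_snps):
        res = {"snp_id": geno.snps["snp_id"].iloc[j],
               "chrom": geno.snps["chrom"].iloc[j],
               "pos": int(geno.snps["pos"].iloc[j])}
        stats_g = []
        for rows in (rows_a, rows_b):
            x = X[rows, j]
            x = x[~np.isnan(x)]
            ni = len(x)
            if ni == 0:
                stats_g = None
                break
            pi = x.mean() / 2.0
            hi = np.mean(x == 1)  # observed heterozygote frequency
            stats_g.append((ni, pi, hi))
        if stats_g is None:
            res.update(fst=np.nan, p_a=np.nan, p_b=np.nan, n_a=0, n_b=0)
            out.append(res)
            continue
        (n1, p1, h1), (n2, p2, h2) = stats_g
        res.update(p_a=p1, p_b=p2, n_a=n1, n_b=n2)
        if (p1 == 0 and p2 == 0) or (p1 == 1 and p2 == 1):
            res["fst"] = np.nan  # monomorphic across both groups
            logger.debug("fst: SNP %s monomorphic in both groups",
                         res["snp_id"])
            out.append(res)
            continue
        n_bar = (n1 + n2) / 2.0
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        a = (n_bar / n_c) * (
            s2
            - (1.0 / (n_bar - 1.0))
            * (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1 - p_bar)
            - s2 * (r - 1) / r
            - h_bar * (2 * n_bar - 1) / (4 * n_bar)
        )
        c = h_bar / 2.0
        denom = a + b + c
        res["fst"] = a / denom if denom != 0 else np.nan
        out.append(res)
    return pd.DataFrame(out)
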