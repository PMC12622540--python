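"""Minimal marker sets and prediction models.

LASSO with k-fold cross-validated penalty picks a sparse SNP panel from
candidate-gene markers; backward stepwise elimination under AIC
(n*ln(RSS/n) + 2k) prunes it further; the model's PVE is the in-sample R^2
(as a percent) of the unpenalized refit on the selected SNPs. Combined
models pool mean-effect and plasticity-effect marker sets and may be fit
against raw phenotypes or multi-environment BLUPs.

Collinear markers (pairwise r^2 above a cutoff) are pre-filtered before
the LASSO, keeping the higher-MAF member of each pair.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, LassoCV

from .containers import GenotypeMatrix

__all__ = [
    "MarkerModel",
    "lasso_select",
    "stepwise_prune",
    "model_pve",
    "combined_model",
]

logger = logging.getLogger(__name__)


@dataclass
class MarkerModel:
    snp_ids: list[str]
    coefficients: np.ndarray  # aligned with snp_ids, trait units per allele
    intercept: float
    lambda_: float
    pve: float   # percent of phenotypic variance, in-sample R^2 x 100
    aic: float
    trait: str = ""
    response: str = "raw"  # "raw" phenotype or "blup"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"snp_id": self.snp_ids, "coefficient": self.coefficients})


def _aic(rss: float, n: int, k: int) -> float:
    """AIC = n*ln(RSS/n) + 2k, k counting all estimated coefficients."""
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2 * k


def _ols(X: np.ndarray, y: np.ndarray):
    Xd = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    fitted = Xd @ coef
    rss = float(np.sum((y - fitted) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return coef[0], coef[1:], rss, r2


def _collinear_filter(X: np.ndarray, maf: np.ndarray, r2_cut: float) -> np.ndarray:
    """Keep-mask dropping one of any pair with r^2 above the cutoff.

    Pairs are visited in column order; the lower-MAF member is dropped
    (tie: the later column).
    """
    m = X.shape[1]
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    keep = sd > 0  # constant columns can never be informative
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(Xc.T)
    R2 = np.nan_to_num(R**2)
    for i in range(m):
        if not keep[i]:
            continue
        for j in range(i + 1, m):
            if keep[j] and R2[i, j] > r2_cut:
                drop = i if maf[i] < maf[j] else j
                keep[drop] = False
                if drop == i:
                    break
    return keep


def lasso_select(
    geno_subset: GenotypeMatrix,
    pheno: pd.Series | np.ndarray,
    k_folds: int = 10,
    seed: int = 0,
    lambda_: float | None = None,
    one_se_rule: bool = False,
    collinearity_r2: float = 0.95,
    trait: str = "",
) -> MarkerModel:
    """Cross-validated LASSO selection of candidate-gene SNPs.

    SNPs are standardized internally; the penalty is chosen at the minimum
    mean cross-validated error over a log-spaced path (``one_se_rule``
    picks the sparsest model within one standard error of that minimum).
    Passing ``lambda_`` skips cross-validation; ``lambda_ = 0`` reduces to
    ordinary least squares. Coefficients are reported on the original
    dosage scale. Returns only the nonzero-coefficient SNPs.
    """
    y = _as_vector(pheno, geno_subset)
    if np.ptp(y) == 0:
        raise ValueError("constant phenotype; nothing to select on")
    X = geno_subset.imputed()
    maf = geno_subset.maf
    ids = geno_subset.snps["snp_id"].tolist()

    keep = _collinear_filter(X, maf, collinearity_r2)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("lasso_select: pre-filtered %d collinear/constant SNP(s)",
                    n_drop)
    X = X[:, keep]
    ids = [s for s, k in zip(ids, keep) if k]
    n, m = X.shape
    if m == 0:
        raise ValueError("no SNPs left after collinearity filtering")

    mu_x = X.mean(axis=0)
    sd_x = X.std(axis=0)
    Xs = (X - mu_x) / sd_x

    if lambda_ is not None and lambda_ == 0.0:
        intercept, coefs_s, rss, r2 = _ols(Xs, y)
        lam = 0.0
    elif lambda_ is not None:
        model = Lasso(alpha=lambda_, max_iter=100_000)
        model.fit(Xs, y)
        coefs_s, intercept, lam = model.coef_, model.intercept_, lambda_
    else:
        if n < k_folds:
            raise ValueError(f"n = {n} below k_folds = {k_folds}")
        # glmnet-style path: 100 penalties down to lambda_max/100
        cv = LassoCV(cv=_folds(n, k_folds, seed), alphas=100, eps=1e-2,
                     max_iter=20_000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cv.fit(Xs, y)
        lam = float(cv.alpha_)
        if one_se_rule:
            mse = cv.mse_path_.mean(axis=1)
            se = cv.mse_path_.std(axis=1, ddof=1) / np.sqrt(cv.mse_path_.shape[1])
            k_min = int(np.argmin(mse))
            ok = mse <= mse[k_min] + se[k_min]
            lam = float(cv.alphas_[np.flatnonzero(ok)[0]])  # alphas descend
            model = Lasso(alpha=lam, max_iter=100_000)
            model.fit(Xs, y)
            coefs_s, intercept = model.coef_, model.intercept_
        else:
            coefs_s, intercept = cv.coef_, cv.intercept_

    nz = np.flatnonzero(np.abs(coefs_s) > 1e-12)
    sel_ids = [ids[j] for j in nz]
    # back to the dosage scale
    coefs = coefs_s[nz] / sd_x[nz]
    intercept_raw = float(np.mean(y) - (X[:, nz] @ coefs)
                          .mean()) if len(nz) else float(np.mean(y))

    if len(nz):
        b0, b, rss, r2 = _ols(X[:, nz], y)
        k = len(nz) + 1
    else:
        rss = float(np.sum((y - y.mean()) ** 2))
        r2, k = 0.0, 1
    return MarkerModel(
        snp_ids=sel_ids,
        coefficients=coefs,
        intercept=intercept_raw,
        lambda_=lam,
        pve=r2 * 100.0,
        aic=_aic(rss, n, k),
        trait=trait,
    )


def _folds(n: int, k: int, seed: int):
    """Seeded fold assignment as a list of (train, test) index pairs."""
    from ._rng import substream

    rng = substream(seed, "lasso-folds")
    perm = rng.permutation(n)
    parts = np.array_split(perm, k)
    return [
        (np.setdiff1d(perm, test, assume_unique=True), test) for test in parts
    ]


def _as_vector(pheno, geno: GenotypeMatrix) -> np.ndarray:
    if isinstance(pheno, pd.Series):
        return pheno.loc[geno.accession_ids].to_numpy(dtype=float)
    y = np.asarray(pheno, dtype=float)
    if len(y) != geno.n_accessions:
        raise ValueError("phenotype length does not match accession count")
    return y


def stepwise_prune(
    model: MarkerModel, geno_subset: GenotypeMatrix, pheno
) -> MarkerModel:
    """Backward elimination under AIC, starting from ``model``'s SNP set.

    At each round the drop yielding the lowest AIC is accepted if it
    improves on the current AIC; the final AIC never exceeds the starting
    one. An empty starting model is returned unchanged.
    """
    if not model.snp_ids:
        return model
    y = _as_vector(pheno, geno_subset)
    id_to_col = {s: k for k, s in enumerate(geno_subset.snps["snp_id"])}
    missing = [s for s in model.snp_ids if s not in id_to_col]
    if missing:
        raise KeyError(f"model SNPs absent from genotype matrix: {missing[:5]}")
    X_all = geno_subset.imputed()
    current = list(model.snp_ids)

    def fit(snps):
        X = X_all[:, [id_to_col[s] for s in snps]]
        b0, b, rss, r2 = _ols(X, y)
        return b0, b, rss, r2, _aic(rss, len(y), len(snps) + 1)

    b0, b, rss, r2, aic = fit(current)
    improved = True
    while improved and len(current) > 0:
        improved = False
        best = None
        for s in current:
            trial = [t for t in current if t != s]
            if trial:
                cand = fit(trial)
                cand_aic = cand[4]
            else:
                rss0 = float(np.sum((y - y.mean()) ** 2))
                cand = (float(y.mean()), np.array([]), rss0, 0.0,
                        _aic(rss0, len(y), 1))
                cand_aic = cand[4]
            if cand_aic < aic and (best is None or cand_aic < best[1][4]):
                best = (trial, cand)
        if best is not None:
            current, (b0, b, rss, r2, aic) = best
            improved = True

    return MarkerModel(
        snp_ids=current,
        coefficients=np.asarray(b),
        intercept=float(b0),
        lambda_=model.lambda_,
        pve=r2 * 100.0,
        aic=aic,
        trait=model.trait,
        response=model.response,
    )


def model_pve(model: MarkerModel, geno_subset: GenotypeMatrix, pheno) -> float:
    """Percent phenotypic variance explained by the unpenalized refit."""
    y = _as_vector(pheno, geno_subset)
    if not model.snp_ids:
        return 0.0
    id_to_col = {s: k for k, s in enumerate(geno_subset.snps["snp_id"])}
    missing = [s for s in model.snp_ids if s not in id_to_col]
    if missing:
        raise KeyError(f"selected SNP(s) absent from genotype matrix: {missing[:5]}")
    X = geno_subset.imputed()[:, [id_to_col[s] for s in model.snp_ids]]
    _, _, _, r2 = _ols(X, y)
    return r2 * 100.0


def combined_model(
    mean_snps: list[str],
    plasticity_snps: list[str],
    geno: GenotypeMatrix,
    pheno,
    trait: str = "",
    response: str = "raw",
) -> MarkerModel:
    """Unpenalized model on the union of mean and plasticity marker sets.

    ``pheno`` may be a raw per-accession phenotype or a BLUP table
    (DataFrame with accession/blup columns). Duplicate SNP ids across the
    two sets are used once (a warning notes the overlap).
    """
    union: list[str] = []
    seen = set()
    dup = 0
    for s in list(mean_snps) + list(plasticity_snps):
        if s in seen:
            dup += 1
            continue
        seen.add(s)
        union.append(s)
    if dup:
        warnings.warn(f"{dup} SNP id(s) appeared in both marker sets; "
                      "deduplicated")
    if not union:
        raise ValueError("union of marker sets is empty")

    if isinstance(pheno, pd.DataFrame) and {"accession", "blup"} <= set(pheno.columns):
        pheno = pheno.set_index("accession")["blup"]
        response = "blup"
    y = _as_vector(pheno, geno)

    id_to_col = {s: k for k, s in enumerate(geno.snps["snp_id"])}
    missing = [s for s in union if s not in id_to_col]
    if missing:
        raise KeyError(f"marker(s) absent from genotype matrix: {missing[:5]}")
    X = geno.imputed()[:, [id_to_col[s] for s in union]]
    b0, b, rss, r2 = _ols(X, y)
    return MarkerModel(
        snp_ids=union,
        coefficients=np.asarray(b),
        intercept=float(b0),
        lambda_=float("nan"),
        pve=r2 * 100.0,
        aic=_aic(rss, len(y), len(union) + 1),
        trait=trait,
        response=response,
    )
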