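"""Synthetic multi-environment trial generator.

Emulates a rice diversity panel scored for grain-chalkiness traits across a
handful of site-years: LD-blocked biallelic SNPs with optional
two-subpopulation differentiation, per-environment temperature covariates,
and phenotypes built from the genotype-specific reaction-norm model

    y_ij = mu + g_i + (1 + b_i) * h_j + eps_ij

where g_i is the accession main effect (partly driven by planted mean-effect
QTL plus a polygenic term), (1 + b_i) the linear environmental sensitivity
(partly driven by planted plasticity QTL), h_j the environment effect, and
eps_ij a zero-mean error with accession-specific variance sigma^2_i — the
accession-level residual spread that downstream analysis reads as nonlinear
plasticity.

Every stochastic draw comes from a named substream of the master seed, so
genotypes, environments and phenotypes are independently reproducible.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .containers import GenotypeMatrix, PERCENT_TRAITS

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_genotypes",
    "simulate_environments",
    "simulate_phenotypes",
    "write_fixture",
]

logger = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """Knobs of the synthetic panel.

    Defaults describe the emulated study conditions: ~500 accessions in 5
    site-year environments, a chalkiness-like percent trait with a grand
    mean near 30%, temperature-coupled environment effects, genotype /
    environment / G-by-E variance placing broad-sense heritability in the
    0.64-0.85 band, and SNPs in LD blocks with MAF >= 0.05.
    """

    n_accessions: int = 500
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 10
    ld_rho: float = 0.6
    n_chromosomes: int = 12
    n_subpops: int = 1
    divergence: float = 0.0  # Balding-Nichols F between subpopulations
    missing_rate: float = 0.0
    n_envs: int = 5
    mu: float = 32.0
    env_effect_sd: float = 8.0
    env_temp_coupling: float = 0.9  # corr(h_j, grain-filling tmean)
    n_mean_qtl: int = 5
    n_plasticity_qtl: int = 5
    mean_qtl_pve: float = 0.3       # share of Var(g) due to planted QTL
    plasticity_qtl_pve: float = 0.3  # share of Var(b) due to planted QTL
    polygenic_var: float = 133.0     # non-QTL part of Var(g), trait units^2
    slope_noise_var: float = 0.105   # non-QTL part of Var(b)
    residual_var: float = 4.0        # median of sigma^2_i
    residual_var_log_sd: float = 0.5  # SD of log sigma^2_i across accessions
    trait_ids: tuple[str, ...] = ("GCR",)
    clip_percent_traits: bool = True
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError(f"ld_rho must be in [0, 1), got {self.ld_rho}")
        if not (0.0 <= self.divergence < 1.0):
            raise ValueError(f"divergence must be in [0, 1), got {self.divergence}")
        for name in ("n_accessions", "n_snps", "ld_block_size", "n_subpops",
                     "n_envs", "n_chromosomes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("n_mean_qtl", "n_plasticity_qtl"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("mean_qtl_pve", "plasticity_qtl_pve"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class SimTruth:
    """Generating values recorded for parameter-recovery tests.

    All effect vectors follow the identifiability convention sum(h) = 0 and
    mean(b) = 0; g is centred so the grand mean of noiseless phenotypes
    equals ``mu``.
    """

    mean_qtl_idx: np.ndarray      # column indices of planted mean-effect QTL
    alpha: np.ndarray             # allelic effects of mean QTL (trait units)
    plasticity_qtl_idx: np.ndarray
    gamma: np.ndarray             # allelic effects on the slope deviation b
    g_true: np.ndarray            # per-accession main effect
    b_true: np.ndarray            # per-accession slope deviation
    h_true: np.ndarray            # per-environment effect
    sigma2: np.ndarray            # per-accession residual variance
    vc_true: dict[str, float]     # generating variance components
    clipped_fraction: float = 0.0


def _block_dosages(rng: np.random.Generator, n: int, freqs: np.ndarray,
                   rho: float) -> np.ndarray:
    """Correlated HWE dosages for one LD block via a Gaussian copula.

    Two independent latent haplotype draws share an equicorrelation-``rho``
    covariance across the SNPs of the block; each is thresholded at the
    normal quantile of its allele frequency.
    """
    m = len(freqs)
    thresh = stats.norm.ppf(freqs)  # P(Z < t) = freq
    dose = np.zeros((n, m))
    for _ in range(2):  # two haplotypes per accession
        shared = rng.standard_normal((n, 1))
        indep = rng.standard_normal((n, m))
        z = math.sqrt(rho) * shared + math.sqrt(1.0 - rho) * indep
        dose += (z < thresh[None, :]).astype(float)
    return dose


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Draw the SNP panel: LD-blocked dosages at target MAF.

    Ancestral minor-allele frequencies are uniform on ``maf_range``; with
    ``n_subpops > 1`` each subpopulation's frequency is a Balding-Nichols
    Beta draw around the ancestral value with differentiation parameter
    ``divergence``, which sets the expected per-SNP Fst.
    """
    cfg.validate()
    rng = substream(cfg.seed, "genotypes")
    n, m = cfg.n_accessions, cfg.n_snps

    lo, hi = cfg.maf_range
    p_anc = rng.uniform(lo, hi, size=m)

    # equal split of accessions over subpopulations
    pop = np.repeat(np.arange(cfg.n_subpops), math.ceil(n / cfg.n_subpops))[:n]

    if cfg.n_subpops > 1 and cfg.divergence > 0:
        F = cfg.divergence
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        p_pop = rng.beta(a[None, :].repeat(cfg.n_subpops, 0),
                         b[None, :].repeat(cfg.n_subpops, 0))
        p_pop = np.clip(p_pop, 1e-4, 1 - 1e-4)
    else:
        p_pop = np.tile(p_anc, (cfg.n_subpops, 1))

    # blocks never span a chromosome boundary: chromosomes get whole blocks
    n_blocks = math.ceil(m / cfg.ld_block_size)
    block_of_snp = np.repeat(np.arange(n_blocks), cfg.ld_block_size)[:m]
    chrom_of_block = np.linspace(0, cfg.n_chromosomes, n_blocks,
                                 endpoint=False).astype(int)
    chrom = chrom_of_block[block_of_snp] + 1

    dose = np.zeros((n, m))
    for s in range(cfg.n_subpops):
        rows = np.flatnonzero(pop == s)
        for blk in range(n_blocks):
            cols = np.flatnonzero(block_of_snp == blk)
            dose[np.ix_(rows, cols)] = _block_dosages(
                rng, len(rows), p_pop[s, cols], cfg.ld_rho
            )

    if cfg.missing_rate > 0:
        mask = rng.random(dose.shape) < cfg.missing_rate
        dose[mask] = np.nan

    # orient dosages to the empirical minor allele (target frequencies near
    # 0.5 can drift past it), so serialisation round-trips exactly
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dose, axis=0) / 2.0
    flip = freq > 0.5
    dose[:, flip] = 2.0 - dose[:, flip]

    # positions ~1 kb apart with jitter, restarting per chromosome
    pos = np.zeros(m, dtype=int)
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        gaps = rng.integers(200, 2000, size=len(idx))
        pos[idx] = 1 + np.cumsum(gaps)

    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{c}_{p}" for c, p in zip(chrom, pos)],
            "chrom": [f"chr{c:02d}" for c in chrom],
            "pos": pos,
            "ref": np.where(flip, "T", "A"),
            "alt": np.where(flip, "A", "T"),
        }
    )
    accession_ids = [f"acc{i:04d}" for i in range(n)]
    return GenotypeMatrix(accession_ids=accession_ids, snps=snps, dosages=dose)


def simulate_environments(cfg: SimConfig) -> pd.DataFrame:
    """Site-year environments with grain-filling temperature covariates.

    tmean spans roughly 25-32 degC (the band over which chalkiness responds
    steeply to heat); tmin/tmax bracket it by a few degrees.
    """
    rng = substream(cfg.seed, "environments")
    tmean = np.sort(rng.uniform(25.0, 32.0, size=cfg.n_envs))
    tmin = tmean - rng.uniform(3.0, 6.0, size=cfg.n_envs)
    tmax = tmean + rng.uniform(3.0, 6.0, size=cfg.n_envs)
    years = 2012 + np.arange(cfg.n_envs)
    return pd.DataFrame(
        {
            "environment": [f"E{j + 1}" for j in range(cfg.n_envs)],
            "site": "SiteA",
            "year": years,
            "tmin": np.round(tmin, 2),
            "tmean": np.round(tmean, 2),
            "tmax": np.round(tmax, 2),
        }
    )


def _planted_effects(rng, X: np.ndarray, n_qtl: int, qtl_pve: float,
                     background_var: float):
    """Pick QTL columns and scale effects so they explain ``qtl_pve`` of the
    component's variance, the rest (``background_var``) coming from noise."""
    m = X.shape[1]
    if n_qtl == 0 or qtl_pve == 0.0:
        return np.array([], dtype=int), np.array([]), np.zeros(X.shape[0])
    idx = rng.choice(m, size=min(n_qtl, m), replace=False)
    raw = rng.choice([-1.0, 1.0], size=len(idx)) * rng.uniform(0.5, 1.0, len(idx))
    contrib = X[:, idx] @ raw
    v = contrib.var()
    target = background_var * qtl_pve / (1.0 - qtl_pve)
    scale = math.sqrt(target / v) if v > 0 else 0.0
    return idx, raw * scale, contrib * scale


def simulate_phenotypes(
    geno: GenotypeMatrix, env: pd.DataFrame, cfg: SimConfig
) -> tuple[pd.DataFrame, SimTruth]:
    """Build phenotypes from the reaction-norm model and return the truth.

    Returns a long-format phenotype table (one record per accession x
    environment x trait) and the generating parameters. When several
    ``trait_ids`` are configured each trait is an independent draw of the
    same model (own QTL, own effects) from its own substream.
    """
    cfg.validate()
    if cfg.n_envs < 2:
        raise ValueError("at least 2 environments are required; plasticity is "
                         "undefined in a single environment")
    if len(env) != cfg.n_envs:
        raise ValueError("environment table size does not match cfg.n_envs")
    X = geno.imputed()
    n = geno.n_accessions

    rng_env = substream(cfg.seed, "env-effects")
    # environment effects are temperature-driven: h_j correlates with the
    # grain-filling mean temperature at strength env_temp_coupling (hot
    # years push the trait up), with an orthogonal year/site remainder
    noise = rng_env.standard_normal(cfg.n_envs)
    tm = env["tmean"].to_numpy(dtype=float)
    if np.ptp(tm) > 0 and abs(cfg.env_temp_coupling) > 0:
        tz = (tm - tm.mean()) / tm.std()
        noise = noise - noise.mean()
        if noise.std() > 0:
            noise = (noise - tz * (noise @ tz) / (tz @ tz))
            nz = noise / noise.std() if noise.std() > 0 else noise
        else:
            nz = noise
        c = cfg.env_temp_coupling
        h = c * tz + math.sqrt(max(0.0, 1.0 - c * c)) * nz
    else:
        h = noise
    h -= h.mean()  # sum-to-zero convention
    # scale to the configured spread exactly, so the environment variance
    # is a set condition rather than a chi-square draw
    sd = h.std()
    if sd > 0 and cfg.env_effect_sd > 0:
        h *= cfg.env_effect_sd / sd
    else:
        h[:] = 0.0

    records = []
    truth = None
    for trait in cfg.trait_ids:
        rng = substream(cfg.seed, f"phenotypes:{trait}")

        mean_idx, alpha, g_qtl = _planted_effects(
            rng, X, cfg.n_mean_qtl, cfg.mean_qtl_pve, cfg.polygenic_var
        )
        g = g_qtl + rng.standard_normal(n) * math.sqrt(cfg.polygenic_var)
        g -= g.mean()

        pl_idx, gamma, b_qtl = _planted_effects(
            rng, X, cfg.n_plasticity_qtl, cfg.plasticity_qtl_pve,
            cfg.slope_noise_var
        )
        b = b_qtl + rng.standard_normal(n) * math.sqrt(cfg.slope_noise_var)
        b -= b.mean()  # mean slope = 1 convention

        log_sig = rng.standard_normal(n) * cfg.residual_var_log_sd
        sigma2 = cfg.residual_var * np.exp(log_sig)
        if cfg.residual_var == 0.0:
            sigma2 = np.zeros(n)

        eps = rng.standard_normal((n, cfg.n_envs)) * np.sqrt(sigma2)[:, None]
        y = cfg.mu + g[:, None] + (1.0 + b)[:, None] * h[None, :] + eps

        clipped = 0.0
        if cfg.clip_percent_traits and trait in PERCENT_TRAITS:
            out_of_range = (y < 0) | (y > 100)
            clipped = float(out_of_range.mean())
            if clipped > 0:
                logger.info("trait %s: clipped %.2f%% of values to [0, 100]",
                            trait, 100 * clipped)
            y = np.clip(y, 0.0, 100.0)

        for i, acc in enumerate(geno.accession_ids):
            for j, e in enumerate(env["environment"]):
                records.append((acc, e, trait, y[i, j]))

        # sample (ddof=1) variances of the realised effects: the estimand a
        # random-effects fit targets given these finite draws
        vc_true = {
            "Vg": float(g.var(ddof=1)),
            "VE": float(h.var(ddof=1)),
            "VGE": float(b.var(ddof=1) * h.var(ddof=1)),
            "Ve": float(sigma2.mean()),
        }
        t = SimTruth(
            mean_qtl_idx=mean_idx, alpha=alpha,
            plasticity_qtl_idx=pl_idx, gamma=gamma,
            g_true=g, b_true=b, h_true=h, sigma2=sigma2,
            vc_true=vc_true, clipped_fraction=clipped,
        )
        if truth is None:
            truth = t
        else:  # multi-trait runs keep per-trait truths
            if not isinstance(truth, dict):
                truth = {cfg.trait_ids[0]: truth}
            truth[trait] = t

    pheno = pd.DataFrame(records,
                         columns=["accession", "environment", "trait", "value"])
    return pheno, truth


def write_fixture(geno: GenotypeMatrix, pheno: pd.DataFrame, env: pd.DataFrame,
                  truth: SimTruth, out_dir, cfg: SimConfig | None = None) -> dict:
    """Serialise a simulated dataset to plain-text files plus a manifest.

    Emits ``genotypes.vcf``, ``phenotypes.tsv``, ``environments.tsv``, truth
    tables, and ``manifest.json``. Returns the manifest dict.
    """
    from . import io as pio  # local import to avoid a cycle

    out = Path(out_dir)
    if not out.exists():
        logger.info("creating fixture directory %s", out)
        out.mkdir(parents=True)

    pio.write_vcf(geno, out / "genotypes.vcf")
    pheno.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
    env.to_csv(out / "environments.tsv", sep="\t", index=False)

    pd.DataFrame(
        {
            "accession": geno.accession_ids,
            "g_true": truth.g_true,
            "b_true": truth.b_true,
            "sigma2": truth.sigma2,
        }
    ).to_csv(out / "truth_accessions.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"environment": env["environment"], "h_true": truth.h_true}
    ).to_csv(out / "truth_environments.tsv", sep="\t", index=False)
    qtl_rows = [
        {"kind": "mean", "snp_id": geno.snps["snp_id"].iloc[i], "effect": a}
        for i, a in zip(truth.mean_qtl_idx, truth.alpha)
    ] + [
        {"kind": "plasticity", "snp_id": geno.snps["snp_id"].iloc[i], "effect": gmm}
        for i, gmm in zip(truth.plasticity_qtl_idx, truth.gamma)
    ]
    pd.DataFrame(qtl_rows, columns=["kind", "snp_id", "effect"]).to_csv(
        out / "truth_qtl.tsv", sep="\t", index=False
    )

    manifest = {
        "seed": cfg.seed if cfg is not None else None,
        "config": asdict(cfg) if cfg is not None else None,
        "vc_true": truth.vc_true,
        "clipped_fraction": truth.clipped_fraction,
        "files": [
            "genotypes.vcf", "phenotypes.tsv", "environments.tsv",
            "truth_accessions.tsv", "truth_environments.tsv", "truth_qtl.tsv",
        ],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
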