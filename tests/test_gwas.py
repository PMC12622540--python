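"""Association machinery: kinship, LMM calibration, pruning, PVE, Fst."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plastmap import gwas, simulate
from plastmap.containers import GenotypeMatrix
from plastmap.gwas import (
    bonferroni_threshold,
    compute_kinship,
    fst_scan,
    ld_prune_effective_tests,
    lmm_scan,
    snp_pve,
)


def _geno_from_matrix(X, chrom=None, pos=None):
    n, m = X.shape
    return GenotypeMatrix(
        accession_ids=[f"a{i:03d}" for i in range(n)],
        snps=pd.DataFrame(
            {
                "snp_id": [f"s{j}" for j in range(m)],
                "chrom": chrom if chrom is not None else ["chr01"] * m,
                "pos": pos if pos is not None else np.arange(1, m + 1) * 1000,
                "ref": "A",
                "alt": "T",
            }
        ),
        dosages=np.asarray(X, dtype=float),
    )


class TestKinship:
    def test_identical_accessions_share_diagonal_value(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 3, size=(10, 50)).astype(float)
        X[1] = X[0]  # clone
        K = compute_kinship(_geno_from_matrix(X))
        assert K[0, 1] == pytest.approx(K[0, 0], rel=1e-12)
        assert K[0, 1] == pytest.approx(K[1, 1], rel=1e-12)

    def test_symmetric_psd_unit_diagonal(self, small_panel):
        K = compute_kinship(small_panel["geno"])
        assert np.allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() >= -1e-8
        assert abs(K.diagonal().mean() - 1.0) < 0.05

    def test_monomorphic_snps_excluded(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 3, size=(20, 10)).astype(float)
        X[:, 3] = 2.0  # monomorphic
        K = compute_kinship(_geno_from_matrix(X))
        assert np.all(np.isfinite(K))


class TestLmmScan:
    def test_identity_kinship_equals_ols(self):
        rng = np.random.default_rng(2)
        cfg = simulate.SimConfig(n_accessions=120, n_snps=40, seed=5)
        geno = simulate.simulate_genotypes(cfg)
        y = pd.Series(rng.normal(size=120), index=geno.accession_ids)
        res = lmm_scan(y, geno, np.eye(120))
        X = geno.imputed()
        for j in range(geno.n_snps):
            sl = stats.linregress(X[:, j], y.to_numpy())
            t_ols = sl.slope / sl.stderr
            t_lmm = res.table["beta"][j] / res.table["se"][j]
            assert abs(t_ols - t_lmm) < 1e-8
            assert res.table["p"][j] == pytest.approx(sl.pvalue, abs=1e-10)

    def test_null_calibration_and_genomic_control(self):
        cfg = simulate.SimConfig(n_accessions=300, n_snps=5000, seed=11)
        geno = simulate.simulate_genotypes(cfg)
        rng = np.random.default_rng(7)
        y = pd.Series(rng.normal(size=300), index=geno.accession_ids)
        K = compute_kinship(geno)
        res = lmm_scan(y, geno, K)
        p = res.table["p"].to_numpy()
        assert 0.04 <= (p < 0.05).mean() <= 0.06
        lam = np.median(stats.chi2.isf(p, 1)) / stats.chi2.ppf(0.5, 1)
        assert 0.95 <= lam <= 1.05

    def test_planted_snp_detected_at_bonferroni(self):
        """PVE-10% SNP at n=500: power ~1 by the noncentral-chi2 oracle.

        NCP = n*PVE/(1-PVE) = 55.6, threshold chi2_1 at 1.37e-6 is 23.3,
        so per-seed power is >0.999; 20/20 to 19/20 expected.
        """
        ncp = 500 * 0.10 / 0.90
        thresh = stats.chi2.isf(1.37e-6, 1)
        power = stats.ncx2.sf(thresh, 1, ncp)
        assert power > 0.99
        hits = 0
        for seed in range(20):
            cfg = simulate.SimConfig(n_accessions=500, n_snps=200,
                                     seed=400 + seed)
            geno = simulate.simulate_genotypes(cfg)
            rng = np.random.default_rng(500 + seed)
            x = geno.imputed()[:, 100]
            xs = (x - x.mean()) / x.std()
            y = pd.Series(
                np.sqrt(0.10) * xs + rng.normal(0, np.sqrt(0.90), 500),
                index=geno.accession_ids,
            )
            # leave-one-chromosome-out kinship: the causal SNP's LD block
            # must not absorb its own signal into the random effect
            loco = (geno.snps["chrom"]
                    != geno.snps["chrom"].iloc[100]).to_numpy()
            K = compute_kinship(geno.subset_snps(loco))
            res = lmm_scan(y, geno, K)
            hits += res.table["p"][100] < 1.37e-6
        assert hits >= 19

    def test_covariate_absorbing_phenotype_zeroes_betas(self):
        cfg = simulate.SimConfig(n_accessions=100, n_snps=30, seed=8)
        geno = simulate.simulate_genotypes(cfg)
        rng = np.random.default_rng(3)
        cov = rng.normal(size=100)
        y = pd.Series(cov.copy(), index=geno.accession_ids)
        res = lmm_scan(y, geno, np.eye(100), covariates=cov[:, None])
        assert np.nanmax(np.abs(res.table["beta"])) < 1e-8

    def test_missing_phenotypes_dropped_with_count(self, small_panel):
        geno = small_panel["geno"]
        rng = np.random.default_rng(4)
        y = pd.Series(rng.normal(size=geno.n_accessions),
                      index=geno.accession_ids)
        y.iloc[:7] = np.nan
        K = compute_kinship(geno)
        res = lmm_scan(y, geno, K)
        assert res.n_dropped == 7

    def test_scan_deterministic(self, small_panel):
        geno = small_panel["geno"]
        rng = np.random.default_rng(5)
        y = pd.Series(rng.normal(size=geno.n_accessions),
                      index=geno.accession_ids)
        K = compute_kinship(geno)
        a = lmm_scan(y, geno, K).table
        b = lmm_scan(y, geno, K).table
        pd.testing.assert_frame_equal(a, b)

    def test_singular_covariates_rejected(self, small_panel):
        geno = small_panel["geno"]
        y = pd.Series(np.arange(geno.n_accessions, dtype=float),
                      index=geno.accession_ids)
        C = np.ones((geno.n_accessions, 2))  # collinear with intercept
        with pytest.raises(ValueError, match="singular"):
            lmm_scan(y, geno, np.eye(geno.n_accessions), covariates=C)


class TestPruning:
    def test_uncorrelated_snps_all_retained(self):
        cfg = simulate.SimConfig(n_accessions=400, n_snps=60, ld_rho=0.0,
                                 seed=6)
        geno = simulate.simulate_genotypes(cfg)
        assert ld_prune_effective_tests(geno, r2_threshold=0.3) == 60

    def test_duplicated_columns_keep_one_representative(self):
        rng = np.random.default_rng(7)
        base = rng.integers(0, 3, size=(100, 1)).astype(float)
        X = np.repeat(base, 5, axis=1)
        geno = _geno_from_matrix(X)
        assert ld_prune_effective_tests(geno) == 1

    def test_matches_unwindowed_greedy_oracle(self):
        cfg = simulate.SimConfig(n_accessions=150, n_snps=100,
                                 ld_rho=0.5, ld_block_size=5, seed=9)
        geno = simulate.simulate_genotypes(cfg)
        # oracle: same greedy rule, no windowing, brute force over pairs
        X = geno.imputed()
        maf = geno.maf
        m = X.shape[1]
        R2 = np.corrcoef(X.T) ** 2
        keep = np.ones(m, dtype=bool)
        for i in range(m):
            if not keep[i]:
                continue
            for j in range(i + 1, m):
                if keep[j] and R2[i, j] > 0.3:
                    drop = i if maf[i] < maf[j] else j
                    keep[drop] = False
                    if drop == i:
                        break
        span_kb = (geno.snps["pos"].max() + 1) / 1000.0
        n_kept, mask = ld_prune_effective_tests(
            geno, window_kb=span_kb, step=m, r2_threshold=0.3,
            return_mask=True,
        )
        assert n_kept == keep.sum()
        np.testing.assert_array_equal(mask, keep)

    def test_empty_input_rejected(self):
        geno = _geno_from_matrix(np.zeros((5, 0)),
                                 chrom=[], pos=[])
        with pytest.raises(ValueError, match="empty"):
            ld_prune_effective_tests(geno)


class TestThresholdAndPve:
    def test_bonferroni_published_scale(self):
        thr = bonferroni_threshold(0.05, 36508)
        assert thr == pytest.approx(1.37e-6, rel=5e-3)  # 3 significant figures

    @pytest.mark.parametrize("alpha,n,expected", [(0.05, 1, 0.05),
                                                  (0.05, 5, 0.01)])
    def test_bonferroni_small_cases(self, alpha, n, expected):
        assert bonferroni_threshold(alpha, n) == pytest.approx(expected)

    def test_bonferroni_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_threshold(-0.1, 10)

    def test_pve_hand_case_and_form_agreement(self):
        # beta=0.5, se=0.05, N=100: 0.25 / (0.25 + 100*0.0025) = 0.5
        full = snp_pve(0.5, 0.05, 0.25, 100, simplified=False)
        simple = snp_pve(0.5, 0.05, 0.25, 100, simplified=True)
        assert simple == pytest.approx(0.5)
        assert abs(full - simple) < 1e-12

    def test_pve_limits(self):
        assert snp_pve(0.0, 0.1, 0.3, 50) == 0.0
        assert snp_pve(0.4, 0.0, 0.3, 50) == 1.0
        with pytest.raises(ValueError):
            snp_pve(0.0, 0.0, 0.3, 50)

    def test_pve_monotone_in_se_and_n(self):
        ses = np.linspace(0.01, 1.0, 10)
        vals = [snp_pve(0.5, s, 0.2, 100) for s in ses]
        assert np.all(np.diff(vals) < 0)
        ns = [10, 50, 100, 500, 1000]
        vals_n = [snp_pve(0.5, 0.1, 0.2, n) for n in ns]
        assert np.all(np.diff(vals_n) < 0)


class TestFst:
    @staticmethod
    def _wc_oracle(n1, p1, h1, n2, p2, h2):
        """Independent hand-coded Weir-Cockerham (1984) two-deme estimator."""
        r = 2
        nb = (n1 + n2) / 2
        nc = (r * nb - (n1**2 + n2**2) / (r * nb)) / (r - 1)
        pb = (n1 * p1 + n2 * p2) / (r * nb)
        s2 = (n1 * (p1 - pb) ** 2 + n2 * (p2 - pb) ** 2) / ((r - 1) * nb)
        hb = (n1 * h1 + n2 * h2) / (r * nb)
        a = nb / nc * (s2 - 1 / (nb - 1) * (pb * (1 - pb)
                                            - (r - 1) / r * s2 - hb / 4))
        b = nb / (nb - 1) * (pb * (1 - pb) - (r - 1) / r * s2
                             - (2 * nb - 1) / (4 * nb) * hb)
        c = hb / 2
        return a / (a + b + c)

    def test_no_differentiation(self):
        rng = np.random.default_rng(10)
        X = rng.binomial(2, 0.4, size=(1000, 30)).astype(float)
        geno = _geno_from_matrix(X)
        labels = {a: ("A" if i < 500 else "B")
                  for i, a in enumerate(geno.accession_ids)}
        fst = fst_scan(geno, labels)
        assert np.nanmax(np.abs(fst["fst"])) < 0.02

    def test_fixed_difference_is_one(self):
        X = np.zeros((40, 3))
        X[:20, :] = 2.0
        geno = _geno_from_matrix(X)
        labels = {a: ("A" if i < 20 else "B")
                  for i, a in enumerate(geno.accession_ids)}
        fst = fst_scan(geno, labels)
        np.testing.assert_allclose(fst["fst"], 1.0)

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(12)
        X = np.vstack(
            [rng.binomial(2, 0.2, size=(50, 20)),
             rng.binomial(2, 0.8, size=(50, 20))]
        ).astype(float)
        geno = _geno_from_matrix(X)
        labels = {a: ("A" if i < 50 else "B")
                  for i, a in enumerate(geno.accession_ids)}
        fst = fst_scan(geno, labels)
        for j in range(20):
            xa, xb = X[:50, j], X[50:, j]
            expect = self._wc_oracle(
                50, xa.mean() / 2, (xa == 1).mean(),
                50, xb.mean() / 2, (xb == 1).mean(),
            )
            assert fst["fst"][j] == pytest.approx(expect, abs=1e-12)

    def test_monomorphic_snp_reported_missing(self):
        X = np.ones((20, 1)) * 0.0
        geno = _geno_from_matrix(X)
        labels = {a: ("A" if i < 10 else "B")
                  for i, a in enumerate(geno.accession_ids)}
        fst = fst_scan(geno, labels)
        assert np.isnan(fst["fst"][0])
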