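"""QTL regions, hotspot condensation, candidate genes, trade-off profiles."""

import numpy as np
import pandas as pd
import pytest

from plastmap import atlas
from plastmap.atlas import (
    Hotspot,
    QtlRegion,
    call_qtl_regions,
    candidate_genes,
    category_accounting,
    condense_hotspots,
    effect_sign_tradeoff,
    haplotype_contrast,
    subphenotype_overlap,
)
from plastmap.gwas import GwasResult


def _result(positions, pvalues, chrom="chr01", category="mean"):
    m = len(positions)
    table = pd.DataFrame(
        {
            "snp_id": [f"s{k}" for k in range(m)],
            "chrom": chrom,
            "pos": positions,
            "beta": 0.1,
            "se": 0.01,
            "p": pvalues,
            "maf": 0.2,
            "n_eff": 100,
            "pve": 0.01,
        }
    )
    return GwasResult(table=table, category=category)


class TestCallRegions:
    def test_nothing_significant_gives_empty_list(self):
        res = _result([100, 200], [0.5, 0.9])
        assert call_qtl_regions(res, 1e-6) == []

    def test_single_snp_padding_rule(self):
        res = _result([1_000_000], [1e-8])
        (reg,) = call_qtl_regions(res, 1e-6, merge_kb=200)
        assert (reg.start, reg.end) == (900_001, 1_100_000)
        assert reg.lead_snp == "s0"

    def test_nearby_snps_merge_into_one_region(self):
        res = _result([1_000_000, 1_050_000], [1e-8, 1e-7])
        regions = call_qtl_regions(res, 1e-6, merge_kb=200)
        assert len(regions) == 1
        assert regions[0].start == 900_001
        assert regions[0].end == 1_150_000
        assert regions[0].lead_p == 1e-8

    def test_distant_snps_stay_separate(self):
        res = _result([1_000_000, 2_000_000], [1e-8, 1e-8])
        assert len(call_qtl_regions(res, 1e-6, merge_kb=200)) == 2

    def test_lead_tie_broken_by_position(self):
        res = _result([1_000_000, 1_010_000], [1e-8, 1e-8])
        (reg,) = call_qtl_regions(res, 1e-6)
        assert reg.lead_snp == "s0"


def _q(qid, chrom, start, end, cat="mean"):
    return QtlRegion(qtl_id=qid, chrom=chrom, start=start, end=end,
                     lead_snp="x", lead_p=1e-8, category=cat)


class TestCondense:
    def test_hand_worked_example(self):
        qtl = [_q("A", "chr01", 100, 200), _q("B", "chr01", 150, 250),
               _q("C", "chr01", 400, 500)]
        hs = condense_hotspots(qtl)
        assert len(hs) == 1
        assert hs[0].member_qtl == ["A", "B"]
        assert (hs[0].start, hs[0].end) == (100, 250)
        assert not hs[0].is_key

    def test_disjoint_intervals_give_no_hotspots(self):
        qtl = [_q(f"Q{i}", "chr01", i * 1000, i * 1000 + 100)
               for i in range(10)]
        assert condense_hotspots(qtl) == []

    def test_key_flag_requires_more_than_three_members(self):
        qtl = [_q(f"Q{i}", "chr01", 100, 200) for i in range(4)]
        hs = condense_hotspots(qtl)
        assert hs[0].n_members == 4
        assert hs[0].is_key
        hs3 = condense_hotspots(qtl[:3])
        assert not hs3[0].is_key

    def test_matches_brute_force_components_on_random_intervals(self):
        rng = np.random.default_rng(13)
        qtl = []
        for k in range(1000):
            chrom = f"chr{rng.integers(1, 6):02d}"
            start = int(rng.integers(1, 2_000_000))
            end = start + int(rng.integers(1, 150_000))
            qtl.append(_q(f"Q{k}", chrom, start, end))
        hs = condense_hotspots(qtl, min_members=2)

        # oracle: union-find over all overlapping pairs
        parent = list(range(len(qtl)))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(len(qtl)):
            for j in range(i + 1, len(qtl)):
                a, b = qtl[i], qtl[j]
                if (a.chrom == b.chrom and a.start <= b.end
                        and b.start <= a.end):
                    parent[find(i)] = find(j)
        comps = {}
        for i, q in enumerate(qtl):
            comps.setdefault(find(i), []).append(q.qtl_id)
        expected = sorted(
            [sorted(v) for v in comps.values() if len(v) >= 2]
        )
        got = sorted([h.member_qtl for h in hs])
        assert got == expected

    def test_order_invariant(self):
        rng = np.random.default_rng(14)
        qtl = [_q(f"Q{k}", "chr01", int(rng.integers(1, 100_000)),
                  int(rng.integers(1, 100_000)) + 120_000)
               for k in range(50)]
        a = condense_hotspots(qtl)
        perm = [qtl[i] for i in rng.permutation(len(qtl))]
        b = condense_hotspots(perm)
        assert [h.member_qtl for h in a] == [h.member_qtl for h in b]

    def test_members_plus_singletons_account_for_all_qtl(self):
        rng = np.random.default_rng(15)
        qtl = []
        for k in range(200):
            start = int(rng.integers(1, 1_000_000))
            qtl.append(_q(f"Q{k}", "chr01", start,
                          start + int(rng.integers(1, 80_000))))
        hs = condense_hotspots(qtl)
        in_hotspots = sum(h.n_members for h in hs)
        singles = condense_hotspots(qtl, min_members=1)
        singletons = sum(1 for h in singles if h.n_members == 1)
        assert in_hotspots + singletons == len(qtl)

    def test_pairwise_mode_is_stricter(self):
        # chain A-B-C where A and C do not overlap
        qtl = [_q("A", "chr01", 0, 100), _q("B", "chr01", 90, 300),
               _q("C", "chr01", 250, 400)]
        transitive = condense_hotspots(qtl)
        assert transitive[0].member_qtl == ["A", "B", "C"]
        pairwise = condense_hotspots(qtl, pairwise=True)
        assert all(len(h.member_qtl) < 3 for h in pairwise)


class TestCandidateGenes:
    genes = pd.DataFrame(
        {
            "gene_id": ["g1", "g2", "g3", "g4"],
            "chrom": ["chr01", "chr01", "chr02", "chr01"],
            "start": [995_000, 2_000_000, 1_000_000, 1_010_000],
            "end": [996_000, 2_001_000, 1_001_000, 1_030_000],
        }
    )
    snps = pd.DataFrame(
        {"snp_id": ["s1"], "chrom": ["chr01"], "pos": [1_000_000]}
    )

    def test_window_membership(self):
        out = candidate_genes(self.snps, self.genes, window_bp=20_000)
        assert set(out["gene_id"]) == {"g1", "g4"}

    def test_other_chromosome_excluded(self):
        out = candidate_genes(self.snps, self.genes, window_bp=20_000)
        assert "g3" not in set(out["gene_id"])

    def test_boundary_gene_included_closed_interval(self):
        genes = pd.DataFrame(
            {"gene_id": ["edge"], "chrom": ["chr01"],
             "start": [1_010_000], "end": [1_010_000]}
        )
        out = candidate_genes(self.snps, genes, window_bp=20_000)
        assert list(out["gene_id"]) == ["edge"]

    def test_monotone_in_window(self):
        small = candidate_genes(self.snps, self.genes, window_bp=2_000)
        large = candidate_genes(self.snps, self.genes, window_bp=4_000_000)
        assert set(small["gene_id"]) <= set(large["gene_id"])
        assert set(large["gene_id"]) == {"g1", "g2", "g4"}


class TestOverlapAndSigns:
    def test_disjoint_sets(self):
        out = subphenotype_overlap({"a"}, {"b"}, {"c"})
        assert out["mean_lp"] == out["mean_nlp"] == out["lp_nlp"] == 0
        assert out["mean_lp_nlp"] == 0

    def test_identical_sets(self):
        out = subphenotype_overlap({"a", "b"}, {"a", "b"}, {"a", "b"})
        assert out["mean_lp_nlp"] == 2
        assert out["mean_only"] == 0

    def test_hand_enumeration(self):
        out = subphenotype_overlap({"a", "b", "c"}, {"b", "c", "d"}, {"c"})
        assert out["mean_lp_nlp"] == 1  # {c}
        assert out["mean_lp"] == 1      # {b}
        assert out["mean_only"] == 1    # {a}
        assert out["lp_only"] == 1      # {d}

    def test_effect_sign_classification(self):
        mean = _result([100, 200, 300], [1e-8] * 3)
        mean.table["beta"] = [0.4, 0.3, 0.2]
        lp = _result([100, 200, 300], [1e-8] * 3)
        lp.table["beta"] = [-0.2, 0.3, 1e-12]
        prof = effect_sign_tradeoff(mean, lp, ["s0", "s1", "s2", "absent"])
        assert list(prof["flag"]) == ["antagonistic", "concordant",
                                      "neutral", "missing"]


class TestHaplotypeContrast:
    @staticmethod
    def _panel(n, delta, seed, m_snps=3):
        from plastmap.containers import GenotypeMatrix

        rng = np.random.default_rng(seed)
        half = n // 2
        X = np.zeros((n, m_snps))
        X[half:, :] = 2.0
        geno = GenotypeMatrix(
            accession_ids=[f"a{i:03d}" for i in range(n)],
            snps=pd.DataFrame(
                {"snp_id": [f"s{j}" for j in range(m_snps)],
                 "chrom": "chr01", "pos": np.arange(1, m_snps + 1) * 100,
                 "ref": "A", "alt": "T"}
            ),
            dosages=X,
        )
        y = rng.normal(0, 1, n)
        y[half:] += delta
        pheno = pd.Series(y, index=geno.accession_ids)
        return geno, pheno

    def test_null_groups_have_small_difference(self):
        geno, pheno = self._panel(400, 0.0, seed=1)
        out = haplotype_contrast(geno, ["s0", "s1", "s2"], pheno)
        diff = abs(out["summary"]["mean"].iloc[0]
                   - out["summary"]["mean"].iloc[1])
        assert diff < 0.3  # ~3 SE of the two-group mean difference
        assert out["anova_p"] > 0.001

    def test_planted_shift_detected(self):
        hits = 0
        for seed in range(20):
            geno, pheno = self._panel(200, 1.0, seed=seed)
            out = haplotype_contrast(geno, ["s0", "s1", "s2"], pheno)
            hits += out["anova_p"] < 0.05
        assert hits >= 19

    def test_missing_alleles_excluded_and_counted(self):
        geno, pheno = self._panel(60, 1.0, seed=3)
        geno.dosages[0, 1] = np.nan
        out = haplotype_contrast(geno, ["s0", "s1", "s2"], pheno,
                                 min_group_size=5)
        assert out["n_excluded_missing"] == 1

    def test_monomorphic_panel_rejected(self):
        geno, pheno = self._panel(40, 0.0, seed=4)
        geno.dosages[:, :] = 0.0
        with pytest.raises(ValueError, match="haplotype group"):
            haplotype_contrast(geno, ["s0", "s1", "s2"], pheno)


class TestAccounting:
    def test_published_scale_category_totals(self):
        """The five per-category counts sum to the atlas grand total."""
        counts = {"mean": 77, "LP": 107, "environment-specific": 333,
                  "condition-specific": 1070, "grain-width": 115}
        qtl = []
        k = 0
        for cat, n in counts.items():
            for _ in range(n):
                qtl.append(_q(f"Q{k}", "chr01", 1 + 200 * k, 100 + 200 * k,
                              cat=cat))
                k += 1
        out = category_accounting(qtl)
        assert out["total"] == 1702
        chalkiness = out["total"] - out["grain-width"]
        assert chalkiness == 1587
        for cat, n in counts.items():
            assert out[cat] == n

    def test_empty_list_gives_zero_total(self):
        assert category_accounting([]) == {"total": 0}

    def test_untagged_qtl_rejected(self):
        with pytest.raises(ValueError, match="category"):
            category_accounting([_q("Q1", "chr01", 1, 10, cat="")])
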