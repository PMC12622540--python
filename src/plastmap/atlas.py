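"""QTL atlas construction: regions, hotspots, genes, and trade-off profiles.

Significant SNPs from each association scan are clustered into QTL
intervals; QTL from different scans (mean, linear/nonlinear plasticity,
environment-specific, condition-specific, grain-width) that overlap on a
chromosome are condensed into hotspot QTL (H-QTL) as connected components
of the interval-overlap graph. Hotspots covering more than three member
QTL are flagged as key hotspots. Candidate genes are genes intersecting
20-kb windows centred on significant SNPs; per-SNP effect signs across the
mean and plasticity scans classify loci as antagonistic (trade-off),
concordant, or neutral.

All coordinates are 1-based inclusive internally; BED export converts to
0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix
from .gwas import GwasResult

__all__ = [
    "QtlRegion",
    "Hotspot",
    "call_qtl_regions",
    "condense_hotspots",
    "candidate_genes",
    "subphenotype_overlap",
    "haplotype_contrast",
    "effect_sign_tradeoff",
    "category_accounting",
]

logger = logging.getLogger(__name__)


@dataclass
class QtlRegion:
    qtl_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    lead_snp: str
    lead_p: float
    category: str
    trait: str = ""
    scan: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.qtl_id}: start {self.start} > end {self.end}")


@dataclass
class Hotspot:
    hqtl_id: str
    chrom: str
    start: int
    end: int
    member_qtl: list[str]

    @property
    def n_members(self) -> int:
        return len(self.member_qtl)

    @property
    def is_key(self) -> bool:
        """Key hotspots cover more than three member QTL."""
        return self.n_members > 3


def call_qtl_regions(
    result: GwasResult,
    threshold: float,
    merge_kb: float = 200.0,
    pad_kb: float | None = None,
    id_prefix: str = "Q",
) -> list[QtlRegion]:
    """Cluster significant SNPs into QTL intervals.

    SNPs below ``threshold`` on the same chromosome are merged when within
    ``merge_kb`` of each other; each cluster becomes a region spanning its
    min/max SNP positions padded by ``pad_kb`` (default merge_kb / 2) on
    both sides, floored at 1. The lead SNP is the smallest p (tie: smallest
    position).
    """
    pad = int((merge_kb / 2 if pad_kb is None else pad_kb) * 1000)
    merge = merge_kb * 1000.0
    tab = result.table
    sig = tab[tab["p"] <= threshold].sort_values(["chrom", "pos"])
    regions: list[QtlRegion] = []
    counter = 0
    for chrom, grp in sig.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > merge)
        bounds = np.concatenate([[0], breaks + 1, [len(pos)]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            cluster = grp.iloc[a:b]
            lead = cluster.sort_values(["p", "pos"]).iloc[0]
            counter += 1
            regions.append(
                QtlRegion(
                    qtl_id=f"{id_prefix}{counter}",
                    chrom=str(chrom),
                    # closed interval of width 2*pad around a lone SNP:
                    # [pos - pad + 1, pos + pad]
                    start=max(1, int(cluster["pos"].min()) - pad + 1),
                    end=int(cluster["pos"].max()) + pad,
                    lead_snp=str(lead["snp_id"]),
                    lead_p=float(lead["p"]),
                    category=result.category,
                    trait=result.trait,
                    scan=result.condition or result.category,
                )
            )
    return regions


def condense_hotspots(
    qtl: list[QtlRegion], min_members: int = 2, pairwise: bool = False
) -> list[Hotspot]:
    """Merge overlapping QTL into hotspot H-QTL.

    Default semantics: connected components of the pairwise interval-
    overlap graph per chromosome (overlap chains transitively — a cluster
    of QTL forms one hotspot even when its extremes do not touch).
    ``pairwise=True`` instead requires every member to overlap the running
    hotspot span. Components with fewer than ``min_members`` QTL are not
    reported. Output is order-invariant: members and hotspots are sorted
    by coordinate.
    """
    by_chrom: dict[str, list[QtlRegion]] = {}
    for q in qtl:
        by_chrom.setdefault(q.chrom, []).append(q)

    hotspots: list[Hotspot] = []
    for chrom in sorted(by_chrom):
        regs = sorted(by_chrom[chrom], key=lambda q: (q.start, q.end, q.qtl_id))
        # sweep: intervals sorted by start; a new component begins when the
        # next start exceeds the running max end (closed-interval overlap)
        comp: list[QtlRegion] = []
        max_end = min_end = None
        comps: list[list[QtlRegion]] = []
        for q in regs:
            # transitive mode: overlap any member (q.start <= max end);
            # pairwise mode: overlap every member (q.start <= min end)
            bound = min_end if pairwise else max_end
            if bound is None or q.start <= bound:
                comp.append(q)
                max_end = q.end if max_end is None else max(max_end, q.end)
                min_end = q.end if min_end is None else min(min_end, q.end)
            else:
                comps.append(comp)
                comp, max_end, min_end = [q], q.end, q.end
        if comp:
            comps.append(comp)
        for members in comps:
            if len(members) < min_members:
                continue
            hotspots.append(
                Hotspot(
                    hqtl_id="",
                    chrom=chrom,
                    start=min(q.start for q in members),
                    end=max(q.end for q in members),
                    member_qtl=sorted(q.qtl_id for q in members),
                )
            )
    hotspots.sort(key=lambda h: (h.chrom, h.start, h.end))
    for k, h in enumerate(hotspots, start=1):
        h.hqtl_id = f"HQTL{k}"
    return hotspots


def candidate_genes(
    snps: pd.DataFrame, genes: pd.DataFrame, window_bp: int = 20_000
) -> pd.DataFrame:
    """Genes intersecting windows centred on significant SNPs.

    ``snps`` needs columns snp_id, chrom, pos; ``genes`` needs gene_id,
    chrom, start, end (1-based inclusive, e.g. from
    :func:`plastmap.io.read_gff3_genes`). A gene is reported when its span
    intersects [pos - window_bp/2, pos + window_bp/2] (closed intervals —
    a gene ending exactly at the window edge is included). Returns one row
    per (gene, SNP) pair.
    """
    half = window_bp // 2
    out = []
    for chrom, snp_grp in snps.groupby("chrom"):
        gsub = genes[genes["chrom"] == chrom]
        if gsub.empty:
            continue
        gs = gsub["start"].to_numpy()
        ge = gsub["end"].to_numpy()
        for _, s in snp_grp.iterrows():
            lo, hi = s["pos"] - half, s["pos"] + half
            hit = (gs <= hi) & (ge >= lo)
            for _, g in gsub[hit].iterrows():
                out.append(
                    {
                        "gene_id": g["gene_id"],
                        "chrom": chrom,
                        "start": int(g["start"]),
                        "end": int(g["end"]),
                        "snp_id": s["snp_id"],
                        "snp_pos": int(s["pos"]),
                        "window_bp": window_bp,
                    }
                )
    return pd.DataFrame(
        out,
        columns=["gene_id", "chrom", "start", "end", "snp_id", "snp_pos",
                 "window_bp"],
    )


def subphenotype_overlap(mean_set, lp_set, nlp_set) -> dict[str, int]:
    """Venn-region counts for mean / LP / NLP candidate-gene sets.

    Inputs may be DataFrames from :func:`candidate_genes` (the gene_id
    column is used) or plain iterables of gene ids.
    """

    def ids(x):
        if isinstance(x, pd.DataFrame):
            return set(x["gene_id"]) if len(x) else set()
        return set(x)

    a, b, c = ids(mean_set), ids(lp_set), ids(nlp_set)
    abc = a & b & c
    return {
        "mean_only": len(a - b - c),
        "lp_only": len(b - a - c),
        "nlp_only": len(c - a - b),
        "mean_lp": len((a & b) - c),
        "mean_nlp": len((a & c) - b),
        "lp_nlp": len((b & c) - a),
        "mean_lp_nlp": len(abc),
    }


def haplotype_contrast(
    geno: GenotypeMatrix,
    snp_ids: list[str],
    pheno: pd.Series,
    min_group_size: int = 10,
) -> dict:
    """Phenotype contrasts between haplotype groups at a set of SNPs.

    Accessions are grouped by their exact dosage string over ``snp_ids``;
    accessions missing any defining allele are excluded (count reported).
    Groups with at least ``min_group_size`` members are compared by
    one-way ANOVA with Tukey-Kramer family-wise adjusted pairwise
    comparisons; unadjusted two-tailed Welch t-tests are also emitted.
    """
    order = {s: k for k, s in enumerate(geno.snps["snp_id"])}
    missing = [s for s in snp_ids if s not in order]
    if missing:
        raise KeyError(f"SNPs absent from genotype matrix: {missing[:5]}")
    cols = [order[s] for s in snp_ids]
    X = geno.dosages[:, cols]
    pheno = pheno.dropna()

    hap_of: dict[str, list] = {}
    n_excluded = 0
    for i, acc in enumerate(geno.accession_ids):
        if acc not in pheno.index:
            continue
        row = X[i]
        if np.any(np.isnan(row)):
            n_excluded += 1
            continue
        key = "".join(str(int(d)) for d in row)
        hap_of.setdefault(key, []).append(float(pheno[acc]))

    groups = {k: np.asarray(v) for k, v in hap_of.items()
              if len(v) >= min_group_size}
    if len(groups) < 2:
        raise ValueError(
            f"fewer than 2 haplotype groups of size >= {min_group_size} "
            f"({len(hap_of)} raw haplotypes)"
        )
    names = sorted(groups, key=lambda k: -len(groups[k]))
    labels = [f"Hap{i + 1}" for i in range(len(names))]

    summary = pd.DataFrame(
        {
            "haplotype": labels,
            "allele_string": names,
            "n": [len(groups[k]) for k in names],
            "mean": [groups[k].mean() for k in names],
            "sd": [groups[k].std(ddof=1) for k in names],
        }
    )
    f_stat, anova_p = stats.f_oneway(*[groups[k] for k in names])

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate([groups[k] for k in names])
    grp_lab = np.concatenate(
        [[lab] * len(groups[k]) for lab, k in zip(labels, names)]
    )
    tukey = pairwise_tukeyhsd(values, grp_lab)
    tukey_df = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )

    ttests = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            t, p = stats.ttest_ind(groups[names[i]], groups[names[j]],
                                   equal_var=False)
            ttests.append({"group1": labels[i], "group2": labels[j],
                           "t": float(t), "p": float(p)})

    return {
        "summary": summary,
        "anova_F": float(f_stat),
        "anova_p": float(anova_p),
        "tukey": tukey_df,
        "ttests": pd.DataFrame(ttests),
        "n_excluded_missing": n_excluded,
    }


def effect_sign_tradeoff(
    mean_result: GwasResult,
    plasticity_result: GwasResult,
    snp_ids: list[str],
    epsilon: float = 1e-6,
) -> pd.DataFrame:
    """Classify SNPs by the signs of their mean vs plasticity effects.

    ``antagonistic`` — opposite signs, both |beta| > epsilon (trade-off);
    ``concordant`` — same sign, both above epsilon; ``neutral`` — either
    effect within epsilon of zero; ``missing`` — SNP absent from a scan.
    """
    bm = mean_result.table.set_index("snp_id")["beta"]
    bp = plasticity_result.table.set_index("snp_id")["beta"]
    rows = []
    for s in snp_ids:
        m = bm.get(s, np.nan)
        p = bp.get(s, np.nan)
        if np.isnan(m) or np.isnan(p):
            flag = "missing"
        elif abs(m) <= epsilon or abs(p) <= epsilon:
            flag = "neutral"
        elif np.sign(m) != np.sign(p):
            flag = "antagonistic"
        else:
            flag = "concordant"
        rows.append({"snp_id": s, "beta_mean": m, "beta_plasticity": p,
                     "flag": flag})
    return pd.DataFrame(rows)


def category_accounting(qtl: list[QtlRegion]) -> dict[str, int]:
    """Count QTL per scan category plus the grand total."""
    counts: dict[str, int] = {}
    for q in qtl:
        if not q.category:
            raise ValueError(f"QTL {q.qtl_id} has no category tag")
        counts[q.category] = counts.get(q.category, 0) + 1
    counts["total"] = len(qtl)
    return counts
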