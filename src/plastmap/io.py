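"""Readers and writers for the pipeline's file formats.

Genotypes travel as biallelic GT-only VCF v4.2 (read through cyvcf2) or as
a dosage TSV (header: snp_id, chrom, pos, ref, alt, then one column per
accession); phenotypes, environments and most results as TSV; QTL and
hotspot intervals as BED (0-based half-open on disk, 1-based inclusive in
memory); every pipeline run can record a JSON manifest with input
checksums for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, validate_environments, validate_phenotypes

__all__ = [
    "read_genotypes",
    "write_vcf",
    "write_dosage_tsv",
    "read_phenotypes",
    "read_environments",
    "write_bed",
    "read_gff3_genes",
    "RunManifest",
]

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    command: str
    seed: int | None = None
    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # path -> sha256
    version: str = ""
    timestamp: str = ""

    def add_input(self, path) -> None:
        h = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.inputs[str(path)] = h

    def write(self, path) -> None:
        from . import __version__

        self.version = self.version or __version__
        self.timestamp = datetime.now(timezone.utc).isoformat()
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def read_genotypes(path, fmt: str | None = None) -> GenotypeMatrix:
    """Load a genotype matrix from VCF or dosage TSV.

    ``fmt`` is inferred from the suffix when omitted. VCF records that are
    not biallelic SNPs are skipped with a count; ``./.`` calls become
    missing (NaN) dosages. Dosages are oriented to the minor allele: when
    the ALT frequency exceeds 0.5 the column is flipped (2 - dosage) so
    stored counts always refer to the minor allele.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "vcf" if path.suffix in {".vcf", ".gz", ".bcf"} else "tsv"
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise ValueError(f"failed to parse VCF header of {path}: {exc}") from exc
    samples = list(vcf.samples)
    snp_rows, dosage_cols = [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = var.gt_types.astype(float)
        dose = np.where(gt == 3, 2.0, gt)
        dose[gt == 2] = np.nan
        dosage_cols.append(dose)
        snp_rows.append(
            (var.ID or f"{var.CHROM}_{var.POS}", var.CHROM, var.POS,
             var.REF, var.ALT[0])
        )
    if n_skipped:
        logger.info("read_genotypes: skipped %d non-biallelic-SNP record(s)",
                    n_skipped)
    if not snp_rows:
        raise ValueError(f"no usable biallelic SNP records in {path}")
    snps = pd.DataFrame(snp_rows,
                        columns=["snp_id", "chrom", "pos", "ref", "alt"])
    dosages = np.column_stack(dosage_cols)
    dosages = _orient_minor(dosages)
    return GenotypeMatrix(accession_ids=samples, snps=snps, dosages=dosages)


def _orient_minor(dosages: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dosages, axis=0) / 2.0
    flip = freq > 0.5
    dosages[:, flip] = 2.0 - dosages[:, flip]
    return dosages


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["snp_id", "chrom", "pos", "ref", "alt"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise ValueError(f"dosage TSV missing column(s) {missing} in {path}")
    samples = [c for c in df.columns if c not in meta_cols]
    if not samples:
        raise ValueError(f"dosage TSV has no accession columns in {path}")
    dosages = df[samples].to_numpy(dtype=float).T
    return GenotypeMatrix(
        accession_ids=samples,
        snps=df[meta_cols].reset_index(drop=True),
        dosages=_orient_minor(dosages),
    )


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write biallelic GT-only VCF v4.2. Missing dosages become ``./.``."""
    gt_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(geno.snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.accession_ids) + "\n")
        for j, row in geno.snps.iterrows():
            calls = [
                "./." if np.isnan(d) else gt_code[float(d)]
                for d in geno.dosages[:, j]
            ]
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['snp_id']}\t{row['ref']}"
                f"\t{row['alt']}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def write_dosage_tsv(geno: GenotypeMatrix, path) -> None:
    dose = pd.DataFrame(geno.dosages.T, columns=geno.accession_ids)
    pd.concat([geno.snps.reset_index(drop=True), dose], axis=1).to_csv(
        path, sep="\t", index=False
    )


def read_phenotypes(path) -> pd.DataFrame:
    """Long-format phenotype TSV -> validated DataFrame.

    Percent-scale traits outside [0, 100] are reported through the logger
    but kept; duplicated (accession, environment, trait) keys raise.
    """
    df = pd.read_csv(path, sep="\t", dtype={"accession": str,
                                            "environment": str, "trait": str})
    bad = validate_phenotypes(df)
    if len(bad):
        logger.warning("read_phenotypes: %d percent-trait value(s) outside "
                       "[0, 100] in %s", len(bad), path)
    return df


def read_environments(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"environment": str})
    validate_environments(df)
    return df


def write_bed(intervals, path) -> None:
    """QTL or hotspot intervals -> BED (0-based half-open, sorted).

    The name field is ``id|category|n_members`` — category for QTL
    regions, member count for hotspots (the other slot left blank).
    """
    rows = []
    for iv in intervals:
        if hasattr(iv, "member_qtl"):  # Hotspot
            name = f"{iv.hqtl_id}||{iv.n_members}"
        else:  # QtlRegion
            name = f"{iv.qtl_id}|{iv.category}|"
        rows.append((iv.chrom, iv.start - 1, iv.end, name))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w") as fh:
        for chrom, start, end, name in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def read_gff3_genes(path) -> pd.DataFrame:
    """Gene features from a GFF3 file -> (gene_id, chrom, start, end).

    Malformed records are skipped with a warning count. Coordinates stay
    1-based inclusive, as in the file.
    """
    rows = []
    n_bad = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                n_bad += 1
                continue
            chrom, _, ftype, start, end, _, _, _, attrs = parts
            if ftype != "gene":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                n_bad += 1
                continue
            gene_id = None
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    gene_id = kv[3:]
                    break
            if gene_id is None:
                n_bad += 1
                continue
            rows.append({"gene_id": gene_id, "chrom": chrom,
                         "start": start_i, "end": end_i})
    if n_bad:
        logger.warning("read_gff3_genes: skipped %d malformed record(s)", n_bad)
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])
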