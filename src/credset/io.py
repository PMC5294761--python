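"""Readers and writers for the pipeline's on-disk formats.

Everything tabular is tab-separated with an explicit header; BED files
are 0-based half-open; VCF is 1-based with GT genotypes (parsed back
with cyvcf2).  Floats are written at full precision so write/read
round-trips are lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .finemap import CredibleSet
from .enrich import EnrichmentModel
from .simulate import SimTruth

__all__ = [
    "read_summary_stats",
    "write_summary_stats",
    "read_annotation_matrix",
    "write_annotation_matrix",
    "read_segments_bed",
    "write_segments_bed",
    "read_allele_counts",
    "write_allele_counts",
    "read_expression",
    "write_expression",
    "read_covariates",
    "write_covariates",
    "read_genotypes_vcf",
    "write_genotypes_vcf",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "write_posterior_table",
    "read_posterior_table",
    "write_credible_sets",
    "read_credible_sets",
    "write_model",
    "read_model",
    "write_truth",
    "read_truth",
]


def _read_tsv(path, required: list[str], numeric: list[str] = ()) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in ("chrom",)})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for c in numeric:
        if c in df.columns:
            vals = pd.to_numeric(df[c], errors="coerce")
            bad = vals.isna() & df[c].notna()
            if bad.any():
                row = int(np.flatnonzero(bad)[0]) + 2  # header is line 1
                raise ValueError(f"{path}: non-numeric value in column '{c}' at line {row}")
            df[c] = vals
    return df


def read_summary_stats(path) -> pd.DataFrame:
    """Summary-statistics TSV; needs either z or beta+se."""
    df = _read_tsv(
        path,
        required=["variant_id", "chrom", "pos", "signal_id"],
        numeric=["pos", "z", "beta", "se"],
    )
    if "z" not in df.columns and not {"beta", "se"}.issubset(df.columns):
        raise ValueError(f"{path}: needs a 'z' column or 'beta' and 'se' columns")
    return df


def write_summary_stats(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_annotation_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="variant_id")
    return df.astype(np.int8)


def write_annotation_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index=True, index_label="variant_id")


def read_segments_bed(path, cell_type: str | None = None) -> pd.DataFrame:
    """BED4 (chrom, start, end, state) or BED5 with cell_type in column 5."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] == 4:
        if cell_type is None:
            raise ValueError(f"{path}: BED4 input needs an explicit cell_type")
        df.columns = ["chrom", "start", "end", "state"]
        df["cell_type"] = cell_type
    elif df.shape[1] >= 5:
        df = df.iloc[:, :5]
        df.columns = ["chrom", "start", "end", "state", "cell_type"]
    else:
        raise ValueError(f"{path}: expected BED4 or BED5")
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def write_segments_bed(segments: pd.DataFrame, path, with_cell_type: bool = True) -> None:
    cols = ["chrom", "start", "end", "state"] + (["cell_type"] if with_cell_type else [])
    segments[cols].to_csv(path, sep="\t", index=False, header=False)


def read_allele_counts(path) -> pd.DataFrame:
    df = _read_tsv(
        path,
        required=["variant_id", "sample_id", "ref_count", "alt_count", "het_flag"],
        numeric=["ref_count", "alt_count"],
    )
    df["het_flag"] = df["het_flag"].astype(bool)
    return df


def write_allele_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_expression(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression TSV (feature_id, chrom, tss, <sample columns>).

    Returns (values features x samples, feature metadata).
    """
    df = _read_tsv(path, required=["feature_id", "chrom", "tss"], numeric=["tss"])
    features = df[["feature_id", "chrom", "tss"]].copy()
    values = df.drop(columns=["chrom", "tss"]).set_index("feature_id")
    return values.astype(float), features


def write_expression(values: pd.DataFrame, features: pd.DataFrame, path) -> None:
    out = features.set_index("feature_id").join(values)
    out.to_csv(path, sep="\t", index=True, index_label="feature_id")


def read_covariates(path) -> pd.DataFrame:
    df = _read_tsv(path, required=["sample_id"])
    return df.set_index("sample_id").astype(float)


def write_covariates(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=True, index_label="sample_id")


def write_genotypes_vcf(genotypes: pd.DataFrame, variants: pd.DataFrame, path) -> None:
    """Dosage matrix (0/1/2) as a minimal VCF with GT fields."""
    samples = list(genotypes.columns)
    vmeta = variants.set_index("variant_id")
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for vid, row in genotypes.iterrows():
            meta = vmeta.loc[vid]
            ref = meta.get("ref", "A")
            alt = meta.get("alt", "G")
            gts = "\t".join(gt_map[int(round(d))] for d in row)
            fh.write(
                f"{meta['chrom']}\t{int(meta['pos'])}\t{vid}\t{ref}\t{alt}\t.\t.\t.\tGT\t{gts}\n"
            )


def read_genotypes_vcf(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parse GT genotypes into a dosage matrix (variants x samples)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, meta = [], []
    for rec in vcf:
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        dosage = np.where(rec.gt_types == 3, 2, np.where(rec.gt_types == 1, 1, 0))
        rows.append(dosage)
        meta.append((rec.ID, rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
    variants = pd.DataFrame(meta, columns=["variant_id", "chrom", "pos", "ref", "alt"])
    genotypes = pd.DataFrame(
        np.array(rows, dtype=float), index=variants["variant_id"].to_list(), columns=samples
    )
    return genotypes, variants


def read_dosage_tsv(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    df = _read_tsv(path, required=["variant_id", "chrom", "pos"], numeric=["pos"])
    variants = df[["variant_id", "chrom", "pos"]].copy()
    genotypes = df.drop(columns=["chrom", "pos"]).set_index("variant_id").astype(float)
    return genotypes, variants


def write_dosage_tsv(genotypes: pd.DataFrame, variants: pd.DataFrame, path) -> None:
    out = variants.set_index("variant_id").join(genotypes)
    out.to_csv(path, sep="\t", index=True, index_label="variant_id")


def write_posterior_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_posterior_table(path) -> pd.DataFrame:
    return _read_tsv(
        path,
        required=["variant_id", "signal_id", "log_abf", "posterior"],
        numeric=["log_abf", "abf_log10", "prior", "posterior"],
    )


def write_credible_sets(sets: dict[str, CredibleSet], path) -> None:
    with open(path, "w") as fh:
        json.dump({sid: cs.to_dict() for sid, cs in sets.items()}, fh, indent=1)


def read_credible_sets(path) -> dict[str, CredibleSet]:
    with open(path) as fh:
        raw = json.load(fh)
    return {
        sid: CredibleSet(
            signal_id=d["signal_id"],
            level=d["level"],
            variant_ids=d["variant_ids"],
            cumulative=d["cumulative"],
            posteriors=d.get("posteriors", []),
        )
        for sid, d in raw.items()
    }


def write_model(model: EnrichmentModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=1)


def read_model(path) -> EnrichmentModel:
    with open(path) as fh:
        return EnrichmentModel.from_dict(json.load(fh))


def write_truth(truth: SimTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1)


def read_truth(path) -> SimTruth:
    with open(path) as fh:
        return SimTruth.from_dict(json.load(fh))
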