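"""Allelic imbalance in chromatin accessibility at heterozygous sites.

At a heterozygous variant, accessibility reads carrying each allele
should split 50:50 unless the variant itself perturbs local chromatin.
Counts from heterozygote samples are pooled per variant and tested with
an exact binomial test against p = 0.5; the direction of any imbalance
is reported relative to the variant's designated risk allele.

A variant is testable when enough heterozygote samples each carry
enough reads at the variant base (by default: at least 5 reads in at
least 3 samples).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ImbalanceResult",
    "filter_testable_variants",
    "pooled_binomial_test",
    "analyze_allelic_imbalance",
    "imbalance_report",
]

COUNT_COLUMNS = ["variant_id", "sample_id", "ref_count", "alt_count", "het_flag"]


@dataclass
class ImbalanceResult:
    variant_id: str
    n_het_samples_passing: int
    pooled_ref: int
    pooled_alt: int
    p_value: float
    direction: str  # {"risk_lower", "risk_higher", "none"}


def _validate_counts(records: pd.DataFrame) -> None:
    missing = [c for c in COUNT_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"allele-count table missing columns: {missing}")
    for c in ("ref_count", "alt_count"):
        vals = records[c]
        if (vals < 0).any() or not (vals == vals.astype(int)).all():
            raise ValueError(f"{c} must contain nonnegative integers")


def filter_testable_variants(
    records: pd.DataFrame,
    min_reads: int = 5,
    min_het_samples: int = 3,
    mode: str = "per_sample",
) -> list[str]:
    """Variants with sufficient heterozygote read support.

    mode="per_sample" (default): keep a variant iff at least
    ``min_het_samples`` heterozygote samples each carry at least
    ``min_reads`` reads at the variant base.  mode="pooled" applies the
    looser reading: total reads >= ``min_reads`` summed over at least
    ``min_het_samples`` het samples with any coverage.

    Non-heterozygote records are ignored.  The filter is monotone:
    adding reads never drops a retained variant.
    """
    if mode not in {"per_sample", "pooled"}:
        raise ValueError(f"unknown filter mode: {mode!r}")
    _validate_counts(records)
    het = records[records["het_flag"].astype(bool)].copy()
    het["depth"] = het["ref_count"] + het["alt_count"]
    out = []
    for vid, grp in het.groupby("variant_id", sort=True):
        if mode == "per_sample":
            ok = (grp["depth"] >= min_reads).sum() >= min_het_samples
        else:
            covered = grp[grp["depth"] > 0]
            ok = len(covered) >= min_het_samples and covered["depth"].sum() >= min_reads
        if ok:
            out.append(str(vid))
    return out


def pooled_binomial_test(
    records: pd.DataFrame,
    risk_allele: str,
    min_reads: int = 5,
    method: str = "min_likelihood",
) -> ImbalanceResult:
    """Exact two-sided binomial test of the pooled allelic counts.

    Ref and alt counts are pooled across the heterozygote samples that
    pass the per-sample read threshold.  The default two-sided p-value
    sums the probabilities of all outcomes no more likely than the
    observed one (the usual exact-binomial convention);
    method="double" doubles the smaller tail and caps at 1.

    Direction is "risk_lower" when the risk allele carries fewer pooled
    reads than the other allele — the signature of a risk allele that
    decreases local accessibility.
    """
    if risk_allele not in {"ref", "alt"}:
        raise ValueError("risk_allele must be 'ref' or 'alt'")
    _validate_counts(records)
    het = records[records["het_flag"].astype(bool)]
    passing = het[(het["ref_count"] + het["alt_count"]) >= min_reads]
    ref = int(passing["ref_count"].sum())
    alt = int(passing["alt_count"].sum())
    total = ref + alt
    if total == 0:
        raise ValueError("pooled depth is zero; variant should not have passed the filter")
    if method == "min_likelihood":
        p = binomtest(alt, total, 0.5).pvalue
    elif method == "double":
        from scipy.stats import binom

        p = min(1.0, 2.0 * min(binom.cdf(alt, total, 0.5), binom.sf(alt - 1, total, 0.5)))
    else:
        raise ValueError(f"unknown p-value method: {method!r}")
    risk_count, other_count = (ref, alt) if risk_allele == "ref" else (alt, ref)
    if risk_count < other_count:
        direction = "risk_lower"
    elif risk_count > other_count:
        direction = "risk_higher"
    else:
        direction = "none"
    return ImbalanceResult(
        variant_id=str(records["variant_id"].iloc[0]),
        n_het_samples_passing=int(len(passing)),
        pooled_ref=ref,
        pooled_alt=alt,
        p_value=float(p),
        direction=direction,
    )


def analyze_allelic_imbalance(
    counts: pd.DataFrame,
    variants: pd.DataFrame,
    min_reads: int = 5,
    min_het_samples: int = 3,
    filter_mode: str = "per_sample",
    method: str = "min_likelihood",
    include_indels: bool = False,
) -> pd.DataFrame:
    """Filter and test every variant; returns one row per retained variant.

    ``variants`` names each variant's ref/alt alleles and risk allele
    ("ref" or "alt").  Indels are excluded by default because their
    allelic coverage cannot be counted reliably.
    """
    required = {"variant_id", "risk_allele"}
    missing = required - set(variants.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    vmeta = variants.set_index("variant_id")
    if not include_indels and {"ref", "alt"}.issubset(variants.columns):
        snv = (vmeta["ref"].str.len() == 1) & (vmeta["alt"].str.len() == 1)
        vmeta = vmeta[snv]
    keep = filter_testable_variants(counts, min_reads, min_het_samples, filter_mode)
    rows = []
    for vid in keep:
        if vid not in vmeta.index:
            continue
        res = pooled_binomial_test(
            counts[counts["variant_id"] == vid],
            risk_allele=str(vmeta.loc[vid, "risk_allele"]),
            min_reads=min_reads,
            method=method,
        )
        rows.append(res.__dict__)
    return pd.DataFrame(
        rows,
        columns=[
            "variant_id",
            "n_het_samples_passing",
            "pooled_ref",
            "pooled_alt",
            "p_value",
            "direction",
        ],
    )


def imbalance_report(results: pd.DataFrame, bh: bool = False) -> pd.DataFrame:
    """Results sorted by p-value, optionally with a Benjamini–Hochberg
    q-value column (off by default; raw p-values are the primary output)."""
    if len(results) == 0:
        raise ValueError("no imbalance results to report")
    report = results.sort_values(["p_value", "variant_id"], kind="mergesort").reset_index(
        drop=True
    )
    if bh:
        report["q_value"] = multipletests(report["p_value"], method="fdr_bh")[1]
    return report
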