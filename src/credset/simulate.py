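"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the study designs the pipeline is meant for:

* per-signal GWAS z-score vectors with exactly one causal variant per
  signal, whose placement is tilted by binary annotations with known
  log-enrichments (49 signals of 50 variants by default, mirroring a
  dense fine-mapping array of 49 association signals);
* chromatin-state segmentations over 12 cell types with active
  enhancer / weak enhancer / active promoter states, including
  active-enhancer runs longer than 3 kb (stretch enhancers);
* binomial allelic read counts at heterozygous sites across 23
  heterozygote samples, with a configurable true allelic ratio tied to
  each variant's designated risk allele;
* an expression dataset with a per-allele genotype effect plus age and
  sex covariate effects and unit-SD Gaussian noise.

Everything is drawn from ``numpy.random.default_rng`` seeded from the
configuration, so identical configurations give identical outputs, and
the accompanying :class:`SimTruth` records every quantity a downstream
recovery test needs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "SimTruth",
    "EqtlDataset",
    "simulate_signals",
    "simulate_chromatin_states",
    "simulate_allele_counts",
    "simulate_eqtl_dataset",
]

_BASES = np.array(list("ACGT"))

# distinct sub-streams per operation so each draw is reproducible on its own
_STREAM = {"signals": 1, "chromatin": 2, "ase": 3, "eqtl": 4}


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic generator.

    Defaults are the emulated study's conditions: 49 association
    signals, one annotation with log-enrichment ln 4 hitting 10% of
    variants, causal z-scores centred at 5, 12 cell types, a 0.3 true
    allelic ratio over 23 heterozygote samples, and an eQTL cohort of
    174 individuals with MAF 0.15 and a 0.15 SD-per-allele effect.
    """

    # fine-mapping signals
    n_signals: int = 49
    n_variants_per_signal: int = 50
    n_annotations: int = 1
    true_log_enrichments: tuple[float, ...] = (math.log(4.0),)
    annotation_frequency: float = 0.1
    causal_z_mean: float = 5.0
    null_z_sd: float = 1.0
    rho: float = 0.0  # optional AR(1) on null z, LD stand-in
    # chromatin states
    n_cell_types: int = 12
    states: tuple[str, ...] = ("EnhA", "EnhWk", "TssA", "Quies")
    state_probs: tuple[float, ...] = (0.15, 0.15, 0.1, 0.6)
    segment_mean_length: float = 1800.0
    segment_max_length: int | None = None
    region_length: int = 200_000
    # allelic accessibility
    ase_true_ratio: float = 0.3
    ase_depth_mean: float = 20.0
    n_het_samples: int = 23
    # eQTL cohort
    eqtl_beta: float = 0.15
    maf: float = 0.15
    n_individuals: int = 174
    n_genes: int = 20
    age_effect: float = 0.02
    sex_effect: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_signals": self.n_signals,
            "n_variants_per_signal": self.n_variants_per_signal,
            "n_cell_types": self.n_cell_types,
            "n_individuals": self.n_individuals,
            "n_genes": self.n_genes,
            "region_length": self.region_length,
        }
        for name, v in counts.items():
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.n_annotations < 0 or self.n_het_samples < 0:
            raise ValueError("n_annotations and n_het_samples must be >= 0")
        probs = {
            "annotation_frequency": self.annotation_frequency,
            "ase_true_ratio": self.ase_true_ratio,
            "maf": self.maf,
        }
        for name, v in probs.items():
            if not (np.isfinite(v) and 0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1), got {v!r}")
        reals = [
            self.causal_z_mean, self.null_z_sd, self.eqtl_beta,
            self.age_effect, self.sex_effect, self.segment_mean_length,
            self.ase_depth_mean, self.rho, *self.true_log_enrichments,
        ]
        if not all(np.isfinite(v) for v in reals):
            raise ValueError("all real-valued parameters must be finite")
        if len(self.true_log_enrichments) != self.n_annotations:
            raise ValueError(
                "true_log_enrichments must have n_annotations entries"
            )
        if len(self.state_probs) != len(self.states) or not np.isclose(
            sum(self.state_probs), 1.0
        ):
            raise ValueError("state_probs must match states and sum to 1")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAM[stream]])


@dataclass
class SimTruth:
    """Ground truth stored alongside every generated dataset."""

    causal_index: dict[str, int] = field(default_factory=dict)
    true_log_enrichments: list[float] = field(default_factory=list)
    true_allelic_ratio: dict[str, float] = field(default_factory=dict)
    true_eqtl_beta: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimTruth":
        return cls(
            causal_index={k: int(v) for k, v in d.get("causal_index", {}).items()},
            true_log_enrichments=[float(v) for v in d.get("true_log_enrichments", [])],
            true_allelic_ratio={k: float(v) for k, v in d.get("true_allelic_ratio", {}).items()},
            true_eqtl_beta={k: float(v) for k, v in d.get("true_eqtl_beta", {}).items()},
        )


def simulate_signals(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Per-signal summary statistics with annotation-tilted causals.

    Within each signal the causal variant is drawn with probability
    proportional to exp(sum of true log-enrichments over its
    annotations); its z-score is Normal(causal_z_mean, 1) while
    non-causal z are Normal(0, null_z_sd) (optionally AR(1)-correlated
    with coefficient rho).  Annotations are independent
    Bernoulli(annotation_frequency) columns.

    Returns (summary statistics, annotation matrix, truth).
    """
    rng = config.rng("signals")
    gamma = np.asarray(config.true_log_enrichments, dtype=float)
    n, m = config.n_variants_per_signal, config.n_annotations
    truth = SimTruth(true_log_enrichments=list(gamma))
    frames, ann_blocks, ann_index = [], [], []
    for s in range(config.n_signals):
        sid = f"signal_{s:03d}"
        A = (rng.random((n, m)) < config.annotation_frequency).astype(np.int8)
        w = np.exp(A @ gamma) if m else np.ones(n)
        causal = int(rng.choice(n, p=w / w.sum()))
        truth.causal_index[sid] = causal
        z = rng.normal(0.0, config.null_z_sd, size=n)
        if config.rho != 0.0:
            for j in range(1, n):
                z[j] = config.rho * z[j - 1] + math.sqrt(1 - config.rho**2) * z[j]
        z[causal] = rng.normal(config.causal_z_mean, 1.0)
        ref_idx = rng.integers(0, 4, size=n)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
        vids = [f"{sid}_v{j:03d}" for j in range(n)]
        frames.append(
            pd.DataFrame(
                {
                    "variant_id": vids,
                    "chrom": f"chr{(s % 22) + 1}",
                    "pos": 10_000_000 + s * 2_000_000 + np.arange(n) * 2000 + 1,
                    "ref": _BASES[ref_idx],
                    "alt": _BASES[alt_idx],
                    "risk_allele": "alt",
                    "z": z,
                    "signal_id": sid,
                }
            )
        )
        ann_blocks.append(A)
        ann_index.extend(vids)
    stats = pd.concat(frames, ignore_index=True)
    annotations = pd.DataFrame(
        np.concatenate(ann_blocks, axis=0) if ann_blocks else np.zeros((0, m), np.int8),
        index=pd.Index(ann_index, name="variant_id"),
        columns=[f"A{a}" for a in range(m)],
    )
    return stats, annotations, truth


def simulate_chromatin_states(config: SimConfig) -> pd.DataFrame:
    """Chromatin-state segmentations tiling one region per cell type.

    Segments are non-overlapping, sorted, half-open and gapless within
    [0, region_length); consecutive segments never share a state, so
    run lengths are exactly the drawn lengths.  Lengths are exponential
    with mean ``segment_mean_length`` (floor 200 bp, optional cap
    ``segment_max_length``), so active-enhancer runs beyond 3 kb occur
    unless capped below it.
    """
    rng = config.rng("chromatin")
    states = list(config.states)
    probs = np.asarray(config.state_probs, dtype=float)
    out = []
    for c in range(config.n_cell_types):
        cell = f"cell_{c:02d}"
        pos, prev = 0, None
        while pos < config.region_length:
            state = states[rng.choice(len(states), p=probs)]
            while state == prev:
                state = states[rng.choice(len(states), p=probs)]
            length = int(rng.exponential(config.segment_mean_length)) + 200
            if config.segment_max_length is not None:
                length = min(length, config.segment_max_length)
            end = min(pos + length, config.region_length)
            out.append(("chr1", pos, end, state, cell))
            pos, prev = end, state
    return pd.DataFrame(out, columns=["chrom", "start", "end", "state", "cell_type"])


def simulate_allele_counts(
    config: SimConfig, variants: pd.DataFrame
) -> tuple[pd.DataFrame, SimTruth]:
    """Binomial allelic read counts at heterozygous sites.

    Per heterozygote sample, the read depth is Poisson(ase_depth_mean)
    — zero-depth rows are emitted, downstream filtering handles them —
    and the risk-allele count is Binomial(depth, ase_true_ratio).  With
    ase_true_ratio < 0.5 the risk allele is therefore the
    lower-accessibility allele; for the default risk_allele="alt"
    bookkeeping the alt count itself is Binomial(depth, ase_true_ratio).
    """
    rng = config.rng("ase")
    truth = SimTruth()
    rows = []
    risk = (
        variants["risk_allele"]
        if "risk_allele" in variants.columns
        else pd.Series("alt", index=variants.index)
    )
    for (_, v), risk_allele in zip(variants.iterrows(), risk):
        vid = str(v["variant_id"])
        truth.true_allelic_ratio[vid] = config.ase_true_ratio
        for s in range(config.n_het_samples):
            depth = int(rng.poisson(config.ase_depth_mean))
            risk_count = int(rng.binomial(depth, config.ase_true_ratio)) if depth else 0
            other = depth - risk_count
            ref_c, alt_c = (risk_count, other) if risk_allele == "ref" else (other, risk_count)
            rows.append((vid, f"het_{s:02d}", ref_c, alt_c, True))
    counts = pd.DataFrame(
        rows, columns=["variant_id", "sample_id", "ref_count", "alt_count", "het_flag"]
    )
    return counts, truth


@dataclass
class EqtlDataset:
    """Genotypes, expression, covariates and metadata for an eQTL scan."""

    genotypes: pd.DataFrame  # variants x samples, dosage 0/1/2
    variants: pd.DataFrame  # variant_id, chrom, pos
    expression: pd.DataFrame  # features x samples
    features: pd.DataFrame  # feature_id, chrom, tss
    covariates: pd.DataFrame  # samples x {age, sex}
    truth: SimTruth


def simulate_eqtl_dataset(config: SimConfig) -> EqtlDataset:
    """Expression with a per-allele genotype effect plus covariates.

    Genotypes are Binomial(2, maf) (Hardy–Weinberg); expression of gene
    g is eqtl_beta * genotype + age_effect * age + sex_effect * sex +
    Normal(0, 1) noise.  Each gene gets one cis variant 10 kb from its
    TSS so both cis-window conventions capture it.
    """
    rng = config.rng("eqtl")
    n, g = config.n_individuals, config.n_genes
    samples = [f"ind_{i:04d}" for i in range(n)]
    age = rng.normal(50.0, 10.0, size=n)
    sex = rng.integers(0, 2, size=n)
    covariates = pd.DataFrame({"age": age, "sex": sex}, index=pd.Index(samples, name="sample_id"))
    truth = SimTruth()
    geno_rows, expr_rows, var_rows, feat_rows = [], [], [], []
    for k in range(g):
        gene = f"gene_{k:03d}"
        vid = f"eqtl_v{k:03d}"
        chrom = f"chr{(k % 22) + 1}"
        tss = 1_000_000 + k * 3_000_000
        dosage = rng.binomial(2, config.maf, size=n)
        noise = rng.normal(0.0, 1.0, size=n)
        expr = config.eqtl_beta * dosage + config.age_effect * age + config.sex_effect * sex + noise
        truth.true_eqtl_beta[gene] = config.eqtl_beta
        geno_rows.append(dosage)
        expr_rows.append(expr)
        var_rows.append((vid, chrom, tss + 10_000))
        feat_rows.append((gene, chrom, tss))
    genotypes = pd.DataFrame(
        np.array(geno_rows), index=[v[0] for v in var_rows], columns=samples
    )
    expression = pd.DataFrame(
        np.array(expr_rows), index=[f[0] for f in feat_rows], columns=samples
    )
    variants = pd.DataFrame(var_rows, columns=["variant_id", "chrom", "pos"])
    features = pd.DataFrame(feat_rows, columns=["feature_id", "chrom", "tss"])
    return EqtlDataset(genotypes, variants, expression, features, covariates, truth)
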