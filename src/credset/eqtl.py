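"""Covariate-adjusted cis-eQTL linear modelling and power.

Expression features (genes or exons) are tested for association with
nearby variant dosages by ordinary least squares with covariates such
as age and sex.  Two cis-window conventions are supported: a 100 kb
window around the feature anchor (the Matrix-eQTL style cisDist) and a
1 Mb flank either side of the transcription start site.  Expression
preprocessing follows common eQTL practice: library-size scaling,
removal of features with <1 normalised count in more than 20% of
samples, and a per-feature rank-based inverse-normal transform.

Power for a single-variant test uses the noncentral chi-square
approximation with noncentrality n * beta^2 * 2 * maf * (1 - maf),
where beta is the per-allele effect in phenotype-SD units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "EqtlResult",
    "PowerSpec",
    "normalize_library_size",
    "filter_low_expression",
    "rank_inverse_normal",
    "rank_normalize",
    "cis_pairs",
    "fit_cis_eqtl",
    "CisEqtlModel",
    "CisEqtlResults",
    "eqtl_power",
]


@dataclass
class EqtlResult:
    feature_id: str
    variant_id: str
    beta: float
    se: float
    t: float
    p: float
    n: int


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of the single-variant power computation."""

    n: int
    maf: float
    beta_sd_units: float
    alpha: float

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not (0 < self.maf < 1):
            raise ValueError("maf must lie in (0, 1)")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if not np.isfinite(self.beta_sd_units):
            raise ValueError("beta must be finite")


def normalize_library_size(values: pd.DataFrame, target_total: float = 20e6) -> pd.DataFrame:
    """Scale each sample column so its counts sum to ``target_total``."""
    totals = values.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("every sample must have positive total counts")
    return values * (target_total / totals)


def filter_low_expression(
    values: pd.DataFrame, min_count: float = 1.0, max_frac_below: float = 0.20
) -> pd.DataFrame:
    """Drop features lowly expressed in too many samples.

    A feature is removed when the fraction of samples with value below
    ``min_count`` strictly exceeds ``max_frac_below`` (a feature below
    threshold in exactly 20% of samples is kept).
    """
    frac_below = (values < min_count).mean(axis=1)
    return values.loc[frac_below <= max_frac_below]


def rank_inverse_normal(values) -> np.ndarray:
    """Rank-based inverse-normal transform of one feature's values.

    Rank r of n maps to the standard-normal quantile at (r - 0.5)/n;
    ties receive their average rank.  The output depends on the input
    only through its ranks, so any strictly monotone transform of the
    input yields the identical result.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D vector")
    if np.unique(x).size < 2:
        raise ValueError("cannot rank-normalize a constant vector")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.5) / len(x))


def rank_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`rank_inverse_normal` to every feature (row)."""
    out = values.apply(lambda row: pd.Series(rank_inverse_normal(row), index=row.index), axis=1)
    return out


def cis_pairs(
    features: pd.DataFrame, variants: pd.DataFrame, mode: str = "gene_window_100kb"
) -> pd.DataFrame:
    """Feature-variant pairs within the chosen cis window.

    mode="gene_window_100kb": |variant pos - feature anchor| <= 100 kb;
    mode="tss_flank_1mb": |variant pos - TSS| <= 1 Mb.  Both boundaries
    are inclusive and the chromosome must match.
    """
    windows = {"gene_window_100kb": 100_000, "tss_flank_1mb": 1_000_000}
    if mode not in windows:
        raise ValueError(f"unknown cis-window mode: {mode!r}")
    w = windows[mode]
    anchor_col = "tss"
    if anchor_col not in features.columns:
        raise ValueError("feature table needs a 'tss' anchor position column")
    pairs = []
    for _, f in features.iterrows():
        near = variants[
            (variants["chrom"] == f["chrom"])
            & ((variants["pos"] - f[anchor_col]).abs() <= w)
        ]
        for vid in near["variant_id"]:
            pairs.append((f["feature_id"], vid))
    return pd.DataFrame(pairs, columns=["feature_id", "variant_id"])


def _check_collinear(design: pd.DataFrame) -> None:
    X = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                raise ValueError(
                    f"collinear design: column '{design.columns[j]}' is linearly "
                    "dependent on the others"
                )
        raise ValueError("collinear design matrix")


def fit_cis_eqtl(
    expression, dosage, covariates: pd.DataFrame | None = None,
    feature_id: str = "", variant_id: str = ""
) -> EqtlResult:
    """OLS of one feature's expression on one variant's dosage.

    The model is expression ~ intercept + dosage + covariates; the
    reported beta/se/t/p describe the dosage term (two-sided t-test on
    the residual degrees of freedom).  Rows with missing values in any
    of the three inputs are dropped pairwise-complete first.  An exact
    fit (zero residual variance) reports p at the smallest positive
    float rather than zero.
    """
    y = pd.Series(np.asarray(expression, dtype=float))
    g = pd.Series(np.asarray(dosage, dtype=float))
    if len(y) != len(g):
        raise ValueError("expression and dosage lengths differ")
    design = pd.DataFrame({"dosage": g})
    if covariates is not None:
        cov = covariates.reset_index(drop=True)
        if len(cov) != len(y):
            raise ValueError("covariate rows must match sample count")
        design = pd.concat([design, cov], axis=1)
    keep = y.notna() & design.notna().all(axis=1)
    y, design = y[keep], design[keep]
    n = len(y)
    if n < design.shape[1] + 2:
        raise ValueError(f"too few complete samples (n={n}) for the design")
    X = sm.add_constant(design, prepend=True)
    _check_collinear(X)
    fit = sm.OLS(y.to_numpy(), X.to_numpy()).fit()
    idx = list(X.columns).index("dosage")
    beta = float(fit.params[idx])
    se = float(fit.bse[idx])
    t = float(fit.tvalues[idx])
    p = float(fit.pvalues[idx])
    if not np.isfinite(p) or p == 0.0:
        p = float(np.finfo(float).tiny)
    return EqtlResult(feature_id, variant_id, beta, se, t, p, n)


class CisEqtlModel:
    """cis-eQTL scan: every feature against every cis variant.

    Parameters
    ----------
    expression : DataFrame, features x samples (already preprocessed).
    features : DataFrame with feature_id, chrom, tss.
    genotypes : DataFrame, variants x samples, dosages in [0, 2].
    variants : DataFrame with variant_id, chrom, pos.
    covariates : DataFrame, samples x covariates (e.g. age, sex), or None.
    mode : cis-window convention, see :func:`cis_pairs`.
    """

    def __init__(
        self,
        expression: pd.DataFrame,
        features: pd.DataFrame,
        genotypes: pd.DataFrame,
        variants: pd.DataFrame,
        covariates: pd.DataFrame | None = None,
        mode: str = "gene_window_100kb",
    ) -> None:
        samples = list(expression.columns)
        if list(genotypes.columns) != samples:
            genotypes = genotypes[samples]
        if covariates is not None:
            covariates = covariates.loc[samples]
        self.expression = expression
        self.features = features
        self.genotypes = genotypes
        self.variants = variants
        self.covariates = covariates
        self.mode = mode

    def fit(self) -> "CisEqtlResults":
        pairs = cis_pairs(self.features, self.variants, self.mode)
        cov = self.covariates.reset_index(drop=True) if self.covariates is not None else None
        rows = []
        for fid, vid in pairs.itertuples(index=False):
            res = fit_cis_eqtl(
                self.expression.loc[fid].to_numpy(),
                self.genotypes.loc[vid].to_numpy(),
                cov,
                feature_id=str(fid),
                variant_id=str(vid),
            )
            rows.append(res.__dict__)
        table = pd.DataFrame(
            rows, columns=["feature_id", "variant_id", "beta", "se", "t", "p", "n"]
        )
        return CisEqtlResults(self, table)


@dataclass
class CisEqtlResults:
    model: CisEqtlModel
    table: pd.DataFrame

    def bonferroni(self) -> pd.DataFrame:
        """Per-feature Bonferroni correction over the variants tested."""
        out = self.table.copy()
        m = out.groupby("feature_id")["p"].transform("size")
        out["p_bonferroni"] = np.minimum(out["p"] * m, 1.0)
        return out

    def summary(self, top: int = 10) -> str:
        best = self.table.sort_values("p").head(top)
        lines = [
            "cis-eQTL scan",
            "=" * 64,
            f"pairs tested: {len(self.table)}   window: {self.model.mode}",
            "-" * 64,
            f"{'feature':<14}{'variant':<16}{'beta':>9}{'se':>9}{'p':>12}",
        ]
        for r in best.itertuples(index=False):
            lines.append(
                f"{r.feature_id:<14}{r.variant_id:<16}{r.beta:>9.4f}{r.se:>9.4f}{r.p:>12.3e}"
            )
        return "\n".join(lines)


def eqtl_power(spec: PowerSpec) -> float:
    """Power of the single-variant Wald test at significance ``alpha``.

    Noncentrality n * beta^2 * 2 * maf * (1 - maf) against the 1-df
    chi-square critical value; beta in phenotype-SD units per allele.
    """
    ncp = spec.n * spec.beta_sd_units**2 * 2 * spec.maf * (1 - spec.maf)
    crit = stats.chi2.ppf(1 - spec.alpha, 1)
    return float(stats.ncx2.sf(crit, 1, ncp)) if ncp > 0 else float(spec.alpha)
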