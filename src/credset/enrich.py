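"""Hierarchical annotation-enrichment model and posterior reweighting.

Across many association signals, binary functional annotations can be
tested for enrichment among causal variants.  Under the single-causal
assumption, each variant j of a signal carries the prior

    p_j  proportional to  exp( sum_a gamma_a * A_ja ),

a multinomial-logistic prior over the variants of the signal, where
A is the binary annotation matrix and gamma the vector of log
prior-odds coefficients.  Each signal contributes

    log sum_j p_j * ABF_j

to the marginal likelihood; the total objective subtracts a ridge
penalty lambda * ||gamma||^2.  Annotations are chosen by greedy forward
selection, the penalty by k-fold cross-validation over signals, and the
model pruned by backward elimination on the cross-validation
likelihood.  The fitted coefficients then act as functional priors for
a target signal: its flat-prior posteriors are reweighted and the
credible set recomputed, typically shrinking it when the annotations
are genuinely informative.

The model/fit API follows the statsmodels convention: construct
:class:`AnnotationEnrichment` from data, call :meth:`~AnnotationEnrichment.fit`,
and read estimates off the returned :class:`EnrichmentResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .finemap import ABFConfig, credible_set, signal_posteriors, CredibleSet

__all__ = [
    "FitConfig",
    "EnrichmentModel",
    "AnnotationEnrichment",
    "EnrichmentResults",
    "model_loglik",
    "forward_select",
    "select_penalty",
    "backward_eliminate",
    "reweight_posteriors",
]

_GAMMA_BOUND = 30.0  # |gamma| cap; e^30 prior odds is effectively infinite


@dataclass(frozen=True)
class FitConfig:
    """Knobs of the selection procedure.

    lambda_grid : candidate ridge penalties for cross-validation.
    n_folds : folds over signals (signals, not variants, are the
        independent units).
    forward_tolerance : minimum log-likelihood gain (in log units) for
        forward selection to add an annotation; 2 is an AIC-like choice.
    seed : seeds the fold assignment (deterministic given signal ids).
    penalize_forward : apply the first grid penalty during forward
        selection instead of selecting unpenalized.
    """

    lambda_grid: tuple[float, ...] = (0.01, 0.05, 0.1, 0.25, 0.5, 1.0)
    n_folds: int = 10
    forward_tolerance: float = 2.0
    max_iter: int = 500
    convergence_tol: float = 1e-8
    seed: int = 0
    penalize_forward: bool = False

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if len(self.lambda_grid) == 0:
            raise ValueError("lambda_grid must be non-empty")
        if any(l < 0 for l in self.lambda_grid):
            raise ValueError("penalties must be nonnegative")


@dataclass
class EnrichmentModel:
    """Selected annotations with their log prior-odds coefficients."""

    annotations: list[str]
    gamma: np.ndarray
    penalty: float
    loglik: float
    cv_loglik: float

    def to_dict(self) -> dict:
        return {
            "annotations": list(self.annotations),
            "gamma": [float(g) for g in self.gamma],
            "penalty": float(self.penalty),
            "loglik": float(self.loglik),
            "cv_loglik": float(self.cv_loglik),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnrichmentModel":
        return cls(
            annotations=list(d["annotations"]),
            gamma=np.asarray(d["gamma"], dtype=float),
            penalty=float(d["penalty"]),
            loglik=float(d["loglik"]),
            cv_loglik=float(d["cv_loglik"]),
        )


def _segments(signal_ids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start offsets of each contiguous signal block (input pre-sorted)."""
    change = np.flatnonzero(np.r_[True, signal_ids[1:] != signal_ids[:-1]])
    counts = np.diff(np.r_[change, len(signal_ids)])
    return change, counts


def _seg_logsumexp(x: np.ndarray, starts: np.ndarray, counts: np.ndarray) -> np.ndarray:
    m = np.maximum.reduceat(x, starts)
    rep = np.repeat(m, counts)
    return m + np.log(np.add.reduceat(np.exp(x - rep), starts))


def _seg_softmax(x: np.ndarray, starts: np.ndarray, counts: np.ndarray) -> np.ndarray:
    lse = _seg_logsumexp(x, starts, counts)
    return np.exp(x - np.repeat(lse, counts))


class AnnotationEnrichment:
    """Enrichment model over many fine-mapped signals.

    Parameters
    ----------
    posteriors : DataFrame
        Per-variant table with ``variant_id``, ``signal_id`` and
        ``log_abf`` columns (the output of
        :func:`credset.finemap.finemap_signals`).
    annotations : DataFrame
        Binary annotation matrix indexed by variant_id (from
        :func:`credset.annot.build_annotation_matrix`).
    config : FitConfig
    """

    def __init__(
        self,
        posteriors: pd.DataFrame,
        annotations: pd.DataFrame,
        config: FitConfig = FitConfig(),
    ) -> None:
        required = {"variant_id", "signal_id", "log_abf"}
        missing = required - set(posteriors.columns)
        if missing:
            raise ValueError(f"posterior table missing columns: {sorted(missing)}")
        work = posteriors.sort_values("signal_id", kind="mergesort").reset_index(drop=True)
        absent = set(work["variant_id"]) - set(annotations.index)
        if absent:
            raise ValueError(
                f"annotation matrix missing rows for variants: {sorted(absent)[:5]}"
            )
        A = annotations.reindex(work["variant_id"])
        self.config = config
        self.column_names: list[str] = list(annotations.columns)
        self._A = A.to_numpy(dtype=float)
        self._log_abf = work["log_abf"].to_numpy(dtype=float)
        sids = work["signal_id"].to_numpy()
        self._starts, self._counts = _segments(sids)
        self.signal_ids = sids[self._starts]
        self.n_signals = len(self.signal_ids)

    # ---- likelihood -------------------------------------------------

    def _cols(self, names: list[str]) -> np.ndarray:
        try:
            idx = [self.column_names.index(n) for n in names]
        except ValueError as e:
            raise ValueError(f"unknown annotation column: {e}") from None
        return self._A[:, idx]

    def _loglik_grad(
        self,
        gamma: np.ndarray,
        A: np.ndarray,
        lam: float,
        mask: np.ndarray | None = None,
    ) -> tuple[float, np.ndarray]:
        """Penalized log-likelihood and its gradient.

        ``mask`` restricts to a boolean subset of rows/signals (used for
        cross-validation); the penalty always applies in full.
        """
        log_abf, starts, counts = self._log_abf, self._starts, self._counts
        if mask is not None:
            log_abf = log_abf[mask]
            A = A[mask]
            starts, counts = _segments(np.repeat(np.arange(len(self._starts)), self._counts)[mask])
        eta = A @ gamma
        q = _seg_softmax(log_abf + eta, starts, counts)
        p = _seg_softmax(eta, starts, counts)
        ll = float(
            np.sum(_seg_logsumexp(log_abf + eta, starts, counts))
            - np.sum(_seg_logsumexp(eta, starts, counts))
        )
        grad = (q - p) @ A
        return ll - lam * float(gamma @ gamma), grad - 2.0 * lam * gamma

    def loglik(
        self,
        gamma,
        lam: float = 0.0,
        columns: list[str] | None = None,
        signal_mask: np.ndarray | None = None,
    ) -> float:
        """Penalized marginal log-likelihood at ``gamma``."""
        columns = columns if columns is not None else self.column_names
        gamma = np.asarray(gamma, dtype=float)
        if gamma.shape != (len(columns),):
            raise ValueError(
                f"gamma has {gamma.shape} entries for {len(columns)} annotation columns"
            )
        mask = None
        if signal_mask is not None:
            mask = np.repeat(np.asarray(signal_mask, bool), self._counts)
        return self._loglik_grad(gamma, self._cols(columns), lam, mask)[0]

    def fit_gamma(
        self,
        columns: list[str],
        lam: float,
        signal_mask: np.ndarray | None = None,
    ) -> tuple[np.ndarray, float]:
        """Maximise the penalized log-likelihood over ``gamma``."""
        if not columns:
            empty = np.zeros(0)
            return empty, self._flat_loglik(signal_mask)
        A = self._cols(columns)
        mask = None
        if signal_mask is not None:
            mask = np.repeat(np.asarray(signal_mask, bool), self._counts)

        def objective(g):
            ll, grad = self._loglik_grad(g, A, lam, mask)
            return -ll, -grad

        res = minimize(
            objective,
            x0=np.zeros(len(columns)),
            jac=True,
            method="L-BFGS-B",
            bounds=[(-_GAMMA_BOUND, _GAMMA_BOUND)] * len(columns),
            options={
                "maxiter": self.config.max_iter,
                "gtol": self.config.convergence_tol,
                "ftol": 1e-14,
            },
        )
        return res.x, float(-res.fun)

    def _flat_loglik(self, signal_mask: np.ndarray | None = None) -> float:
        mask = None
        if signal_mask is not None:
            mask = np.repeat(np.asarray(signal_mask, bool), self._counts)
        return self._loglik_grad(np.zeros(0), self._A[:, :0], 0.0, mask)[0]

    # ---- folds ------------------------------------------------------

    def cv_folds(self) -> list[np.ndarray]:
        """Deterministic fold assignment: a function of (seed, signal ids)."""
        order = np.argsort(self.signal_ids.astype(str), kind="mergesort")
        rng = np.random.default_rng(self.config.seed)
        perm = order[rng.permutation(self.n_signals)]
        n_folds = min(self.config.n_folds, self.n_signals)
        return [np.sort(chunk) for chunk in np.array_split(perm, n_folds)]

    def cv_loglik(self, columns: list[str], lam: float) -> float:
        """Summed held-out (unpenalized) log-likelihood across folds."""
        total = 0.0
        for fold in self.cv_folds():
            train = np.ones(self.n_signals, dtype=bool)
            train[fold] = False
            test = ~train
            gamma, _ = self.fit_gamma(columns, lam, signal_mask=train)
            if columns:
                total += self.loglik(gamma, 0.0, columns, signal_mask=test)
            else:
                total += self._flat_loglik(signal_mask=test)
        return total

    # ---- selection stages -------------------------------------------

    def forward_select(self, lam: float | None = None) -> tuple[list[str], np.ndarray]:
        """Greedily add annotations while the penalized gain exceeds
        ``forward_tolerance``; ties go to the earlier column."""
        if self.n_signals < 2:
            raise ValueError("annotation selection needs at least 2 signals")
        if lam is None:
            lam = self.config.lambda_grid[0] if self.config.penalize_forward else 0.0
        selected: list[str] = []
        gamma = np.zeros(0)
        current = self._flat_loglik()
        while True:
            best_gain, best_col, best_fit = 0.0, None, None
            for col in self.column_names:
                if col in selected:
                    continue
                g, ll = self.fit_gamma(selected + [col], lam)
                gain = ll - current
                if gain > best_gain + 1e-12 and gain >= self.config.forward_tolerance:
                    best_gain, best_col, best_fit = gain, col, (g, ll)
            if best_col is None:
                break
            selected.append(best_col)
            gamma, current = best_fit
        return selected, gamma

    def select_penalty(self, columns: list[str]) -> float:
        """Pick the grid penalty with the highest cross-validation
        likelihood (largest penalty wins ties, shrinking to zero)."""
        grid = self.config.lambda_grid
        if len(grid) == 1 or not columns:
            return grid[-1] if not columns else grid[0] if len(grid) == 1 else grid[-1]
        best_lam, best_cv = None, -np.inf
        for lam in grid:
            cv = self.cv_loglik(columns, lam)
            if cv >= best_cv:  # >= : prefer the larger penalty on ties
                best_cv, best_lam = cv, lam
        return float(best_lam)

    def backward_eliminate(
        self, columns: list[str], lam: float
    ) -> tuple[list[str], np.ndarray]:
        """Drop annotations while doing so raises the CV likelihood."""
        columns = list(columns)
        if not columns:
            return [], np.zeros(0)
        current_cv = self.cv_loglik(columns, lam)
        while columns:
            best_cv, best_drop = current_cv, None
            for col in columns:
                reduced = [c for c in columns if c != col]
                cv = self.cv_loglik(reduced, lam)
                if cv > best_cv + 1e-12:
                    best_cv, best_drop = cv, col
            if best_drop is None:
                break
            columns.remove(best_drop)
            current_cv = best_cv
        gamma, _ = self.fit_gamma(columns, lam)
        return columns, gamma

    # ---- the statsmodels-style entry point --------------------------

    def fit(self) -> "EnrichmentResults":
        """Run forward selection, penalty cross-validation and backward
        elimination; refit the surviving model on all signals."""
        selected, _ = self.forward_select()
        lam = self.select_penalty(selected)
        selected, gamma = self.backward_eliminate(selected, lam)
        gamma, loglik = self.fit_gamma(selected, lam)
        cv = self.cv_loglik(selected, lam)
        model = EnrichmentModel(
            annotations=selected,
            gamma=gamma,
            penalty=lam,
            loglik=loglik,
            cv_loglik=cv,
        )
        return EnrichmentResults(self, model)


@dataclass
class EnrichmentResults:
    """Fitted enrichment model plus reweighting helpers."""

    model_obj: AnnotationEnrichment
    model: EnrichmentModel

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.model.gamma, index=self.model.annotations, name="gamma")

    @property
    def penalty(self) -> float:
        return self.model.penalty

    @property
    def loglik(self) -> float:
        return self.model.loglik

    @property
    def cv_loglik(self) -> float:
        return self.model.cv_loglik

    def summary(self) -> str:
        lines = [
            "Annotation enrichment model",
            "=" * 46,
            f"signals:               {self.model_obj.n_signals}",
            f"penalty (lambda):      {self.model.penalty:g}",
            f"log-likelihood:        {self.model.loglik:.6g}",
            f"CV log-likelihood:     {self.model.cv_loglik:.6g}",
            "-" * 46,
            f"{'annotation':<30}{'log-enrichment':>16}",
        ]
        if self.model.annotations:
            for name, g in zip(self.model.annotations, self.model.gamma):
                lines.append(f"{name:<30}{g:>16.4f}")
        else:
            lines.append("(no annotation retained)")
        return "\n".join(lines)

    def reweight(
        self,
        target: pd.DataFrame,
        annotations: pd.DataFrame,
        config: ABFConfig = ABFConfig(),
    ) -> tuple[pd.DataFrame, CredibleSet]:
        """Reweight one signal's posteriors with the fitted priors."""
        table = reweight_posteriors(target, annotations, self.model, config)
        return table, credible_set(table, config.level)


# ---- functional surface ---------------------------------------------


def model_loglik(posteriors, annotations, gamma, lam: float = 0.0) -> float:
    """Penalized enrichment log-likelihood at a given ``gamma``.

    ``gamma`` may be a mapping {column: coefficient} or a vector aligned
    with the annotation columns.
    """
    model = AnnotationEnrichment(posteriors, annotations)
    if isinstance(gamma, dict):
        columns = list(gamma)
        vec = np.array([gamma[c] for c in columns], dtype=float)
    else:
        columns = list(annotations.columns)
        vec = np.asarray(gamma, dtype=float)
    return model.loglik(vec, lam, columns)


def forward_select(posteriors, annotations, config: FitConfig = FitConfig()) -> EnrichmentModel:
    m = AnnotationEnrichment(posteriors, annotations, config)
    selected, gamma = m.forward_select()
    ll = m.fit_gamma(selected, 0.0)[1] if selected else m._flat_loglik()
    return EnrichmentModel(selected, gamma, 0.0, ll, np.nan)


def select_penalty(posteriors, annotations, model: EnrichmentModel, config: FitConfig = FitConfig()) -> float:
    m = AnnotationEnrichment(posteriors, annotations, config)
    return m.select_penalty(model.annotations)


def backward_eliminate(
    posteriors, annotations, model: EnrichmentModel, lam: float, config: FitConfig = FitConfig()
) -> EnrichmentModel:
    m = AnnotationEnrichment(posteriors, annotations, config)
    cols, gamma = m.backward_eliminate(model.annotations, lam)
    gamma, ll = m.fit_gamma(cols, lam)
    return EnrichmentModel(cols, gamma, lam, ll, m.cv_loglik(cols, lam))


def reweight_posteriors(
    target: pd.DataFrame,
    annotations: pd.DataFrame,
    model: EnrichmentModel,
    config: ABFConfig = ABFConfig(),
) -> pd.DataFrame:
    """Update one signal's posteriors with annotation-derived priors.

    prior_j is proportional to exp(sum_a gamma_a A_ja), normalised
    within the signal; posteriors are prior * ABF renormalised.  An
    empty model reproduces the flat-prior posteriors bitwise.
    """
    missing = [c for c in model.annotations if c not in annotations.columns]
    if missing:
        raise ValueError(f"annotation matrix missing columns: {missing}")
    absent = set(target["variant_id"]) - set(annotations.index)
    if absent:
        raise ValueError(f"annotation matrix missing rows for variants: {sorted(absent)[:5]}")
    A = annotations.reindex(target["variant_id"])[model.annotations].to_numpy(dtype=float)
    eta = A @ model.gamma if model.annotations else np.zeros(len(target))
    priors = np.exp(eta - eta.max()) if len(eta) else eta
    return signal_posteriors(target, priors=priors, config=config)
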