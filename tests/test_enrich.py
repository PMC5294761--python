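"""Annotation-enrichment likelihood, selection stages, reweighting."""

import numpy as np
import pandas as pd
import pytest

from credset.enrich import (
    AnnotationEnrichment,
    EnrichmentModel,
    FitConfig,
    backward_eliminate,
    forward_select,
    model_loglik,
    reweight_posteriors,
)
from credset.finemap import ABFConfig, credible_set, finemap_signals, signal_posteriors
from credset.simulate import SimConfig, simulate_signals

from conftest import Z_SCALE_W, make_posterior_frame


def annotation_frame(rows, columns, variant_ids):
    return pd.DataFrame(
        np.asarray(rows, dtype=np.int8),
        index=pd.Index(variant_ids, name="variant_id"),
        columns=columns,
    )


class TestModelLoglik:
    def test_flat_prior_reduces_to_log_mean_abf(self):
        post = make_posterior_frame(np.log([2.0, 1.0]))
        ann = annotation_frame([[1], [0]], ["A"], ["v0", "v1"])
        ll = model_loglik(post, ann, np.zeros(1), 0.0)
        assert ll == pytest.approx(np.log(1.5), abs=1e-12)

    def test_likelihood_increases_toward_log_max_abf(self):
        post = make_posterior_frame(np.log([2.0, 1.0]))
        ann = annotation_frame([[1], [0]], ["A"], ["v0", "v1"])
        lls = [model_loglik(post, ann, np.array([g]), 0.0) for g in (0.0, 2.0, 5.0, 10.0)]
        assert np.all(np.diff(lls) > 0)
        assert lls[-1] < np.log(2.0)  # sup as gamma -> inf

    def test_penalized_maximiser_matches_grid_search_oracle(self):
        post = make_posterior_frame(np.log([2.0, 1.0]))
        ann = annotation_frame([[1], [0]], ["A"], ["v0", "v1"])
        model = AnnotationEnrichment(post, ann)
        grid = np.arange(-2.0, 6.0, 1e-4)
        vals = [model.loglik(np.array([g]), 0.1, ["A"]) for g in grid]
        g_oracle = grid[int(np.argmax(vals))]
        g_hat, _ = model.fit_gamma(["A"], 0.1)
        assert g_hat[0] == pytest.approx(g_oracle, abs=1e-4)

    def test_dimension_mismatch_rejected(self):
        post = make_posterior_frame(np.log([2.0, 1.0]))
        ann = annotation_frame([[1], [0]], ["A"], ["v0", "v1"])
        with pytest.raises(ValueError, match="entries"):
            model_loglik(post, ann, np.zeros(3), 0.0)


class TestForwardSelection:
    def test_true_annotation_selected_noise_rejected(self, small_study):
        cfg, stats, annotations, truth, posteriors, _ = small_study
        rng = np.random.default_rng(7)
        ann = annotations.copy()
        ann["noise"] = (rng.random(len(ann)) < 0.1).astype(np.int8)
        model = forward_select(posteriors, ann, FitConfig(n_folds=5))
        assert model.annotations[:1] == ["A0"]
        assert "noise" not in model.annotations

    def test_pure_noise_usually_selects_nothing(self):
        cfg = SimConfig(
            n_signals=120, n_annotations=3, true_log_enrichments=(0.0, 0.0, 0.0), seed=21
        )
        stats, ann, _ = simulate_signals(cfg)
        post, _ = finemap_signals(stats, ABFConfig(W=Z_SCALE_W))
        model = forward_select(post, ann, FitConfig(n_folds=5))
        assert model.annotations == []

    def test_duplicate_columns_tie_broken_by_order(self, small_study):
        cfg, stats, annotations, truth, posteriors, _ = small_study
        ann = annotations.copy()
        ann["A0_copy"] = ann["A0"]
        m = AnnotationEnrichment(posteriors, ann, FitConfig(n_folds=5))
        selected, gamma = m.forward_select()
        assert selected[0] == "A0"
        assert "A0_copy" not in selected
        g_single, _ = m.fit_gamma(["A0"], 0.0)
        assert gamma[0] == pytest.approx(g_single[0], abs=1e-6)


class TestPenaltyAndBackward:
    def test_single_value_grid_returned_unchanged(self, small_study):
        _, _, annotations, _, posteriors, _ = small_study
        m = AnnotationEnrichment(posteriors, annotations, FitConfig(lambda_grid=(0.5,)))
        assert m.select_penalty(["A0"]) == 0.5

    def test_penalty_selection_deterministic_given_seed(self, small_study):
        _, _, annotations, _, posteriors, _ = small_study
        cfgs = [FitConfig(n_folds=4, seed=3) for _ in range(2)]
        lams = [
            AnnotationEnrichment(posteriors, annotations, c).select_penalty(["A0"])
            for c in cfgs
        ]
        assert lams[0] == lams[1]

    def test_cv_folds_partition_depends_only_on_seed_and_ids(self, small_study):
        _, _, annotations, _, posteriors, _ = small_study
        m1 = AnnotationEnrichment(posteriors, annotations, FitConfig(n_folds=4, seed=3))
        shuffled = posteriors.sample(frac=1, random_state=9)
        m2 = AnnotationEnrichment(shuffled, annotations, FitConfig(n_folds=4, seed=3))
        f1 = [m1.signal_ids[f].tolist() for f in m1.cv_folds()]
        f2 = [m2.signal_ids[f].tolist() for f in m2.cv_folds()]
        assert f1 == f2
        m3 = AnnotationEnrichment(posteriors, annotations, FitConfig(n_folds=4, seed=4))
        f3 = [m3.signal_ids[f].tolist() for f in m3.cv_folds()]
        assert f1 != f3
        all_ids = sorted(sid for fold in f1 for sid in fold)
        assert all_ids == sorted(m1.signal_ids.tolist())

    def test_backward_drops_noise_keeps_true(self, small_study):
        cfg, stats, annotations, truth, posteriors, _ = small_study
        rng = np.random.default_rng(13)
        ann = annotations.copy()
        ann["noise"] = (rng.random(len(ann)) < 0.1).astype(np.int8)
        start = EnrichmentModel(["A0", "noise"], np.array([1.2, 0.1]), 0.1, 0.0, 0.0)
        out = backward_eliminate(posteriors, ann, start, 0.1, FitConfig(n_folds=5))
        assert "A0" in out.annotations
        assert "noise" not in out.annotations

    def test_empty_model_is_a_no_op(self, small_study):
        _, _, annotations, _, posteriors, _ = small_study
        start = EnrichmentModel([], np.zeros(0), 0.1, 0.0, 0.0)
        out = backward_eliminate(posteriors, annotations, start, 0.1, FitConfig(n_folds=5))
        assert out.annotations == []


class TestReweighting:
    def test_zero_gamma_reproduces_flat_posteriors_bitwise(self, small_study):
        _, _, annotations, _, posteriors, _ = small_study
        sid = posteriors["signal_id"].iloc[0]
        target = posteriors[posteriors["signal_id"] == sid].reset_index(drop=True)
        model = EnrichmentModel(["A0"], np.zeros(1), 0.0, 0.0, 0.0)
        rw = reweight_posteriors(target, annotations, model, ABFConfig(W=Z_SCALE_W))
        assert (rw["posterior"].to_numpy() == target["posterior"].to_numpy()).all()
        empty = EnrichmentModel([], np.zeros(0), 0.0, 0.0, 0.0)
        rw2 = reweight_posteriors(target, annotations, empty, ABFConfig(W=Z_SCALE_W))
        assert (rw2["posterior"].to_numpy() == target["posterior"].to_numpy()).all()

    def test_ln4_prior_on_equal_abfs_gives_80_20(self):
        target = pd.DataFrame({"variant_id": ["v0", "v1"], "signal_id": "s0", "z": [2.0, 2.0]})
        ann = annotation_frame([[1], [0]], ["A"], ["v0", "v1"])
        model = EnrichmentModel(["A"], np.array([np.log(4.0)]), 0.0, 0.0, 0.0)
        rw = reweight_posteriors(target, ann, model)
        assert np.allclose(rw["posterior"], [0.8, 0.2], atol=1e-12)

    def test_missing_annotation_columns_named(self):
        target = make_posterior_frame(np.log([2.0, 1.0]))
        target["z"] = [2.0, 1.0]
        ann = annotation_frame([[1], [0]], ["A"], ["v0", "v1"])
        model = EnrichmentModel(["B"], np.ones(1), 0.0, 0.0, 0.0)
        with pytest.raises(ValueError, match="B"):
            reweight_posteriors(target, ann, model)

    def test_identical_annotation_rows_keep_their_ranking(self):
        rng = np.random.default_rng(2)
        z = rng.normal(0, 3, size=8)
        target = pd.DataFrame(
            {"variant_id": [f"v{i}" for i in range(8)], "signal_id": "s0", "z": z}
        )
        ann = annotation_frame(
            [[1], [1], [0], [0], [1], [0], [1], [0]], ["A"], target["variant_id"]
        )
        base = signal_posteriors(target, config=ABFConfig(W=Z_SCALE_W))
        model = EnrichmentModel(["A"], np.array([1.5]), 0.0, 0.0, 0.0)
        rw = reweight_posteriors(target, ann, model, ABFConfig(W=Z_SCALE_W))
        for grp in ([0, 1, 4, 6], [2, 3, 5, 7]):  # same annotation row
            b = base["posterior"].iloc[grp].to_numpy()
            r = rw["posterior"].iloc[grp].to_numpy()
            assert (np.argsort(b) == np.argsort(r)).all()


class TestFullFit:
    def test_fit_recovers_log_enrichment_and_shrinks_credible_set(self, small_study):
        cfg, stats, annotations, truth, posteriors, credsets = small_study
        results = AnnotationEnrichment(posteriors, annotations, FitConfig(n_folds=5)).fit()
        assert results.model.annotations == ["A0"]
        assert results.params["A0"] == pytest.approx(np.log(4.0), abs=0.8)
        assert results.penalty in FitConfig().lambda_grid
        assert "log-enrichment" in results.summary()
        # reweighting with the fitted prior should not enlarge the average set
        sizes_base, sizes_rw = [], []
        for sid, cs in credsets.items():
            target = posteriors[posteriors["signal_id"] == sid].reset_index(drop=True)
            _, rw_cs = results.reweight(target, annotations, ABFConfig(W=Z_SCALE_W))
            sizes_base.append(len(cs))
            sizes_rw.append(len(rw_cs))
        assert np.mean(sizes_rw) < np.mean(sizes_base)
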