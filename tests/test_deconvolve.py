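import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from cfdeconv import (
    InsufficientOverlapError,
    MethylationDeconvolver,
    ValidationError,
    aggregate_entities,
    classify,
    estimated_tumor_fraction,
    nnls_deconvolve,
)
from cfdeconv.quant import ClusterBetaVector
from cfdeconv.simulate import region_counts_to_beta_vector, simulate_sample

from _oracles import grid_search_mixture


def _fit(beta, entities, tumoral, **params):
    est = MethylationDeconvolver(min_clusters=1, **params)
    return est.fit(np.asarray(beta).T, entities, tumoral=np.asarray(tumoral))


class TestNnlsDeconvolve:
    def test_exact_column_is_recovered(self, rng):
        A = rng.uniform(0, 1, (30, 3))
        est = _fit(A, ["MB", "EPN", "healthy"], [True, True, False])
        res = est.deconvolve(A[:, 1])
        assert res.column_weights["ref1"] == pytest.approx(1.0, abs=1e-9)
        assert res.predicted_entity == "EPN"
        assert res.residual_norm == pytest.approx(0.0, abs=1e-9)

    def test_noise_free_two_component_mixture(self, rng):
        A = rng.uniform(0, 1, (40, 2))
        est = _fit(A, ["MB", "EPN"], [True, True])
        b = 0.3 * A[:, 0] + 0.7 * A[:, 1]
        res = est.deconvolve(b)
        assert res.column_weights["ref0"] == pytest.approx(0.3, abs=1e-6)
        assert res.column_weights["ref1"] == pytest.approx(0.7, abs=1e-6)
        # independent brute-force check on this instance
        oracle = grid_search_mixture(A, b)
        assert oracle[0] == pytest.approx(0.3, abs=2e-3)

    def test_zero_sample_is_degenerate(self, rng):
        A = rng.uniform(0.2, 1, (20, 2))
        est = _fit(A, ["MB", "healthy"], [True, False])
        res = est.deconvolve(np.zeros(20))
        assert res.degenerate
        assert res.predicted_entity is None
        assert res.etf == 0.0

    def test_missing_clusters_use_complete_case(self, rng):
        A = rng.uniform(0, 1, (20, 2))
        A[3, 0] = np.nan  # missing in one atlas column
        b = A[:, 1].copy()
        b[7] = np.nan  # missing in the sample
        est = _fit(A, ["MB", "EPN"], [True, True])
        res = est.deconvolve(b)
        assert res.n_clusters_used == 18

    def test_cluster_floor_enforced(self, rng):
        A = rng.uniform(0, 1, (20, 2))
        est = MethylationDeconvolver(min_clusters=50).fit(
            A.T, ["MB", "EPN"], tumoral=[True, True]
        )
        with pytest.raises(InsufficientOverlapError):
            est.deconvolve(A[:, 0])

    def test_sample_alignment_by_cluster_id(self, tiny_atlas):
        """ClusterBetaVector entries are matched to atlas clusters by id,
        independent of order and coverage gaps."""
        counts = simulate_sample(
            tiny_atlas, {"TUM01": 1.0, "healthy_cfDNA": 0.0, "WBC": 0.0}, 200, seed=4
        )
        bv = region_counts_to_beta_vector(counts, tiny_atlas, "s1")
        shuffled = ClusterBetaVector("s1", bv.values.sample(frac=1, random_state=0))
        est = MethylationDeconvolver.from_atlas(
            tiny_atlas.to_reference_atlas(), min_clusters=10
        )
        r1, r2 = est.deconvolve(bv), est.deconvolve(shuffled)
        assert r1.column_weights == r2.column_weights
        assert r1.predicted_entity == "TUM01"

    def test_scale_free_in_read_counts(self, tiny_atlas):
        counts = simulate_sample(
            tiny_atlas, {"TUM01": 0.5, "healthy_cfDNA": 0.5, "WBC": 0.0}, 100, seed=5
        )
        scaled = counts.assign(
            count_meth=counts["count_meth"] * 13, count_total=counts["count_total"] * 13
        )
        est = MethylationDeconvolver.from_atlas(
            tiny_atlas.to_reference_atlas(), min_clusters=10
        )
        r1 = est.deconvolve(region_counts_to_beta_vector(counts, tiny_atlas))
        r2 = est.deconvolve(region_counts_to_beta_vector(scaled, tiny_atlas))
        assert r1.column_weights == pytest.approx(r2.column_weights)

    def test_weights_normalized_and_nonnegative(self, rng):
        A = rng.uniform(0, 1, (30, 3))
        est = _fit(A, ["MB", "EPN", "healthy"], [True, True, False])
        res = est.deconvolve(np.clip(A @ [0.2, 0.3, 0.5] + rng.normal(0, 0.05, 30), 0, 1))
        w = np.array(list(res.column_weights.values()))
        assert (w >= 0).all()
        assert w.sum() == pytest.approx(1.0, abs=1e-9)
        assert res.etf == pytest.approx(
            1.0 - res.entity_fractions["healthy"], abs=1e-9
        )


class TestAggregateAndClassify:
    def test_aggregate_sums_columns_per_entity(self):
        fractions = aggregate_entities(
            {"a": 0.2, "b": 0.1, "c": 0.7}, {"a": "MB", "b": "MB", "c": "healthy"}
        )
        assert fractions == pytest.approx({"MB": 0.3, "healthy": 0.7})
        assert sum(fractions.values()) == pytest.approx(1.0)

    def test_aggregate_rejects_unmapped_column(self):
        with pytest.raises(ValidationError):
            aggregate_entities({"a": 1.0}, {})

    @pytest.mark.parametrize(
        "fractions,expected",
        [
            ({"healthy_cfDNA": 0.6, "WBC": 0.1, "MB": 0.3}, 0.30),
            ({"healthy_cfDNA": 1.0, "MB": 0.0}, 0.0),
            ({"MB": 0.4, "EPN": 0.6}, 1.0),
        ],
    )
    def test_estimated_tumor_fraction(self, fractions, expected):
        flags = {"MB": True, "EPN": True, "healthy_cfDNA": False, "WBC": False}
        assert estimated_tumor_fraction(fractions, flags) == pytest.approx(expected)

    def test_classify_excludes_non_tumoral_argmax(self):
        flags = {"MB": True, "EPN": True, "healthy": False}
        assert classify({"MB": 0.25, "EPN": 0.05, "healthy": 0.7}, flags) == ("MB", False)

    def test_classify_all_zero_tumoral_is_none(self):
        flags = {"MB": True, "EPN": True, "healthy": False}
        assert classify({"MB": 0.0, "EPN": 0.0, "healthy": 1.0}, flags) == (None, False)

    def test_classify_tie_breaks_lexicographically_with_flag(self):
        flags = {"MB": True, "EPN": True}
        assert classify({"MB": 0.2, "EPN": 0.2}, flags) == ("EPN", True)

    def test_classify_requires_tumoral_entity(self):
        with pytest.raises(ValidationError):
            classify({"healthy": 1.0}, {"healthy": False})


class TestSklearnInterface:
    def test_get_set_params_and_clone(self):
        est = MethylationDeconvolver(min_clusters=7, unknown_component=True)
        assert est.get_params() == {"min_clusters": 7, "unknown_component": True}
        c = clone(est)
        assert c.get_params()["min_clusters"] == 7

    def test_predict_and_transform_batches(self, tiny_atlas):
        est = MethylationDeconvolver.from_atlas(
            tiny_atlas.to_reference_atlas(), min_clusters=10
        )
        X = np.vstack([tiny_atlas.beta[:, 0], tiny_atlas.beta[:, 1]])
        preds = est.predict(X)
        assert preds[0] == "TUM01"
        assert preds[1] is None  # pure healthy background: no tumoral signal
        frac = est.transform(X)
        assert frac.shape == (2, 3)
        np.testing.assert_allclose(frac.sum(axis=1), 1.0, atol=1e-9)

    def test_unknown_component_absorbs_unmodeled_signal(self, rng):
        A = rng.uniform(0, 1, (60, 2))
        est = _fit(A, ["MB", "healthy"], [True, False], unknown_component=True)
        res = est.deconvolve(np.full(60, 0.5))
        assert res.entity_fractions["unknown"] > 0.9

    def test_nnls_deconvolve_wrapper(self, tiny_atlas):
        counts = simulate_sample(
            tiny_atlas, {"TUM01": 0.6, "healthy_cfDNA": 0.4, "WBC": 0.0}, 100, seed=6
        )
        bv = region_counts_to_beta_vector(counts, tiny_atlas, "s")
        res = nnls_deconvolve(tiny_atlas.to_reference_atlas(), bv, min_clusters=10)
        assert res.predicted_entity == "TUM01"
        assert res.etf == pytest.approx(0.6, abs=0.1)


class TestDilutionMonotonicity:
    def test_median_etf_non_increasing_with_background(self):
        """Raising the true background fraction can only dilute the estimated
        tumor fraction (20 replicates per dilution level)."""
        from cfdeconv import simulate_atlas

        atlas = simulate_atlas(5, 500, 20, margin=0.5, seed=11)
        est = MethylationDeconvolver.from_atlas(
            atlas.to_reference_atlas(), min_clusters=10
        )
        medians = []
        for level, bg in enumerate([0.2, 0.5, 0.8]):
            etfs = []
            for rep in range(20):
                w = {e: 0.0 for e in atlas.entities}
                w["TUM01"] = 1.0 - bg
                w["healthy_cfDNA"] = bg
                counts = simulate_sample(atlas, w, 30, seed=1000 * level + rep)
                res = est.deconvolve(region_counts_to_beta_vector(counts, atlas))
                etfs.append(res.etf)
            medians.append(np.median(etfs))
        assert medians[0] >= medians[1] >= medians[2]
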