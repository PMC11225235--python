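import numpy as np
import pandas as pd
import pytest

from cfdeconv import (
    ValidationError,
    cfdna_fraction,
    simulate_atlas,
    simulate_cnv_bins,
    simulate_cohort,
    simulate_fragment_profile,
    simulate_sample,
)
from cfdeconv.simulate import TrueAtlas, simulate_mixture_cohort


class TestSimulateAtlas:
    def test_marker_architecture(self, tiny_atlas):
        a = tiny_atlas
        assert a.beta.shape == (100, 3)
        assert np.all((a.beta >= 0) & (a.beta <= 1))
        all_markers = np.concatenate([a.marker_map[e] for e in a.entities])
        assert len(all_markers) == 30
        assert len(set(all_markers)) == 30  # disjoint marker sets
        # at a marker region the owner differs from every other entity by >= margin
        for k, entity in enumerate(a.entities):
            for r in a.marker_map[entity]:
                others = np.delete(a.beta[r], k)
                assert np.all(np.abs(a.beta[r, k] - others) >= a.margin - 1e-12)
        # non-marker regions share a common baseline
        nonmarker = np.setdiff1d(np.arange(100), all_markers)
        assert np.all(np.ptp(a.beta[nonmarker], axis=1) == 0)

    def test_deterministic_given_seed(self):
        a1 = simulate_atlas(3, 100, 10, 0.5, 1)
        a2 = simulate_atlas(3, 100, 10, 0.5, 1)
        np.testing.assert_array_equal(a1.beta, a2.beta)

    @pytest.mark.parametrize(
        "args",
        [
            (2, 100, 10, 0.5),  # too few entities
            (2, 10, 6, 0.5),    # 12 markers > 10 regions
            (3, 100, 10, 1.5),  # margin out of range
        ],
    )
    def test_preconditions(self, args):
        with pytest.raises(ValidationError):
            simulate_atlas(*args, seed=1)


class TestSimulateSample:
    def _pure_atlas(self):
        # hand-built atlas with a saturated marker (beta exactly 1.0)
        beta = np.array([[1.0, 0.0, 0.0], [0.5, 0.5, 0.5]])
        return TrueAtlas(
            ("TUM01", "healthy_cfDNA", "WBC"), beta,
            {"TUM01": np.array([0])}, 0.5, 0,
        )

    def test_pure_entity_saturated_marker(self):
        atlas = self._pure_atlas()
        s = simulate_sample(
            atlas, {"TUM01": 1.0, "healthy_cfDNA": 0.0, "WBC": 0.0}, 50, seed=2
        )
        row = s.iloc[0]
        assert row["count_meth"] == row["count_total"]  # Binomial(n, 1) == n

    def test_fifty_fifty_mix_high_coverage(self):
        beta = np.array([[0.0, 1.0, 0.0]])
        atlas = TrueAtlas(("TUM01", "healthy_cfDNA", "WBC"), beta, {}, 0.5, 0)
        s = simulate_sample(
            atlas, {"TUM01": 0.5, "healthy_cfDNA": 0.5, "WBC": 0.0}, 1_000_000, seed=3
        )
        emp = s["count_meth"].iloc[0] / s["count_total"].iloc[0]
        assert emp == pytest.approx(0.5, abs=0.01)

    def test_zero_coverage_gives_zero_totals(self, tiny_atlas):
        w = {"TUM01": 1.0, "healthy_cfDNA": 0.0, "WBC": 0.0}
        s = simulate_sample(tiny_atlas, w, 0, seed=1)
        assert (s["count_total"] == 0).all()

    def test_beta_binomial_dispersion_inflates_variance(self, tiny_atlas):
        """Overdispersed sampling preserves the mean beta but widens the
        spread of empirical betas across regions."""
        w = {"TUM01": 0.5, "healthy_cfDNA": 0.5, "WBC": 0.0}
        tight = simulate_sample(tiny_atlas, w, 500, seed=8, dispersion=0.0)
        wide = simulate_sample(tiny_atlas, w, 500, seed=8, dispersion=0.3)
        wv = np.array([w[e] for e in tiny_atlas.entities])
        mixed = tiny_atlas.beta @ wv
        dev_tight = (tight["count_meth"] / tight["count_total"] - mixed).abs()
        dev_wide = (wide["count_meth"] / wide["count_total"] - mixed).abs()
        assert dev_wide.mean() > 2 * dev_tight.mean()
        assert np.isclose(
            (wide["count_meth"] / wide["count_total"]).mean(), mixed.mean(), atol=0.05
        )

    def test_fractions_must_sum_to_one(self, tiny_atlas):
        with pytest.raises(ValidationError):
            simulate_sample(
                tiny_atlas, {"TUM01": 0.5, "healthy_cfDNA": 0.3, "WBC": 0.1}, 30
            )

    def test_law_of_large_numbers(self, tiny_atlas):
        """Empirical betas converge to the mixed beta within 3 binomial SEs."""
        w = {"TUM01": 0.4, "healthy_cfDNA": 0.4, "WBC": 0.2}
        wv = np.array([w[e] for e in tiny_atlas.entities])
        mixed = tiny_atlas.beta @ wv
        s = simulate_sample(tiny_atlas, w, 10_000, seed=7)
        emp = s["count_meth"] / s["count_total"]
        se = np.sqrt(np.maximum(mixed * (1 - mixed), 1e-12) / s["count_total"])
        # allow the handful of expected >3-sigma excursions out of 100 regions
        assert (np.abs(emp - mixed) <= 3 * se + 1e-12).mean() >= 0.97


class TestFragmentProfile:
    def test_mass_conservation_and_gate_placement(self):
        prof = simulate_fragment_profile(4.0, 6.0, seed=1)
        assert prof["mass_ng"].sum() == pytest.approx(10.0, abs=1e-9)
        assert cfdna_fraction(prof) == pytest.approx(0.40, abs=1e-9)
        inside = prof["length_bp"].between(70, 700)
        assert prof.loc[inside, "mass_ng"].sum() == pytest.approx(4.0, abs=1e-9)
        assert (prof.loc[~inside, "length_bp"] > 700).all()

    @pytest.mark.parametrize("cf,hmw,expected", [(5.0, 0.0, 1.0), (0.0, 5.0, 0.0)])
    def test_pure_profiles(self, cf, hmw, expected):
        prof = simulate_fragment_profile(cf, hmw, seed=1)
        assert cfdna_fraction(prof) == pytest.approx(expected)

    def test_both_masses_zero_rejected(self):
        with pytest.raises(ValidationError):
            simulate_fragment_profile(0.0, 0.0)


class TestSimulateCnvBins:
    GENOME = {"chr1": 10_000_000}
    BINSIZE = 100_000

    def test_null_expectation_is_depth(self):
        sample, panel = simulate_cnv_bins(self.GENOME, self.BINSIZE, [], 0.0, 500, 3, 1)
        assert sample.counts.mean() == pytest.approx(500, rel=0.05)
        assert len(panel) == 3

    def test_gain_expectation(self):
        seg = [("chr1", 0, 10_000_000, 1.5)]
        sample, _ = simulate_cnv_bins(self.GENOME, self.BINSIZE, seg, 1.0, 1000, 0, 2)
        assert sample.counts.mean() == pytest.approx(1500, rel=0.05)

    def test_partial_tumor_fraction_expectation(self):
        # copy_ratio 0.5 at tumor fraction 0.5 -> 0.75 x depth
        seg = [("chr1", 0, 10_000_000, 0.5)]
        sample, _ = simulate_cnv_bins(self.GENOME, self.BINSIZE, seg, 0.5, 1000, 0, 3)
        assert sample.counts.mean() == pytest.approx(750, rel=0.05)

    def test_segment_outside_genome_rejected(self):
        with pytest.raises(ValidationError):
            simulate_cnv_bins(
                self.GENOME, self.BINSIZE, [("chr1", 0, 20_000_000, 1.5)], 1.0, 100, 3
            )


class TestSimulateCohort:
    CFG = {
        "n_tumor_entities": 3,
        "n_regions": 60,
        "markers_per_entity": 5,
        "mean_coverage": 20,
        "fractions": [0.2, 0.8],
        "samples_per_fraction": 2,
        "seed": 5,
    }

    def test_writes_expected_files_and_truth(self, tmp_path):
        truth = simulate_cohort(self.CFG, tmp_path)
        assert len(truth) == 4
        assert len(list(tmp_path.glob("*.cov"))) == 4
        assert len(list(tmp_path.glob("*.fragments.csv"))) == 4
        for name in ("truth.csv", "manifest.csv", "regions.bed", "atlas.csv"):
            assert (tmp_path / name).exists()

    def test_truth_table_reproducible(self, tmp_path):
        simulate_cohort(self.CFG, tmp_path / "a")
        simulate_cohort(self.CFG, tmp_path / "b")
        assert (tmp_path / "a/truth.csv").read_bytes() == (
            tmp_path / "b/truth.csv"
        ).read_bytes()
        assert (tmp_path / "a/sim000.cov").read_bytes() == (
            tmp_path / "b/sim000.cov"
        ).read_bytes()

    def test_empty_fraction_grid_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            simulate_cohort({**self.CFG, "fractions": []}, tmp_path)


class TestMixtureCohort:
    def test_truth_weights_consistent(self, tiny_atlas):
        cohort = simulate_mixture_cohort(tiny_atlas, [0.3], 5, 30, seed=9)
        for s in cohort:
            w = s.truth.fractions
            assert sum(w.values()) == pytest.approx(1.0, abs=1e-12)
            assert w[s.entity] == pytest.approx(s.tumor_fraction)
            # cfDNA fraction never below the tumor weight (HMW carries 1 - c)
            assert s.truth.cfdna_fraction_true >= s.tumor_fraction - 1e-12
            assert w["WBC"] == pytest.approx(1 - s.truth.cfdna_fraction_true)
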