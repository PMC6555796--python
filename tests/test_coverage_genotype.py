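import numpy as np
import pandas as pd
import pytest

from refgraft import coverage_genotype as cg
from refgraft.simulate import sim_insertion_coverage_values


def reads(rows):
    return pd.DataFrame(rows, columns=["chrom", "midpoint", "mapq"])


@pytest.fixture
def flat_ref():
    # constant 50% GC so every window falls in one GC bin
    return {"chr1": "AC" * 5000}


class TestWindowCoverage:
    def test_midpoint_assignment(self, flat_ref):
        # read midpoints 49 and 50 land in windows 0 and 1 respectively
        win = cg.window_coverage(
            reads([("chr1", 49, 60), ("chr1", 50, 60)]), flat_ref
        )
        assert win.loc[0, "total_count"] == 1
        assert win.loc[1, "total_count"] == 1

    def test_alignable_boundary_inclusive_at_40_percent(self, flat_ref):
        rows = [("chr1", 10, 60)] * 6 + [("chr1", 10, 1)] * 4  # 40% low quality
        win = cg.window_coverage(reads(rows), flat_ref)
        assert bool(win.loc[0, "alignable"])

    def test_alignable_fails_above_40_percent(self, flat_ref):
        rows = [("chr1", 10, 60)] * 5 + [("chr1", 10, 0)] * 5  # 50%
        win = cg.window_coverage(reads(rows), flat_ref)
        assert not bool(win.loc[0, "alignable"])

    def test_empty_windows_not_alignable(self, flat_ref):
        win = cg.window_coverage(reads([]), flat_ref)
        assert (win["total_count"] == 0).all()
        assert not win["alignable"].any()

    def test_gc_fraction_from_400bp_flank(self):
        ref = {"chr1": "G" * 300 + "A" * 700}
        win = cg.window_coverage(reads([]), ref)
        # window at 400: flank [200, 600) holds 100 G -> 0.25
        assert win.loc[8, "start"] == 400
        assert win.loc[8, "gc_fraction"] == pytest.approx(0.25)


class TestTruncatedMean:
    def test_sort_trim_mean_oracle(self):
        mean, n = cg.truncated_mean(np.arange(1, 101))
        assert mean == pytest.approx(np.mean(np.arange(11, 91)))  # 50.5
        assert n == 80

    def test_identical_values(self):
        mean, _ = cg.truncated_mean(np.full(500, 7.0))
        assert mean == 7.0


class TestGcStandard:
    def _windows(self, counts, gc=0.5):
        return pd.DataFrame(
            {
                "ref_name": "chr1",
                "start": np.arange(len(counts)) * 50,
                "total_count": counts,
                "lowq_count": 0,
                "gc_fraction": gc,
                "alignable": True,
            }
        )

    def test_bin_with_100_after_truncation_valid(self):
        # 125 windows -> trim 12 each side -> 101 remain: valid
        table = cg.gc_standard(self._windows(np.arange(1, 126)))
        assert np.isfinite(table.standards[25])

    def test_bin_below_100_after_truncation_invalid(self):
        # 120 windows -> trim 12 each side -> 96 remain: invalid
        table = cg.gc_standard(self._windows(np.arange(1, 121)))
        assert np.isnan(table.standards[25])

    def test_uniform_coverage_standard_equals_value(self):
        table = cg.gc_standard(self._windows(np.full(500, 30)))
        assert table.standards[25] == 30

    def test_normalize_uniform_gives_unity(self):
        win = self._windows(np.full(500, 30))
        out = cg.normalize(win, cg.gc_standard(win))
        assert np.allclose(out["normalized"], 1.0)

    def test_scale_invariance(self):
        base = np.concatenate([np.full(300, 20), np.full(300, 40)])
        win1 = self._windows(base)
        win7 = self._windows(base * 7)
        n1 = cg.normalize(win1, cg.gc_standard(win1))["normalized"]
        n7 = cg.normalize(win7, cg.gc_standard(win7))["normalized"]
        assert np.allclose(n1, n7)

    def test_window_in_invalid_bin_propagates_nan(self):
        win = pd.concat(
            [self._windows(np.full(500, 30), gc=0.5), self._windows([10], gc=0.1)],
            ignore_index=True,
        )
        out = cg.normalize(win, cg.gc_standard(win))
        assert np.isnan(out["normalized"].iloc[-1])


class TestInsertionCoverage:
    def _win(self, starts, normalized, alignable=True):
        return pd.DataFrame(
            {
                "ref_name": "chr1",
                "start": starts,
                "total_count": 10,
                "lowq_count": 0,
                "gc_fraction": 0.5,
                "alignable": alignable,
                "normalized": normalized,
            }
        )

    def test_mean_of_contained_alignable_windows(self):
        win = self._win([100, 150], [0.4, 0.6])
        x = cg.insertion_coverage(win, {"i1": ("chr1", 100, 300)})
        assert x["i1"] == pytest.approx(0.5)  # 100 bp of 200 = 50%: valid

    def test_under_30_percent_coverage_invalid(self):
        # 250 bp alignable of a 1000-bp insertion = 25% -> invalid
        win = self._win([0, 50, 100, 150, 200], [1.0] * 5)
        x = cg.insertion_coverage(win, {"i1": ("chr1", 0, 1000)})
        assert np.isnan(x["i1"])

    def test_under_50_bp_invalid(self):
        win = self._win([0], [1.0])
        x = cg.insertion_coverage(win, {"i1": ("chr1", 10, 70)})  # no full window
        assert np.isnan(x["i1"])

    def test_zero_alignable_windows_invalid(self):
        win = self._win([100, 150], [0.5, 0.5], alignable=False)
        x = cg.insertion_coverage(win, {"i1": ("chr1", 100, 200)})
        assert np.isnan(x["i1"])

    def test_straddling_windows_excluded(self):
        win = self._win([50, 100, 150], [9.0, 0.5, 0.5])
        # window at 50 straddles the 75 boundary: excluded from the mean
        x = cg.insertion_coverage(win, {"i1": ("chr1", 75, 200)})
        assert x["i1"] == pytest.approx(0.5)

    def test_unknown_chromosome_errors(self):
        win = self._win([0], [1.0])
        with pytest.raises(KeyError):
            cg.insertion_coverage(win, {"i1": ("chrZ", 0, 100)})


class TestCopyNumberFit:
    def test_recovers_known_parameters(self, rng):
        x, S = sim_insertion_coverage_values(0.0, 1.0, 25.0, 0.3, 500, rng)
        A = np.full(500, 2)
        model = cg.fit_copy_number(x, A)
        assert model.accepted
        assert abs(model.a) <= 0.05
        assert 0.95 <= model.b <= 1.05
        calls = cg.call_copy_numbers(model, x, A)
        called = calls["S"].notna()
        assert (calls["S"][called] == S[called]).mean() >= 0.98
        # dual route: a Bayes-optimal caller built from the TRUE parameters
        # must agree with the fitted caller wherever both are confident
        theta_true = np.zeros(cg.DEFAULT_M + 1)
        theta_true[:2] = (0.7, 0.3)
        oracle = cg.CopyNumberModel(a=0.0, b=1.0, c=25.0, theta=theta_true)
        ocalls = cg.call_copy_numbers(oracle, x, A)
        both = called & ocalls["S"].notna()
        assert (calls["S"][both] == ocalls["S"][both]).mean() >= 0.995

    def test_objective_monotone_over_iterations(self, rng):
        x, _ = sim_insertion_coverage_values(0.2, 0.9, 25.0, 0.5, 300, rng)
        model = cg.fit_copy_number(x, np.full(300, 2))
        trace = model.objective_trace
        assert all(b >= a - 1e-6 for a, b in zip(trace, trace[1:]))

    def test_all_zero_coverage_collapses_to_null(self):
        x = np.zeros(100)
        model = cg.fit_copy_number(x, np.full(100, 2))
        assert model.theta[0] == pytest.approx(1.0, abs=1e-3)
        calls = cg.call_copy_numbers(model, x, np.full(100, 2))
        assert (calls["S"] == 0).all()

    def test_offset_outside_band_not_accepted(self, rng):
        x, _ = sim_insertion_coverage_values(0.9, 1.0, 100.0, 0.3, 400, rng)
        model = cg.fit_copy_number(x, np.full(400, 2))
        assert abs(model.a - 0.9) < 0.1  # fit finds the true offset
        assert not model.accepted  # but 0.9 > 0.75 fails the band

    def test_restart_offsets_as_configured(self):
        assert cg.RESTART_A == (0.0, 0.4, 0.8)

    def test_too_few_values_errors(self):
        with pytest.raises(ValueError):
            cg.fit_copy_number([1.0], [2])


class TestPosteriorCalling:
    @pytest.fixture
    def sharp_model(self):
        theta = np.zeros(cg.DEFAULT_M + 1)
        theta[:2] = 0.5
        return cg.CopyNumberModel(a=0.0, b=1.0, c=400.0, theta=theta)

    def test_posterior_normalizes(self, sharp_model, rng):
        for x in rng.uniform(-0.5, 2.5, 20):
            post = cg.posterior_over_S(sharp_model, x, 2)
            assert post.sum() == pytest.approx(1.0, abs=1e-9)

    def test_confident_posterior_called(self, sharp_model):
        calls = cg.call_copy_numbers(sharp_model, [0.0, 1.0, 2.0], [2, 2, 2])
        assert list(calls["S"]) == [0.0, 1.0, 2.0]
        assert (calls["posterior_max"] > 0.99).all()

    def test_ambiguous_posterior_missing(self, sharp_model):
        # midway between components: max posterior ~0.5 < 0.8
        calls = cg.call_copy_numbers(sharp_model, [0.5], [2])
        assert np.isnan(calls["S"].iloc[0])

    def test_invalid_coverage_missing(self, sharp_model):
        calls = cg.call_copy_numbers(sharp_model, [np.nan], [2])
        assert np.isnan(calls["S"].iloc[0])

    def test_zero_chromosomes_deterministic_null(self, sharp_model):
        calls = cg.call_copy_numbers(sharp_model, [1.7], [0])
        assert calls["S"].iloc[0] == 0.0
        assert calls["posterior_max"].iloc[0] == 1.0

    def test_haploid_support(self, sharp_model):
        post = cg.posterior_over_S(sharp_model, 1.0, 1)
        assert len(post) == cg.DEFAULT_M + 1

    def test_threshold_is_strict(self):
        theta = np.zeros(cg.DEFAULT_M + 1)
        theta[0] = 0.8
        theta[1:] = 0.2 / cg.DEFAULT_M
        flat = cg.CopyNumberModel(a=0.0, b=1.0, c=1e-6, theta=theta)
        # with a flat likelihood the posterior equals the prior over S;
        # P(S=0) = 0.64 + small terms stays below the 0.8 threshold
        calls = cg.call_copy_numbers(flat, [0.5], [2])
        assert np.isnan(calls["S"].iloc[0])


class TestApplyFittedModel:
    @pytest.fixture
    def model(self):
        theta = np.zeros(cg.DEFAULT_M + 1)
        theta[:3] = (0.5, 0.3, 0.2)
        return cg.CopyNumberModel(a=0.1, b=1.0, c=400.0, theta=theta)

    def test_two_copy_coverage_called_present(self, model):
        out = cg.apply_fitted_model(model, [model.a + 2 * model.b], [2])
        assert out["S"].iloc[0] == 2.0
        assert out["presence"].iloc[0] == ">=1"

    def test_invalid_not_determined(self, model):
        out = cg.apply_fitted_model(model, [np.nan], [2])
        assert out["presence"].iloc[0] == "ND"

    def test_zero_coverage_absent(self, model):
        out = cg.apply_fitted_model(model, [model.a], [2])
        assert out["presence"].iloc[0] == "0"
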