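"""Tests of the decile-wise windowed structural-change statistic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spetfold.align_io import annotate_transcript
from spetfold.counting import DecileCounts
from spetfold.deciles import (
    STATUS_AMBIGUOUS,
    STATUS_CHANGED,
    STATUS_STABLE,
    Window,
    WindowParams,
    compare_deciles,
    enumerate_windows,
    filter_window,
    half_normalize,
    residue_trajectory,
    transcriptome_summary,
    window_values,
)
from spetfold.reactivity import winsorise


def windows_oracle(ac_positions, per_window=40, offset=20):
    """Exhaustive enumeration from the stated rule."""
    out = []
    k = 0
    while True:
        lo = offset * k
        hi = lo + per_window
        if hi > len(ac_positions):
            return out
        out.append(tuple(ac_positions[lo:hi]))
        k += 1


def annotation_with_n_ac(n_ac, spacing=2):
    seq = ("A" + "G" * (spacing - 1)) * n_ac + "GG"
    return annotate_transcript("t", seq)


class TestEnumerateWindows:
    @pytest.mark.parametrize("n_ac, expected", [(40, 1), (59, 1), (60, 2), (100, 4), (39, 0)])
    def test_window_counts(self, n_ac, expected):
        ann = annotation_with_n_ac(n_ac)
        assert len(enumerate_windows(ann)) == expected

    def test_matches_oracle_layout(self):
        ann = annotation_with_n_ac(100)
        got = [w.ac_positions for w in enumerate_windows(ann)]
        assert got == windows_oracle([int(p) for p in ann.ac_positions])

    @given(st.lists(st.sampled_from("ACGT"), min_size=40, max_size=400))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_matches_oracle_on_random_layouts(self, letters):
        ann = annotate_transcript("t", "".join(letters) + "G")
        got = [w.ac_positions for w in enumerate_windows(ann)]
        assert got == windows_oracle([int(p) for p in ann.ac_positions])
        for w in enumerate_windows(ann):
            assert len(w.ac_positions) == 40


def make_decile(decile, interval, stops_value=10.0, coverage_value=500.0, length=None):
    end = interval[1] if length is None else length
    return DecileCounts("t", decile, interval,
                        stops=np.full(end, stops_value),
                        coverage=np.full(end, coverage_value))


def make_window(ac_positions):
    return Window("t", 0, tuple(int(p) for p in ac_positions))


class TestFilterWindow:
    def setup_method(self):
        self.window = make_window(range(301, 341))   # 40 consecutive A/C ending at 340
        self.prev = make_decile(4, (301, 400))
        self.nxt = make_decile(5, (401, 500), length=500)

    def test_passes_at_defaults(self):
        assert filter_window(self.window, self.prev, self.nxt) is None

    def test_median_coverage_99_fails(self):
        low = make_decile(4, (301, 400), coverage_value=99.0)
        assert filter_window(self.window, low, self.nxt) == "low_coverage"

    def test_39_stops_over_40_ac_fails(self):
        weak = make_decile(5, (401, 500), stops_value=39.0 / 40.0, length=500)
        assert filter_window(self.window, self.prev, weak) == "low_signal"

    def test_positional_rules(self):
        near_end = make_window(range(351, 391))      # ends 10 nt before decile end
        assert filter_window(near_end, self.prev, self.nxt) == "positional"
        far_before = make_window(range(61, 101))     # ends 200+ nt before decile start
        assert filter_window(far_before, self.prev, self.nxt) == "positional"
        at_limit = make_window(range(336, 376))      # ends exactly 25 nt before end
        assert filter_window(at_limit, self.prev, self.nxt) is None


class TestHalfNormalize:
    def test_constant_halves_become_ones(self):
        out, degenerate = half_normalize(np.full(40, 6.0))
        assert not degenerate and (out == 1.0).all()

    def test_each_half_scaled_independently(self):
        values = np.concatenate([np.full(20, 100.0), np.full(20, 10.0)])
        out, _ = half_normalize(values)
        assert (out == 1.0).all()

    def test_composition_with_winsorise_oracle(self):
        rng = np.random.default_rng(9)
        values = rng.gamma(1.0, 10.0, 40)
        out, degenerate = half_normalize(values)
        np.testing.assert_allclose(out[:20], winsorise(values[:20]).values)
        np.testing.assert_allclose(out[20:], winsorise(values[20:]).values)

    def test_all_zero_half_is_degenerate(self):
        values = np.concatenate([np.zeros(20), np.ones(20)])
        _, degenerate = half_normalize(values)
        assert degenerate


class TestCompareDeciles:
    def setup_method(self):
        self.window = make_window(range(1, 41))

    def score(self, prev, nxt, **kw):
        return compare_deciles(self.window, (4, 5), np.asarray(prev, float),
                               np.asarray(nxt, float), WindowParams(**kw))

    def test_identical_vectors_are_stable(self):
        rng = np.random.default_rng(10)
        v = rng.gamma(1.0, 5.0, 40) + 0.5
        rec = self.score(v, v)
        assert rec.status == STATUS_STABLE
        assert rec.r == pytest.approx(1.0) and rec.dgini == pytest.approx(0.0)

    def test_anticorrelated_vectors_are_changed(self):
        base = np.tile([10.0, 1.0], 20)
        rec = self.score(base, base[::-1])
        assert rec.status == STATUS_CHANGED and rec.r < 0.8

    def test_zero_variance_is_ambiguous(self):
        rec = self.score(np.full(40, 5.0), np.arange(40.0) + 1.0)
        # constant prev: Winsorised next has variance, prev does not
        assert rec.status in (STATUS_AMBIGUOUS, STATUS_STABLE)
        rec2 = compare_deciles(self.window, (4, 5), np.full(40, 5.0), np.full(40, 5.0))
        assert rec2.status == STATUS_AMBIGUOUS and np.isnan(rec2.r)

    def test_high_r_with_large_dgini_is_ambiguous(self):
        prev = np.tile([30.0, 28.0, 26.0, 24.0], 10)
        nxt = prev ** 6                     # same ordering, very unequal
        rec = self.score(prev, nxt)
        assert rec.r > 0.8 and abs(rec.dgini) >= 0.1
        assert rec.status == STATUS_AMBIGUOUS

    def test_too_few_shared_values_ambiguous(self):
        prev = np.full(40, np.nan)
        prev[:9] = [5, 6, 7, 8, 9, 10, 11, 12, 13]
        nxt = np.arange(40.0) + 1
        rec = self.score(prev, nxt)
        assert rec.status == STATUS_AMBIGUOUS


class TestSummary:
    def test_all_identical_windows_are_all_stable(self):
        rng = np.random.default_rng(11)
        v = rng.gamma(1.0, 5.0, 40) + 0.5
        recs = [compare_deciles(make_window(range(1, 41)), (d, d + 1), v, v)
                for d in range(1, 10)]
        table, scatter = transcriptome_summary(recs)
        assert table.loc["ALL", "frac_stable"] == 1.0
        assert len(scatter) == 9

    def test_empty_summary(self):
        table, scatter = transcriptome_summary([])
        assert table.loc["ALL"].iloc[:4].sum() == 0
        assert scatter.empty


class TestResidueTrajectory:
    def test_rejects_non_ac_positions(self, demo_matrix, demo_annotation):
        from spetfold.reactivity import profiles_per_intermediate

        profiles = profiles_per_intermediate(demo_matrix, demo_annotation)
        with pytest.raises(ValueError):
            residue_trajectory(profiles, [1], demo_annotation)   # position 1 is G

    def test_untranscribed_intermediates_excluded(self, demo_matrix, demo_annotation):
        from spetfold.reactivity import profiles_per_intermediate

        profiles = profiles_per_intermediate(demo_matrix, demo_annotation)
        series = residue_trajectory(profiles, [20, 21, 22], demo_annotation)
        assert series.index.min() >= 22
        assert list(series.index) == sorted(series.index)

    def test_sequestration_phase_sequence(self, demo_matrix, demo_annotation):
        from spetfold.reactivity import profiles_per_intermediate

        profiles = profiles_per_intermediate(demo_matrix, demo_annotation)
        series = residue_trajectory(profiles, [20, 21, 22], demo_annotation)
        assert series[40] > 0.5 and series[80] > 0.5 and series[90] > 0.5
        assert series[50] < 0.2 and series[70] < 0.2 and series[110] < 0.2
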