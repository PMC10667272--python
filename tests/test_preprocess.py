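import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from titrofit.datamodel import Cycle, PhaseSchedule, TitrationSeries
from titrofit.preprocess import (PreprocessError, SelectionError,
                                 align_baseline, end_of_association,
                                 extract_fit_windows, junction_offsets,
                                 select_concentrations, subtract_blank,
                                 thin_to_rate)
from titrofit.simulate import SimSpec, simulate_series

from conftest import make_entry


def flat_cycle(index, conc, start, level=0.0, n=60, dt=1.0):
    t = start + np.arange(n) * dt
    sched = PhaseSchedule(start, start + 10.0, start + 30.0, start + n * dt - dt)
    return Cycle(index, conc, t, np.full(n, level), sched)


class TestAlignBaseline:
    def test_already_zeroed_regenerative_series_unchanged(self, regen_series):
        out = align_baseline(regen_series)
        for before, after in zip(regen_series.cycles, out.cycles):
            np.testing.assert_allclose(after.responses, before.responses,
                                       atol=1e-12)

    def test_constant_offset_removed(self):
        s = TitrationSeries(series_id="s",
                            cycles=[flat_cycle(1, 1e-8, 0.0, level=7.3)])
        out = align_baseline(s)
        base = out.cycles[0].responses[out.cycles[0].times < 10.0]
        assert abs(base.mean()) < 1e-12

    def test_nonregenerative_stitching_repairs_injected_jump(self,
                                                             nonregen_series):
        s = nonregen_series.copy_with_cycles(
            [c if c.index < 3 else c.with_responses(c.responses + 5.0)
             for c in nonregen_series.cycles])
        out = align_baseline(s)
        assert np.all(np.abs(junction_offsets(out)) < 1e-9)

    def test_idempotent(self, nonregen_series):
        once = align_baseline(nonregen_series)
        twice = align_baseline(once)
        for a, b in zip(once.cycles, twice.cycles):
            np.testing.assert_allclose(a.responses, b.responses, atol=1e-12)

    def test_empty_baseline_raises_naming_cycle(self):
        c = flat_cycle(2, 1e-8, 0.0)
        c = Cycle(2, 1e-8, c.times[11:], c.responses[11:], c.schedule)
        with pytest.raises(PreprocessError, match="cycle 2"):
            align_baseline(TitrationSeries(series_id="s", cycles=[c]))


class TestSubtractBlank:
    def make_series_with_blank(self, blank_resp=None):
        cyc = flat_cycle(1, 1e-8, 0.0, level=3.0)
        blank = flat_cycle(2, 0.0, 100.0)
        if blank_resp is not None:
            blank = blank.with_responses(blank_resp(blank.times - 100.0))
        return TitrationSeries(series_id="s", cycles=[cyc], blank=blank)

    def test_blank_identical_to_cycle_zeroes_it(self):
        s = self.make_series_with_blank(lambda trel: np.full_like(trel, 3.0))
        out = subtract_blank(s)
        np.testing.assert_allclose(out.cycles[0].responses, 0.0, atol=1e-12)
        assert out.blank is None

    def test_zero_blank_is_identity(self):
        s = self.make_series_with_blank()
        out = subtract_blank(s)
        np.testing.assert_allclose(out.cycles[0].responses, 3.0)

    def test_no_blank_is_noop(self):
        s = TitrationSeries(series_id="s", cycles=[flat_cycle(1, 1e-8, 0.0)])
        assert subtract_blank(s) is s

    def test_interpolated_subtraction_matches_linear_ramp(self):
        # blank on a 0.5 s grid, cycle on 1.0 s grid, blank = 0.2*t_rel:
        # interpolation of a linear ramp is exact
        t_b = 100.0 + np.arange(0.0, 60.0, 0.5)
        sched_b = PhaseSchedule(100.0, 110.0, 130.0, 159.5)
        blank = Cycle(2, 0.0, t_b, 0.2 * (t_b - 110.0), sched_b)
        cyc = flat_cycle(1, 1e-8, 0.0, level=5.0)
        s = TitrationSeries(series_id="s", cycles=[cyc], blank=blank)
        out = subtract_blank(s)
        expected = 5.0 - 0.2 * (cyc.times - 10.0)
        np.testing.assert_allclose(out.cycles[0].responses, expected, atol=1e-12)

    def test_short_blank_raises_naming_cycle(self):
        blank = flat_cycle(2, 0.0, 100.0, n=20)
        cyc = flat_cycle(1, 1e-8, 0.0, n=60)
        s = TitrationSeries(series_id="s", cycles=[cyc], blank=blank)
        with pytest.raises(PreprocessError, match="cycle 1"):
            subtract_blank(s)

    def test_simulated_zero_blank_round_trip(self):
        spec = SimSpec(include_blank=True)
        s = simulate_series(spec)
        out = subtract_blank(s)
        ref = simulate_series(SimSpec())
        for a, b in zip(out.cycles, ref.cycles):
            np.testing.assert_allclose(a.responses, b.responses, atol=1e-12)


class TestThinToRate:
    def test_five_hz_to_one_hz_count(self):
        t = np.arange(0.0, 100.0, 0.2)
        c = Cycle(1, 1e-8, t, np.zeros_like(t),
                  PhaseSchedule(0.0, 10.0, 50.0, 99.8))
        s = TitrationSeries(series_id="s", cycles=[c])
        out = thin_to_rate(s, 1.0)
        assert abs(out.cycles[0].n_points - 100) <= 1
        assert out.cycles[0].times[0] == t[0]
        assert np.all(np.diff(out.cycles[0].times) >= 1.0 - 1e-9)

    def test_rate_above_native_sampling_is_identity(self, regen_series):
        out = thin_to_rate(regen_series, 10.0)  # native is 0.5 Hz
        for a, b in zip(out.cycles, regen_series.cycles):
            np.testing.assert_array_equal(a.times, b.times)

    def test_single_point_cycle_unchanged(self):
        c = Cycle(1, 1e-8, [5.0], [1.0], PhaseSchedule(0.0, 1.0, 2.0, 6.0))
        out = thin_to_rate(TitrationSeries(series_id="s", cycles=[c]), 1.0)
        assert out.cycles[0].n_points == 1

    def test_preserves_first_timestamp_and_order(self, regen_series):
        out = thin_to_rate(regen_series, 0.2)
        for a, b in zip(out.cycles, regen_series.cycles):
            assert a.times[0] == b.times[0]
            assert np.all(np.diff(a.times) > 0)


def series_from_plateaus(plateaus):
    """One cycle per plateau whose end-of-association response is the
    given value; ascending synthetic concentrations."""
    cycles = []
    for j, e in enumerate(plateaus):
        start = 200.0 * j
        t = start + np.arange(0.0, 100.0, 1.0)
        sched = PhaseSchedule(start, start + 10.0, start + 50.0, start + 99.0)
        r = np.where(t < sched.t0, 0.0, float(e))
        cycles.append(Cycle(j + 1, 1e-9 * 2.0 ** j, t, r, sched))
    return TitrationSeries(series_id="s", cycles=cycles)


def brute_force_best_window(e):
    scores = [e[j + 4] - e[j] for j in range(len(e) - 4)]
    best = max(range(len(scores)), key=lambda j: (scores[j], -j))
    return best


class TestSelectConcentrations:
    def test_worked_example_selects_cycles_3_to_7(self):
        # E = [2,5,11,22,40,65,85,95] -> window scores [38,60,74,73]
        s = series_from_plateaus([2, 5, 11, 22, 40, 65, 85, 95])
        assert select_concentrations(s, "auto") == [3, 4, 5, 6, 7]

    def test_five_or_fewer_cycles_all_selected(self):
        s = series_from_plateaus([1, 2, 3, 4, 5])
        assert select_concentrations(s, "auto") == [1, 2, 3, 4, 5]

    def test_tie_breaks_to_lowest_concentration_window(self):
        s = series_from_plateaus([0, 10, 10, 10, 10, 10, 20])
        # windows 1-5 and 2-6 both score 10; window 3-7 scores 10 too
        assert select_concentrations(s, "auto") == [1, 2, 3, 4, 5]

    def test_manual_selection_verbatim(self):
        s = series_from_plateaus([1, 2, 3, 4, 5, 6])
        sel = select_concentrations(s, "manual", [1e-9, 4e-9])
        assert sel == [1, 3]

    def test_manual_absent_concentration_raises(self):
        s = series_from_plateaus([1, 2, 3])
        with pytest.raises(SelectionError):
            select_concentrations(s, "manual", [7e-9])

    @settings(deadline=None, max_examples=250)
    @given(st.lists(st.floats(min_value=0.0, max_value=100.0),
                    min_size=6, max_size=12))
    def test_matches_brute_force_on_random_response_vectors(self, e):
        s = series_from_plateaus(e)
        best = brute_force_best_window(e)
        assert select_concentrations(s, "auto") == list(range(best + 1, best + 6))


class TestExtractFitWindows:
    def test_zero_skips_span_full_phases(self, regen_series):
        w = extract_fit_windows(regen_series, make_entry(), [4, 5, 6, 7, 8])
        for slot in range(w.n_cycles):
            assert w.assoc_times[slot][0] == pytest.approx(w.t0[slot])
            assert w.assoc_times[slot][-1] <= w.t_asso[slot]
            assert w.dissoc_times[slot][0] > w.t_asso[slot]

    def test_skip_dissoc_boundary(self, regen_series):
        cfg = make_entry(skip_dissoc=5.0)
        w = extract_fit_windows(regen_series, cfg, [1, 2, 3])
        for slot in range(w.n_cycles):
            assert np.all(w.dissoc_times[slot] >= w.t_asso[slot] + 5.0)

    def test_dissoc_fit_len_truncates(self, regen_series):
        cfg = make_entry(dissoc_fit_len=300.0)
        w = extract_fit_windows(regen_series, cfg, [1])
        assert w.dissoc_times[0][-1] <= w.t_asso[0] + 300.0

    def test_skip_assoc_boundary(self, regen_series):
        cfg = make_entry(skip_assoc=10.0)
        w = extract_fit_windows(regen_series, cfg, [1])
        assert np.all(w.assoc_times[0] >= w.t0[0] + 10.0)

    def test_empty_window_raises_naming_cycle(self, regen_series):
        cfg = make_entry(skip_dissoc=749.0, dissoc_fit_len=749.5)
        with pytest.raises(PreprocessError, match="cycle 1"):
            extract_fit_windows(regen_series, cfg, [1])


class TestEndOfAssociation:
    def test_uses_last_association_point(self, regen_series):
        top = regen_series.cycles[-1]
        sched = top.schedule
        m = (top.times >= sched.t0) & (top.times <= sched.t_asso)
        assert end_of_association(top) == top.responses[m][-1]
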