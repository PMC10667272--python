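"""Sensorgram preparation: baseline alignment, blank subtraction,
thinning, concentration down-selection and fit-window extraction.

These are the steps run between import and fitting, in this order:

1. baseline alignment (mode depends on regenerative vs non-regenerative);
2. optional blank-cycle subtraction;
3. thinning to a target sampling rate;
4. sorting + down-selection to at most five analyte concentrations;
5. extraction of the association/dissociation point windows to fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .datamodel import Cycle, TitrationSeries

if TYPE_CHECKING:  # pragma: no cover
    from .io import SampleSheetEntry

__all__ = [
    "PreprocessError",
    "SelectionError",
    "FitWindows",
    "align_baseline",
    "junction_offsets",
    "subtract_blank",
    "thin_to_rate",
    "end_of_association",
    "select_concentrations",
    "extract_fit_windows",
]

log = logging.getLogger(__name__)

# terminal slice of the previous dissociation used as the continuity
# anchor when stitching non-regenerative cycles (seconds)
STITCH_ANCHOR_S = 5.0


class PreprocessError(ValueError):
    pass


class SelectionError(PreprocessError):
    pass


@dataclass
class FitWindows:
    """Per-cycle association/dissociation points selected for fitting.

    Arrays are parallel lists indexed by fitted-cycle slot; ``cycle_indices``
    maps slots back to the 1-based cycle indices of the series.
    """

    cycle_indices: list[int]
    concentrations: np.ndarray
    t0: np.ndarray            # per-cycle association start (absolute s)
    t_asso: np.ndarray        # per-cycle association end (absolute s)
    assoc_times: list[np.ndarray]
    assoc_responses: list[np.ndarray]
    dissoc_times: list[np.ndarray]
    dissoc_responses: list[np.ndarray]

    @property
    def n_cycles(self) -> int:
        return len(self.cycle_indices)

    @property
    def n_points(self) -> int:
        return int(sum(t.size for t in self.assoc_times)
                   + sum(t.size for t in self.dissoc_times))


def _baseline_mask(cycle: Cycle) -> np.ndarray:
    s = cycle.schedule
    return (cycle.times >= s.baseline_start) & (cycle.times < s.t0)


def _dissoc_tail_mean(cycle: Cycle, span: float = STITCH_ANCHOR_S) -> float:
    s = cycle.schedule
    m = (cycle.times > s.dissoc_end - span) & (cycle.times <= s.dissoc_end)
    if not m.any():
        # fall back to the last recorded point of the cycle
        return float(cycle.responses[-1])
    return float(cycle.responses[m].mean())


def align_baseline(series: TitrationSeries) -> TitrationSeries:
    """Shift each cycle so phases join up consistently.

    Regenerative series: every cycle is shifted so the mean response over
    its baseline window ``[baseline_start, t0)`` is zero.

    Non-regenerative series: cycle 1 is zeroed on its baseline; each later
    cycle is shifted so its baseline mean equals the mean of the final 5 s
    of the previous cycle's dissociation, stitching the accumulated signal
    into one continuous trace.  Idempotent in both modes.
    """
    out_cycles: list[Cycle] = []
    prev: Cycle | None = None
    for cycle in series.cycles:
        m = _baseline_mask(cycle)
        if m.sum() < 2:
            raise PreprocessError(
                f"cycle {cycle.index}: baseline window has fewer than 2 points"
            )
        base_mean = float(cycle.responses[m].mean())
        if series.regenerative or prev is None:
            target = 0.0
        else:
            target = _dissoc_tail_mean(prev)
        shifted = cycle.with_responses(cycle.responses - base_mean + target)
        out_cycles.append(shifted)
        prev = shifted
    blank = series.blank
    if blank is not None:
        m = _baseline_mask(blank)
        if m.sum() >= 2:
            blank = blank.with_responses(
                blank.responses - float(blank.responses[m].mean()))
    return series.copy_with_cycles(out_cycles, blank=blank)


def junction_offsets(series: TitrationSeries) -> np.ndarray:
    """Stitching residual at each cycle junction of a non-regenerative
    series: baseline mean minus the previous cycle's 5 s dissociation-tail
    mean.  All ~0 after :func:`align_baseline`."""
    offs = []
    for prev, cur in zip(series.cycles, series.cycles[1:]):
        m = _baseline_mask(cur)
        offs.append(float(cur.responses[m].mean()) - _dissoc_tail_mean(prev))
    return np.array(offs)


def subtract_blank(series: TitrationSeries) -> TitrationSeries:
    """Subtract the blank (zero-concentration) cycle from every cycle.

    The blank is matched in cycle-relative time (t - t0); blank values at
    non-matching timestamps are obtained by linear interpolation.  The
    blank is removed from the series afterwards.  Without a blank this is
    a logged no-op.
    """
    blank = series.blank
    if blank is None:
        log.info("series %s: no blank cycle, skipping blank subtraction",
                 series.series_id)
        return series
    bt = blank.times - blank.schedule.t0
    out_cycles = []
    for cycle in series.cycles:
        ct = cycle.times - cycle.schedule.t0
        if ct[0] < bt[0] - 1e-9 or ct[-1] > bt[-1] + 1e-9:
            raise PreprocessError(
                f"cycle {cycle.index}: blank trace does not cover the cycle "
                f"window ([{ct[0]:g}, {ct[-1]:g}] s vs blank "
                f"[{bt[0]:g}, {bt[-1]:g}] s relative to t0)"
            )
        interp = np.interp(ct, bt, blank.responses)
        out_cycles.append(cycle.with_responses(cycle.responses - interp))
    out = series.copy_with_cycles(out_cycles)
    out.blank = None
    return out


def thin_to_rate(series: TitrationSeries, rate_hz: float) -> TitrationSeries:
    """Thin each cycle to at most ``rate_hz`` points per second.

    Keeps the first point of each consecutive bin of width ``1/rate_hz``
    starting at the cycle's first timestamp; never upsamples, never
    averages, never reorders.
    """
    if rate_hz <= 0:
        raise PreprocessError("rate_hz must be positive")
    width = 1.0 / rate_hz

    def thin(cycle: Cycle) -> Cycle:
        if cycle.times.size <= 1:
            return cycle
        bins = np.floor((cycle.times - cycle.times[0]) / width + 1e-9).astype(int)
        keep = np.concatenate(([True], np.diff(bins) > 0))
        return Cycle(cycle.index, cycle.concentration, cycle.times[keep],
                     cycle.responses[keep], cycle.schedule)

    blank = thin(series.blank) if series.blank is not None else None
    return series.copy_with_cycles([thin(c) for c in series.cycles], blank=blank)


def end_of_association(cycle: Cycle) -> float:
    """Response at the end of association: the last point in
    ``[t0, t_asso]`` (used for down-selection and dose-response plots)."""
    s = cycle.schedule
    m = (cycle.times >= s.t0) & (cycle.times <= s.t_asso)
    if not m.any():
        raise PreprocessError(
            f"cycle {cycle.index}: no points in the association phase")
    return float(cycle.responses[m][-1])


def select_concentrations(series: TitrationSeries, mode: str = "auto",
                          manual: Sequence[float] | None = None) -> list[int]:
    """Down-select at most five analyte concentrations for fitting.

    Auto mode on a concentration-sorted series: with five or fewer cycles
    all are kept; otherwise, over every window of five consecutive sorted
    concentrations, pick the window with the largest accumulated increase
    of end-of-association response (last minus first of the window; ties
    go to the lowest-concentration window).  This tracks the steep, most
    information-rich part of the dose response.

    Manual mode selects the user's (<= 5) concentrations verbatim.
    Returns 1-based cycle indices in ascending-concentration order.
    """
    cycles = sorted(series.cycles, key=lambda c: c.concentration)
    if mode == "manual":
        if manual is None or len(manual) == 0:
            raise SelectionError("manual selection requires a concentration list")
        if len(manual) > 5:
            raise SelectionError("manual selection is limited to 5 concentrations")
        chosen = []
        for target in sorted(manual):
            match = [c for c in cycles
                     if np.isclose(c.concentration, target, rtol=1e-6, atol=0.0)]
            if not match:
                raise SelectionError(
                    f"manual concentration {target:g} M not present in series "
                    f"{series.series_id!r}")
            chosen.append(match[0].index)
        return chosen
    if mode != "auto":
        raise SelectionError(f"unknown selection mode {mode!r}")
    if len(cycles) <= 5:
        return [c.index for c in cycles]
    e = np.array([end_of_association(c) for c in cycles])
    scores = e[4:] - e[:-4]          # window j covers cycles j..j+4
    best = int(np.argmax(scores))    # argmax takes the first (lowest) on ties
    return [c.index for c in cycles[best:best + 5]]


def extract_fit_windows(series: TitrationSeries, config: "SampleSheetEntry",
                        selected: Sequence[int]) -> FitWindows:
    """Cut the association/dissociation point sets to fit.

    Association keeps ``t0 + skip_assoc <= t <= t_asso``; dissociation
    keeps ``t_asso + skip_dissoc <= t <= t_asso + dissoc_fit_len`` (and
    strictly after ``t_asso``, so the shared boundary point is not fitted
    twice).  Raises if any selected cycle yields an empty window.
    """
    if not selected:
        raise PreprocessError("no cycles selected for fitting")
    cyc = {c.index: c for c in series.cycles}
    w = FitWindows([], np.zeros(len(selected)), np.zeros(len(selected)),
                   np.zeros(len(selected)), [], [], [], [])
    for slot, idx in enumerate(selected):
        c = cyc[idx]
        s = c.schedule
        am = (c.times >= s.t0 + config.skip_assoc) & (c.times <= s.t_asso)
        dm = ((c.times >= s.t_asso + config.skip_dissoc)
              & (c.times > s.t_asso)
              & (c.times <= s.t_asso + config.dissoc_fit_len))
        if not am.any():
            raise PreprocessError(
                f"cycle {idx}: association window is empty")
        if not dm.any():
            raise PreprocessError(
                f"cycle {idx}: dissociation window is empty")
        w.cycle_indices.append(idx)
        w.concentrations[slot] = c.concentration
        w.t0[slot] = s.t0
        w.t_asso[slot] = s.t_asso
        w.assoc_times.append(c.times[am])
        w.assoc_responses.append(c.responses[am])
        w.dissoc_times.append(c.times[dm])
        w.dissoc_responses.append(c.responses[dm])
    return w
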