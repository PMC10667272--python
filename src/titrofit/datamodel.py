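"""Core domain types for titration sensorgrams.

A *titration series* is one ligand surface probed with an ordered set of
analyte injection cycles; it is the unit that gets fitted.  Each cycle
carries a reference-subtracted response trace, the analyte concentration,
and the absolute timestamps that delimit its baseline, association and
dissociation phases.

Conventions
-----------
* Time is stored in absolute seconds exactly as exported by the
  instrument; all window arithmetic downstream is done relative to the
  per-cycle association start ``t0``.  Both stitched single-clock exports
  (Carterra) and per-cycle clocks (Biacore) fit this model.
* Response units (RU for SPR, nm for BLI) are an opaque label; the
  kinetics math is unit-agnostic.
* Concentrations are stored in molar; file readers convert from
  nM/µM/... on the way in.
* Cycle indices are 1-based, matching instrument exports.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable

import numpy as np

__all__ = [
    "Platform",
    "PhaseSchedule",
    "Cycle",
    "TitrationSeries",
    "validate_series",
    "sort_cycles",
]


class Platform(str, Enum):
    GENERIC = "generic"
    CARTERRA = "carterra"
    BIACORE = "biacore"
    OCTET = "octet"


@dataclass(frozen=True)
class PhaseSchedule:
    """Absolute phase timestamps (seconds) for one cycle.

    ``baseline_start <= t0 < t_asso < dissoc_end`` is required:
    baseline runs up to the association start ``t0``, association ends at
    ``t_asso``, dissociation ends at ``dissoc_end``.
    """

    baseline_start: float
    t0: float
    t_asso: float
    dissoc_end: float

    def violations(self) -> list[str]:
        msgs: list[str] = []
        vals = (self.baseline_start, self.t0, self.t_asso, self.dissoc_end)
        if not all(np.isfinite(vals)):
            msgs.append("schedule timestamps must all be finite")
            return msgs
        if not self.baseline_start <= self.t0:
            msgs.append("baseline_start must be <= t0")
        if not self.t0 < self.t_asso:
            msgs.append("t0 must be < t_asso")
        if not self.t_asso < self.dissoc_end:
            msgs.append("t_asso must be < dissoc_end")
        return msgs


@dataclass
class Cycle:
    """One analyte injection: a (time, response) trace plus its schedule.

    ``concentration`` is molar; 0 is allowed only for blank cycles.
    """

    index: int
    concentration: float
    times: np.ndarray
    responses: np.ndarray
    schedule: PhaseSchedule

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)

    @property
    def n_points(self) -> int:
        return int(self.times.size)

    def violations(self) -> list[str]:
        msgs = [f"cycle {self.index}: {m}" for m in self.schedule.violations()]
        if self.index < 1:
            msgs.append(f"cycle {self.index}: index must be a positive integer")
        if self.times.size == 0:
            msgs.append(f"cycle {self.index}: trace is empty")
        elif np.any(np.diff(self.times) <= 0):
            msgs.append(f"cycle {self.index}: times are not strictly increasing")
        if self.times.size != self.responses.size:
            msgs.append(f"cycle {self.index}: time/response length mismatch")
        if not np.isfinite(self.concentration) or self.concentration < 0:
            msgs.append(f"cycle {self.index}: concentration must be finite and >= 0")
        return msgs

    def with_responses(self, responses: np.ndarray) -> "Cycle":
        return Cycle(self.index, self.concentration, self.times.copy(),
                     np.asarray(responses, dtype=float), self.schedule)


@dataclass
class TitrationSeries:
    """One ligand surface's ordered set of analyte cycles."""

    series_id: str
    ligand: str = ""
    analyte: str = ""
    platform: Platform = Platform.GENERIC
    regenerative: bool = True
    response_unit: str = "RU"
    cycles: list[Cycle] = field(default_factory=list)
    blank: Cycle | None = None

    def cycle_by_index(self, index: int) -> Cycle:
        for c in self.cycles:
            if c.index == index:
                return c
        raise KeyError(f"series {self.series_id!r} has no cycle {index}")

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c.concentration for c in self.cycles])

    def copy_with_cycles(self, cycles: Iterable[Cycle],
                         blank: Cycle | None = None) -> "TitrationSeries":
        out = replace(self)
        out.cycles = list(cycles)
        out.blank = self.blank if blank is None else blank
        return out


def validate_series(series: TitrationSeries) -> list[str]:
    """Check every type invariant; returns [] iff the series is well formed.

    Validation never raises — each message names the cycle and the rule it
    violates so batch runs can log and move on.
    """
    msgs: list[str] = []
    non_blank = series.cycles
    if len(non_blank) < 1:
        msgs.append("series must contain at least one non-blank cycle")
    for c in non_blank:
        msgs.extend(c.violations())
        if c.concentration == 0:
            msgs.append(
                f"cycle {c.index}: zero concentration is only permitted for "
                "the blank cycle"
            )
    if series.blank is not None:
        msgs.extend(f"blank {m}" for m in series.blank.violations())
        if series.blank.concentration != 0:
            msgs.append("blank cycle must have concentration 0")
    # duplicate concentrations (blank excluded)
    by_conc: dict[float, list[int]] = {}
    for c in non_blank:
        by_conc.setdefault(c.concentration, []).append(c.index)
    for conc, idxs in by_conc.items():
        if len(idxs) > 1 and conc != 0:
            msgs.append(
                f"cycles {sorted(idxs)}: duplicated concentration {conc:g} M"
            )
    return msgs


def sort_cycles(series: TitrationSeries) -> TitrationSeries:
    """Return a copy with cycles ordered by ascending concentration.

    The blank cycle is not part of the ordering.  The sort is stable, so
    equal concentrations (flagged by :func:`validate_series` anyway) keep
    their input order.
    """
    ordered = sorted(series.cycles, key=lambda c: c.concentration)
    return series.copy_with_cycles(ordered)
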