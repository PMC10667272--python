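"""Synthetic titration generator.

Generates regenerative and non-regenerative (single-cycle) 1:1 Langmuir
titrations directly from the association/dissociation equations, so every
downstream step — alignment, down-selection, window extraction, fitting —
can be exercised without instrument data.

Non-regenerative series are generated to be *exactly representable* by
the fitted model: the accumulated response carried over from cycle i-1 is
absorbed by solving the association equation for the extrapolated start
time ``t0_i`` that reproduces the carried response, which is precisely
the role ``t0_i`` plays during fitting.  Noise-free simulate→fit round
trips therefore recover the generating parameters to numerical precision.

Defaults mirror a typical high-throughput SPRi acquisition: 120 s
baseline / 300 s association / 750 s dissociation at 0.5 Hz, eight
two-fold dilutions topping at 1 µM, ka = 1e5 M⁻¹s⁻¹, kd = 1e-4 s⁻¹,
Rmax = 100 RU.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass, field

import numpy as np

from .datamodel import Cycle, PhaseSchedule, Platform, TitrationSeries

__all__ = ["SimSpec", "simulate_series", "dilution_series", "write_fixture_bundle"]


def dilution_series(top: float, factor: float, n: int) -> list[float]:
    """Ascending n-step dilution series ending at ``top`` molar."""
    return [top / factor ** k for k in range(n - 1, -1, -1)]


@dataclass
class SimSpec:
    """Everything needed to simulate one titration series."""

    ka: float = 1e5               # M^-1 s^-1
    kd: float = 1e-4              # s^-1
    rmax: float = 100.0           # response units
    concentrations: list[float] = field(
        default_factory=lambda: dilution_series(1e-6, 2.0, 8))
    baseline_len: float = 120.0   # s
    assoc_len: float = 300.0      # s
    dissoc_len: float = 750.0     # s
    rate_hz: float = 0.5
    regenerative: bool = True
    noise_sd: float = 0.0         # response units
    rshift: list[float] | None = None   # bulk-shift amplitude per cycle
    rdrift: list[float] | None = None   # drift amplitude per cycle
    include_blank: bool = False
    seed: int = 0
    series_id: str = "sim-1"
    ligand: str = "sim-ligand"
    analyte: str = "sim-analyte"

    def validate(self) -> None:
        if self.ka <= 0 or self.kd <= 0 or self.rmax <= 0:
            raise ValueError("ka, kd and rmax must be positive")
        for name in ("baseline_len", "assoc_len", "dissoc_len", "rate_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.concentrations:
            raise ValueError("at least one concentration is required")


def _per_cycle(values: list[float] | None, i: int) -> float:
    if values is None:
        return 0.0
    return values[i] if i < len(values) else 0.0


def simulate_series(spec: SimSpec) -> TitrationSeries:
    """Generate one titration series from a :class:`SimSpec`.

    Cycles are emitted in ascending concentration order (the injection
    order of a single-cycle titration) on a contiguous absolute clock.
    Gaussian noise of sd ``spec.noise_sd`` is added pointwise with
    ``spec.seed``; the optional blank cycle (C = 0) is pure noise.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    dt = 1.0 / spec.rate_hz
    cyc_len = spec.baseline_len + spec.assoc_len + spec.dissoc_len
    concs = sorted(spec.concentrations)

    cycles: list[Cycle] = []
    carry = 0.0          # response at the end of the previous dissociation
    carry_t = None       # absolute time of that response
    for i, conc in enumerate(concs):
        start = i * cyc_len
        sched = PhaseSchedule(
            baseline_start=start,
            t0=start + spec.baseline_len,
            t_asso=start + spec.baseline_len + spec.assoc_len,
            dissoc_end=start + cyc_len,
        )
        times = start + np.arange(0.0, cyc_len - 1e-9, dt)
        resp = np.zeros_like(times)
        kobs = spec.ka * conc + spec.kd
        occ = spec.ka * conc / kobs
        plateau = spec.rmax * occ
        rs = _per_cycle(spec.rshift, i)
        rd = _per_cycle(spec.rdrift, i)

        base = times < sched.t0
        asso = (times >= sched.t0) & (times <= sched.t_asso)
        diss = times > sched.t_asso

        if spec.regenerative or i == 0:
            t0_eff = sched.t0
            resp[base] = 0.0
        else:
            # previous cycle's signal keeps dissociating through baseline
            resp[base] = carry * np.exp(-spec.kd * (times[base] - carry_t))
            r_start = carry * np.exp(-spec.kd * (sched.t0 - carry_t))
            # solve the association equation for the extrapolated start
            # time that reproduces the carried response at t0
            frac = min(r_start / plateau, 1.0 - 1e-12)
            t0_eff = sched.t0 + np.log1p(-frac) / kobs

        resp[asso] = rs + plateau * (1.0 - np.exp(-kobs * (times[asso] - t0_eff)))
        end_occ = 1.0 - np.exp(-kobs * (sched.t_asso - t0_eff))
        amp = (spec.rmax + rd) * occ * end_occ
        resp[diss] = amp * np.exp(-spec.kd * (times[diss] - sched.t_asso))

        carry = amp * np.exp(-spec.kd * (sched.dissoc_end - sched.t_asso))
        carry_t = sched.dissoc_end
        cycles.append(Cycle(i + 1, conc, times, resp, sched))

    blank = None
    if spec.include_blank:
        start = len(concs) * cyc_len
        sched = PhaseSchedule(start, start + spec.baseline_len,
                              start + spec.baseline_len + spec.assoc_len,
                              start + cyc_len)
        times = start + np.arange(0.0, cyc_len - 1e-9, dt)
        blank = Cycle(len(concs) + 1, 0.0, times, np.zeros_like(times), sched)

    if spec.noise_sd > 0:
        cycles = [c.with_responses(
            c.responses + rng.normal(0.0, spec.noise_sd, c.n_points))
            for c in cycles]
        if blank is not None:
            blank = blank.with_responses(
                blank.responses + rng.normal(0.0, spec.noise_sd, blank.n_points))

    return TitrationSeries(
        series_id=spec.series_id, ligand=spec.ligand, analyte=spec.analyte,
        platform=Platform.GENERIC, regenerative=spec.regenerative,
        cycles=cycles, blank=blank,
    )


def write_fixture_bundle(spec: SimSpec, dest: str | pathlib.Path,
                         **entry_overrides) -> tuple[pathlib.Path, pathlib.Path]:
    """Simulate and write a ready-to-fit (sensorgram CSV, sample sheet) pair.

    The pair parses through :func:`titrofit.io.read_canonical_table` and
    :func:`titrofit.io.read_sample_sheet` and exercises the full batch
    path.  Returns (data_path, sheet_path).
    """
    from . import io as tio

    dest = pathlib.Path(dest)
    dest.mkdir(parents=True, exist_ok=True)
    series = simulate_series(spec)
    data_path = dest / f"{spec.series_id}_sensorgram.csv"
    tio.write_canonical_table([series], data_path)

    entry = {
        "location": spec.series_id,
        "series_id": spec.series_id,
        "ligand": spec.ligand,
        "analyte": spec.analyte,
        "concentrations": ";".join(f"{c:.9E}" for c in sorted(spec.concentrations)),
        "conc_unit": "M",
        "regenerative": spec.regenerative,
        "baseline_len": spec.baseline_len,
        "assoc_len": spec.assoc_len,
        "dissoc_fit_len": spec.dissoc_len,
        "skip_assoc": 0.0,
        "skip_dissoc": 0.0,
        "selection_mode": "auto",
        "manual_concs": "",
        "global_rmax": True,
        "bulk_shift": spec.rshift is not None,
        "drift": spec.rdrift is not None,
        "blank_cycle": len(spec.concentrations) + 1 if spec.include_blank else "",
    }
    entry.update(entry_overrides)
    sheet_path = dest / f"{spec.series_id}_samples.csv"
    import pandas as pd

    pd.DataFrame([entry]).to_csv(sheet_path, index=False)
    return data_path, sheet_path
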