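"""Batch driver and graphical reporting.

`run_batch` executes the full pipeline — read, align, blank-subtract,
thin, down-select, fit — for every sample-sheet entry, then writes the
estimates CSV, a multi-page PDF report (one page per series: fit overlay,
residuals, dose-response and a parameter summary block) and a plain-text
run log.  Partial failures are logged, flagged in the outputs and
reflected in the exit status; they never abort the remaining entries.
"""

from __future__ import annotations

import pathlib
import time
from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
from matplotlib.backends.backend_pdf import PdfPages  # noqa: E402

from . import __version__  # noqa: E402
from . import io as tio  # noqa: E402
from .datamodel import Platform, TitrationSeries, validate_series  # noqa: E402
from .fitting import FitResult, fit_series  # noqa: E402
from .preprocess import (align_baseline, end_of_association,  # noqa: E402
                         subtract_blank, thin_to_rate)

__all__ = ["render_report", "run_batch", "BatchOutcome"]


def _summary_text(r: FitResult) -> str:
    lines = [
        f"series: {r.series_id}",
        f"ligand: {r.ligand}   analyte: {r.analyte}",
        f"n_points = {r.n_points}   dof = {r.dof}",
        f"ka = {r.ka:.3E} 1/(M*s)   SE = {r.se_ka:.3E}",
        f"kd = {r.kd:.3E} 1/s   SE = {r.se_kd:.3E}",
        f"KD = {r.kD:.3E} M   SE = {r.se_kD:.3E}",
    ]
    rmax = np.atleast_1d(r.rmax_values)
    if rmax.size == 1:
        lines.append(f"Rmax = {rmax[0]:.3E}   SE = {np.atleast_1d(r.se_rmax)[0]:.3E}")
    else:
        lines.append("Rmax_i = " + ", ".join(f"{v:.3E}" for v in rmax))
    lines.append("selected C = "
                 + ", ".join(f"{c:.2E} M" for c in r.selected_concentrations))
    lines.append(f"converged: {r.converged}")
    if not r.converged:
        lines.append("*** FIT DID NOT CONVERGE ***")
    return "\n".join(lines)


def _render_page(pdf: PdfPages, r: FitResult,
                 series: TitrationSeries | None = None) -> None:
    fig, axes = plt.subplots(2, 2, figsize=(11, 8.5))
    (ax_fit, ax_res), (ax_dose, ax_txt) = axes
    cmap = plt.get_cmap("viridis")
    n = r.windows.n_cycles
    for slot in range(n):
        color = cmap(slot / max(n - 1, 1))
        w = r.windows
        t = np.concatenate((w.assoc_times[slot], w.dissoc_times[slot]))
        y = np.concatenate((w.assoc_responses[slot], w.dissoc_responses[slot]))
        pa, pdn = r.predictions[slot]
        pred = np.concatenate((pa, pdn))
        ax_fit.plot(t, y, ".", ms=2, color=color, alpha=0.5)
        ax_fit.plot(t, pred, "-", color=color, lw=1.2,
                    label=f"{w.concentrations[slot]:.2E} M")
        ra, rd = r.residuals(slot)
        ax_res.plot(t, np.concatenate((ra, rd)), ".", ms=2, color=color)
    ax_fit.set(xlabel="time (s)", ylabel="response", title="fit overlay")
    ax_fit.legend(fontsize=6)
    ax_res.axhline(0.0, color="k", lw=0.5)
    ax_res.set(xlabel="time (s)", ylabel="residual", title="fit residuals")

    # dose response: end-of-association response vs log10 C, all cycles,
    # the fitted (selected) subset highlighted
    if series is not None:
        concs = [c.concentration for c in series.cycles]
        eoa = [end_of_association(c) for c in series.cycles]
        sel = set(r.selected)
        sel_mask = [c.index in sel for c in series.cycles]
        ax_dose.plot(np.log10(concs), eoa, "o", color="0.6", label="all cycles")
        ax_dose.plot(np.log10(np.array(concs)[sel_mask]),
                     np.array(eoa)[sel_mask], "o", color="crimson",
                     label="selected")
    else:
        eoa = [r.windows.assoc_responses[s][-1] for s in range(n)]
        ax_dose.plot(np.log10(r.windows.concentrations), eoa, "o",
                     color="crimson", label="selected")
    ax_dose.set(xlabel="log10 C (M)", ylabel="response at end of association",
                title="dose response")
    ax_dose.legend(fontsize=7)

    ax_txt.axis("off")
    ax_txt.text(0.02, 0.98, _summary_text(r), va="top", family="monospace",
                fontsize=9,
                color="black" if r.converged else "firebrick")
    fig.suptitle(f"{r.series_id}: {r.ligand} / {r.analyte}")
    fig.tight_layout()
    pdf.savefig(fig)
    plt.close(fig)


def _render_failure_page(pdf: PdfPages, series_id: str, error: str) -> None:
    fig, ax = plt.subplots(figsize=(11, 8.5))
    ax.axis("off")
    ax.text(0.05, 0.9, f"series {series_id}: FIT FAILED\n\n{error}",
            va="top", family="monospace", fontsize=10, color="firebrick",
            wrap=True)
    pdf.savefig(fig)
    plt.close(fig)


def render_report(results: list[FitResult], dest,
                  series_map: dict[str, TitrationSeries] | None = None) -> None:
    """Write the multi-page PDF report, one page per result in order.

    Non-converged fits still render, visibly flagged.  ``series_map``
    (series_id → preprocessed series) enables the full dose-response
    panel including the non-selected cycles.
    """
    if not results:
        raise ValueError("render_report needs at least one result")
    with PdfPages(dest) as pdf:
        for r in results:
            series = (series_map or {}).get(r.series_id)
            _render_page(pdf, r, series)


@dataclass
class BatchOutcome:
    exit_status: int
    results: list[FitResult] = field(default_factory=list)
    failures: dict[str, str] = field(default_factory=dict)  # series_id -> error
    estimates_path: pathlib.Path | None = None
    report_path: pathlib.Path | None = None
    log_path: pathlib.Path | None = None


@dataclass
class _FailedRow:
    """Placeholder row for a series whose fit failed."""

    series_id: str
    ligand: str = ""
    analyte: str = ""
    n_points: int = 0
    ka = se_ka = kd = se_kd = kD = se_kD = float("nan")
    rmax_values = np.array([float("nan")])
    se_rmax = np.array([float("nan")])
    selected_concentrations = np.array([])
    converged: bool = False


def run_batch(data_path, sheet_path, out_dir, platform: str = "generic",
              thin_hz: float | None = 1.0, blank_subtract: bool = True,
              align: bool = True, make_report: bool = True) -> BatchOutcome:
    """Execute the full pipeline for every sample-sheet entry.

    Writes ``estimates.csv``, ``report.pdf`` and ``run.log`` under
    ``out_dir``.  A malformed sheet aborts before any fitting; a failure
    in one series is logged and flagged while the rest proceed, and the
    exit status is non-zero if anything failed.
    """
    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines = [f"titrofit {__version__}",
                 f"data={data_path} sheet={sheet_path} platform={platform} "
                 f"thin_hz={thin_hz} blank_subtract={blank_subtract} "
                 f"align={align}"]

    entries = tio.read_sample_sheet(sheet_path)  # malformed sheet raises here
    platform = Platform(platform)
    if platform is Platform.GENERIC:
        raw = {s.series_id: s for s in tio.read_canonical_table(data_path)}
        series_list = []
        for e in entries:
            if e.series_id not in raw:
                series_list.append((e, None, f"series {e.series_id!r} not "
                                    "found in the data file"))
            else:
                series_list.append((e, raw[e.series_id], None))
    else:
        loaded = tio.read_platform_export(data_path, platform, entries)
        series_list = [(e, s, None) for e, s in zip(entries, loaded)]

    results: list[object] = []
    failures: dict[str, str] = {}
    fitted: list[FitResult] = []
    series_map: dict[str, TitrationSeries] = {}
    for entry, series, early_error in series_list:
        t_start = time.perf_counter()
        try:
            if early_error:
                raise tio.TableFormatError(early_error)
            if platform is Platform.GENERIC:
                series = tio.attach_schedules(series, entry)
            problems = validate_series(series)
            if problems:
                raise tio.TableFormatError("; ".join(problems))
            if align:
                series = align_baseline(series)
            if blank_subtract and series.blank is not None:
                series = subtract_blank(series)
            if thin_hz is not None:
                series = thin_to_rate(series, thin_hz)
            result = fit_series(series, entry)
            results.append(result)
            fitted.append(result)
            series_map[result.series_id] = series
            log_lines.append(
                f"OK {entry.series_id}: ka={result.ka:.3E} kd={result.kd:.3E} "
                f"KD={result.kD:.3E} converged={result.converged} "
                f"[{time.perf_counter() - t_start:.2f} s]")
            if not result.converged:
                log_lines.append(
                    f"WARNING {entry.series_id}: fit did not converge")
        except Exception as exc:  # noqa: BLE001 - batch runs never abort
            failures[entry.series_id] = str(exc)
            results.append(_FailedRow(entry.series_id, entry.ligand,
                                      entry.analyte))
            log_lines.append(f"FAILED {entry.series_id}: {exc}")

    est_path = out_dir / "estimates.csv"
    tio.write_estimates_table(results, est_path)
    rep_path = None
    if make_report and results:
        rep_path = out_dir / "report.pdf"
        with PdfPages(rep_path) as pdf:
            for r in results:
                if isinstance(r, FitResult):
                    _render_page(pdf, r, series_map.get(r.series_id))
                else:
                    _render_failure_page(pdf, r.series_id,
                                         failures.get(r.series_id, ""))
    log_path = out_dir / "run.log"
    log_path.write_text("\n".join(log_lines) + "\n")
    return BatchOutcome(exit_status=1 if failures else 0, results=fitted,
                        failures=failures, estimates_path=est_path,
                        report_path=rep_path, log_path=log_path)
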