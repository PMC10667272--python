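"""File input/output.

Three surfaces, all delimited text (delimiter auto-detected among comma,
tab and semicolon; decimal points only):

* the **canonical sensorgram table** — long format with columns
  ``series_id, cycle, concentration, conc_unit, time_s, response`` (plus
  optional ``ligand, analyte, regenerative, is_blank, baseline_start,
  t0, t_asso, dissoc_end, response_unit`` columns which the writer emits
  so a written series re-reads identically);
* **platform adapters** that reshape wide instrument exports onto the
  canonical model: one time column followed by one response column per
  spot (Carterra LSA, the whole stitched titration per column), per cycle
  (Biacore T200, one file per channel) or per cycle of a single sensor
  (Octet);
* the **sample sheet** — one row of sample information and analysis
  preferences per sensorgram series (see :class:`SampleSheetEntry`), as
  CSV or a single-tab Excel workbook (first sheet);
* the **estimates table** — one CSV row of parameter estimates and
  standard errors per fitted series.
"""

from __future__ import annotations

import io as _stdio
import math
import pathlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datamodel import Cycle, PhaseSchedule, Platform, TitrationSeries

__all__ = [
    "TableFormatError",
    "SampleSheetError",
    "SampleSheetEntry",
    "read_canonical_table",
    "write_canonical_table",
    "read_sample_sheet",
    "read_platform_export",
    "attach_schedules",
    "write_estimates_table",
    "read_estimates_table",
    "ESTIMATE_COLUMNS",
]

CANONICAL_COLUMNS = ["series_id", "cycle", "concentration", "conc_unit",
                     "time_s", "response"]
SCHEDULE_COLUMNS = ["baseline_start", "t0", "t_asso", "dissoc_end"]
ESTIMATE_COLUMNS = [
    "series_id", "ligand", "analyte", "n_points",
    "ka", "SE_ka", "kd", "SE_kd", "KD", "SE_KD", "Rmax", "SE_Rmax",
    "selected_concentrations", "converged",
]

CONC_UNITS = {"M": 1.0, "mM": 1e-3, "µM": 1e-6, "uM": 1e-6,
              "nM": 1e-9, "pM": 1e-12}

_TRUE = {"true", "yes", "y", "t", "1", "1.0"}
_FALSE = {"false", "no", "n", "f", "0", "0.0", "", "nan", "none"}


class TableFormatError(ValueError):
    pass


class SampleSheetError(ValueError):
    pass


def _sniff_sep(source) -> str:
    """Pick the delimiter (comma/tab/semicolon) from the header line."""
    if hasattr(source, "read"):
        head = source.readline()
        source.seek(0)
    else:
        with open(source, "r", encoding="utf-8-sig") as fh:
            head = fh.readline()
    counts = {sep: head.count(sep) for sep in (",", "\t", ";")}
    return max(counts, key=counts.get) if max(counts.values()) else ","


def _read_delimited(source) -> pd.DataFrame:
    sep = _sniff_sep(source)
    return pd.read_csv(source, sep=sep, dtype=str, skipinitialspace=True,
                       encoding="utf-8-sig")


def _parse_bool(value, row: int, column: str) -> bool:
    text = str(value).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise SampleSheetError(
        f"row {row}: column {column!r} has non-boolean value {value!r}")


def to_molar(value: float, unit: str) -> float:
    unit = unit.strip()
    if unit not in CONC_UNITS:
        raise TableFormatError(
            f"unknown concentration unit {unit!r}; expected one of "
            f"{sorted(CONC_UNITS)}")
    return float(value) * CONC_UNITS[unit]


# ---------------------------------------------------------------------------
# canonical long format

def read_canonical_table(source) -> list[TitrationSeries]:
    """Read the canonical long-format sensorgram table.

    One :class:`TitrationSeries` per distinct ``series_id``; rows are
    grouped by (series_id, cycle).  A single zero-concentration cycle in
    a series becomes its blank.  Empty response cells are dropped per
    point.  Schedules default to a zero-span placeholder and are normally
    attached later from the sample sheet (:func:`attach_schedules`)
    unless schedule columns are present.
    """
    df = _read_delimited(source)
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            raise TableFormatError(f"missing required column {col!r}")
    if df.empty:
        return []

    for col in ("time_s", "response", "concentration"):
        raw = df[col].astype(str).str.strip()
        num = pd.to_numeric(raw, errors="coerce")
        bad = num.isna() & ~raw.isin(["", "nan", "None"])
        if bad.any():
            line = int(df.index[bad][0]) + 2  # header is line 1
            raise TableFormatError(
                f"non-numeric {col!r} value {raw[bad].iloc[0]!r} on line {line}")
        df[col] = num
    df = df.dropna(subset=["time_s", "response"])
    df["cycle"] = df["cycle"].astype(float).astype(int)

    has_sched = all(c in df.columns for c in SCHEDULE_COLUMNS)
    out: list[TitrationSeries] = []
    for sid, sdf in df.groupby("series_id", sort=False):
        cycles: list[Cycle] = []
        blank = None
        first = sdf.iloc[0]
        for idx, cdf in sdf.groupby("cycle", sort=True):
            conc = to_molar(float(cdf["concentration"].iloc[0]),
                            str(cdf["conc_unit"].iloc[0]))
            t = cdf["time_s"].to_numpy(dtype=float)
            r = cdf["response"].to_numpy(dtype=float)
            if has_sched:
                row = cdf.iloc[0]
                sched = PhaseSchedule(float(row["baseline_start"]),
                                      float(row["t0"]), float(row["t_asso"]),
                                      float(row["dissoc_end"]))
            else:
                sched = PhaseSchedule(t[0], t[0], t[0] + 1.0,
                                      max(t[-1], t[0] + 2.0))
            cycle = Cycle(int(idx), conc, t, r, sched)
            is_blank = conc == 0.0
            if "is_blank" in cdf.columns:
                is_blank = str(cdf["is_blank"].iloc[0]).strip().lower() in _TRUE
            if is_blank and blank is None:
                blank = cycle
            else:
                cycles.append(cycle)
        series = TitrationSeries(
            series_id=str(sid),
            ligand=str(first.get("ligand", "") or ""),
            analyte=str(first.get("analyte", "") or ""),
            regenerative=(_parse_bool(first["regenerative"], 0, "regenerative")
                          if "regenerative" in sdf.columns else True),
            response_unit=str(first.get("response_unit", "RU") or "RU"),
            cycles=cycles, blank=blank,
        )
        out.append(series)
    return out


def write_canonical_table(series_list: Iterable[TitrationSeries], dest) -> None:
    """Write series to the canonical long format, including schedule and
    metadata columns so that a re-read round-trips field-by-field."""
    rows = []
    for s in series_list:
        members = list(s.cycles) + ([s.blank] if s.blank is not None else [])
        for c in members:
            sched = c.schedule
            for t, r in zip(c.times, c.responses):
                rows.append({
                    "series_id": s.series_id, "cycle": c.index,
                    "concentration": f"{c.concentration:.11E}",
                    "conc_unit": "M",
                    "time_s": f"{t:.11E}", "response": f"{r:.11E}",
                    "ligand": s.ligand, "analyte": s.analyte,
                    "regenerative": str(s.regenerative).lower(),
                    "response_unit": s.response_unit,
                    "is_blank": str(c is s.blank).lower(),
                    "baseline_start": f"{sched.baseline_start:.11E}",
                    "t0": f"{sched.t0:.11E}",
                    "t_asso": f"{sched.t_asso:.11E}",
                    "dissoc_end": f"{sched.dissoc_end:.11E}",
                })
    cols = CANONICAL_COLUMNS + ["ligand", "analyte", "regenerative",
                                "response_unit", "is_blank"] + SCHEDULE_COLUMNS
    pd.DataFrame(rows, columns=cols).to_csv(dest, index=False)


# ---------------------------------------------------------------------------
# sample sheet

@dataclass
class SampleSheetEntry:
    """One row of the user sample-information sheet.

    ``concentrations`` holds (1-based cycle index, molar value) pairs in
    cycle order; ``manual_concs`` is in molar.  ``bulk_shift`` and
    ``drift`` are mutually exclusive (the drift term is dropped whenever
    a bulk-shift term is fitted).
    """

    location: str
    series_id: str
    ligand: str = ""
    analyte: str = ""
    concentrations: list[tuple[int, float]] = field(default_factory=list)
    conc_unit: str = "M"
    regenerative: bool = True
    baseline_len: float = 120.0
    assoc_len: float = 300.0
    dissoc_fit_len: float = 750.0
    skip_assoc: float = 0.0
    skip_dissoc: float = 0.0
    selection_mode: str = "auto"
    manual_concs: list[float] | None = None
    global_rmax: bool = True
    bulk_shift: bool = False
    drift: bool = False
    blank_cycle: int | None = None

    def violations(self) -> list[str]:
        msgs = []
        if not self.skip_dissoc >= 0 or not self.dissoc_fit_len > self.skip_dissoc:
            msgs.append("dissoc_fit_len must exceed skip_dissoc >= 0")
        if not self.skip_assoc >= 0 or not self.assoc_len > self.skip_assoc:
            msgs.append("assoc_len must exceed skip_assoc >= 0")
        if self.selection_mode not in ("auto", "manual"):
            msgs.append(f"unknown selection_mode {self.selection_mode!r}")
        if self.selection_mode == "manual":
            if not self.manual_concs:
                msgs.append("selection_mode=manual requires manual_concs")
            elif len(self.manual_concs) > 5:
                msgs.append("manual selection is limited to 5 concentrations")
        elif self.manual_concs:
            msgs.append("manual_concs given but selection_mode is not manual")
        if self.bulk_shift and self.drift:
            msgs.append("bulk_shift and drift are mutually exclusive")
        return msgs


def _split_list(text) -> list[str]:
    if text is None or (isinstance(text, float) and math.isnan(text)):
        return []
    items = [p.strip() for p in str(text).replace("|", ";").split(";")]
    return [p for p in items if p and p.lower() != "nan"]


def read_sample_sheet(source) -> list[SampleSheetEntry]:
    """Read the sample sheet (CSV or first sheet of an Excel workbook).

    Boolean and enum columns parse case-insensitively; concentrations are
    converted to molar from the row's ``conc_unit``.  A violated entry
    invariant raises :class:`SampleSheetError` naming the row and rule.
    """
    path = pathlib.Path(source) if isinstance(source, (str, pathlib.Path)) else None
    if path is not None and path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, sheet_name=0, dtype=str)
    else:
        df = _read_delimited(source)
    required = ["location", "series_id", "concentrations", "conc_unit"]
    for col in required:
        if col not in df.columns:
            raise SampleSheetError(f"missing required column {col!r}")

    def get(row, col, default=""):
        if col in df.columns and not pd.isna(row[col]):
            return row[col]
        return default

    entries = []
    for i, (_, row) in enumerate(df.iterrows()):
        rownum = i + 2
        unit = str(get(row, "conc_unit", "M")).strip()
        try:
            concs = [(j + 1, to_molar(float(v), unit))
                     for j, v in enumerate(_split_list(row["concentrations"]))]
            manual = [to_molar(float(v), unit)
                      for v in _split_list(get(row, "manual_concs"))] or None
        except (TableFormatError, ValueError) as exc:
            raise SampleSheetError(f"row {rownum}: {exc}") from exc
        blank_raw = str(get(row, "blank_cycle", "")).strip()
        entry = SampleSheetEntry(
            location=str(get(row, "location")).strip(),
            series_id=str(get(row, "series_id")).strip(),
            ligand=str(get(row, "ligand")).strip(),
            analyte=str(get(row, "analyte")).strip(),
            concentrations=concs,
            conc_unit=unit,
            regenerative=_parse_bool(get(row, "regenerative", "true"),
                                     rownum, "regenerative"),
            baseline_len=float(get(row, "baseline_len", 120.0)),
            assoc_len=float(get(row, "assoc_len", 300.0)),
            dissoc_fit_len=float(get(row, "dissoc_fit_len", 750.0)),
            skip_assoc=float(get(row, "skip_assoc", 0.0)),
            skip_dissoc=float(get(row, "skip_dissoc", 0.0)),
            selection_mode=str(get(row, "selection_mode", "auto")).strip().lower(),
            manual_concs=manual,
            global_rmax=_parse_bool(get(row, "global_rmax", "true"),
                                    rownum, "global_rmax"),
            bulk_shift=_parse_bool(get(row, "bulk_shift", "false"),
                                   rownum, "bulk_shift"),
            drift=_parse_bool(get(row, "drift", "false"), rownum, "drift"),
            blank_cycle=(int(float(blank_raw))
                         if blank_raw and blank_raw.lower() != "nan" else None),
        )
        problems = entry.violations()
        if problems:
            raise SampleSheetError(f"row {rownum}: " + "; ".join(problems))
        entries.append(entry)
    return entries


# ---------------------------------------------------------------------------
# schedules and platform adapters

def attach_schedules(series: TitrationSeries,
                     entry: SampleSheetEntry) -> TitrationSeries:
    """Place per-cycle phase timestamps from the sheet's phase lengths.

    For each cycle, baseline starts at the cycle's first timestamp, the
    association start sits ``baseline_len`` later and ends ``assoc_len``
    after that; dissociation runs to the cycle's last timestamp.  Also
    applies the entry's regenerative flag, identity fields and blank
    designation.
    """
    def place(c: Cycle) -> Cycle:
        start = float(c.times[0])
        t0 = start + entry.baseline_len
        t_asso = t0 + entry.assoc_len
        end = float(c.times[-1])
        if end <= t_asso:
            raise TableFormatError(
                f"cycle {c.index}: trace ends at {end:g} s, before the "
                f"declared association end {t_asso:g} s")
        return Cycle(c.index, c.concentration, c.times, c.responses,
                     PhaseSchedule(start, t0, t_asso, end))

    cycles = []
    blank = series.blank
    for c in series.cycles:
        placed = place(c)
        if entry.blank_cycle is not None and c.index == entry.blank_cycle:
            placed.concentration = 0.0
            blank = placed
        else:
            cycles.append(placed)
    if blank is not None and blank.schedule.t_asso <= blank.schedule.t0:
        blank = place(blank)
    out = series.copy_with_cycles(cycles, blank=blank)
    out.regenerative = entry.regenerative
    out.series_id = entry.series_id or series.series_id
    out.ligand = entry.ligand or series.ligand
    out.analyte = entry.analyte or series.analyte
    return out


def _wide_frame(source) -> pd.DataFrame:
    df = _read_delimited(source)
    if df.shape[1] < 2:
        raise TableFormatError(
            "wide export needs one time column plus response column(s)")
    return df.apply(pd.to_numeric, errors="coerce")


def read_platform_export(source, platform: Platform | str,
                         mapping: Sequence[SampleSheetEntry]) -> list[TitrationSeries]:
    """Reshape a wide instrument export onto canonical series.

    carterra: one response column per spot, each carrying the whole
    stitched titration; only spots named by a mapping entry's
    ``location`` are materialized, and the trace is split into as many
    equal-duration cycles as the entry lists concentrations.

    biacore / octet: one response column per cycle sharing the time
    column; each mapping entry yields one series from the whole file, so
    the same trace may appear under several entries with different
    analysis preferences.
    """
    platform = Platform(platform)
    if platform not in (Platform.CARTERRA, Platform.BIACORE, Platform.OCTET):
        raise TableFormatError(f"unsupported platform {platform.value!r}")
    if isinstance(source, (str, pathlib.Path, _stdio.IOBase, _stdio.StringIO)):
        df = _wide_frame(source)
    else:
        df = source
    time = df.iloc[:, 0].to_numpy(dtype=float)

    out: list[TitrationSeries] = []
    for entry in mapping:
        if platform is Platform.CARTERRA:
            if entry.location not in df.columns:
                raise TableFormatError(
                    f"spot {entry.location!r} not found among export columns")
            resp = df[entry.location].to_numpy(dtype=float)
            ok = np.isfinite(time) & np.isfinite(resp)
            t, r = time[ok], resp[ok]
            n = len(entry.concentrations)
            if n == 0:
                raise SampleSheetError(
                    f"entry {entry.series_id!r}: no concentrations listed")
            dt = np.median(np.diff(t)) if t.size > 1 else 1.0
            seg = (t[-1] + dt - t[0]) / n
            cycles = []
            for j, (idx, conc) in enumerate(entry.concentrations):
                lo, hi = t[0] + j * seg, t[0] + (j + 1) * seg
                m = (t >= lo) & (t < hi)
                sched = PhaseSchedule(lo, lo + entry.baseline_len,
                                      lo + entry.baseline_len + entry.assoc_len,
                                      hi)
                cycles.append(Cycle(idx, conc, t[m], r[m], sched))
            series = TitrationSeries(
                series_id=entry.series_id, ligand=entry.ligand,
                analyte=entry.analyte, platform=platform,
                regenerative=entry.regenerative, cycles=cycles)
        else:
            resp_cols = list(df.columns[1:])
            if len(resp_cols) != len(entry.concentrations):
                raise TableFormatError(
                    f"entry {entry.series_id!r}: export has {len(resp_cols)} "
                    f"response columns but the sheet lists "
                    f"{len(entry.concentrations)} concentrations")
            cycles = []
            for col, (idx, conc) in zip(resp_cols, entry.concentrations):
                resp = df[col].to_numpy(dtype=float)
                ok = np.isfinite(time) & np.isfinite(resp)
                t, r = time[ok], resp[ok]
                start = float(t[0])
                sched = PhaseSchedule(
                    start, start + entry.baseline_len,
                    start + entry.baseline_len + entry.assoc_len, float(t[-1]))
                cycles.append(Cycle(idx, conc, t, r, sched))
            series = TitrationSeries(
                series_id=entry.series_id, ligand=entry.ligand,
                analyte=entry.analyte, platform=platform,
                regenerative=entry.regenerative, cycles=cycles)
        if entry.blank_cycle is not None:
            keep, blank = [], None
            for c in series.cycles:
                if c.index == entry.blank_cycle:
                    c.concentration = 0.0
                    blank = c
                else:
                    keep.append(c)
            series = series.copy_with_cycles(keep, blank=blank)
        out.append(series)
    return out


# ---------------------------------------------------------------------------
# estimates table

def _fmt(x) -> str:
    if x is None:
        return "NA"
    x = float(x)
    if not math.isfinite(x):
        return "NA"
    return f"{x:.11E}"


def write_estimates_table(results, dest) -> None:
    """Write one CSV row of estimates per fitted series.

    Columns: ``series_id, ligand, analyte, n_points, ka, SE_ka, kd,
    SE_kd, KD, SE_KD, Rmax, SE_Rmax, selected_concentrations, converged``.
    Per-cycle local Rmax values are semicolon-joined in their column;
    numbers carry 12 significant digits so a re-read round-trips.
    """
    rows = []
    for r in results:
        rows.append({
            "series_id": r.series_id, "ligand": r.ligand, "analyte": r.analyte,
            "n_points": str(int(r.n_points)),
            "ka": _fmt(r.ka), "SE_ka": _fmt(r.se_ka),
            "kd": _fmt(r.kd), "SE_kd": _fmt(r.se_kd),
            "KD": _fmt(r.kD), "SE_KD": _fmt(r.se_kD),
            "Rmax": ";".join(_fmt(v) for v in np.atleast_1d(r.rmax_values)),
            "SE_Rmax": ";".join(_fmt(v) for v in np.atleast_1d(r.se_rmax)),
            "selected_concentrations":
                ";".join(_fmt(c) for c in r.selected_concentrations),
            "converged": str(bool(r.converged)).lower(),
        })
    pd.DataFrame(rows, columns=ESTIMATE_COLUMNS).to_csv(
        dest, index=False, lineterminator="\n")


def read_estimates_table(source) -> pd.DataFrame:
    """Read an estimates CSV back with numeric scalar columns restored."""
    df = pd.read_csv(source, dtype=str)
    for col in ("n_points", "ka", "SE_ka", "kd", "SE_kd", "KD", "SE_KD"):
        df[col] = pd.to_numeric(df[col].replace("NA", np.nan))
    return df
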