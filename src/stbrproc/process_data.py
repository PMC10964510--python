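"""Domain types and tidy-CSV interchange for bioreactor process time series.

A *run* is an ordered list of passages; a *passage* is an ordered list of
samples taken from one suspension culture between inoculation and harvest,
plus the perfusion (continuous medium exchange) schedule that was active.

Canonical internal units, used by every module in this package:

========================  =================
quantity                  unit
========================  =================
time                      d (days)
viable cell density       cells/mL
metabolite concentration  mmol/L (mM)
culture volume            L
perfusion rate            L/d, or vessel volumes per day ("vvd")
========================  =================

Unit conversions required by the rate formulas (cells/L, pmol/L) happen
inside :mod:`stbrproc.kinetics`, never in storage.

The interchange format is a set of plain CSV files sharing one ``run_id``:

* ``samples.csv``   — run_id, passage_label, time_d, viable_density_cells_per_ml,
  viability_pct, glucose_mM, lactate_mM
* ``passages.csv``  — run_id, passage_label, volume_L, inoc_density_cells_per_ml,
  duration_d
* ``perfusion.csv`` — run_id, passage_label, t_start_d, t_end_d, rate_value,
  rate_unit ("L_per_day" | "vvd"), feed_glucose_mM
* ``cryo.csv``      — optional; run_id, before_passage_label, cpd_cells_per_ml,
  recovery_post_thaw, recovery_d1

Comma separated, dot decimal, UTF-8. Lines starting with ``#`` are comments
(used to embed provenance such as the generator seed). Missing optional
values are empty fields. Floats are written with ``repr`` so a write→read
round-trip is bit-exact.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ValidationError",
    "ProcessSample",
    "PerfusionSegment",
    "PerfusionSchedule",
    "PassageRecord",
    "ProcessRun",
    "load_run",
    "write_run",
    "summarize_run",
]

RATE_UNITS = ("L_per_day", "vvd")

SAMPLES_COLUMNS = [
    "run_id", "passage_label", "time_d", "viable_density_cells_per_ml",
    "viability_pct", "glucose_mM", "lactate_mM",
]
PASSAGES_COLUMNS = [
    "run_id", "passage_label", "volume_L", "inoc_density_cells_per_ml",
    "duration_d",
]
PERFUSION_COLUMNS = [
    "run_id", "passage_label", "t_start_d", "t_end_d", "rate_value",
    "rate_unit", "feed_glucose_mM",
]
CRYO_COLUMNS = [
    "run_id", "before_passage_label", "cpd_cells_per_ml",
    "recovery_post_thaw", "recovery_d1",
]


class ValidationError(ValueError):
    """Raised when data violates a type invariant or the file schema."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass(frozen=True)
class ProcessSample:
    """One timestamped measurement of a suspension culture.

    Parameters
    ----------
    t : float
        Time since passage inoculation [d].
    X : float
        Viable cell density [cells/mL].
    glc : float
        Glucose concentration [mM].
    lac : float
        Lactate concentration [mM].
    viability : float, optional
        Percent viable cells in [0, 100].
    """

    t: float
    X: float
    glc: float
    lac: float
    viability: float | None = None

    def __post_init__(self) -> None:
        _require(self.t >= 0, f"sample time must be >= 0, got {self.t}")
        _require(self.X >= 0, f"viable density must be >= 0, got {self.X}")
        _require(self.glc >= 0, f"glucose must be >= 0, got {self.glc}")
        _require(self.lac >= 0, f"lactate must be >= 0, got {self.lac}")
        if self.viability is not None:
            _require(
                0 <= self.viability <= 100,
                f"viability must be in [0, 100], got {self.viability}",
            )


@dataclass(frozen=True)
class PerfusionSegment:
    """Constant-rate perfusion over ``[t_start, t_end)``.

    ``rate`` carries the unit named by ``unit``: "L_per_day" for an absolute
    flow F, "vvd" for vessel volumes per day (F/V). ``glc_feed`` is the
    glucose concentration of the feed stream [mM]; the feed is lactate-free.
    """

    t_start: float
    t_end: float
    rate: float
    unit: str
    glc_feed: float

    def __post_init__(self) -> None:
        _require(self.t_start < self.t_end,
                 f"segment needs t_start < t_end, got [{self.t_start}, {self.t_end}]")
        _require(self.rate >= 0, f"perfusion rate must be >= 0, got {self.rate}")
        _require(self.unit in RATE_UNITS,
                 f"rate unit must be one of {RATE_UNITS}, got {self.unit!r}")
        _require(self.glc_feed >= 0,
                 f"feed glucose must be >= 0, got {self.glc_feed}")

    def rate_L_per_day(self, volume: float) -> float:
        """Absolute flow F [L/d] for a culture of ``volume`` litres."""
        return self.rate if self.unit == "L_per_day" else self.rate * volume


@dataclass(frozen=True)
class PerfusionSchedule:
    """Ordered, non-overlapping piecewise-constant perfusion segments."""

    segments: tuple[PerfusionSegment, ...] = ()

    def __post_init__(self) -> None:
        segs = tuple(self.segments)
        object.__setattr__(self, "segments", segs)
        for a, b in zip(segs, segs[1:]):
            _require(a.t_end <= b.t_start + 1e-12,
                     f"segments overlap or are unordered at t={b.t_start}")

    @classmethod
    def empty(cls) -> "PerfusionSchedule":
        return cls(())

    def rate_L_per_day(self, t: float, volume: float) -> float:
        """F [L/d] at time ``t`` (0 outside any segment)."""
        for seg in self.segments:
            if seg.t_start <= t < seg.t_end:
                return seg.rate_L_per_day(volume)
        return 0.0

    def overlapping(self, t0: float, t1: float) -> list[PerfusionSegment]:
        """Segments with positive rate intersecting the open interval (t0, t1)."""
        return [s for s in self.segments
                if s.rate > 0 and s.t_start < t1 - 1e-12 and s.t_end > t0 + 1e-12]

    def mean_rate_L_per_day(self, t0: float, t1: float, volume: float) -> float:
        """Time-weighted mean F [L/d] over ``[t0, t1]`` (gaps count as 0)."""
        _require(t1 > t0, "mean_rate needs t1 > t0")
        total = 0.0
        for seg in self.segments:
            lo, hi = max(t0, seg.t_start), min(t1, seg.t_end)
            if hi > lo:
                total += seg.rate_L_per_day(volume) * (hi - lo)
        return total / (t1 - t0)

    def feed_concentrations(self, t0: float, t1: float) -> set[float]:
        """Distinct feed glucose levels of active segments in ``(t0, t1)``."""
        return {s.glc_feed for s in self.overlapping(t0, t1)}


@dataclass(frozen=True)
class PassageRecord:
    """Ordered samples plus configuration for one passage."""

    label: str
    volume: float
    inoc_density: float
    duration: float
    samples: tuple[ProcessSample, ...]
    schedule: PerfusionSchedule = field(default_factory=PerfusionSchedule.empty)

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", tuple(self.samples))
        _require(self.volume > 0,
                 f"passage {self.label!r}: volume must be > 0, got {self.volume}")
        _require(self.inoc_density > 0,
                 f"passage {self.label!r}: inoc_density must be > 0")
        _require(self.duration > 0,
                 f"passage {self.label!r}: duration must be > 0")
        if self.samples:
            _require(self.samples[0].t == 0,
                     f"passage {self.label!r}: first sample must be at t=0, "
                     f"got t={self.samples[0].t}")
            for a, b in zip(self.samples, self.samples[1:]):
                _require(b.t > a.t,
                         f"passage {self.label!r}: sample times must be strictly "
                         f"increasing (t={a.t} followed by t={b.t})")


@dataclass(frozen=True)
class ProcessRun:
    """Ordered passages with optional cryopreservation markers between them.

    ``cryo_events`` maps the index of the passage that *follows* the event
    (1 ≤ index ≤ n_passages − 1 when the run continues after thaw, or
    == n_passages for a terminal freeze) to a
    :class:`stbrproc.seedtrain.CryoEvent`.
    """

    passages: tuple[PassageRecord, ...]
    run_id: str = "run1"
    cryo_events: tuple[tuple[int, "object"], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "passages", tuple(self.passages))
        object.__setattr__(self, "cryo_events", tuple(self.cryo_events))
        n = len(self.passages)
        for idx, _ in self.cryo_events:
            _require(1 <= idx <= n,
                     f"cryo event position {idx} outside valid range 1..{n}")
        labels = [p.label for p in self.passages]
        _require(len(set(labels)) == len(labels),
                 f"duplicate passage labels in run {self.run_id!r}")


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

def _fmt(x: float | None) -> str:
    if x is None:
        return ""
    return repr(float(x))


def _resolve_dir(path: str | Path) -> Path:
    p = Path(path)
    return p.parent if p.suffix == ".csv" else p


def write_run(run: ProcessRun, path: str | Path,
              header_comment: str | None = None) -> Path:
    """Write ``run`` to ``path`` (a directory) as the tidy CSV file set.

    Returns the directory written. ``header_comment`` lines (without the
    leading ``#``) are embedded at the top of every file.
    """
    d = _resolve_dir(path)
    d.mkdir(parents=True, exist_ok=True)
    prefix = ""
    if header_comment:
        prefix = "".join(f"# {line}\n" for line in header_comment.splitlines())

    rows = []
    for p in run.passages:
        for s in p.samples:
            rows.append([run.run_id, p.label, _fmt(s.t), _fmt(s.X),
                         _fmt(s.viability), _fmt(s.glc), _fmt(s.lac)])
    _write_csv(d / "samples.csv", SAMPLES_COLUMNS, rows, prefix)

    rows = [[run.run_id, p.label, _fmt(p.volume), _fmt(p.inoc_density),
             _fmt(p.duration)] for p in run.passages]
    _write_csv(d / "passages.csv", PASSAGES_COLUMNS, rows, prefix)

    rows = []
    for p in run.passages:
        for seg in p.schedule.segments:
            rows.append([run.run_id, p.label, _fmt(seg.t_start), _fmt(seg.t_end),
                         _fmt(seg.rate), seg.unit, _fmt(seg.glc_feed)])
    _write_csv(d / "perfusion.csv", PERFUSION_COLUMNS, rows, prefix)

    if run.cryo_events:
        rows = []
        for idx, ev in run.cryo_events:
            label = run.passages[idx].label if idx < len(run.passages) else ""
            rows.append([run.run_id, label, _fmt(ev.cpd),
                         _fmt(ev.recovery_post_thaw), _fmt(ev.recovery_d1)])
        _write_csv(d / "cryo.csv", CRYO_COLUMNS, rows, prefix)
    return d


def _write_csv(path: Path, columns: Sequence[str],
               rows: Iterable[Sequence[str]], prefix: str) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(prefix)
        fh.write(",".join(columns) + "\n")
        for row in rows:
            fh.write(",".join(str(c) for c in row) + "\n")


def _read_csv(path: Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", float_precision="round_trip",
                     dtype={"run_id": str,
                                               "passage_label": str,
                                               "rate_unit": str,
                                               "before_passage_label": str})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing columns {missing}")
    return df


def _float_cell(df_name: str, row: int, col: str, value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValidationError(
            f"{df_name} row {row}: non-numeric value {value!r} in column {col!r}"
        ) from None


def load_run(path: str | Path, format: str = "samples-csv") -> ProcessRun:
    """Load a validated :class:`ProcessRun` from the tidy CSV file set.

    ``path`` may be the directory containing the file set or the
    ``samples.csv`` path itself; ``passages.csv`` and ``perfusion.csv``
    (and optional ``cryo.csv``) are read from the same directory.
    Malformed rows raise :class:`ValidationError` naming the file, row and
    offending field.
    """
    if format != "samples-csv":
        raise ValidationError(f"unknown format {format!r}")
    d = _resolve_dir(path)
    samples_path = d / "samples.csv"
    if not samples_path.exists():
        raise ValidationError(f"no samples.csv in {d}")
    samples = _read_csv(samples_path, SAMPLES_COLUMNS)
    passages = _read_csv(d / "passages.csv", PASSAGES_COLUMNS)
    perfusion_path = d / "perfusion.csv"
    perfusion = (_read_csv(perfusion_path, PERFUSION_COLUMNS)
                 if perfusion_path.exists() else pd.DataFrame(columns=PERFUSION_COLUMNS))

    run_ids = set(samples["run_id"]) | set(passages["run_id"])
    if len(run_ids) > 1:
        raise ValidationError(f"file set contains multiple run_ids {sorted(run_ids)}; "
                              "one run per file set")
    run_id = next(iter(run_ids)) if run_ids else "run1"

    sched_by_label: dict[str, list[PerfusionSegment]] = {}
    for i, row in perfusion.iterrows():
        try:
            seg = PerfusionSegment(
                t_start=_float_cell("perfusion.csv", i, "t_start_d", row["t_start_d"]),
                t_end=_float_cell("perfusion.csv", i, "t_end_d", row["t_end_d"]),
                rate=_float_cell("perfusion.csv", i, "rate_value", row["rate_value"]),
                unit=str(row["rate_unit"]),
                glc_feed=_float_cell("perfusion.csv", i, "feed_glucose_mM",
                                     row["feed_glucose_mM"]),
            )
        except ValidationError as e:
            raise ValidationError(f"perfusion.csv row {i}: {e}") from None
        sched_by_label.setdefault(str(row["passage_label"]), []).append(seg)

    samples_by_label: dict[str, list[ProcessSample]] = {}
    for i, row in samples.iterrows():
        viability = _float_cell("samples.csv", i, "viability_pct", row["viability_pct"])
        try:
            s = ProcessSample(
                t=_float_cell("samples.csv", i, "time_d", row["time_d"]),
                X=_float_cell("samples.csv", i, "viable_density_cells_per_ml",
                              row["viable_density_cells_per_ml"]),
                glc=_float_cell("samples.csv", i, "glucose_mM", row["glucose_mM"]),
                lac=_float_cell("samples.csv", i, "lactate_mM", row["lactate_mM"]),
                viability=viability,
            )
        except ValidationError as e:
            raise ValidationError(f"samples.csv row {i}: {e}") from None
        samples_by_label.setdefault(str(row["passage_label"]), []).append(s)

    records = []
    for i, row in passages.iterrows():
        label = str(row["passage_label"])
        try:
            rec = PassageRecord(
                label=label,
                volume=_float_cell("passages.csv", i, "volume_L", row["volume_L"]),
                inoc_density=_float_cell("passages.csv", i,
                                         "inoc_density_cells_per_ml",
                                         row["inoc_density_cells_per_ml"]),
                duration=_float_cell("passages.csv", i, "duration_d", row["duration_d"]),
                samples=tuple(samples_by_label.pop(label, [])),
                schedule=PerfusionSchedule(tuple(sched_by_label.pop(label, []))),
            )
        except ValidationError as e:
            raise ValidationError(f"passages.csv row {i} (passage {label!r}): {e}") from None
        records.append(rec)
    if samples_by_label:
        raise ValidationError(
            f"samples.csv references passages missing from passages.csv: "
            f"{sorted(samples_by_label)}")

    cryo_events: list[tuple[int, object]] = []
    cryo_path = d / "cryo.csv"
    if cryo_path.exists():
        from .seedtrain import CryoEvent  # deferred: avoids import cycle
        cryo = _read_csv(cryo_path, CRYO_COLUMNS)
        label_index = {p.label: k for k, p in enumerate(records)}
        for i, row in cryo.iterrows():
            ev = CryoEvent(
                cpd=_float_cell("cryo.csv", i, "cpd_cells_per_ml",
                                row["cpd_cells_per_ml"]),
                recovery_post_thaw=_float_cell("cryo.csv", i, "recovery_post_thaw",
                                               row["recovery_post_thaw"]),
                recovery_d1=_float_cell("cryo.csv", i, "recovery_d1",
                                        row["recovery_d1"]),
            )
            label = row["before_passage_label"]
            if label is None or (isinstance(label, float) and math.isnan(label)) or label == "":
                idx = len(records)
            elif str(label) in label_index:
                idx = label_index[str(label)]
            else:
                raise ValidationError(
                    f"cryo.csv row {i}: unknown passage label {label!r}")
            cryo_events.append((idx, ev))

    return ProcessRun(passages=tuple(records), run_id=run_id,
                      cryo_events=tuple(cryo_events))


def summarize_run(run: ProcessRun) -> pd.DataFrame:
    """Per-passage summary: harvest density, fold expansion, day-1 density,
    glucose extrema and peak lactate.

    Fold expansion is harvest density over inoculation density
    (:func:`stbrproc.seedtrain.fold_expansion`). Raises
    :class:`ValidationError` for passages with fewer than two samples.
    """
    from .seedtrain import fold_expansion

    rows = []
    for p in run.passages:
        if len(p.samples) < 2:
            raise ValidationError(
                f"passage {p.label!r} has {len(p.samples)} sample(s); "
                "need at least 2 to summarize")
        harvest = p.samples[-1].X
        day1 = next((s.X for s in p.samples if math.isclose(s.t, 1.0, abs_tol=1e-9)),
                    math.nan)
        glc = [s.glc for s in p.samples]
        lac = [s.lac for s in p.samples]
        rows.append({
            "run_id": run.run_id,
            "passage_label": p.label,
            "harvest_density_cells_per_ml": harvest,
            "fold_expansion": fold_expansion(harvest, p.inoc_density),
            "day1_density_cells_per_ml": day1,
            "glucose_max_mM": max(glc),
            "glucose_min_mM": min(glc),
            "lactate_max_mM": max(lac),
        })
    return pd.DataFrame(rows)
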