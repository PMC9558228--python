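"""Cerebral oximetry (rSO2) series: I/O, validation, baseline and
desaturation-burden summaries.

A series is a uniformly sampled saturation trace (one sample every 2 s) with
two annotated index windows: a 60-sample pre-induction baseline and the
intraoperative segment used for all downstream analysis.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import (
    SeriesDomainError,
    SeriesFormatError,
    SeriesTooShortError,
    WindowError,
)

log = logging.getLogger(__name__)

SAMPLING_INTERVAL_S = 2.0
BASELINE_SAMPLES = 60  # 2 min at 2 s
MIN_INTRAOP_SAMPLES = 100
MAX_GAP_S = 10.0  # longest dropout bridged by carry-forward
STANDARD_FRACTIONS = (1.0, 0.9, 0.8)

CSV_HEADER = ("time_s", "rso2_pct")


@dataclass
class Rso2Series:
    """One subject's oximetry trace with its annotated windows.

    ``baseline_window`` and ``intraop_window`` are half-open index ranges
    into ``values``; the baseline spans exactly 60 samples and precedes the
    intraoperative window.
    """

    subject_id: str
    values: np.ndarray
    baseline_window: tuple[int, int]
    intraop_window: tuple[int, int]
    side: str = "left"
    sampling_interval: float = SAMPLING_INTERVAL_S

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise SeriesFormatError("values must be one-dimensional")
        if np.any(self.values < 0) or np.any(self.values > 100):
            raise SeriesDomainError("saturation values must lie in [0, 100]")
        b0, b1 = self.baseline_window
        i0, i1 = self.intraop_window
        if b1 - b0 != BASELINE_SAMPLES:
            raise WindowError(
                f"baseline window must span exactly {BASELINE_SAMPLES} samples, "
                f"got {b1 - b0}"
            )
        if not (0 <= b0 < b1 <= i0 < i1 <= self.values.size):
            raise WindowError("windows must be ordered baseline < intraop and in range")
        if i1 - i0 < MIN_INTRAOP_SAMPLES:
            raise SeriesTooShortError(
                f"intraoperative window has {i1 - i0} samples; "
                f"at least {MIN_INTRAOP_SAMPLES} required"
            )
        if self.side not in ("left", "right"):
            raise SeriesFormatError(f"side must be 'left' or 'right', got {self.side!r}")

    @property
    def baseline_values(self) -> np.ndarray:
        b0, b1 = self.baseline_window
        return self.values[b0:b1]

    @property
    def intraop_values(self) -> np.ndarray:
        i0, i1 = self.intraop_window
        return self.values[i0:i1]

    @property
    def n_intraop(self) -> int:
        return self.intraop_window[1] - self.intraop_window[0]


@dataclass(frozen=True)
class SeriesSummary:
    baseline: float
    mean: float
    lowest: float
    highest: float
    n_points: int
    duration_min: float


@dataclass(frozen=True)
class DesatMetrics:
    """Time (min) and area (min.%) spent strictly below a baseline fraction."""

    threshold_fraction: float
    threshold_value: float
    duration: float
    area: float


def _meta_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def read_series(path: str | Path) -> Rso2Series:
    """Read a series CSV (`time_s,rso2_pct`) plus its `.meta.json` sidecar.

    The grid must be uniform at 2 s; dropouts up to 10 s are bridged by
    previous-value carry-forward (logged), longer gaps are format errors.
    """
    path = Path(path)
    meta_file = _meta_path(path)
    if not meta_file.exists():
        raise SeriesFormatError(f"missing sidecar {meta_file}")
    meta = json.loads(meta_file.read_text())
    for key in ("subject_id", "side", "baseline_start_s", "baseline_end_s",
                "intraop_start_s", "intraop_end_s"):
        if key not in meta:
            raise SeriesFormatError(f"sidecar {meta_file} missing key {key!r}")

    times: list[float] = []
    vals: list[float] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or tuple(h.strip() for h in header) != CSV_HEADER:
            raise SeriesFormatError(
                f"{path}: expected header {','.join(CSV_HEADER)}, got {header}"
            )
        for row in reader:
            if not row:
                continue
            try:
                times.append(float(row[0]))
                vals.append(float(row[1]))
            except (ValueError, IndexError) as exc:
                raise SeriesFormatError(f"{path}: bad row {row!r}") from exc
    if not times:
        raise SeriesFormatError(f"{path}: no data rows")

    t = np.asarray(times)
    v = np.asarray(vals)
    dt = SAMPLING_INTERVAL_S
    # every timestamp must sit on the 2-s grid anchored at the first sample
    offsets = (t - t[0]) / dt
    if np.any(np.abs(offsets - np.round(offsets)) > 1e-6):
        raise SeriesFormatError(f"{path}: samples do not lie on a uniform {dt}-s grid")
    idx = np.round(offsets).astype(int)
    if np.any(np.diff(idx) <= 0):
        raise SeriesFormatError(f"{path}: timestamps not strictly increasing")

    n = int(idx[-1]) + 1
    filled = np.empty(n)
    filled.fill(np.nan)
    filled[idx] = v
    missing = np.isnan(filled)
    if missing.any():
        gaps = np.diff(idx)
        worst = (int(gaps.max()) - 1) * dt
        if worst > MAX_GAP_S:
            raise SeriesFormatError(
                f"{path}: dropout of {worst:.0f} s exceeds the {MAX_GAP_S:.0f}-s limit"
            )
        log.warning(
            "%s: bridging %d missing samples by carry-forward", path, int(missing.sum())
        )
        for i in np.flatnonzero(missing):
            filled[i] = filled[i - 1]

    def to_index(seconds: float) -> int:
        rel = (float(seconds) - t[0]) / dt
        if abs(rel - round(rel)) > 1e-6:
            raise SeriesFormatError(f"{path}: window bound {seconds} off the grid")
        return int(round(rel))

    return Rso2Series(
        subject_id=str(meta["subject_id"]),
        values=filled,
        baseline_window=(to_index(meta["baseline_start_s"]), to_index(meta["baseline_end_s"])),
        intraop_window=(to_index(meta["intraop_start_s"]), to_index(meta["intraop_end_s"])),
        side=str(meta["side"]),
    )


def write_series(series: Rso2Series, path: str | Path) -> Path:
    """Write the CSV + sidecar pair in the dialect `read_series` consumes."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dt = series.sampling_interval
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for i, val in enumerate(series.values):
            writer.writerow([f"{i * dt:g}", repr(float(val))])
    meta = {
        "subject_id": series.subject_id,
        "side": series.side,
        "baseline_start_s": series.baseline_window[0] * dt,
        "baseline_end_s": series.baseline_window[1] * dt,
        "intraop_start_s": series.intraop_window[0] * dt,
        "intraop_end_s": series.intraop_window[1] * dt,
    }
    _meta_path(path).write_text(json.dumps(meta, indent=1))
    return path


def compute_baseline(series: Rso2Series) -> float:
    """Mean saturation over the 60-sample pre-induction window."""
    vals = series.baseline_values
    if vals.size != BASELINE_SAMPLES:
        raise WindowError(f"baseline window has {vals.size} samples, expected {BASELINE_SAMPLES}")
    return float(np.mean(vals))


def summarize(series: Rso2Series) -> SeriesSummary:
    intra = series.intraop_values
    n = intra.size
    return SeriesSummary(
        baseline=compute_baseline(series),
        mean=float(np.mean(intra)),
        lowest=float(np.min(intra)),
        highest=float(np.max(intra)),
        n_points=n,
        duration_min=n * series.sampling_interval / 60.0,
    )


def desaturation_metrics(
    series: Rso2Series, baseline: float, fraction: float
) -> DesatMetrics:
    """Desaturation burden strictly below ``fraction x baseline``.

    Each sample below threshold contributes its full 2-s dwell; duration is
    in minutes, area in min.% (rectangular integration, no interpolation of
    crossings).
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    if fraction not in STANDARD_FRACTIONS:
        log.warning("nonstandard threshold fraction %s (study used 1.0/0.9/0.8)", fraction)
    threshold = fraction * baseline
    intra = series.intraop_values
    below = intra < threshold
    minutes_per_sample = series.sampling_interval / 60.0
    duration = float(below.sum()) * minutes_per_sample
    area = float(np.sum(threshold - intra[below])) * minutes_per_sample
    return DesatMetrics(
        threshold_fraction=fraction,
        threshold_value=float(threshold),
        duration=duration,
        area=area,
    )
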