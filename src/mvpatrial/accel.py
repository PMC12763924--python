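"""Epoch-level accelerometer processing.

Converts triaxial ActiGraph-style count series recorded at short (typically
1-second) epochs into per-child, per-timepoint intensity-spectrum descriptors:

* restriction to the preschool-hours window (08:30–15:30),
* non-wear detection as maximal runs of >= 20 min of zero counts,
* classification of each wear epoch into counts-per-minute (cpm) intensity
  bins — either the traditional 4-class descriptor (SED/LPA/MPA/VPA, Evenson
  cut points on the vertical axis) or a 17-bin intensity spectrum per axis,
* day-level aggregation and wear-time validity screening
  (>= 300 min/day wear on >= 3 weekdays).

Cut points are published in cpm; epoch counts are compared after scaling the
integer count by ``60 / epoch_len`` so that all threshold comparisons stay in
exact integer arithmetic for 1-s epochs.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AXES",
    "EpochSeries",
    "DescriptorSpec",
    "DaySummary",
    "ChildSpectrum",
    "restrict_window",
    "detect_nonwear",
    "classify_epoch",
    "summarize_day",
    "aggregate_child",
    "read_epoch_csv",
    "spectra_to_frame",
    "process_epoch_files",
]

#: Axis order used throughout: vertical, anteroposterior, mediolateral.
AXES = ("vertical", "ap", "ml")

# Evenson cut points (cpm, vertical axis): SED <= 100, LPA 101-2295,
# MPA 2296-4011, VPA >= 4012. Stored as inclusive upper bounds.
_TRADITIONAL_UPPER = np.array([100, 2295, 4011])
_TRADITIONAL_NAMES = ("sed", "lpa", "mpa", "vpa")

# Intensity-spectrum lower edges (cpm): 0-99, 100-999, then 1000-wide bins up
# to 14000-14999, and >= 15000 — 17 bins.
_SPECTRUM_LOWER = np.array([0, 100] + list(range(1000, 15001, 1000)))
assert len(_SPECTRUM_LOWER) == 17


@dataclass
class EpochSeries:
    """One child-day of contiguous triaxial epoch counts.

    ``counts`` has shape (n_epochs, 3) with columns ordered as :data:`AXES`.
    ``start`` is the clock time of the first epoch; epochs are contiguous at
    ``epoch_len`` seconds.
    """

    child_id: str
    date: dt.date
    start: dt.time
    counts: np.ndarray
    epoch_len: int = 1

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[1] != 3:
            raise ValueError("counts must have shape (n_epochs, 3)")
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("negative counts are invalid")
        if self.epoch_len <= 0:
            raise ValueError("epoch_len must be positive")

    def __len__(self) -> int:
        return self.counts.shape[0]

    @property
    def start_seconds(self) -> int:
        t = self.start
        return t.hour * 3600 + t.minute * 60 + t.second

    def epoch_offsets(self) -> np.ndarray:
        """Seconds since midnight of each epoch's start."""
        return self.start_seconds + np.arange(len(self)) * self.epoch_len

    @property
    def is_weekday(self) -> bool:
        return self.date.weekday() < 5  # Monday=0 .. Friday=4


@dataclass(frozen=True)
class DescriptorSpec:
    """An intensity descriptor: which axes and which cpm bins.

    Two bin conventions coexist, both honoured as printed in the source
    classifications: the traditional descriptor uses inclusive upper bounds
    (SED means cpm <= 100), the spectrum uses lower-inclusive edges (bin 1 is
    [0, 100) so exactly 100 cpm is spectrum bin 2 but traditional SED).
    """

    name: str
    axes: tuple[str, ...]
    kind: str  # "traditional" | "spectrum"

    @staticmethod
    def traditional() -> "DescriptorSpec":
        return DescriptorSpec("traditional", ("vertical",), "traditional")

    @staticmethod
    def spectrum_uniaxial() -> "DescriptorSpec":
        return DescriptorSpec("spectrum_uniaxial", ("vertical",), "spectrum")

    @staticmethod
    def spectrum_triaxial() -> "DescriptorSpec":
        return DescriptorSpec("spectrum_triaxial", AXES, "spectrum")

    @staticmethod
    def from_name(name: str) -> "DescriptorSpec":
        try:
            return {
                "traditional": DescriptorSpec.traditional,
                "spectrum_uniaxial": DescriptorSpec.spectrum_uniaxial,
                "uniaxial": DescriptorSpec.spectrum_uniaxial,
                "spectrum_triaxial": DescriptorSpec.spectrum_triaxial,
                "triaxial": DescriptorSpec.spectrum_triaxial,
            }[name]()
        except KeyError:
            raise ValueError(f"unknown descriptor {name!r}") from None

    @property
    def n_bins(self) -> int:
        return 4 if self.kind == "traditional" else 17

    @property
    def variable_names(self) -> list[str]:
        if self.kind == "traditional":
            return list(_TRADITIONAL_NAMES)
        prefix = {"vertical": "v", "ap": "ap", "ml": "ml"}
        return [
            f"{prefix[ax]}_bin{b + 1:02d}" for ax in self.axes for b in range(17)
        ]

    def classify_rates(self, rates_cpm: np.ndarray) -> np.ndarray:
        """Vectorized bin index (0-based) for cpm-equivalent rates."""
        rates_cpm = np.asarray(rates_cpm)
        if rates_cpm.size and rates_cpm.min() < 0:
            raise ValueError("negative rate")
        if self.kind == "traditional":
            # first index whose inclusive upper bound covers the rate
            return np.searchsorted(_TRADITIONAL_UPPER, rates_cpm, side="left")
        return np.searchsorted(_SPECTRUM_LOWER, rates_cpm, side="right") - 1


def restrict_window(
    series: EpochSeries, start: dt.time, end: dt.time
) -> EpochSeries:
    """Keep only epochs whose start time lies in the half-open [start, end).

    An empty result is legitimate (the day then contributes zero wear).
    """
    if start >= end:
        raise ValueError("window start must precede end within one day")
    offs = series.epoch_offsets()
    s = start.hour * 3600 + start.minute * 60 + start.second
    e = end.hour * 3600 + end.minute * 60 + end.second
    keep = (offs >= s) & (offs < e)
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        new_start = start
        counts = series.counts[:0]
    else:
        first = int(offs[idx[0]])
        new_start = dt.time(first // 3600, (first % 3600) // 60, first % 60)
        counts = series.counts[idx[0] : idx[-1] + 1]
    return EpochSeries(
        child_id=series.child_id,
        date=series.date,
        start=new_start,
        counts=counts,
        epoch_len=series.epoch_len,
    )


def detect_nonwear(series: EpochSeries, min_zero_minutes: float = 20) -> np.ndarray:
    """Boolean wear mask: False inside qualifying zero-count runs.

    An epoch is non-wear iff it belongs to a maximal run of consecutive
    zero-count epochs on the vertical axis lasting >= ``min_zero_minutes``
    (threshold inclusive). A single nonzero epoch breaks a run.
    """
    if min_zero_minutes <= 0:
        raise ValueError("min_zero_minutes must be positive")
    n = len(series)
    wear = np.ones(n, dtype=bool)
    if n == 0:
        return wear
    zero = series.counts[:, 0] == 0
    # run-length encode the zero indicator
    change = np.flatnonzero(np.diff(zero.astype(np.int8)))
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [n]))
    min_epochs = min_zero_minutes * 60.0 / series.epoch_len
    for s, e in zip(starts, ends):
        if zero[s] and (e - s) >= min_epochs:
            wear[s:e] = False
    return wear


def classify_epoch(
    count: int, epoch_len: int, spec: DescriptorSpec, axis: str = "vertical"
) -> int:
    """Bin index for a single epoch count.

    The count is scaled to a cpm-equivalent rate ``count * 60 / epoch_len``
    and placed in the unique bin containing that rate.
    """
    if count < 0:
        raise ValueError("negative count")
    if axis not in spec.axes:
        raise ValueError(f"axis {axis!r} not part of descriptor {spec.name!r}")
    rate = count * (60.0 / epoch_len)
    return int(spec.classify_rates(np.array([rate]))[0])


@dataclass
class DaySummary:
    """Wear time and per-axis bin minutes for one child-day."""

    child_id: str
    date: dt.date
    is_weekday: bool
    wear_minutes: float
    bin_minutes: dict[str, np.ndarray] = field(default_factory=dict)

    def closure_gap(self, axis: str) -> float:
        return float(self.bin_minutes[axis].sum() - self.wear_minutes)


def summarize_day(
    series: EpochSeries, mask: np.ndarray | None, spec: DescriptorSpec
) -> DaySummary:
    """Tally wear epochs into descriptor bins, in minutes.

    ``mask`` is the wear mask from :func:`detect_nonwear` (``None`` means all
    wear). Closure holds exactly: per axis, bin minutes sum to wear minutes.
    """
    n = len(series)
    if mask is None:
        mask = np.ones(n, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (n,):
        raise ValueError("mask not aligned to series")
    per_min = series.epoch_len / 60.0
    wear_minutes = float(mask.sum() * per_min)
    scale = 60.0 / series.epoch_len
    bins: dict[str, np.ndarray] = {}
    for axis in spec.axes:
        col = AXES.index(axis)
        rates = series.counts[mask, col] * scale
        idx = spec.classify_rates(rates)
        bins[axis] = np.bincount(idx, minlength=spec.n_bins) * per_min
    return DaySummary(
        child_id=series.child_id,
        date=series.date,
        is_weekday=series.is_weekday,
        wear_minutes=wear_minutes,
        bin_minutes=bins,
    )


@dataclass
class ChildSpectrum:
    """Mean min/day per descriptor variable over a child's valid days."""

    child_id: str
    timepoint: str
    valid: bool
    n_valid_days: int
    wear_minutes: float | None
    values: dict[str, float] | None


def aggregate_child(
    days: Sequence[DaySummary],
    spec: DescriptorSpec,
    timepoint: str = "baseline",
    min_wear_minutes: float = 300,
    min_days: int = 3,
) -> ChildSpectrum:
    """Average valid days into a per-timepoint spectrum.

    A day is valid iff it is a weekday (Mon–Fri) with wear >= 300 min (5 h);
    the measurement is valid iff at least ``min_days`` such days exist.
    Weekend days never count: the analysis targets preschool hours.
    """
    if not days:
        raise ValueError("no days supplied")
    child_ids = {d.child_id for d in days}
    if len(child_ids) != 1:
        raise ValueError("days must belong to one child")
    child_id = days[0].child_id
    valid_days = [
        d for d in days if d.is_weekday and d.wear_minutes >= min_wear_minutes
    ]
    if len(valid_days) < min_days:
        return ChildSpectrum(child_id, timepoint, False, len(valid_days), None, None)
    names = spec.variable_names
    per_day = np.array(
        [
            np.concatenate([d.bin_minutes[ax] for ax in spec.axes])
            for d in valid_days
        ]
    )
    values = dict(zip(names, per_day.mean(axis=0)))
    wear = float(np.mean([d.wear_minutes for d in valid_days]))
    return ChildSpectrum(child_id, timepoint, True, len(valid_days), wear, values)


# ---------------------------------------------------------------------------
# I/O


def read_epoch_csv(path: str | Path, epoch_len: int | None = None) -> list[EpochSeries]:
    """Read an epoch CSV (child_id, timestamp, axis1, axis2, axis3).

    Timestamps are ISO-8601; one series is produced per child-day. Epoch
    length is inferred from the first timestamp difference unless given.
    """
    df = pd.read_csv(path)
    expected = ["child_id", "timestamp", "axis1", "axis2", "axis3"]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"epoch CSV missing columns: {missing}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    out: list[EpochSeries] = []
    for (child, day), g in df.groupby(
        ["child_id", df["timestamp"].dt.date], sort=True
    ):
        g = g.sort_values("timestamp")
        ts = g["timestamp"]
        if epoch_len is None:
            if len(g) < 2:
                raise ValueError("cannot infer epoch length from a single row")
            step = int((ts.iloc[1] - ts.iloc[0]).total_seconds())
        else:
            step = epoch_len
        deltas = ts.diff().dt.total_seconds().iloc[1:]
        if not np.allclose(deltas, step):
            raise ValueError(
                f"epochs for child {child} on {day} are not contiguous"
            )
        out.append(
            EpochSeries(
                child_id=str(child),
                date=day,
                start=ts.iloc[0].time(),
                counts=g[["axis1", "axis2", "axis3"]].to_numpy(dtype=np.int64),
                epoch_len=step,
            )
        )
    return out


def spectra_to_frame(
    spectra: Iterable[ChildSpectrum], spec: DescriptorSpec
) -> pd.DataFrame:
    """Tidy frame of valid child spectra: one row per child, one column per variable."""
    rows = []
    for cs in spectra:
        row: dict[str, object] = {
            "child_id": cs.child_id,
            "timepoint": cs.timepoint,
            "valid": cs.valid,
            "n_valid_days": cs.n_valid_days,
            "wear_minutes": cs.wear_minutes,
        }
        if cs.valid and cs.values is not None:
            row.update(cs.values)
        rows.append(row)
    cols = ["child_id", "timepoint", "valid", "n_valid_days", "wear_minutes"]
    return pd.DataFrame(rows, columns=cols + spec.variable_names)


def process_epoch_files(
    paths: Sequence[str | Path],
    descriptor: str | DescriptorSpec = "traditional",
    window: tuple[dt.time, dt.time] = (dt.time(8, 30), dt.time(15, 30)),
    min_zero_minutes: float = 20,
    min_wear_minutes: float = 300,
    min_days: int = 3,
    timepoint: str = "baseline",
) -> pd.DataFrame:
    """Full epoch→spectrum pipeline over a set of epoch CSV files."""
    spec = (
        descriptor
        if isinstance(descriptor, DescriptorSpec)
        else DescriptorSpec.from_name(descriptor)
    )
    by_child: dict[str, list[DaySummary]] = {}
    for path in paths:
        for series in read_epoch_csv(path):
            series = restrict_window(series, *window)
            if len(series) == 0:
                day = DaySummary(
                    series.child_id,
                    series.date,
                    series.is_weekday,
                    0.0,
                    {ax: np.zeros(spec.n_bins) for ax in spec.axes},
                )
            else:
                mask = detect_nonwear(series, min_zero_minutes)
                day = summarize_day(series, mask, spec)
            by_child.setdefault(series.child_id, []).append(day)
    spectra = [
        aggregate_child(
            days,
            spec,
            timepoint=timepoint,
            min_wear_minutes=min_wear_minutes,
            min_days=min_days,
        )
        for _, days in sorted(by_child.items())
    ]
    return spectra_to_frame(spectra, spec)
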