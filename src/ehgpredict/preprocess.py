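"""Record I/O, band-pass filtering, artifact excision and windowing.

The electrohysterogram (EHG) is recorded as three bipolar abdominal
channels (S1, S2, S3) sampled at 20 Hz.  Analysis proceeds on two
bandwidths: the whole EHG bandwidth (WBW, 0.1-4 Hz) and the fast-wave-high
bandwidth (FWH, 0.34-4 Hz).  Corrupt segments (motion artifacts,
respiratory interference) are excised before the signal is cut into
120 s windows with 50% overlap; per-window features are later reduced to
one value per record/channel/band by the median.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

logger = logging.getLogger(__name__)

CHANNELS = ("S1", "S2", "S3")

#: Missing-value sentinel used throughout the package.
MISSING = float("nan")


class FormatError(ValueError):
    """Raised when an input file does not match the expected dialect."""


@dataclass(frozen=True)
class BandSpec:
    """An analysis band, ``low``-``high`` Hz."""

    name: str
    low: float
    high: float

    def validate(self, fs: float) -> None:
        if not (0.0 < self.low < self.high < fs / 2.0):
            raise ValueError(
                f"band {self.name} ({self.low}-{self.high} Hz) invalid for fs={fs} Hz"
            )


#: Whole EHG bandwidth.
WBW = BandSpec("WBW", 0.1, 4.0)
#: Fast-wave-high bandwidth (extended to 4 Hz as is usual for EHG study).
FWH = BandSpec("FWH", 0.34, 4.0)
BANDS = (WBW, FWH)


@dataclass
class EHGRecord:
    """A 3-channel EHG recording with obstetric metadata and a label.

    ``signals`` is an (n_samples, 3) float array in µV, channel order
    S1, S2, S3.  ``artifact_intervals`` maps channel name to a list of
    half-open ``[start_s, end_s)`` intervals flagged as corrupt.
    """

    record_id: str
    signals: np.ndarray
    fs: float
    obstetric: dict = field(default_factory=dict)
    label: str = "unknown"
    artifact_intervals: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2 or self.signals.shape[1] != len(CHANNELS):
            raise FormatError(
                f"record {self.record_id}: expected {len(CHANNELS)} channels, "
                f"got shape {self.signals.shape}"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.signals.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        return self.signals[:, CHANNELS.index(name)]


@dataclass
class WindowSet:
    """Windows cut from the artifact-free segments of one channel/band."""

    windows: list
    start_times: list
    channel: str | None = None
    band: BandSpec | None = None

    def __len__(self) -> int:
        return len(self.windows)


def design_bandpass(fs: float, band: BandSpec, order: int = 5) -> np.ndarray:
    """Second-order sections of an order-``order`` Butterworth band-pass."""
    band.validate(fs)
    return sps.butter(order, [band.low, band.high], btype="bandpass", fs=fs,
                      output="sos")


def zero_phase_bandpass(x: Sequence[float], fs: float, band: BandSpec,
                        order: int = 5) -> np.ndarray:
    """Forward-backward (zero-phase) Butterworth band-pass.

    The filter is designed at the given order and applied in both
    directions, so the effective magnitude response is that of an
    order ``2*order`` filter with no phase distortion.
    """
    x = np.asarray(x, dtype=float)
    sos = design_bandpass(fs, band, order)
    if x.size <= 3 * (2 * order + 1):
        raise ValueError("input too short for zero-phase filtering")
    return sps.sosfiltfilt(sos, x)


def _merge_intervals(intervals) -> list:
    ivs = sorted((float(a), float(b)) for a, b in intervals)
    merged: list = []
    for a, b in ivs:
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def artifact_free_segments(record: EHGRecord, channel: str,
                           signal: np.ndarray | None = None) -> list:
    """Contiguous sample runs of ``channel`` outside all annotated intervals.

    ``signal`` may supply an already-filtered version of the channel; it
    must have the record's length.  Overlapping annotations are merged.
    """
    x = record.channel(channel) if signal is None else np.asarray(signal, float)
    if x.size != record.n_samples:
        raise ValueError("signal length does not match record")
    intervals = _merge_intervals(record.artifact_intervals.get(channel, []))
    fs = record.fs
    segments = []
    pos = 0
    for a, b in intervals:
        i0 = max(0, int(math.ceil(a * fs)))
        i1 = min(x.size, int(math.ceil(b * fs)))
        if i0 > pos:
            segments.append(x[pos:i0])
        pos = max(pos, i1)
    if pos < x.size:
        segments.append(x[pos:])
    return [s for s in segments if s.size > 0]


def segment_windows(segments: Sequence[np.ndarray], fs: float,
                    win_s: float = 120.0, overlap: float = 0.5) -> WindowSet:
    """Cut each segment into ``win_s`` windows with the given overlap.

    Windows never span a segment boundary; trailing partial windows are
    discarded.  With the defaults this is the 120 s / 50%-overlap moving
    window used for whole-window EHG analysis.
    """
    if not (0.0 <= overlap < 1.0):
        raise ValueError("overlap must be in [0, 1)")
    win = win_s * fs
    if abs(win - round(win)) > 1e-9:
        raise ValueError("win_s * fs must be an integer number of samples")
    win = int(round(win))
    hop = int(round(win * (1.0 - overlap)))
    if hop < 1:
        raise ValueError("hop must be at least one sample")
    windows, starts = [], []
    t0 = 0.0
    for seg in segments:
        seg = np.asarray(seg, dtype=float)
        for start in range(0, seg.size - win + 1, hop):
            windows.append(seg[start:start + win])
            starts.append(t0 + start / fs)
        t0 += seg.size / fs
    return WindowSet(windows=windows, start_times=starts)


def aggregate_median(values: Sequence[float]) -> float:
    """Median of the non-missing values; NaN when nothing remains."""
    arr = np.asarray(list(values), dtype=float)
    good = arr[~np.isnan(arr)]
    n_dropped = arr.size - good.size
    if n_dropped:
        logger.info("aggregate_median: dropped %d missing value(s)", n_dropped)
    if good.size == 0:
        return MISSING
    return float(np.median(good))


# ---------------------------------------------------------------------------
# CSV cohort I/O (dialect shared with the synthetic generator)
# ---------------------------------------------------------------------------

OBSTETRIC_FIELDS = ("age", "parity", "abortions", "weight", "gestation_week")


def write_record_csv(record: EHGRecord, path: str | Path) -> None:
    """Write one record as CSV with columns t, S1, S2, S3."""
    t = np.arange(record.n_samples) / record.fs
    df = pd.DataFrame({"t": t})
    for i, ch in enumerate(CHANNELS):
        df[ch] = record.signals[:, i]
    df.to_csv(path, index=False, float_format="%.17g")


def write_cohort(records: Sequence[EHGRecord], out_dir: str | Path) -> None:
    """Write a cohort: one CSV per record + manifest.csv + artifacts.csv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_rows, artifact_rows = [], []
    for rec in records:
        write_record_csv(rec, out_dir / f"{rec.record_id}.csv")
        row = {"record_id": rec.record_id, "label": rec.label, "fs": rec.fs}
        for f in OBSTETRIC_FIELDS:
            row[f] = rec.obstetric.get(f, MISSING)
        manifest_rows.append(row)
        for ch, ivs in rec.artifact_intervals.items():
            for a, b in ivs:
                artifact_rows.append({"record_id": rec.record_id, "channel": ch,
                                      "start_s": a, "end_s": b})
    pd.DataFrame(manifest_rows).to_csv(out_dir / "manifest.csv", index=False,
                                       float_format="%.17g")
    cols = ["record_id", "channel", "start_s", "end_s"]
    pd.DataFrame(artifact_rows, columns=cols).to_csv(
        out_dir / "artifacts.csv", index=False, float_format="%.17g")


def read_record(path: str | Path, format: str = "csv",
                manifest: dict | None = None) -> EHGRecord:
    """Read one record from disk.

    ``format="csv"`` reads the package's CSV dialect (header row, optional
    ``t`` column, channels S1, S2, S3); metadata (fs, label, obstetric
    fields) come from ``manifest``, a dict such as one row of
    ``manifest.csv``.  ``format="wfdb"`` delegates to the optional
    ``wfdb`` package for Physionet-style header+signal pairs.
    """
    path = Path(path)
    if format == "wfdb":
        try:
            import wfdb  # noqa: F401
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise RuntimeError(
                "reading WFDB records requires the optional 'wfdb' package"
            ) from exc
        rec = wfdb.rdrecord(str(path.with_suffix("")))  # pragma: no cover
        sig = rec.p_signal  # pragma: no cover
        if sig.shape[1] != 3:  # pragma: no cover
            raise FormatError("expected 3 channels")  # pragma: no cover
        return EHGRecord(record_id=path.stem, signals=sig,  # pragma: no cover
                         fs=float(rec.fs))
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    cols = [c for c in df.columns if c != "t"]
    if list(cols) != list(CHANNELS):
        raise FormatError(
            f"{path}: expected channel columns {CHANNELS}, got {tuple(cols)}")
    manifest = dict(manifest or {})
    fs = float(manifest.get("fs", MISSING))
    if "t" in df.columns:
        dt = np.diff(df["t"].to_numpy())
        if dt.size and (dt.max() - dt.min()) > 1e-6:
            raise FormatError(f"{path}: non-uniform sampling")
        if math.isnan(fs) and dt.size:
            fs = 1.0 / float(np.median(dt))
    if math.isnan(fs):
        raise FormatError(f"{path}: sampling rate not in manifest or t column")
    if abs(fs - 20.0) > 1e-9:
        logger.info("record %s sampled at %g Hz (not 20 Hz)", path.stem, fs)
    obstetric = {f: float(manifest[f]) for f in OBSTETRIC_FIELDS
                 if f in manifest and not pd.isna(manifest[f])}
    return EHGRecord(
        record_id=str(manifest.get("record_id", path.stem)),
        signals=df[list(CHANNELS)].to_numpy(dtype=float),
        fs=fs,
        obstetric=obstetric,
        label=str(manifest.get("label", "unknown")),
    )


def read_cohort(cohort_dir: str | Path) -> list:
    """Read a cohort directory written by :func:`write_cohort`."""
    cohort_dir = Path(cohort_dir)
    manifest = pd.read_csv(cohort_dir / "manifest.csv",
                           float_precision="round_trip")
    art_path = cohort_dir / "artifacts.csv"
    artifacts = (pd.read_csv(art_path, float_precision="round_trip")
                 if art_path.exists() else
                 pd.DataFrame(columns=["record_id", "channel",
                                       "start_s", "end_s"]))
    records = []
    for _, row in manifest.iterrows():
        rec = read_record(cohort_dir / f"{row['record_id']}.csv", "csv",
                          manifest=row.to_dict())
        sub = artifacts[artifacts["record_id"] == row["record_id"]]
        for _, arow in sub.iterrows():
            rec.artifact_intervals.setdefault(arow["channel"], []).append(
                (float(arow["start_s"]), float(arow["end_s"])))
        records.append(rec)
    return records
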