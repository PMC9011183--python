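"""Plain-text I/O for eye-tracking sample recordings, event tables and summaries.

Samples are tab-separated (``time_ms, x_deg, y_deg, pupil_mm``), matching the
ASCII exports of common video-based eye trackers; events and result summaries
are comma-separated.  Timestamps are integers in milliseconds on the source
sampling grid (500 Hz gives an exact 2 ms spacing), which avoids floating-point
drift in window arithmetic.

Missing pupil samples may be encoded as an empty field, a non-numeric token,
or the sentinel value 0 (the convention used by EyeLink-style exports during
blinks); all of these are flagged invalid but the row is kept, so a recording
never loses time points at the I/O layer.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Stimulus categories understood by the analysis.
CATEGORIES = ("sun", "moon", "scrambled", "bright", "dark")


@dataclass
class RawRecording:
    """A uniform-rate monocular recording of pupil diameter and gaze position.

    Attributes
    ----------
    subject_id : str
        Identifier of the participant.
    sampling_rate : float
        Nominal sampling rate in Hz (500 for the supported recordings).
    time : ndarray of int
        Sample timestamps in ms, strictly increasing.
    pupil : ndarray of float
        Pupil diameter in mm; NaN where missing.
    gaze_x, gaze_y : ndarray of float
        Gaze position in degrees of visual angle; NaN allowed.
    valid : ndarray of bool
        Per-sample validity mask.  Invalid samples are flagged, never deleted.
    """

    subject_id: str
    sampling_rate: float
    time: np.ndarray
    pupil: np.ndarray
    gaze_x: np.ndarray
    gaze_y: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=np.int64)
        self.pupil = np.asarray(self.pupil, dtype=float)
        self.gaze_x = np.asarray(self.gaze_x, dtype=float)
        self.gaze_y = np.asarray(self.gaze_y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.time)
        if not (len(self.pupil) == len(self.gaze_x) == len(self.gaze_y) == len(self.valid) == n):
            raise ValueError("all sample arrays must have equal length")
        if n == 0:
            raise ValueError("recording has no samples")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(self.valid & ~np.isfinite(self.pupil)):
            raise ValueError("valid samples must have finite pupil values")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def nominal_dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate

    @property
    def duration_ms(self) -> float:
        """Span of the recording including the last sample's own interval."""
        return float(self.time[-1] - self.time[0]) + self.nominal_dt_ms

    def copy(self) -> "RawRecording":
        return RawRecording(
            self.subject_id,
            self.sampling_rate,
            self.time.copy(),
            self.pupil.copy(),
            self.gaze_x.copy(),
            self.gaze_y.copy(),
            self.valid.copy(),
        )


@dataclass
class EventTable:
    """Stimulus onsets with category labels and durations (all in ms)."""

    onset: np.ndarray
    category: np.ndarray
    duration: np.ndarray

    def __post_init__(self) -> None:
        self.onset = np.asarray(self.onset, dtype=np.int64)
        self.category = np.asarray(self.category, dtype=object)
        self.duration = np.asarray(self.duration, dtype=np.int64)
        if not (len(self.onset) == len(self.category) == len(self.duration)):
            raise ValueError("event columns must have equal length")
        unknown = set(self.category) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown stimulus categories: {sorted(unknown)}")
        order = np.argsort(self.onset, kind="stable")
        self.onset = self.onset[order]
        self.category = self.category[order]
        self.duration = self.duration[order]
        ends = self.onset + self.duration
        if np.any(self.onset[1:] < ends[:-1]):
            raise ValueError("events overlap in time")

    def __len__(self) -> int:
        return len(self.onset)

    def select(self, category: str) -> "EventTable":
        m = self.category == category
        return EventTable(self.onset[m], self.category[m], self.duration[m])


@dataclass
class SubjectSummary:
    """Per-subject analysis summary: one peak per stimulus category plus
    trial-exclusion, resting-diameter and gaze-dispersion statistics."""

    subject_id: str
    group: str = ""
    peaks: dict = field(default_factory=dict)          # category -> mm (signed)
    normalized: dict = field(default_factory=dict)     # category -> unitless
    exclusion_fraction: float = np.nan
    resting_diameter: float = np.nan                   # mm
    bce_area: float = np.nan                           # deg^2
    n_retained: dict = field(default_factory=dict)     # category -> trial count
    aq: float = np.nan


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

SAMPLE_COLUMNS = ["time_ms", "x_deg", "y_deg", "pupil_mm"]
EVENT_COLUMNS = ["onset_ms", "category", "duration_ms"]


def read_samples(path, sampling_rate: float = 500.0, subject_id: str | None = None) -> RawRecording:
    """Read a tab-separated sample file into a :class:`RawRecording`.

    Rows whose pupil cell is empty, non-numeric, or the blink sentinel 0 are
    flagged invalid but retained, so the time base is unchanged.

    Raises
    ------
    ValueError
        If the file is empty or timestamps are not strictly increasing.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise ValueError(f"no data rows in {path}")
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample file lacks columns {missing}")
    time = pd.to_numeric(df["time_ms"], errors="raise").to_numpy(dtype=np.int64)
    pupil = pd.to_numeric(df["pupil_mm"], errors="coerce").to_numpy(dtype=float)
    gx = pd.to_numeric(df["x_deg"], errors="coerce").to_numpy(dtype=float)
    gy = pd.to_numeric(df["y_deg"], errors="coerce").to_numpy(dtype=float)
    valid = np.isfinite(pupil) & (pupil > 0)
    sid = subject_id if subject_id is not None else _stem(path)
    return RawRecording(sid, sampling_rate, time, pupil, gx, gy, valid)


def write_samples(rec: RawRecording, path) -> None:
    """Write a recording as TSV; NaN cells are emitted empty."""
    df = pd.DataFrame(
        {
            "time_ms": rec.time,
            "x_deg": rec.gaze_x,
            "y_deg": rec.gaze_y,
            "pupil_mm": rec.pupil,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="")


def read_events(path) -> EventTable:
    """Read a comma-separated event table; output is sorted by onset.

    Unknown category labels and overlapping events are hard errors.
    """
    df = pd.read_csv(path, dtype={"category": str})
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event file lacks columns {missing}")
    return EventTable(
        df["onset_ms"].to_numpy(dtype=np.int64),
        df["category"].to_numpy(dtype=object),
        df["duration_ms"].to_numpy(dtype=np.int64),
    )


def write_events(events: EventTable, path) -> None:
    pd.DataFrame(
        {"onset_ms": events.onset, "category": events.category, "duration_ms": events.duration}
    ).to_csv(path, index=False)


def write_summary(summaries: list[SubjectSummary], path) -> None:
    """Write one CSV row per subject x stimulus category.

    The category list is the union over subjects; a subject lacking a
    category still gets a row, with an empty peak cell.
    """
    if not summaries:
        raise ValueError("no summaries to write")
    cats = [c for c in CATEGORIES if any(c in s.peaks for s in summaries)]
    if not cats:
        cats = list(CATEGORIES[:1])
    rows = []
    for s in summaries:
        for c in cats:
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "group": s.group,
                    "category": c,
                    "peak_mm": s.peaks.get(c, np.nan),
                    "normalized_peak": s.normalized.get(c, np.nan),
                    "n_retained": s.n_retained.get(c, np.nan),
                    "exclusion_fraction": s.exclusion_fraction,
                    "resting_diameter_mm": s.resting_diameter,
                    "bce_area_deg2": s.bce_area,
                    "aq": s.aq,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.9g", na_rep="")


def read_summary(path) -> pd.DataFrame:
    return pd.read_csv(path)


def _stem(path) -> str:
    if isinstance(path, (str, bytes)):
        import os

        return os.path.splitext(os.path.basename(path))[0]
    if isinstance(path, io.IOBase) or hasattr(path, "read"):
        return getattr(path, "name", "recording")
    try:  # pathlib
        return path.stem
    except AttributeError:
        return "recording"
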