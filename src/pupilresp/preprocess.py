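"""Artifact rejection and downsampling for pupil-diameter recordings.

The cleaning procedure has four steps, applied in a fixed order:

1. ``remove_small``     — flag samples with pupil diameter below 0.1 mm
   (blinks and other signal losses).
2. ``remove_fast``      — flag samples where the diameter changes faster than
   10 mm/s between consecutive retained samples (beyond the physiological
   range; blink flanks and electrical transients).
3. ``remove_fragments`` — flag isolated valid segments spanning 10 ms or less
   that are separated from the rest of the trace.
4. ``downsample_100hz`` — average retained samples in non-overlapping 100 ms
   windows; a window with no retained sample becomes NaN.

Each step marks samples invalid in the shared validity mask; nothing is ever
deleted, so gaze samples inherit the same mask.  Steps 1 and 3 are idempotent.
Step 2 is a single identification pass over the currently retained samples
(re-applying it can flag further samples; see the velocity note below).

Velocities in step 2 are computed over the *actual* time gap between retained
neighbours, not the nominal sampling interval, so that gaps opened by step 1
do not inflate speeds.  Both endpoints of a super-threshold pair are flagged;
no record is kept of which rule fired for a given sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import RawRecording

#: Default cleaning parameters (units: mm, mm/s, ms, ms).
MIN_PUPIL_MM = 0.1
MAX_SPEED_MM_S = 10.0
FRAGMENT_MS = 10.0
WINDOW_MS = 100


@dataclass
class CleanTrace:
    """A pupil trace block-averaged into fixed 100 ms windows.

    ``time`` holds window start times in ms; window *k* covers
    ``[time[k], time[k] + window_ms)``.  ``pupil`` is the mean of retained
    source samples in the window (NaN if none survived) and ``counts`` the
    number of retained samples that entered each mean.
    """

    subject_id: str
    time: np.ndarray      # window start, ms
    pupil: np.ndarray     # mm, NaN = missing
    counts: np.ndarray    # retained source samples per window
    window_ms: int = WINDOW_MS

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=np.int64)
        self.pupil = np.asarray(self.pupil, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(np.isfinite(self.pupil) != (self.counts > 0)):
            raise ValueError("windows with zero retained samples must be NaN and vice versa")

    def __len__(self) -> int:
        return len(self.time)


def remove_small(rec: RawRecording, min_mm: float = MIN_PUPIL_MM) -> RawRecording:
    """Invalidate samples with pupil diameter strictly below ``min_mm``."""
    out = rec.copy()
    too_small = np.isfinite(out.pupil) & (out.pupil < min_mm)
    out.valid &= ~(too_small | ~np.isfinite(out.pupil))
    return out


def remove_fast(rec: RawRecording, max_speed: float = MAX_SPEED_MM_S) -> RawRecording:
    """Invalidate both endpoints of consecutive retained samples whose pupil
    diameter changes strictly faster than ``max_speed`` mm/s.

    The speed between retained neighbours is |d pupil| / d t with the actual
    time gap (ms converted to s), so invalid stretches between them do not
    bias the estimate.  The comparison is strict, with a 1e-9 relative guard
    so that values sitting exactly on the threshold are retained regardless
    of binary representation noise.
    """
    out = rec.copy()
    idx = np.flatnonzero(out.valid)
    if idx.size < 2:
        return out
    dt_s = np.diff(out.time[idx]) / 1000.0
    dp = np.abs(np.diff(out.pupil[idx]))
    fast = dp / dt_s > max_speed * (1 + 1e-9)
    bad = np.zeros(len(out), dtype=bool)
    bad[idx[:-1][fast]] = True
    bad[idx[1:][fast]] = True
    out.valid &= ~bad
    return out


def remove_fragments(rec: RawRecording, max_len: float = FRAGMENT_MS) -> RawRecording:
    """Invalidate maximal valid runs spanning ``max_len`` ms or less.

    A run's span is the time from its first to its last sample.  Maximal runs
    are by construction bounded by invalid samples or by the trace edge, both
    of which count as separation from the rest of the trace.
    """
    out = rec.copy()
    v = out.valid
    if not v.any():
        return out
    # run boundaries on the validity mask
    padded = np.concatenate(([False], v, [False])).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1  # inclusive
    for s, e in zip(starts, ends):
        if out.time[e] - out.time[s] <= max_len:
            out.valid[s : e + 1] = False
    return out


def downsample_100hz(rec: RawRecording, window_ms: int = WINDOW_MS) -> CleanTrace:
    """Average retained samples in non-overlapping ``window_ms`` windows.

    Windows are anchored at the recording's first timestamp.  The output has
    ``ceil(duration / window_ms)`` windows regardless of artifact content;
    empty windows hold NaN.
    """
    t0 = rec.time[0]
    n_win = int(np.ceil(rec.duration_ms / window_ms))
    which = (rec.time - t0) // window_ms
    sums = np.zeros(n_win)
    counts = np.zeros(n_win, dtype=np.int64)
    np.add.at(sums, which[rec.valid], rec.pupil[rec.valid])
    np.add.at(counts, which[rec.valid], 1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    time = t0 + window_ms * np.arange(n_win, dtype=np.int64)
    return CleanTrace(rec.subject_id, time, means, counts, window_ms)


def clean_recording(
    rec: RawRecording,
    min_mm: float = MIN_PUPIL_MM,
    max_speed: float = MAX_SPEED_MM_S,
    fragment_ms: float = FRAGMENT_MS,
) -> RawRecording:
    """Apply artifact-rejection steps 1-3 and return the flagged recording.

    Useful when the sample-level validity mask is needed downstream (gaze
    pooling uses the same mask as the pupil trace).
    """
    return remove_fragments(remove_fast(remove_small(rec, min_mm), max_speed), fragment_ms)


def preprocess_pipeline(
    rec: RawRecording,
    min_mm: float = MIN_PUPIL_MM,
    max_speed: float = MAX_SPEED_MM_S,
    fragment_ms: float = FRAGMENT_MS,
    window_ms: int = WINDOW_MS,
) -> CleanTrace:
    """Full cleaning pipeline: steps 1-3 then 100 ms block-averaging.

    On an artifact-free recording this reduces to plain block-averaging of
    the raw samples.
    """
    return downsample_100hz(clean_recording(rec, min_mm, max_speed, fragment_ms), window_ms)
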