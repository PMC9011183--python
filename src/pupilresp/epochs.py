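"""Epoching, baseline referencing, trial exclusion and peak-response extraction.

Cleaned traces are cut into per-trial epochs aligned to stimulus onset on the
100 ms analysis grid, expressed as change from each trial's own baseline (the
mean diameter from -800 to +200 ms around onset, i.e. the second preceding the
~200 ms latency of the pupillary light response), screened for trials with no
surviving sample during stimulus presentation, averaged per condition, and
summarized by the signed extremum of the condition-average trace: the most
negative change for constriction responses (sun, moon, scrambled, bright) or
the most positive change for the dilation response to dark stimuli.

Sign convention: values are changes from baseline in mm, so constriction peaks
are negative and dilation peaks positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_formats import EventTable
from .preprocess import CleanTrace

EPOCH_START_MS = -1000
EPOCH_END_MS = 2000
BASELINE_START_MS = -800
BASELINE_END_MS = 200
STIM_START_MS = 0
STIM_END_MS = 1000
SEARCH_START_MS = 200
SEARCH_END_MS = 2000

#: Stimulus categories whose response is a dilation rather than a constriction.
DILATION_CATEGORIES = ("dark",)


@dataclass
class EpochSet:
    """Per-trial pupil segments aligned to stimulus onset.

    ``epochs`` is a (trial x window) matrix on the 100 ms grid; ``times``
    gives each window's start in ms relative to onset (the window whose start
    is 0 contains the onset).  ``baseline_mean`` is NaN until
    :func:`baseline_correct` has run.
    """

    subject_id: str
    category: str
    times: np.ndarray                 # ms relative to onset, window starts
    epochs: np.ndarray                # trial x window, mm (NaN = missing)
    onsets: np.ndarray                # ms, absolute, per trial
    baseline_mean: np.ndarray = field(default=None)  # mm per trial
    baseline_corrected: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.int64)
        self.epochs = np.atleast_2d(np.asarray(self.epochs, dtype=float))
        self.onsets = np.asarray(self.onsets, dtype=np.int64)
        if self.baseline_mean is None:
            self.baseline_mean = np.full(self.n_trials, np.nan)

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    def window_mask(self, start_ms: float, end_ms: float) -> np.ndarray:
        """Boolean mask over windows whose start time lies in [start, end)."""
        return (self.times >= start_ms) & (self.times < end_ms)


def epoch(
    clean: CleanTrace,
    events: EventTable,
    start: int = EPOCH_START_MS,
    end: int = EPOCH_END_MS,
    category: str | None = None,
) -> EpochSet:
    """Cut one epoch per event out of a cleaned trace.

    The epoch spans windows with start times ``start <= t < end`` relative to
    the window containing the stimulus onset.  Events too close to a recording
    edge are dropped with a warning.
    """
    if category is not None:
        events = events.select(category)
    w = clean.window_ms
    if start % w or end % w:
        raise ValueError(f"epoch bounds must be multiples of the {w} ms window")
    lo, hi = start // w, end // w
    rows, kept = [], []
    for onset in events.onset:
        b0 = (onset - clean.time[0]) // w
        if b0 + lo < 0 or b0 + hi > len(clean):
            warnings.warn(
                f"event at {onset} ms too close to the recording edge; trial dropped",
                stacklevel=2,
            )
            continue
        rows.append(clean.pupil[b0 + lo : b0 + hi])
        kept.append(onset)
    cats = set(events.category)
    cat = category if category is not None else (cats.pop() if len(cats) == 1 else "mixed")
    times = np.arange(lo, hi, dtype=np.int64) * w
    epochs = np.array(rows, dtype=float).reshape(len(rows), hi - lo)
    return EpochSet(clean.subject_id, cat, times, epochs, np.array(kept, dtype=np.int64))


def baseline_correct(
    es: EpochSet, b_start: int = BASELINE_START_MS, b_end: int = BASELINE_END_MS
) -> EpochSet:
    """Re-express each trial as the change from its own baseline mean.

    The baseline is the mean over non-missing windows whose start lies in
    ``[b_start, b_end)`` (the defaults span the 10 windows from -800 to
    +200 ms).  A trial whose baseline windows are all missing keeps NaN as its
    baseline and is excluded downstream.
    """
    m = es.window_mask(b_start, b_end)
    if not m.any():
        raise ValueError("baseline window contains no epoch windows")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        base = np.nanmean(es.epochs[:, m], axis=1)
    return EpochSet(
        es.subject_id,
        es.category,
        es.times,
        es.epochs - base[:, None],
        es.onsets,
        baseline_mean=base,
        baseline_corrected=True,
    )


def exclude_invalid_trials(
    es: EpochSet, stim_start: int = STIM_START_MS, stim_end: int = STIM_END_MS
) -> tuple[EpochSet, float]:
    """Drop trials with no surviving sample during stimulus presentation.

    A trial is excluded when every window in ``[stim_start, stim_end)`` is
    missing, or when its baseline could not be computed.  Returns the reduced
    epoch set and the excluded fraction.
    """
    m = es.window_mask(stim_start, stim_end)
    has_stim = np.isfinite(es.epochs[:, m]).any(axis=1)
    keep = has_stim
    if es.baseline_corrected:
        keep = keep & np.isfinite(es.baseline_mean)
    frac = 1.0 - keep.sum() / es.n_trials if es.n_trials else np.nan
    out = EpochSet(
        es.subject_id,
        es.category,
        es.times,
        es.epochs[keep],
        es.onsets[keep],
        baseline_mean=es.baseline_mean[keep],
        baseline_corrected=es.baseline_corrected,
    )
    if out.n_trials == 0:
        warnings.warn(f"all {es.n_trials} trials excluded for {es.subject_id}/{es.category}")
    return out, float(frac)


def condition_average(es: EpochSet) -> np.ndarray:
    """Missing-aware mean trace over trials (NaN where all trials miss)."""
    if es.n_trials == 0:
        return np.full(len(es.times), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(es.epochs, axis=0)


def peak_response(
    mean_trace: np.ndarray,
    times: np.ndarray,
    polarity: str,
    search_start: int = SEARCH_START_MS,
    search_end: int = SEARCH_END_MS,
) -> float:
    """Signed extremum of a condition-average trace after stimulus onset.

    ``polarity='constriction'`` returns the most negative change,
    ``'dilation'`` the most positive; either way the sign is retained.
    Returns NaN (with a warning) when the search window holds no data.
    """
    if polarity not in ("constriction", "dilation"):
        raise ValueError("polarity must be 'constriction' or 'dilation'")
    times = np.asarray(times)
    m = (times >= search_start) & (times < search_end)
    vals = np.asarray(mean_trace)[m]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        warnings.warn("no data in the peak search window; peak is undefined")
        return np.nan
    return float(vals.min() if polarity == "constriction" else vals.max())


def polarity_for(category: str) -> str:
    return "dilation" if category in DILATION_CATEGORIES else "constriction"


def normalize_by_plr(peaks: dict, light_category: str = "bright") -> dict:
    """Divide each peak by the magnitude of the pupillary light response.

    Expresses contextual responses in units of the subject's own light
    response, removing overall pupil reactivity.  Returns an empty mapping
    (with a warning) when the light-response peak is zero or missing.
    """
    light = peaks.get(light_category, np.nan)
    if not np.isfinite(light) or light == 0:
        warnings.warn("zero or missing light-response peak; normalization undefined")
        return {}
    return {c: p / abs(light) for c, p in peaks.items()}


def resting_diameter(epoch_sets: list[EpochSet]) -> float:
    """Mean pre-stimulus pupil diameter across all trials of a subject.

    Averages the per-trial baseline means of baseline-corrected epoch sets,
    ignoring trials whose baseline is missing.
    """
    base = np.concatenate([es.baseline_mean for es in epoch_sets]) if epoch_sets else np.array([])
    base = base[np.isfinite(base)]
    return float(base.mean()) if base.size else np.nan
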