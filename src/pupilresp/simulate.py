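"""Synthetic 500 Hz pupil/gaze recordings with known ground truth.

The generator emulates the statistical structure of event-related
pupillometry sessions: a subject-specific resting diameter (around 3.8-4.1 mm
depending on group), 1 s stimuli presented every 4 s on average (uniform
3-5 s jitter), event-locked responses with ~200 ms latency whose signed
amplitude depends on stimulus category (constriction negative: sun stronger
than phase-scrambled; bright strongest; dark produces a dilation), slow
hippus oscillation, band-limited measurement noise, Gaussian gaze scatter, and
blink/dropout artifacts shaped so that every cleaning rule has work to do
(sub-0.1 mm plateaus, super-10 mm/s flanks, isolated sub-10 ms fragments).

Every simulated quantity is recorded in a :class:`GroundTruth` so each
pipeline stage can be validated against what was injected.  Output is a pure
function of the configuration and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .io_formats import EventTable, RawRecording

DEFAULT_TRIALS = {"sun": 13, "scrambled": 13}

#: Signed response amplitudes in mm used when a config does not override them.
DEFAULT_AMPLITUDES = {"sun": -0.35, "moon": -0.30, "scrambled": -0.20,
                      "bright": -0.70, "dark": 0.25}


@dataclass
class SimConfig:
    """Parameters of one simulated recording (times in ms, sizes in mm)."""

    seed: int = 0
    sampling_rate: float = 500.0
    trials: dict = field(default_factory=lambda: dict(DEFAULT_TRIALS))
    amplitudes: dict = field(default_factory=lambda: dict(DEFAULT_AMPLITUDES))
    isi_mean: float = 4000.0
    isi_jitter: float = 1000.0          # uniform on mean +/- jitter
    stim_duration: int = 1000
    lead_in_ms: float = 2000.0
    tail_ms: float = 3000.0
    baseline_mm: float = 3.9
    latency_ms: float = 200.0
    peak_time_ms: float = 700.0         # kernel time-to-peak after latency
    kernel_shape: float = 10.0
    trial_amp_sd: float = 0.03          # trial-to-trial amplitude scatter
    noise_sd: float = 0.02              # measurement-noise SD, mm
    noise_smooth_ms: float = 25.0       # temporal scale of the noise process
    hippus_amp: float = 0.05
    hippus_freq_hz: float = 0.2
    gaze_sd_deg: float = 0.8
    blink_rate_per_min: float = 10.0
    blink_min_ms: float = 80.0
    blink_max_ms: float = 200.0
    blink_ramp_ms: float = 20.0
    fragment_prob: float = 0.3          # chance a blink hides an isolated island
    blink_avoid_stim: bool = False      # keep blinks clear of analysis windows
    trial_kill_fraction: float = 0.0    # trials wiped for the full stimulus window

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate


@dataclass
class GroundTruth:
    """Everything that was injected, for validating the pipeline."""

    onsets: np.ndarray            # ms, per trial
    categories: np.ndarray        # per trial
    trial_amplitudes: np.ndarray  # mm, per trial (signed, incl. scatter)
    baseline_mm: float
    amplitudes: dict              # per-category subject-level amplitude
    artifact_mask: np.ndarray     # per sample: True where the signal was corrupted
    killed_trials: np.ndarray     # bool per trial: stimulus window wiped

    def amplitude_of(self, category: str) -> float:
        return self.amplitudes[category]


def plr_kernel(t, latency: float = 200.0, amplitude: float = -0.35,
               peak_time: float = 700.0, shape: float = 10.0) -> np.ndarray:
    """Pupil impulse-response kernel: zero before ``latency``, then a gamma-
    shaped deflection peaking exactly at ``amplitude`` ``peak_time`` ms after
    the latency and decaying back to zero.

    The Erlang-type form ``(s/p)^k * exp(k (1 - s/p))`` has its analytic
    maximum of 1 at ``s = p``, so scaling by ``amplitude`` makes the extremum
    equal the configured amplitude exactly.
    """
    t = np.asarray(t, dtype=float)
    s = t - latency
    out = np.zeros_like(s)
    pos = s > 0
    sp = s[pos] / peak_time
    out[pos] = np.exp(shape * (np.log(sp) - sp + 1.0))
    return amplitude * out


def _smooth_noise(rng, n: int, sd: float, smooth_ms: float, dt: float) -> np.ndarray:
    """Temporally correlated measurement noise with the requested SD.

    White noise at the 2 ms sample spacing would produce sample-to-sample
    speeds far beyond the physiological range and be rejected wholesale by
    the velocity rule; real tracker noise is band-limited.  Gaussian-smooth
    white noise over ``smooth_ms`` and rescale to ``sd``.
    """
    from scipy.ndimage import gaussian_filter1d

    if smooth_ms <= 0:
        return rng.normal(0.0, sd, n)
    w = rng.normal(0.0, 1.0, n)
    sigma = smooth_ms / dt
    s = gaussian_filter1d(w, sigma, mode="reflect")
    # variance of filtered white noise: 1 / (2 sqrt(pi) sigma)
    s *= sd * math.sqrt(2.0 * math.sqrt(math.pi) * sigma)
    return s


def simulate_recording(
    cfg: SimConfig, rng: np.random.Generator | None = None, subject_id: str = "sim"
) -> tuple[RawRecording, EventTable, GroundTruth]:
    """Simulate one artifact-free recording plus its event table and truth.

    The trace is baseline + sum of event kernels + hippus sinusoid +
    band-limited measurement noise; gaze is zero-mean Gaussian scatter.  Use
    :func:`inject_artifacts` afterwards to add blinks and dropouts.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    dt = cfg.dt_ms
    cats = [c for c, n in cfg.trials.items() for _ in range(n)]
    rng.shuffle(cats)
    onsets = []
    t = cfg.lead_in_ms
    for _ in cats:
        onsets.append(int(round(t / dt)) * int(dt))
        t += rng.uniform(cfg.isi_mean - cfg.isi_jitter, cfg.isi_mean + cfg.isi_jitter)
    onsets = np.array(onsets, dtype=np.int64)
    total_ms = float(onsets[-1]) + cfg.stim_duration + cfg.tail_ms if len(onsets) else 10_000.0
    n = int(np.ceil(total_ms / dt))
    time = (np.arange(n) * int(dt)).astype(np.int64)

    amps = np.array(
        [cfg.amplitudes[c] + rng.normal(0.0, cfg.trial_amp_sd) for c in cats]
    )
    signal = np.full(n, cfg.baseline_mm)
    if cfg.hippus_amp:
        phase = rng.uniform(0, 2 * np.pi)
        signal = signal + cfg.hippus_amp * np.sin(
            2 * np.pi * cfg.hippus_freq_hz * time / 1000.0 + phase
        )
    support = int(np.ceil(4000.0 / dt))  # kernel is numerically dead beyond 4 s
    for onset, a in zip(onsets, amps):
        i0 = int(onset // dt)
        i1 = min(i0 + support, n)
        signal[i0:i1] += plr_kernel(
            time[i0:i1] - onset, cfg.latency_ms, a, cfg.peak_time_ms, cfg.kernel_shape
        )
    if cfg.noise_sd:
        signal = signal + _smooth_noise(rng, n, cfg.noise_sd, cfg.noise_smooth_ms, dt)
    gx = rng.normal(0.0, cfg.gaze_sd_deg, n)
    gy = rng.normal(0.0, cfg.gaze_sd_deg, n)

    rec = RawRecording(subject_id, cfg.sampling_rate, time, signal, gx, gy,
                       np.isfinite(signal) & (signal > 0))
    events = EventTable(onsets, np.array(cats, dtype=object),
                        np.full(len(cats), cfg.stim_duration, dtype=np.int64))
    truth = GroundTruth(
        onsets=onsets,
        categories=np.array(cats, dtype=object),
        trial_amplitudes=amps,
        baseline_mm=cfg.baseline_mm,
        amplitudes=dict(cfg.amplitudes),
        artifact_mask=np.zeros(n, dtype=bool),
        killed_trials=np.zeros(len(cats), dtype=bool),
    )
    return rec, events, truth


def _apply_dropout(rec: RawRecording, mask_span, ramp_ms: float, artifact: np.ndarray) -> None:
    """Drive the pupil trace to 0 over ``mask_span`` with linear ramps."""
    t0, t1 = mask_span
    t = rec.time
    factor = np.ones(len(rec))
    inside = (t >= t0) & (t < t1)
    factor[inside] = 0.0
    lead = (t >= t0 - ramp_ms) & (t < t0)
    factor[lead] = (t0 - t[lead]) / ramp_ms * 0.0 + (1 - (t[lead] - (t0 - ramp_ms)) / ramp_ms)
    trail = (t >= t1) & (t < t1 + ramp_ms)
    factor[trail] = (t[trail] - t1 + rec.nominal_dt_ms) / ramp_ms
    np.clip(factor, 0.0, 1.0, out=factor)
    changed = factor < 1.0
    rec.pupil[changed] *= factor[changed]
    rec.valid[:] = np.isfinite(rec.pupil) & (rec.pupil > 0)
    artifact |= changed


def inject_artifacts(
    rec: RawRecording,
    truth: GroundTruth,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> RawRecording:
    """Add blinks, dropout fragments, and whole-trial losses to a recording.

    Blinks collapse the trace linearly to 0 over ~20 ms (guaranteeing both
    the amplitude and the velocity cleaning rules fire), stay near 0 for
    80-200 ms, and recover; some blinks hide a short (<=8 ms) island of
    plausible samples that only the fragment rule can catch.  Trials selected
    by ``trial_kill_fraction`` lose their entire stimulus window.  Every
    corrupted sample is recorded in ``truth.artifact_mask``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    out = rec.copy()
    art = truth.artifact_mask
    dur_min = out.duration_ms / 60_000.0
    n_blinks = int(rng.poisson(cfg.blink_rate_per_min * dur_min)) if cfg.blink_rate_per_min else 0
    dt = out.nominal_dt_ms

    forbidden = []
    if cfg.blink_avoid_stim:
        for onset in truth.onsets:
            forbidden.append((onset - 1200.0, onset + 2400.0))

    for _ in range(n_blinks):
        for _attempt in range(50):
            start = rng.uniform(out.time[0] + 500, out.time[-1] - 800)
            dur = rng.uniform(cfg.blink_min_ms, cfg.blink_max_ms)
            if not any(lo - dur - 50 < start < hi for lo, hi in forbidden):
                break
        else:
            continue
        start = round(start / dt) * dt
        _apply_dropout(out, (start, start + dur), cfg.blink_ramp_ms, art)
        if rng.random() < cfg.fragment_prob and dur > 60:
            # restore a <=8 ms island inside the plateau: an isolated fragment
            i0 = np.searchsorted(out.time, start + dur / 2)
            island = slice(i0, min(i0 + 4, len(out)))
            out.pupil[island] = truth.baseline_mm
            out.valid[island] = True
            art[island] = True

    if cfg.trial_kill_fraction > 0:
        kill = rng.random(len(truth.onsets)) < cfg.trial_kill_fraction
        for onset in truth.onsets[kill]:
            _apply_dropout(out, (onset - 200.0, onset + 1200.0), cfg.blink_ramp_ms, art)
        truth.killed_trials |= kill
    return out


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass
class GroupSpec:
    """Population distribution of one group's subject-level parameters."""

    amplitudes: dict                 # category -> mean amplitude, mm
    between_sd: dict                 # category -> between-subject SD, mm
    baseline_mean: float = 3.9       # mm
    baseline_sd: float = 0.5
    gaze_sd_deg: float = 0.8         # group-mean gaze scatter
    gaze_sd_logsd: float = 0.5       # between-subject lognormal spread of scatter
    trial_kill_fraction: float = 0.0


#: Study-condition defaults for the two-group cohort: sun constricts more than
#: phase-scrambled in both groups (0.15 mm within-subject difference), the
#: light response and resting diameter are enhanced in the autistic group,
#: the dark response is equivalent, and the autistic group loses more trials.
DEFAULT_EFFECTS = {
    "autistic": GroupSpec(
        amplitudes={"sun": -0.42, "scrambled": -0.27, "bright": -0.85, "dark": 0.26},
        between_sd={"sun": 0.10, "scrambled": 0.10, "bright": 0.20, "dark": 0.10},
        baseline_mean=4.1, baseline_sd=0.59, gaze_sd_deg=0.9,
        trial_kill_fraction=0.155,
    ),
    "comparison": GroupSpec(
        amplitudes={"sun": -0.35, "scrambled": -0.20, "bright": -0.70, "dark": 0.25},
        between_sd={"sun": 0.10, "scrambled": 0.10, "bright": 0.20, "dark": 0.10},
        baseline_mean=3.8, baseline_sd=0.48, gaze_sd_deg=0.7,
        trial_kill_fraction=0.053,
    ),
}


@dataclass
class SubjectData:
    subject_id: str
    group: str
    recording: RawRecording
    events: EventTable
    truth: GroundTruth


def _draw_signed(rng, mean: float, sd: float) -> float:
    """Draw an amplitude but keep the configured sign (responses do not flip
    polarity between subjects)."""
    a = rng.normal(mean, sd)
    if mean < 0:
        return min(a, -0.01)
    if mean > 0:
        return max(a, 0.01)
    return a


def simulate_cohort(
    n_autistic: int = 18,
    n_comparison: int = 23,
    effects: dict[str, GroupSpec] | None = None,
    base_config: SimConfig | None = None,
    seed: int = 0,
    artifacts: bool = True,
) -> list[SubjectData]:
    """Simulate a two-group cohort with subject-level parameter scatter.

    Per-subject response amplitudes and resting diameters are drawn from the
    group distributions in ``effects`` (see :data:`DEFAULT_EFFECTS`); each
    subject then gets a full recording with every configured stimulus
    category, optionally with artifacts.  Deterministic for a given seed.
    """
    effects = effects if effects is not None else DEFAULT_EFFECTS
    base = base_config if base_config is not None else SimConfig(
        trials={"sun": 13, "scrambled": 13, "bright": 13, "dark": 13}
    )
    rng = np.random.default_rng(seed)
    sizes = {"autistic": n_autistic, "comparison": n_comparison}
    dataset: list[SubjectData] = []
    idx = 0
    for group, size in sizes.items():
        spec = effects[group]
        for _ in range(size):
            idx += 1
            amps = {
                c: _draw_signed(rng, spec.amplitudes[c], spec.between_sd.get(c, 0.0))
                for c in base.trials
                if c in spec.amplitudes
            }
            # lognormal subject-level gaze scatter; the -logsd^2 offset keeps
            # the group-mean ellipse area (proportional to gaze_sd^2) at the
            # value implied by gaze_sd_deg
            gaze_mult = math.exp(rng.normal(0.0, spec.gaze_sd_logsd) - spec.gaze_sd_logsd**2)
            cfg = replace(
                base,
                trials={c: n for c, n in base.trials.items() if c in amps},
                amplitudes=amps,
                baseline_mm=float(rng.normal(spec.baseline_mean, spec.baseline_sd)),
                gaze_sd_deg=spec.gaze_sd_deg * gaze_mult,
                trial_kill_fraction=spec.trial_kill_fraction if artifacts else 0.0,
            )
            rec, events, truth = simulate_recording(cfg, rng, subject_id=f"s{idx:03d}")
            if artifacts:
                rec = inject_artifacts(rec, truth, cfg, rng)
            dataset.append(SubjectData(f"s{idx:03d}", group, rec, events, truth))
    return dataset


def binned_peak_factor(
    cfg: SimConfig,
    window_ms: int = 100,
    search_start: int = 200,
    search_end: int = 2000,
) -> float:
    """Expected attenuation of a kernel extremum at the analysis resolution.

    Averaging a unit-amplitude kernel in 100 ms windows shrinks its extremum
    slightly (the window average never reaches the instantaneous peak), by an
    amount that depends on where the onset falls within a window.  Returns
    the binned peak magnitude averaged over all onset phases on the sample
    grid — the factor by which injected amplitudes appear at the output of a
    noise-free pipeline.
    """
    dt = cfg.dt_ms
    per_win = int(round(window_ms / dt))
    t = np.arange(0, search_end + window_ms, dt)
    k = plr_kernel(t, cfg.latency_ms, 1.0, cfg.peak_time_ms, cfg.kernel_shape)
    peaks = []
    for shift in range(per_win):
        # onset lands `shift` samples after a window boundary
        padded = np.concatenate([np.zeros(shift), k])
        nwin = len(padded) // per_win
        binned = padded[: nwin * per_win].reshape(nwin, per_win).mean(axis=1)
        starts = np.arange(nwin) * window_ms - shift * dt
        m = (starts >= search_start) & (starts < search_end)
        peaks.append(binned[m].max())
    return float(np.mean(peaks))
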