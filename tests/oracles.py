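"""Brute-force per-sample reference implementations of the cleaning steps.

Deliberately written as plain Python loops, independent of the vectorized
package code, for oracle-equivalence checks on short traces.
"""

import math


def oracle_remove_small(pupil, valid, min_mm=0.1):
    out = list(valid)
    for i, p in enumerate(pupil):
        if not (isinstance(p, float) and math.isfinite(p)) or p < min_mm:
            out[i] = False
    return out


def oracle_remove_fast(time, pupil, valid, max_speed=10.0):
    out = list(valid)
    kept = [i for i in range(len(valid)) if valid[i]]
    for a, b in zip(kept, kept[1:]):
        dt_s = (time[b] - time[a]) / 1000.0
        # strict threshold with the documented 1e-9 representation-noise guard
        if abs(pupil[b] - pupil[a]) / dt_s > max_speed * (1 + 1e-9):
            out[a] = False
            out[b] = False
    return out


def oracle_remove_fragments(time, valid, max_len=10.0):
    out = list(valid)
    i = 0
    n = len(valid)
    while i < n:
        if not valid[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and valid[j + 1]:
            j += 1
        if time[j] - time[i] <= max_len:
            for k in range(i, j + 1):
                out[k] = False
        i = j + 1
    return out


def oracle_downsample(time, pupil, valid, window=100):
    t0 = time[0]
    dt = time[1] - time[0] if len(time) > 1 else 2
    duration = time[-1] - t0 + dt
    n_win = math.ceil(duration / window)
    means = []
    for w in range(n_win):
        lo, hi = t0 + w * window, t0 + (w + 1) * window
        vals = [pupil[i] for i in range(len(time)) if lo <= time[i] < hi and valid[i]]
        means.append(sum(vals) / len(vals) if vals else float("nan"))
    return means
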