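#!/usr/bin/env python
"""Group-level statistics for the simulated two-group cohort.

Rebuilds SubjectSummary objects from results/subject_summaries.csv and runs
the full between/within analysis: mixed ANOVAs for light/dark reactivity and
for the sun/phase-scrambled contextual effect, group comparisons of the
normalized sun response, resting diameter and gaze dispersion — each with a
p-value, a log10 Bayes factor and its evidence label.  Writes
results/exp2_stats.csv and results/exp2_report.txt.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from pupilresp.io_formats import SubjectSummary
from pupilresp.pipeline import run_exp2

ROOT = Path(__file__).resolve().parents[1]


def load_summaries(path) -> list[SubjectSummary]:
    df = pd.read_csv(path)
    out = []
    for sid, sub in df.groupby("subject_id", sort=False):
        s = SubjectSummary(str(sid), group=sub.group.iloc[0])
        for row in sub.itertuples():
            if np.isfinite(row.peak_mm):
                s.peaks[row.category] = row.peak_mm
            if np.isfinite(row.normalized_peak):
                s.normalized[row.category] = row.normalized_peak
        s.exclusion_fraction = sub.exclusion_fraction.iloc[0]
        s.resting_diameter = sub.resting_diameter_mm.iloc[0]
        s.bce_area = sub.bce_area_deg2.iloc[0]
        out.append(s)
    return out


def main() -> None:
    src = ROOT / "results" / "subject_summaries.csv"
    if not src.exists():
        raise SystemExit("run analysis/02_extract_responses.py first")
    summaries = load_summaries(src)
    rep = run_exp2(summaries)
    rep.to_frame().to_csv(ROOT / "results" / "exp2_stats.csv", index=False,
                          float_format="%.9g")
    text = rep.render()
    (ROOT / "results" / "exp2_report.txt").write_text(text + "\n")
    print(text)


if __name__ == "__main__":
    main()
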