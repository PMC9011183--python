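#!/usr/bin/env python
"""Run the signal pipeline on the simulated cohort and extract per-subject
peak responses, exclusion fractions, resting diameters and gaze dispersion.

Reads scratch/cohort/ (run 01_simulate_cohort.py first), writes
results/subject_summaries.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from pupilresp import io_formats as iof
from pupilresp.cli import load_directory
from pupilresp.pipeline import analyze_dataset

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "cohort"


def main() -> None:
    if not (COHORT / "manifest.csv").exists():
        raise SystemExit("cohort not found; run analysis/01_simulate_cohort.py first")
    dataset = load_directory(COHORT)
    summaries = analyze_dataset(dataset)
    out = ROOT / "results" / "subject_summaries.csv"
    iof.write_summary(summaries, out)

    df = pd.DataFrame(
        {
            "group": [s.group for s in summaries],
            "sun": [s.peaks.get("sun", np.nan) for s in summaries],
            "scrambled": [s.peaks.get("scrambled", np.nan) for s in summaries],
            "bright": [s.peaks.get("bright", np.nan) for s in summaries],
            "dark": [s.peaks.get("dark", np.nan) for s in summaries],
            "excluded": [s.exclusion_fraction for s in summaries],
            "resting": [s.resting_diameter for s in summaries],
            "bce": [s.bce_area for s in summaries],
        }
    )
    print(f"processed {len(df)} subjects -> {out}")
    for g, sub in df.groupby("group"):
        print(f"  {g:10s} sun {sub.sun.mean():+.3f} mm  scrambled {sub.scrambled.mean():+.3f} mm  "
              f"bright {sub.bright.mean():+.3f} mm  dark {sub.dark.mean():+.3f} mm")
        print(f"             excluded {sub.excluded.mean():.1%}  "
              f"resting {sub.resting.mean():.2f} mm  BCE {sub.bce.mean():.1f} deg^2")


if __name__ == "__main__":
    main()
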