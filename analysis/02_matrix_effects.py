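#!/usr/bin/env python
"""Summarize the per-compound matrix effects of the study.

Reads the bundled per-level matrix-effect table (percent deviation from
100% of the matrix-matched vs solvent response ratio), ranks compounds by
mean effect, and writes results/matrix_effect_summary.csv.  Strong
suppression flags compounds whose quantitation in this matrix rests
entirely on the analyte protectant.
"""
import csv
import sys
from pathlib import Path

import numpy as np

from pestvalid.validate import bundled_matrix_effect

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    me = bundled_matrix_effect()
    rows = []
    for compound, by_level in me.items():
        vals = np.array(list(by_level.values()))
        rows.append((compound, float(vals.mean()), float(vals.min()),
                     float(vals.max())))
    rows.sort(key=lambda r: r[1])

    RESULTS.mkdir(exist_ok=True)
    with open(RESULTS / "matrix_effect_summary.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["compound", "mean_pct", "min_pct", "max_pct"])
        w.writerows([c, f"{m:.1f}", f"{lo:.1f}", f"{hi:.1f}"]
                    for c, m, lo, hi in rows)

    print("strongest suppression (mean matrix effect, %):")
    for c, m, *_ in rows[:5]:
        print(f"  {c}: {m:.1f}")
    print("strongest enhancement (mean matrix effect, %):")
    for c, m, *_ in rows[-5:]:
        print(f"  {c}: {m:.1f}")
    n_within = sum(1 for _, m, *_ in rows if abs(m) <= 20)
    print(f"{n_within} of {len(rows)} compounds have a mean matrix effect "
          f"within +/-20%")
    print(f"table written to {RESULTS/'matrix_effect_summary.csv'}")


if __name__ == "__main__":
    sys.exit(main())
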