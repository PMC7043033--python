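"""Regenerate the Monte-Carlo critical-value table for the Lilliefors test.

For each sample size on the grid, draws 20,000 standard-normal samples with a
fixed seed, computes the Lilliefors D statistic of each, and stores the upper
quantiles at the tabulated significance levels.  The result is written to
``src/leafskew/data/lilliefors_table.json`` and shipped with the package; it
only needs re-running if the grid, replicate count or seed changes.

Usage:  python scripts/make_lilliefors_table.py [--reps 20000] [--seed 20200226]
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import numpy as np
from scipy import stats as sps

N_GRID = [4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20, 25, 30, 35, 40, 50, 60,
          80, 100, 150, 200, 300, 400, 500, 700, 1000, 1500, 2000]
ALPHAS = [0.001, 0.005, 0.01, 0.02, 0.05, 0.10, 0.15, 0.20, 0.30, 0.40, 0.50]


def lilliefors_d_batch(x: np.ndarray) -> np.ndarray:
    """Vectorised Lilliefors D over the rows of ``x`` (reps, n)."""
    reps, n = x.shape
    xs = np.sort(x, axis=1)
    mean = xs.mean(axis=1, keepdims=True)
    sd = xs.std(axis=1, ddof=1, keepdims=True)
    cdf = sps.norm.cdf((xs - mean) / sd)
    i = np.arange(1, n + 1, dtype=np.float64)
    d_plus = np.max(i / n - cdf, axis=1)
    d_minus = np.max(cdf - (i - 1) / n, axis=1)
    return np.maximum(d_plus, d_minus)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--reps", type=int, default=20000)
    ap.add_argument("--seed", type=int, default=20200226)
    ap.add_argument("--out", type=Path,
                    default=Path(__file__).resolve().parents[1]
                    / "src" / "leafskew" / "data" / "lilliefors_table.json")
    args = ap.parse_args()

    rng = np.random.default_rng(args.seed)
    crit = []
    for n in N_GRID:
        d = lilliefors_d_batch(rng.standard_normal((args.reps, n)))
        crit.append(np.quantile(d, [1.0 - a for a in ALPHAS]).round(6).tolist())
        print(f"n={n:5d}  cv(0.05)={crit[-1][ALPHAS.index(0.05)]:.4f}")

    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(
        {"reps": args.reps, "seed": args.seed, "n": N_GRID,
         "alphas": ALPHAS, "crit": crit}, indent=1))
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
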