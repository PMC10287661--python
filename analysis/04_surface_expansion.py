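"""Vertex-wise surface-area expansion maps and growth-region detection.

Fits a growth trajectory to every mesh vertex's local area, evaluates
monthly relative expansion-rate maps, and detects high-/low-growth regions
(top/bottom 20% candidates, bootstrap t-test against the cross-vertex
median, BH-FDR).  Since the cohort is synthetic, the recovered regions are
scored against the planted patches (Dice overlap).
"""

import json
import logging
import sys

import numpy as np
import pandas as pd

from subgrowth.pipeline import (
    PipelineConfig,
    stage_simulate,
    stage_fit_surface,
    stage_detect_regions,
)
from subgrowth import io as sgio


def dice(a, b) -> float:
    a, b = set(a), set(b)
    return 2 * len(a & b) / (len(a) + len(b)) if (a or b) else float("nan")


def main(seed: int = 0) -> None:
    logging.basicConfig(level=logging.INFO, format="%(message)s")
    cfg = PipelineConfig(output_dir="results/run", seed=seed)
    stage_simulate(cfg)
    stage_fit_surface(cfg)
    stage_detect_regions(cfg)
    truth = sgio.read_truth("results/run/truth.json")
    mt = truth.mesh_truth
    regions = json.loads(open("results/run/regions.json").read())
    print("recovered vs planted growth regions (Dice):")
    for month, reg in regions.items():
        dh = dice(reg["high"], mt.high_vertices.tolist())
        dl = dice(reg["low"], mt.low_vertices.tolist())
        print(f"  month {month:>2s}: high {dh:.2f} ({len(reg['high'])} vx), "
              f"low {dl:.2f} ({len(reg['low'])} vx)")
    rates = pd.read_csv("results/run/vertex_rates.tsv", sep="\t", comment="#")
    med = rates.groupby("month").rate.median()
    print("\nmedian expansion rate (fraction/month):")
    print(med.round(4).to_string())


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
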