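"""Simulate the study cohort: longitudinal scans, meshes and behavior scores.

Generates the default synthetic cohort (231 subjects, two sites, ages
0-810 days, unbalanced longitudinal sampling), corresponded surface meshes
for the left thalamus analog with planted high-/low-growth patches, and
Mullen-style behavior scores with planted volume-ratio effects; writes
cohort.tsv, truth.json and meshes/ under results/run.
"""

import logging
import sys

import pandas as pd

from subgrowth.pipeline import PipelineConfig, stage_simulate
from subgrowth import io as sgio


def main(seed: int = 0) -> None:
    logging.basicConfig(level=logging.INFO, format="%(message)s")
    cfg = PipelineConfig(output_dir="results/run", seed=seed)
    stage_simulate(cfg)
    rec = sgio.read_cohort("results/run/cohort.tsv")
    per_subj = rec.groupby("subject_id").size()
    print(f"subjects: {per_subj.size}, scans: {len(rec)}")
    print(f"subjects with >=2 scans: {(per_subj >= 2).mean():.1%}"
          f" (design target 45%)")
    print(f"subjects with >=3 scans: {(per_subj >= 3).mean():.1%}"
          f" (design target 12%)")
    print(rec.groupby(["site", "sex"]).size().rename("scans").to_string())


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
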