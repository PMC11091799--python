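#!/usr/bin/env python
"""Collate the analysis outputs into one printed summary.

Reads the tables written by the earlier numbered scripts and prints the
run's headline numbers: cohort structure, aggregation decisions, the
significant acoustic features, and the classification accuracies.
"""

import json
from pathlib import Path

import pandas as pd

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = pd.read_csv(RESULTS / "cohort.csv")
    print("=== cohort ===")
    print(f"participants: {len(cohort)}; per group:",
          cohort.groupby("group").size().to_dict())

    stats_df = pd.read_csv(RESULTS / "feature_stats.csv")
    sig = stats_df[stats_df["omnibus_p"] < 0.05]
    print("\n=== group statistics (15-s location features) ===")
    print(f"significant features: {len(sig)}/{len(stats_df)}")
    for _, r in sig.iterrows():
        print(f"  {r['feature']}: {r['g1_mean']:.3g} -> {r['g2_mean']:.3g} "
              f"-> {r['g3_mean']:.3g}  (p={r['omnibus_p']:.2g})")

    summary = pd.read_csv(RESULTS / "classification_summary.csv")
    print("\n=== classification ===")
    print(summary.round(3).to_string(index=False))

    gt_path = RESULTS / "voice_ground_truth.json"
    if gt_path.exists():
        gt = json.loads(gt_path.read_text())
        print("\n=== demo signal ground truth ===")
        print(f"unvoiced fraction {gt['unvoiced_fraction']:.2f}, "
              f"shimmer {gt['shimmer_percent']:.1f}%, "
              f"{gt['n_pauses']} pause(s)")


if __name__ == "__main__":
    main()
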