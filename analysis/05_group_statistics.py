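#!/usr/bin/env python
"""Asymmetry and group statistics over simulated subject cohorts.

Runs the full pipeline on two synthetic groups (group "b" carries a
stronger planted coupling, mimicking a group with stronger directed
communication), then emits the asymmetry tables per group and the
between-group comparison of every directed connection among shared
ROIs - the same row layout as the study's connectivity tables.
"""

from pathlib import Path

import pandas as pd

from thetanet.ncreann import TrainConfig
from thetanet.pipeline import PipelineConfig, run_pipeline

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int = 1) -> None:
    cfg = PipelineConfig(
        out_dir=str(ROOT / "results" / "pipeline_demo"),
        seed=seed,
        n_subjects_a=12,
        n_subjects_b=12,
        n_samples=1500,
        train=TrainConfig(folds=3, max_epochs=80, patience=10),
    )
    report = run_pipeline(cfg)
    grp = pd.read_csv(report["stats"]["group_comparison"])
    lin = grp[grp.measure == "linear"]
    print("between-group comparison (linear measure):")
    print(lin[["connection", "t", "d", "p", "p_fdr", "BF10", "evidence"]]
          .to_string(index=False))
    flagged = lin[lin.sig_fdr]
    print(f"\n{len(flagged)} linear connection(s) differ between groups after FDR; "
          "the planted boosted edge is IC -> ATL")
    print(f"tables under {cfg.out_dir}")


if __name__ == "__main__":
    main()
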