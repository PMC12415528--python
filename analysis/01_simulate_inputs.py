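#!/usr/bin/env python
"""Simulate every input class with known ground truth.

Generates a stationary linear VAR, a nonlinear MVAR with a planted
square cross-lag term, flicker-entrained epochs at the tag (4.5 Hz) and
control (8 Hz) frequencies, and a hotspot voxel field. Writes a summary
of what was planted (the ground truth downstream stages must recover)
to results/simulated_inputs.json; array containers go to scratch/.
"""

import json
from pathlib import Path

import numpy as np

from thetanet.synthetic import (
    FlickerSpec,
    Hotspot,
    LinearVARSpec,
    NLTerm,
    NonlinearVARSpec,
    VoxelFieldSpec,
    gen_linear_var,
    gen_nonlinear_var,
    gen_ssvep_epochs,
    gen_voxel_field,
)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "simulated"


def main(seed: int = 1) -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    summary = {}

    A = np.zeros((1, 2, 2))
    A[0] = [[0.5, 0.0], [0.4, 0.5]]
    lin_spec = LinearVARSpec(M=2, p_true=1, A=A, n_samples=4000, seed=seed)
    series, adj = gen_linear_var(lin_spec)
    series.save(SCRATCH / "linear_var")
    summary["linear_var"] = {
        "M": 2, "p": 1, "n_samples": 4000,
        "true_edges": [[int(i), int(j)] for i, j in zip(*np.nonzero(adj)) if i != j],
    }

    nl_spec = NonlinearVARSpec(
        LinearVARSpec(M=2, p_true=1, A=np.diag([0.5, 0.5])[None],
                      n_samples=4000, seed=seed + 1),
        [NLTerm(target=1, source=0, lag=1, form="square", gain=0.4)],
    )
    nl_series, adj_lin, adj_nl = gen_nonlinear_var(nl_spec)
    nl_series.save(SCRATCH / "nonlinear_var")
    summary["nonlinear_var"] = {
        "nonlinear_edges": [[int(i), int(j)] for i, j in zip(*np.nonzero(adj_nl))],
        "form": "square", "gain": 0.4,
    }

    for name, freq in (("tag_4p5", 4.5), ("control_8", 8.0)):
        ep = gen_ssvep_epochs(FlickerSpec(flicker_freq=freq, n_trials=30,
                                          seed=seed + 10))
        ep.save(SCRATCH / f"ssvep_{name}")
        summary[f"ssvep_{name}"] = {"flicker_freq": freq, "n_trials": 30,
                                    "epoch_s": list(ep.times[[0, -1]])}

    field = gen_voxel_field(VoxelFieldSpec(
        hotspots=[Hotspot((-30, -30, -30), 10, 5), Hotspot((30, 30, 30), 10, 5)],
        seed=seed + 20,
    ))
    field.to_table(SCRATCH / "voxel_field.tsv")
    summary["voxel_field"] = {"n_voxels": int(field.power.size),
                              "hotspot_centers_mm": [[-30, -30, -30], [30, 30, 30]]}

    out = RESULTS / "simulated_inputs.json"
    out.write_text(json.dumps(summary, indent=1))
    print(f"planted ground truth written to {out.relative_to(ROOT)}")
    print(f"array containers under {SCRATCH.relative_to(ROOT)}/")


if __name__ == "__main__":
    main()
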