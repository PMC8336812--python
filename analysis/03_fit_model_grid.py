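#!/usr/bin/env python
"""Fit the six-model grid on the simulated survey and write the full
report: model comparison, linear effects, smooth-term curves, spatial
effects and residual diagnostics."""

from pathlib import Path

from distreg.cli import main

ROOT = Path(__file__).resolve().parents[1]
SURVEY = ROOT / "results" / "survey"

main.main(
    args=[
        "report",
        "--survey", str(SURVEY / "survey.csv"),
        "--edges", str(SURVEY / "district_edges.txt"),
        "--nodes", str(SURVEY / "district_nodes.txt"),
        "--seed", "21",
        "--iterations", "1500",
        "--burn-in", "500",
        "--thinning", "4",
        "--n-intervals", "10",
        "--tensor-intervals", "5",
        "--out", str(ROOT / "results" / "model_grid"),
    ],
    standalone_mode=False,
)
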