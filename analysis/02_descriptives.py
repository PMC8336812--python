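#!/usr/bin/env python
"""Wave-level descriptive statistics of the simulated survey."""

from pathlib import Path

from distreg.cli import main

ROOT = Path(__file__).resolve().parents[1]

main.main(
    args=[
        "describe",
        "--survey", str(ROOT / "results" / "survey" / "survey.csv"),
        "--out", str(ROOT / "results" / "descriptives.tsv"),
    ],
    standalone_mode=False,
)
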