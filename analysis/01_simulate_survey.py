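#!/usr/bin/env python
"""Generate the synthetic two-wave survey used by the downstream steps."""

from pathlib import Path

from distreg.cli import main

ROOT = Path(__file__).resolve().parents[1]

main.main(
    args=[
        "simulate",
        "--seed", "20",
        "--n-2007", "800",
        "--n-2013", "1200",
        "--side", "4",
        "--out", str(ROOT / "results" / "survey"),
    ],
    standalone_mode=False,
)
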