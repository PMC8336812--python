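#!/usr/bin/env python
"""Condense the model-grid report into a short plain-text summary."""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
GRID = ROOT / "results" / "model_grid"

comp = pd.read_csv(GRID / "model_comparison.tsv", sep="\t")
effects = pd.read_csv(GRID / "linear_effects.tsv", sep="\t")
spatial = pd.read_csv(GRID / "spatial_effect.tsv", sep="\t")

lines = ["Model comparison (lower DIC/WAIC is better)", ""]
lines.append(comp.to_string(index=False,
                            float_format=lambda v: f"{v:.1f}"))
best_dic = int(comp.loc[comp["selected_by_DIC"], "model"].iloc[0])
best_waic = int(comp.loc[comp["selected_by_WAIC"], "model"].iloc[0])
lines += ["", f"selected by DIC:  model {best_dic}",
          f"selected by WAIC: model {best_waic}", ""]

lines += ["Linear effects of the selected model", ""]
sel = effects[effects["model"] == best_dic] if "model" in effects else effects
lines.append(sel.to_string(index=False,
                           float_format=lambda v: f"{v:.3f}"))

lines += ["", "Spatial effect range (posterior means by district x wave)", ""]
rng = spatial.groupby("wave")["posterior_mean"].agg(["min", "max"])
lines.append(rng.to_string(float_format=lambda v: f"{v:.3f}"))

out = ROOT / "results" / "summary.txt"
out.write_text("\n".join(lines) + "\n")
print(f"wrote {out}")
print("\n".join(lines))
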