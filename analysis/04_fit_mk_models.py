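"""Fit Mk models of biome-preference evolution and simplify the ARD model.

Fits ER, SYM, ARD and the stepwise model on the classified 5-state tip
preferences, then iteratively zeroes the smallest ARD rates until AIC stops
decreasing. Prints the model table (AIC weights) and the source-sink summary
of the best matrix: a ratio > 1 marks a state exporting lineages (an
evolutionary source), < 1 a stable sink.
"""

import runpy
from pathlib import Path

import pandas as pd

CONFIG = runpy.run_path(Path(__file__).parent / "00_config.py")["CONFIG"]

from biomevol.pipeline import run_pipeline

CONFIG.stages = ("fit_mk",)
out = run_pipeline(CONFIG)

tab = pd.read_csv(out / "fit_mk" / "model_table.tsv", sep="\t")
print("model comparison (AIC):")
print(tab.to_string(index=False, float_format=lambda x: f"{x:.2f}"))
ss = pd.read_csv(out / "fit_mk" / "source_sink.tsv", sep="\t")
print("\nsource-sink summary of the best model (away / into / ratio):")
print(ss.to_string(index=False, float_format=lambda x: f"{x:.2f}"))
print(f"\nfitted matrices written under {out / 'fit_mk'}")
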