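"""Simulate the synthetic study dataset.

Writes results/run/simulate/: the ultrametric tree (newick), the true
biome-preference states per tip, the ground-truth sparse transition matrix,
and the biome-structured occupancy table with sample metadata.
"""

import runpy
from pathlib import Path

CONFIG = runpy.run_path(Path(__file__).parent / "00_config.py")["CONFIG"]

from biomevol.pipeline import run_pipeline
from biomevol.trees import read_newick

CONFIG.stages = ("simulate",)
out = run_pipeline(CONFIG)

tree = read_newick((out / "simulate" / "tree.nwk").read_text())
print(f"simulated tree: {tree.n_tips} tips, height {tree.height:.3f} (relative time)")
print(f"occupancy table + metadata written under {out / 'simulate'}")
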