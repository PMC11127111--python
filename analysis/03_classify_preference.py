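"""Assign a biome preference to every taxon by occupancy bootstrap.

Single-biome taxa are specialists outright; multi-biome taxa are called by
resampling their presence records (100 draws x 1000 replicates) against the
biome availabilities (land 0.44 / marine 0.38 / freshwater 0.18). Prints the
specialist share and the number of taxa spanning the salt barrier.
"""

import runpy
from pathlib import Path

import yaml

CONFIG = runpy.run_path(Path(__file__).parent / "00_config.py")["CONFIG"]

from biomevol.pipeline import run_pipeline

CONFIG.stages = ("classify",)
out = run_pipeline(CONFIG)

s = yaml.safe_load((out / "classify" / "summary.yaml").read_text())
print(f"classified {s['total']} taxa")
print(f"specialists: {s['pct_specialist']:.1f}%   generalists: {s['pct_generalist']:.1f}%")
print(f"taxa spanning the salt barrier (saline + nonsaline): {s['n_salt_barrier']}")
for state, n in s["collapsed_counts"].items():
    print(f"  {state:32s} {n}")
print(f"per-taxon calls written to {out / 'classify' / 'calls.tsv'}")
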