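"""Shared configuration for the analysis scripts.

One synthetic study dataset at the survey's structure: a 300-tip ultrametric
tree (relative time, height 1), a sparse 5-state biome-preference history on
it, and a 63-sample occupancy table (27 land / 25 marine / 11 freshwater)
with read counts overlaid. Every script below derives its stage from this
config, so the whole analysis is reproducible from (config, seed).
"""

from biomevol.pipeline import PipelineConfig

CONFIG = PipelineConfig(
    outdir="results/run",
    seed=20_24,
    n_taxa=300,
    n_tips=300,
    n_perm=999,
    gap_B=50,
    sse_models=(("musse", 1), ("ctd", 2), ("ctd", 3), ("muhisse", 2)),
    sse_starts=2,
)
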