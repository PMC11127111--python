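"""Sample x taxon occupancy/abundance tables with a sample->biome map."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["OccupancyTable"]


@dataclass
class OccupancyTable:
    """Rows are samples, columns are taxa. `counts` may hold read counts or
    0/1 presence; `presence()` thresholds at > 0. `true_preference` is only
    populated by the synthetic generator (taxon -> frozenset of biomes)."""

    counts: pd.DataFrame
    sample_biome: pd.Series
    true_preference: dict | None = None

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("negative counts in occupancy table")
        missing = set(self.counts.index) - set(self.sample_biome.index)
        if missing:
            raise ValueError(f"samples without a biome label: {sorted(missing)[:10]}")
        self.sample_biome = self.sample_biome.loc[self.counts.index]

    @property
    def samples(self):
        return list(self.counts.index)

    @property
    def taxa(self):
        return list(self.counts.columns)

    @property
    def biomes(self):
        return sorted(self.sample_biome.unique())

    def presence(self) -> pd.DataFrame:
        return (self.counts > 0).astype(np.int64)

    def relative_abundance(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        if (totals == 0).any():
            empty = list(self.counts.index[totals == 0])
            raise ValueError(f"samples with zero total abundance: {empty}")
        return self.counts.div(totals, axis=0)

    def biome_sample_counts(self) -> pd.Series:
        return self.sample_biome.value_counts().sort_index()

    def subset_taxa(self, taxa) -> "OccupancyTable":
        tp = None
        if self.true_preference is not None:
            tp = {t: self.true_preference[t] for t in taxa if t in self.true_preference}
        return OccupancyTable(self.counts[list(taxa)], self.sample_biome, tp)

    # -- io ---------------------------------------------------------------

    def to_tsv(self, counts_path, metadata_path):
        self.counts.to_csv(counts_path, sep="\t", index_label="sample")
        self.sample_biome.rename("biome").to_csv(metadata_path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, counts_path, metadata_path) -> "OccupancyTable":
        counts = pd.read_csv(counts_path, sep="\t", index_col="sample")
        meta = pd.read_csv(metadata_path, sep="\t", index_col="sample")["biome"]
        return cls(counts, meta)
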