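"""Occupancy-bootstrap classification of taxa into biome preferences.

Each taxon's presence/absence across biome-labeled samples is compared with
the proportion of sampling effort each biome represents ("availability").
A taxon present in a single biome is a specialist outright. For taxa present
in several biomes, the presence records are resampled (n_draws records per
replicate, n_reps replicates) and the taxon is given affinity for every biome
where at least `tail` of the replicate occupancy proportions reach that
biome's availability. The affinity set defines one of seven raw preferences
(three specialists, three two-biome generalists, one full generalist), which
collapse to five analysis states by merging the marine-containing generalists.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import OccupancyTable

__all__ = [
    "BIOMES",
    "RAW_STATES",
    "COLLAPSED_STATES",
    "BiomeAvailability",
    "PreferenceCall",
    "classify_taxon",
    "collapse_preference",
    "classify_table",
    "summarize_preference_counts",
]

BIOMES = ("freshwater", "marine", "land")

_SET_TO_RAW = {
    frozenset({"freshwater"}): "freshwater specialist",
    frozenset({"marine"}): "marine specialist",
    frozenset({"land"}): "land specialist",
    frozenset({"freshwater", "marine"}): "freshwater + marine generalist",
    frozenset({"marine", "land"}): "marine + land generalist",
    frozenset({"freshwater", "land"}): "freshwater + land generalist",
    frozenset({"freshwater", "marine", "land"}): "full generalist",
}
RAW_STATES = tuple(_SET_TO_RAW.values())
RAW_TO_SET = {v: k for k, v in _SET_TO_RAW.items()}

#: analysis alphabet: the three marine-containing generalist classes merge
COLLAPSED_STATES = (
    "freshwater specialist",
    "marine specialist",
    "land specialist",
    "freshwater + land generalist",
    "marine generalist",
)

_COLLAPSE = {
    "freshwater specialist": "freshwater specialist",
    "marine specialist": "marine specialist",
    "land specialist": "land specialist",
    "freshwater + land generalist": "freshwater + land generalist",
    "freshwater + marine generalist": "marine generalist",
    "marine + land generalist": "marine generalist",
    "full generalist": "marine generalist",
}

_SPECIALISTS = {"freshwater specialist", "marine specialist", "land specialist"}
#: raw states straddling the saline/nonsaline ("salt barrier") divide
_SALT_BARRIER = {
    "freshwater + marine generalist",
    "marine + land generalist",
    "full generalist",
}


@dataclass
class BiomeAvailability:
    """Expected per-biome occupancy proportion under no preference.

    The availability vector is an explicit input rather than being derived
    from sample counts: the two need not agree exactly (study designs may
    round or adjust for effort), so we never silently substitute one for the
    other."""

    proportions: dict
    sample_counts: dict | None = None

    def __post_init__(self):
        vals = np.array(list(self.proportions.values()), dtype=float)
        if (vals <= 0).any():
            raise ValueError("availability proportions must be positive")
        if abs(vals.sum() - 1.0) > 1e-6:
            raise ValueError(f"availability must sum to 1 (got {vals.sum():.8f})")

    @classmethod
    def study_default(cls) -> "BiomeAvailability":
        """Three-biome design: land 0.44, marine 0.38, freshwater 0.18
        with 27/25/11 samples."""
        return cls(
            proportions={"freshwater": 0.18, "marine": 0.38, "land": 0.44},
            sample_counts={"freshwater": 11, "marine": 25, "land": 27},
        )

    @property
    def biomes(self):
        return tuple(self.proportions)

    def as_array(self, order) -> np.ndarray:
        return np.array([self.proportions[b] for b in order])


@dataclass
class PreferenceCall:
    taxon: str
    raw: str
    collapsed: str
    affinities: frozenset
    bootstrapped: bool
    #: per-biome (lower-tail quantile, upper-tail quantile, fraction of
    #: replicates at or above availability); None when bootstrap was skipped
    quantiles: dict | None = None


def collapse_preference(raw: str) -> str:
    """Map the 7-state raw preference to the 5-state analysis alphabet."""
    try:
        return _COLLAPSE[raw]
    except KeyError:
        raise ValueError(f"unknown raw preference {raw!r}") from None


def _coupled_biome_counts(rng, p, n_reps, n_draws):
    """Bootstrap biome counts via a shared uniform array and cumulative
    intervals. The coupling makes affinity monotone: adding a presence record
    in biome b only widens b's interval, so at a fixed uniform stream b's
    count per replicate can only grow."""
    u = rng.random((n_reps, n_draws))
    edges = np.concatenate([[0.0], np.cumsum(p)])
    edges[-1] = 1.0 + 1e-12
    counts = np.empty((n_reps, len(p)), dtype=np.int64)
    for b in range(len(p)):
        counts[:, b] = ((u >= edges[b]) & (u < edges[b + 1])).sum(axis=1)
    return counts


def classify_taxon(
    presence: pd.Series,
    biomes: pd.Series,
    avail: BiomeAvailability,
    n_draws: int = 100,
    n_reps: int = 1000,
    tail: float = 0.025,
    seed=None,
    taxon: str = "taxon",
) -> PreferenceCall:
    """Classify one taxon from its 0/1 presence vector across samples.

    `presence` is indexed by sample id; `biomes` maps sample id -> biome.
    """
    present = presence.index[np.asarray(presence) > 0]
    if len(present) == 0:
        raise ValueError(f"taxon {taxon!r} has all-zero presence")
    labels = biomes.loc[present]
    unknown = sorted(set(labels) - set(avail.biomes))
    if unknown:
        raise ValueError(f"unknown biome labels {unknown}; expected {avail.biomes}")

    order = avail.biomes
    c = np.array([(labels == b).sum() for b in order], dtype=float)
    observed = frozenset(b for b, n in zip(order, c) if n > 0)

    if len(observed) == 1:
        raw = _SET_TO_RAW[observed]
        return PreferenceCall(taxon, raw, collapse_preference(raw), observed, False)

    rng = np.random.default_rng(seed)
    p = c / c.sum()
    counts = _coupled_biome_counts(rng, p, n_reps, n_draws)
    props = counts / float(n_draws)
    a = avail.as_array(order)
    frac_ge = (props >= a[None, :]).mean(axis=0)
    affinity = frozenset(b for b, f in zip(order, frac_ge) if f >= tail)
    quantiles = {
        b: (
            float(np.quantile(props[:, i], tail)),
            float(np.quantile(props[:, i], 1.0 - tail)),
            float(frac_ge[i]),
        )
        for i, b in enumerate(order)
    }
    raw = _SET_TO_RAW[affinity]
    return PreferenceCall(taxon, raw, collapse_preference(raw), affinity, True, quantiles)


def _taxon_seed(root_seed, taxon: str):
    # order-independent per-taxon stream: hash the taxon id into the entropy
    return [int(root_seed), zlib.crc32(str(taxon).encode())]


def classify_table(
    table: OccupancyTable,
    avail: BiomeAvailability | None = None,
    n_draws: int = 100,
    n_reps: int = 1000,
    tail: float = 0.025,
    seed: int = 0,
):
    """Classify every taxon in an occupancy table.

    Returns (calls DataFrame indexed by taxon, summary dict). Per-taxon RNG
    streams are derived from (seed, taxon id), so results do not depend on
    column order."""
    if avail is None:
        avail = BiomeAvailability.study_default()
    presence = table.presence()
    rows = []
    for taxon in presence.columns:
        call = classify_taxon(
            presence[taxon],
            table.sample_biome,
            avail,
            n_draws=n_draws,
            n_reps=n_reps,
            tail=tail,
            seed=_taxon_seed(seed, taxon),
            taxon=taxon,
        )
        row = {
            "taxon": call.taxon,
            "raw": call.raw,
            "collapsed": call.collapsed,
            "bootstrapped": call.bootstrapped,
        }
        if call.quantiles:
            for b, (lo, hi, f) in call.quantiles.items():
                row[f"q{100 * (1 - tail):g}_{b}"] = hi
                row[f"frac_ge_avail_{b}"] = f
        rows.append(row)
    calls = pd.DataFrame(rows).set_index("taxon")
    raw_counts = calls["raw"].value_counts().to_dict()
    summary = summarize_preference_counts(raw_counts)
    return calls, summary


def summarize_preference_counts(raw_counts: dict) -> dict:
    """Summary arithmetic over per-category taxon counts: totals, the
    specialist share, and how many taxa span the salt barrier (occur in both
    saline and nonsaline biomes)."""
    unknown = sorted(set(raw_counts) - set(RAW_STATES))
    if unknown:
        raise ValueError(f"unknown raw states in counts: {unknown}")
    total = int(sum(raw_counts.values()))
    if total == 0:
        raise ValueError("no taxa in counts")
    n_spec = sum(raw_counts.get(s, 0) for s in _SPECIALISTS)
    collapsed_counts = {}
    for raw, n in raw_counts.items():
        key = collapse_preference(raw)
        collapsed_counts[key] = collapsed_counts.get(key, 0) + n
    pct_raw = {s: 100.0 * raw_counts.get(s, 0) / total for s in RAW_STATES}
    return {
        "total": total,
        "raw_counts": {s: int(raw_counts.get(s, 0)) for s in RAW_STATES},
        "collapsed_counts": collapsed_counts,
        "raw_percent": pct_raw,
        "pct_specialist": 100.0 * n_spec / total,
        "pct_generalist": 100.0 * (total - n_spec) / total,
        "n_salt_barrier": int(sum(raw_counts.get(s, 0) for s in _SALT_BARRIER)),
    }
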