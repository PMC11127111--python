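"""Synthetic-data generators with known ground truth.

Everything the pipeline consumes can be generated here: birth-death trees
(neutral diversification), Mk trait histories on a fixed tree, trees grown
under state-dependent speciation (with hidden states retained for tests), and
biome-structured occupancy tables mimicking the three-biome sampling design
(27 land / 25 marine / 11 freshwater samples by default).

All simulators are reproducible bit-for-bit given (parameters, seed); tree
growth is a single Gillespie process, while per-branch/per-taxon draws use
child RNG streams derived from (seed, unit index) so results do not depend on
iteration order.

The occupancy generator is a deliberately simple Bernoulli model -- a taxon
is detected with probability p_in in samples of its preferred biome(s) and
p_out elsewhere. p_in/p_out are synthetic constructs (the field data are
observational and come with no generative model); they exist to give the
classifier a known truth to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preference import RAW_TO_SET
from .tables import OccupancyTable
from .trees import PhyloTree, TipStateVector, _Node
from .mk import RateMatrix
from .sse import SSEModel

__all__ = [
    "BDParams",
    "OccupancyScenario",
    "simulate_bd_tree",
    "simulate_mk_history",
    "MkHistory",
    "simulate_sse_tree",
    "simulate_occupancy",
]

RETRY_CAP = 10_000


@dataclass
class BDParams:
    """Constant-rate birth-death process in relative time; stop either at a
    target extant tip count n or at duration T."""

    lam: float
    mu: float = 0.0
    n: int | None = None
    T: float | None = None

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("speciation rate lambda must be > 0 (no branching otherwise)")
        if self.mu < 0:
            raise ValueError("extinction rate mu must be >= 0")
        if (self.n is None) == (self.T is None):
            raise ValueError("specify exactly one stopping rule: n or T")
        if self.n is not None and self.n < 2:
            raise ValueError("target tip count must be >= 2")


# ---------------------------------------------------------------------------
# forward Gillespie engine over combined states


def _forward_simulate(lam, mu, qmat, root_state, stop_n, stop_T, rng):
    """One forward pass. Returns (root node, set of extinct node ids,
    {tip node id: final state}, end time) or None when the process dies out
    (or stalls) before the stopping rule is met."""
    K = len(lam)
    qout = qmat.sum(axis=1) - np.diag(qmat)
    ev_rate = lam + mu + qout

    root = _Node(None, None)
    start = {id(root): 0.0}
    active_nodes = [root]
    states = [root_state]
    extinct = set()
    t = 0.0

    def finish(t_end):
        final = {}
        for node, st in zip(active_nodes, states):
            node.length = t_end - start[id(node)]
            final[id(node)] = st
        return root, extinct, final, t_end

    if stop_n is not None and stop_n == 1:
        raise ValueError("stop_n must be >= 2")

    while True:
        st_arr = np.asarray(states)
        rates = ev_rate[st_arr]
        total = rates.sum()
        if total <= 0:
            # absorbing configuration: nothing can ever happen again
            if stop_T is not None:
                return finish(stop_T)
            return None
        dt = rng.exponential(1.0 / total)
        if stop_T is not None and t + dt > stop_T:
            return finish(stop_T)
        t += dt
        i = rng.choice(len(active_nodes), p=rates / total)
        k = states[i]
        u = rng.random() * ev_rate[k]
        node = active_nodes[i]
        if u < lam[k]:
            # speciation: node closes, two daughters open in the same state
            node.length = t - start[id(node)]
            a, b = _Node(None, None), _Node(None, None)
            a.parent = b.parent = node
            node.children = [a, b]
            start[id(a)] = start[id(b)] = t
            active_nodes[i] = a
            active_nodes.append(b)
            states.append(k)
            if stop_n is not None and len(active_nodes) == stop_n:
                # truncate at a uniform time inside the next holding interval
                # (avoids the push-past bias of stopping exactly at the event)
                st_arr = np.asarray(states)
                total2 = ev_rate[st_arr].sum()
                hold = rng.exponential(1.0 / total2) if total2 > 0 else 1.0
                return finish(t + rng.random() * hold)
        elif u < lam[k] + mu[k]:
            node.length = t - start[id(node)]
            extinct.add(id(node))
            del active_nodes[i]
            del states[i]
            if not active_nodes:
                return None
        else:
            # state change
            probs = qmat[k].copy()
            probs[k] = 0.0
            probs = probs / probs.sum()
            states[i] = int(rng.choice(K, p=probs))


def _reconstruct_extant(root, extinct, final_states):
    """Drop extinct subtrees, splice out unifurcations (lengths summed), and
    re-root at the first split among survivors. Returns (PhyloTree, tip
    states dict keyed by new tip label) with tips labeled t1..tn."""

    def prune(n):
        if not n.children:
            return None if id(n) in extinct else n
        kids = [prune(c) for c in n.children]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            k = kids[0]
            k.length = (k.length or 0.0) + (n.length or 0.0)
            return k
        n.children = kids
        for k in kids:
            k.parent = n
        return n

    new_root = prune(root)
    if new_root is None or not new_root.children:
        return None
    new_root.parent = None
    tip_states = {}
    i = 0
    stack = [new_root]
    while stack:
        n = stack.pop()
        if not n.children:
            i += 1
            n.label = f"t{i}"
            tip_states[n.label] = final_states[id(n)]
        else:
            stack.extend(reversed(n.children))
    if i < 2:
        return None
    return PhyloTree(new_root), tip_states


def simulate_bd_tree(params: BDParams, seed=None) -> PhyloTree:
    """Simulate a birth-death tree of extant tips (extinct lineages pruned),
    conditioned on >= 2 survivors by rejection (retry cap RETRY_CAP)."""
    rng = np.random.default_rng(seed)
    lam = np.array([params.lam])
    mu = np.array([params.mu])
    q = np.zeros((1, 1))
    for _ in range(RETRY_CAP):
        out = _forward_simulate(lam, mu, q, 0, params.n, params.T, rng)
        if out is None:
            continue
        rec = _reconstruct_extant(*out[:3])
        if rec is None:
            continue
        tree, _ = rec
        if params.n is not None and tree.n_tips != params.n:
            continue
        return tree
    raise RuntimeError(
        f"no surviving tree with >= 2 tips after {RETRY_CAP} attempts "
        f"(lambda={params.lam}, mu={params.mu})"
    )


# ---------------------------------------------------------------------------
# Mk trait histories on a fixed tree


@dataclass
class MkHistory:
    """Full simulated character history. Node keys are tip labels for tips
    and 'node_<preorder index>' for internal nodes."""

    tip_states: TipStateVector
    node_states: dict  # node key -> state at the node (rootward end of its edge history)
    events: dict  # node key -> list of (time offset along parent edge, from, to)


def _node_keys(tree: PhyloTree):
    keys = {}
    for i, n in enumerate(tree.iter_preorder()):
        keys[id(n)] = n.label if not n.children else f"node_{i}"
    return keys


def simulate_mk_history(
    tree: PhyloTree,
    Q: RateMatrix,
    root_state: int | None = None,
    root_prior=None,
    seed=None,
) -> MkHistory:
    """Evolve a discrete character along the tree under rate matrix Q by
    sampling exponential waiting times on each branch. Each branch uses an
    RNG stream derived from (seed, branch preorder index)."""
    Qm = Q.matrix
    S = Q.n_states
    out_rates = -np.diag(Qm)
    keys = _node_keys(tree)

    root_rng = np.random.default_rng([0 if seed is None else int(seed), 0])
    if root_state is None:
        prior = np.full(S, 1.0 / S) if root_prior is None else np.asarray(root_prior, float)
        root_state = int(root_rng.choice(S, p=prior / prior.sum()))
    if not (0 <= root_state < S):
        raise ValueError(f"root state {root_state} outside alphabet")

    node_states = {}
    events = {}
    tip_states = {}
    for idx, node in enumerate(tree.iter_preorder()):
        key = keys[id(node)]
        if node.parent is None:
            node_states[key] = root_state
            events[key] = []
        else:
            s = node_states[keys[id(node.parent)]]
            rng = np.random.default_rng([0 if seed is None else int(seed), idx + 1])
            t, ev = 0.0, []
            while True:
                rate = out_rates[s]
                if rate <= 0:
                    break
                dt = rng.exponential(1.0 / rate)
                if t + dt > node.length:
                    break
                t += dt
                probs = Qm[s].copy()
                probs[s] = 0.0
                probs /= probs.sum()
                s2 = int(rng.choice(S, p=probs))
                ev.append((t, s, s2))
                s = s2
            node_states[key] = s
            events[key] = ev
        if not node.children:
            tip_states[node.label] = node_states[key]
    return MkHistory(
        tip_states=TipStateVector(tip_states, list(Q.alphabet)),
        node_states=node_states,
        events=events,
    )


# ---------------------------------------------------------------------------
# state-dependent speciation trees


def simulate_sse_tree(
    model: SSEModel,
    params: np.ndarray,
    stop_n: int | None = None,
    stop_T: float | None = None,
    root_state: int | None = None,
    seed=None,
):
    """Grow a tree forward in time where a lineage in combined state k
    speciates at lambda_k, goes extinct at mu, and moves between combined
    states at the rates of the model's combined transition matrix (dual
    transitions excluded by construction). Extinct lineages are pruned.

    Returns (tree, observed TipStateVector, hidden dict tip->hidden index).
    """
    if (stop_n is None) == (stop_T is None):
        raise ValueError("specify exactly one of stop_n / stop_T")
    lam, mu, Qc = model.unpack(params)
    K, H = model.K, model.H
    qmat = Qc.copy()
    np.fill_diagonal(qmat, 0.0)
    mu_vec = np.full(K, mu)
    rng = np.random.default_rng(seed)
    for _ in range(RETRY_CAP):
        rs = root_state if root_state is not None else int(rng.integers(K))
        out = _forward_simulate(lam, mu_vec, qmat, rs, stop_n, stop_T, rng)
        if out is None:
            continue
        rec = _reconstruct_extant(*out[:3])
        if rec is None:
            continue
        tree, combined = rec
        if stop_n is not None and tree.n_tips != stop_n:
            continue
        alphabet = list(model.Q_obs.alphabet)
        observed = TipStateVector({t: k // H for t, k in combined.items()}, alphabet)
        hidden = {t: k % H for t, k in combined.items()}
        return tree, observed, hidden
    raise RuntimeError(f"total extinction in all {RETRY_CAP} attempts")


# ---------------------------------------------------------------------------
# occupancy tables


#: taxon counts per raw preference observed in the three-biome survey this
#: generator emulates; used as the default mixture over true preferences
_STUDY_MIX = {
    "freshwater specialist": 738,
    "land specialist": 704,
    "marine specialist": 568,
    "freshwater + land generalist": 488,
    "freshwater + marine generalist": 112,
    "full generalist": 6,
    "marine + land generalist": 5,
}


@dataclass
class OccupancyScenario:
    """Biome-structured Bernoulli occupancy. `preferences` may be a list of
    biome frozensets (one per taxon); by default each taxon's true preference
    is drawn from the survey's empirical mixture of the seven classes."""

    n_taxa: int = 500
    samples_per_biome: dict = field(
        default_factory=lambda: {"freshwater": 11, "marine": 25, "land": 27}
    )
    p_in: float = 0.8
    p_out: float = 0.02
    preferences: list | None = None
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.p_out < self.p_in <= 1):
            raise ValueError("need 0 <= p_out < p_in <= 1")
        if any(v < 1 for v in self.samples_per_biome.values()):
            raise ValueError("each biome needs >= 1 sample")
        if self.preferences is not None and len(self.preferences) != self.n_taxa:
            raise ValueError("preferences length must equal n_taxa")


def simulate_occupancy(scenario: OccupancyScenario) -> OccupancyTable:
    """Binary sample x taxon table: presence with probability p_in inside the
    taxon's preferred biome(s), p_out elsewhere; taxa are redrawn until they
    have at least one presence. True preferences are stored on the table."""
    rng_master = np.random.default_rng(scenario.seed)
    biomes = list(scenario.samples_per_biome)
    sample_ids, sample_biome = [], []
    for b in biomes:
        for i in range(scenario.samples_per_biome[b]):
            sample_ids.append(f"{b}_{i + 1:02d}")
            sample_biome.append(b)
    sample_biome = pd.Series(sample_biome, index=sample_ids, name="biome")

    if scenario.preferences is None:
        cats = list(_STUDY_MIX)
        wts = np.array([_STUDY_MIX[c] for c in cats], dtype=float)
        draws = rng_master.choice(len(cats), size=scenario.n_taxa, p=wts / wts.sum())
        prefs = [RAW_TO_SET[cats[d]] for d in draws]
    else:
        prefs = [frozenset(p) for p in scenario.preferences]
        for p in prefs:
            if not p or not p.issubset(set(biomes)):
                raise ValueError(f"invalid preference {set(p)}")

    in_pref = np.array([[b in p for b in sample_biome] for p in prefs], dtype=bool)
    probs = np.where(in_pref, scenario.p_in, scenario.p_out)

    mat = np.zeros((scenario.n_taxa, len(sample_ids)), dtype=np.int64)
    taxa = []
    for j in range(scenario.n_taxa):
        taxon = f"asv{j + 1:04d}"
        taxa.append(taxon)
        rng = np.random.default_rng([scenario.seed, j])
        while True:
            row = (rng.random(len(sample_ids)) < probs[j]).astype(np.int64)
            if row.sum() > 0:
                mat[j] = row
                break
    counts = pd.DataFrame(mat.T, index=sample_ids, columns=taxa)
    return OccupancyTable(
        counts=counts,
        sample_biome=sample_biome,
        true_preference={t: p for t, p in zip(taxa, prefs)},
    )
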