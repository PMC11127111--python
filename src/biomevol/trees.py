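"""Rooted ultrametric phylogenies and the tree utilities used across the analysis.

Trees are stored as flat node arrays (postorder-friendly) with branch lengths
in relative time. The time convention is forward time: the root sits at time 0
and the tips of an ultrametric tree sit at time T (the tree height).

Newick parsing and serialization go through dendropy; everything downstream
(branching times, lineage-through-time curves, subsampling for the bootstrap
robustness schemes) operates on the flat representation.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "TipStateVector",
    "NewickParseError",
    "read_newick",
    "write_newick",
    "branching_times",
    "compute_ltt",
    "subsample_tree",
    "read_tip_states",
    "write_tip_states",
]

#: relative tolerance on tip-depth spread for a tree to count as ultrametric
ULTRAMETRIC_RTOL = 1e-6


class NewickParseError(ValueError):
    pass


class _Node:
    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label=None, length=None):
        self.label = label
        self.length = length
        self.children = []
        self.parent = None


class PhyloTree:
    """A rooted phylogeny with nonnegative branch lengths and unique tip labels.

    Input trees may contain polytomies; likelihood code requires binary trees,
    obtained via :meth:`resolve_polytomies` (deterministic left-to-right
    resolution with zero-length edges).
    """

    def __init__(self, root: _Node):
        self.root = root
        self._validate()
        self._arrays = None

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        return read_newick(text)

    def copy(self) -> "PhyloTree":
        def rec(n):
            m = _Node(n.label, n.length)
            for c in n.children:
                cc = rec(c)
                cc.parent = m
                m.children.append(cc)
            return m

        return PhyloTree(rec(self.root))

    def _validate(self):
        labels = []
        for n in self.iter_postorder():
            if n is not self.root:
                if n.length is None:
                    raise ValueError(
                        f"missing branch length on node {n.label!r}; "
                        "branch lengths are required (no silent default)"
                    )
                if n.length < 0:
                    raise ValueError(f"negative branch length {n.length} on {n.label!r}")
            if not n.children:
                if n.label is None:
                    raise ValueError("unlabeled tip")
                labels.append(n.label)
        if len(labels) != len(set(labels)):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate tip labels: {dup}")
        if self.root.length is None:
            self.root.length = 0.0

    # -- traversal --------------------------------------------------------

    def iter_postorder(self):
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done or not node.children:
                yield node
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))

    def iter_preorder(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for c in reversed(node.children):
                stack.append(c)

    @property
    def tips(self):
        return [n for n in self.iter_postorder() if not n.children]

    @property
    def tip_labels(self):
        return [n.label for n in self.tips]

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def is_binary(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.iter_preorder())

    # -- geometry ---------------------------------------------------------

    def node_depths(self) -> dict:
        """Time of each node measured forward from the root (root = 0)."""
        depths = {id(self.root): 0.0}
        for n in self.iter_preorder():
            if n is self.root:
                continue
            depths[id(n)] = depths[id(n.parent)] + n.length
        return depths

    @property
    def height(self) -> float:
        d = self.node_depths()
        return max(d[id(t)] for t in self.tips)

    def tip_depths(self) -> np.ndarray:
        d = self.node_depths()
        return np.array([d[id(t)] for t in self.tips])

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        td = self.tip_depths()
        h = td.max()
        if h == 0:
            return False
        return (td.max() - td.min()) <= rtol * h

    def assert_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL):
        if not self.is_ultrametric(rtol):
            td = self.tip_depths()
            raise ValueError(
                f"tree is not ultrametric: tip depth spread {td.max() - td.min():.3g} "
                f"exceeds {rtol:g} x height {td.max():.3g}"
            )

    # -- editing ----------------------------------------------------------

    def resolve_polytomies(self) -> "PhyloTree":
        """Return a binary copy, resolving polytomies left-to-right with
        zero-length internal edges. Binary trees are returned unchanged
        (as a copy)."""
        t = self.copy()
        for n in list(t.iter_postorder()):
            while len(n.children) > 2:
                a, b = n.children[0], n.children[1]
                merged = _Node(None, 0.0)
                merged.children = [a, b]
                a.parent = b.parent = merged
                merged.parent = n
                n.children = [merged] + n.children[2:]
        return t

    def rescale_height(self, target: float = 1.0) -> "PhyloTree":
        """Explicitly rescale all branch lengths so the height equals `target`."""
        h = self.height
        if h <= 0:
            raise ValueError("cannot rescale a zero-height tree")
        t = self.copy()
        f = target / h
        for n in t.iter_preorder():
            if n.length is not None:
                n.length *= f
        t._arrays = None
        return t

    def rescale_to_ultrametric(self) -> "PhyloTree":
        """Force exact ultrametricity by stretching each terminal branch so
        every tip reaches the mean tip depth. Never applied automatically."""
        t = self.copy()
        depths = t.node_depths()
        mean_h = float(np.mean([depths[id(x)] for x in t.tips]))
        for tip in t.tips:
            tip.length += mean_h - depths[id(tip)]
            if tip.length < 0:
                raise ValueError("tip-depth averaging produced a negative branch")
        return t

    def keep_tips(self, labels) -> "PhyloTree":
        """Prune to the given tip set; degree-2 internal nodes are removed with
        their branch lengths summed, so retained tip depths are unchanged.
        The root is kept even if it is left with a single child."""
        keep = set(labels)
        missing = keep - set(self.tip_labels)
        if missing:
            raise ValueError(f"tips not in tree: {sorted(missing)}")
        if len(keep) < 2:
            raise ValueError("need at least 2 tips")
        t = self.copy()

        def prune(n):
            if not n.children:
                return n if n.label in keep else None
            kids = [prune(c) for c in n.children]
            kids = [k for k in kids if k is not None]
            if not kids:
                return None
            if len(kids) == 1 and n is not t.root:
                k = kids[0]
                k.length += n.length
                k.parent = n.parent
                return k
            n.children = kids
            for k in kids:
                k.parent = n
            return n

        new_root = prune(t.root)
        return PhyloTree(new_root)

    # -- flat arrays for likelihood kernels -------------------------------

    def flat(self) -> "TreeArrays":
        """Flattened postorder arrays (cached). Requires a binary-or-unary
        topology; resolve polytomies first."""
        if self._arrays is None:
            self._arrays = _flatten(self)
        return self._arrays

    # -- io ---------------------------------------------------------------

    def to_newick(self) -> str:
        return write_newick(self)

    def __repr__(self):
        return f"<PhyloTree {self.n_tips} tips, height {self.height:.4g}>"


@dataclass
class TreeArrays:
    """Postorder-flattened topology. Index 0..n_tips-1 are tips (in
    `tip_labels` order); internal nodes follow in postorder; the root is last."""

    n_tips: int
    tip_labels: list
    postorder: np.ndarray  # internal node indices, postorder (root last)
    left: np.ndarray  # child indices per node, -1 for tips / absent
    right: np.ndarray
    length: np.ndarray  # branch length above each node (root: 0)
    depth: np.ndarray  # time from root


def _flatten(tree: PhyloTree) -> TreeArrays:
    tips = tree.tips
    index = {}
    for i, t in enumerate(tips):
        index[id(t)] = i
    internals = [n for n in tree.iter_postorder() if n.children]
    for j, n in enumerate(internals):
        index[id(n)] = len(tips) + j
    n_nodes = len(tips) + len(internals)
    left = np.full(n_nodes, -1, dtype=np.int64)
    right = np.full(n_nodes, -1, dtype=np.int64)
    length = np.zeros(n_nodes)
    depth = np.zeros(n_nodes)
    depths = tree.node_depths()
    for n in tree.iter_postorder():
        i = index[id(n)]
        length[i] = n.length if n is not tree.root else 0.0
        depth[i] = depths[id(n)]
        if n.children:
            if len(n.children) > 2:
                raise ValueError("polytomy present; resolve_polytomies() first")
            left[i] = index[id(n.children[0])]
            if len(n.children) == 2:
                right[i] = index[id(n.children[1])]
    postorder = np.array([index[id(n)] for n in internals], dtype=np.int64)
    return TreeArrays(
        n_tips=len(tips),
        tip_labels=[t.label for t in tips],
        postorder=postorder,
        left=left,
        right=right,
        length=length,
        depth=depth,
    )


# ---------------------------------------------------------------------------
# tip states


@dataclass
class TipStateVector:
    """Observed discrete state per tip: tip label -> index into `alphabet`."""

    states: dict
    alphabet: list

    def __post_init__(self):
        S = len(self.alphabet)
        for k, v in self.states.items():
            if not (0 <= int(v) < S):
                raise ValueError(f"state index {v} for tip {k!r} outside alphabet of size {S}")

    @property
    def n_states(self) -> int:
        return len(self.alphabet)

    def as_array(self, tip_labels) -> np.ndarray:
        missing = [t for t in tip_labels if t not in self.states]
        if missing:
            raise ValueError(f"tips without a state: {missing[:10]}")
        return np.array([self.states[t] for t in tip_labels], dtype=np.int64)

    def counts(self) -> np.ndarray:
        c = np.zeros(self.n_states, dtype=np.int64)
        for v in self.states.values():
            c[v] += 1
        return c


def read_tip_states(path_or_buf, alphabet=None) -> TipStateVector:
    """Read a 2-column TSV (tip_label, state name). The alphabet defaults to
    the sorted set of observed state names."""
    import pandas as pd

    df = pd.read_csv(path_or_buf, sep="\t", header=None, names=["tip", "state"], dtype=str)
    if alphabet is None:
        alphabet = sorted(df["state"].unique())
    lookup = {s: i for i, s in enumerate(alphabet)}
    unknown = sorted(set(df["state"]) - set(alphabet))
    if unknown:
        raise ValueError(f"states not in alphabet: {unknown}")
    return TipStateVector({r.tip: lookup[r.state] for r in df.itertuples()}, list(alphabet))


def write_tip_states(tsv_path, states: TipStateVector):
    with open(tsv_path, "w") as fh:
        for tip, idx in states.states.items():
            fh.write(f"{tip}\t{states.alphabet[idx]}\n")


# ---------------------------------------------------------------------------
# newick io


def read_newick(text: str) -> PhyloTree:
    """Parse a newick string (branch lengths required)."""
    try:
        dt = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as e:  # dendropy raises several error classes with position info
        raise NewickParseError(f"malformed newick: {e}") from None

    def convert(dn):
        label = None
        if dn.taxon is not None:
            label = dn.taxon.label
        elif dn.label:
            label = dn.label
        n = _Node(label, dn.edge.length)
        for c in dn.child_nodes():
            cc = convert(c)
            cc.parent = n
            n.children.append(cc)
        return n

    root = convert(dt.seed_node)
    if root.length is None:
        root.length = 0.0
    if not root.children:
        raise NewickParseError("newick describes a single node, not a tree")
    return PhyloTree(root)


def write_newick(tree: PhyloTree, precision: int = 12) -> str:
    def rec(n):
        if not n.children:
            return f"{n.label}:{n.length:.{precision}g}"
        inner = ",".join(rec(c) for c in n.children)
        if n is tree.root:
            return f"({inner}):{n.length:.{precision}g}"
        return f"({inner}):{n.length:.{precision}g}"

    return rec(tree.root) + ";"


# ---------------------------------------------------------------------------
# branching times / LTT


def branching_times(tree: PhyloTree) -> np.ndarray:
    """Times of internal nodes measured forward from the root, ascending.

    For a binary n-tip tree this has n-1 entries, the first being 0 (the
    root split). Requires an ultrametric tree.
    """
    tree.assert_ultrametric()
    depths = tree.node_depths()
    times = sorted(depths[id(n)] for n in tree.iter_preorder() if n.children)
    return np.asarray(times)


def compute_ltt(tree: PhyloTree):
    """Lineage-through-time step function for an ultrametric tree.

    Returns (times, counts): times of branching events from the root
    (ascending) and the number of reconstructed lineages immediately after
    each event. Starts at (0, 1 + number of root children); ends with the
    tip count reached at the tree height.
    """
    tree.assert_ultrametric()
    depths = tree.node_depths()
    events = sorted(
        (depths[id(n)], len(n.children) - 1) for n in tree.iter_preorder() if n.children
    )
    times = np.array([e[0] for e in events])
    counts = 1 + np.cumsum([e[1] for e in events])
    return times, counts


# ---------------------------------------------------------------------------
# subsampling (bootstrap robustness schemes)


def subsample_tree(
    tree: PhyloTree,
    mode: str,
    arg,
    states: TipStateVector | None = None,
    seed=None,
) -> PhyloTree:
    """Subsample tips and prune.

    mode="fraction": keep floor(arg * n_tips) tips drawn uniformly at random
    (arg in (0, 1]; arg == 1 returns a copy of the full tree).
    mode="equal_per_state": keep `arg` tips drawn uniformly within each state;
    `arg` must not exceed the smallest state class.
    """
    rng = np.random.default_rng(seed)
    labels = tree.tip_labels
    if mode == "fraction":
        frac = float(arg)
        if not (0 < frac <= 1):
            raise ValueError(f"fraction must be in (0, 1], got {frac}")
        k = int(np.floor(frac * len(labels)))
        if frac == 1.0:
            return tree.copy()
        if k < 2:
            raise ValueError("fraction leaves fewer than 2 tips")
        keep = rng.choice(len(labels), size=k, replace=False)
        return tree.keep_tips([labels[i] for i in sorted(keep)])
    elif mode == "equal_per_state":
        if states is None:
            raise ValueError("equal_per_state requires tip states")
        target = int(arg)
        by_state = {}
        for lab in labels:
            by_state.setdefault(states.states[lab], []).append(lab)
        smallest = min(len(v) for v in by_state.values())
        if target > smallest:
            raise ValueError(
                f"target {target} exceeds smallest state class ({smallest} tips)"
            )
        keep = []
        for s in sorted(by_state):
            members = by_state[s]
            idx = rng.choice(len(members), size=target, replace=False)
            keep.extend(members[i] for i in sorted(idx))
        return tree.keep_tips(keep)
    raise ValueError(f"unknown subsample mode {mode!r}")
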