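"""Multistate Mk models of discrete-character evolution on ultrametric trees.

Implements the likelihood (Felsenstein pruning with P(t) = exp(Qt)), ML
fitting under rate-constraint patterns (ER, SYM, ARD, the stepwise model that
routes biome-preference change through generalist intermediates, and custom
masks), iterative ARD simplification driven by AIC, Akaike weights,
source-sink summaries of a fitted rate matrix, and two bootstrap schemes for
rate uncertainty (80% tree subsampling and equal tips per state).

Numerics: P(t) is computed from one eigendecomposition of Q per likelihood
evaluation, vectorized across branches, with a scaling-and-squaring Pade
fallback whenever the eigenbasis is ill-conditioned (fitted Q matrices are
generically diagonalizable, but sparse masks can produce defective corners).
The pruning recursion runs in a compiled kernel with per-node rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy.linalg import expm
from scipy.optimize import minimize

from .trees import PhyloTree, TipStateVector

__all__ = [
    "RateMatrix",
    "ConstraintPattern",
    "MkModel",
    "make_model",
    "mk_loglik",
    "fit_mk",
    "simplify_ard",
    "aic_weights",
    "akaike_weights",
    "source_sink_ratios",
    "bootstrap_rates",
]

RATE_BOUNDS = (1e-9, 1e3)


@dataclass
class RateMatrix:
    """S x S transition-rate matrix: off-diagonal rates >= 0, rows sum to 0."""

    matrix: np.ndarray
    alphabet: list

    def __post_init__(self):
        Q = np.asarray(self.matrix, dtype=float)
        S = len(self.alphabet)
        if Q.shape != (S, S):
            raise ValueError(f"rate matrix shape {Q.shape} != ({S}, {S})")
        off = Q.copy()
        np.fill_diagonal(off, 0.0)
        if (off < 0).any():
            bad = list(zip(*np.where(off < 0)))
            raise ValueError(f"negative off-diagonal rates at {bad}")
        if np.abs(Q.sum(axis=1)).max() > 1e-10:
            raise ValueError("rows of Q must sum to 0")
        self.matrix = Q

    @classmethod
    def from_rates(cls, off_diag: np.ndarray, alphabet) -> "RateMatrix":
        """Build from off-diagonal rates (diagonal entries are ignored and
        refilled so rows sum to zero)."""
        Q = np.asarray(off_diag, dtype=float).copy()
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return cls(Q, list(alphabet))

    @property
    def n_states(self) -> int:
        return len(self.alphabet)

    def stationary(self) -> np.ndarray:
        Q = self.matrix
        A = np.vstack([Q.T, np.ones(self.n_states)])
        b = np.zeros(self.n_states + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(A, b, rcond=None)
        return np.clip(pi, 0, None) / np.clip(pi, 0, None).sum()

    def to_tsv(self, path):
        pd.DataFrame(self.matrix, index=self.alphabet, columns=self.alphabet).to_csv(
            path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, path) -> "RateMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.values.astype(float), list(df.columns))


# ---------------------------------------------------------------------------
# constraint patterns


@dataclass
class ConstraintPattern:
    """Integer matrix over off-diagonal cells: 0 = transition fixed to zero,
    k >= 1 = cell belongs to free rate class k. Classes may be shared across
    cells (tied rates, as in SYM/ER)."""

    classes: np.ndarray
    kind: str = "custom"

    def __post_init__(self):
        M = np.asarray(self.classes, dtype=np.int64).copy()
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError("pattern must be square")
        np.fill_diagonal(M, 0)
        if (M < 0).any():
            raise ValueError("pattern entries must be nonnegative integers")
        present = np.unique(M[M > 0])
        if len(present) and not np.array_equal(present, np.arange(1, len(present) + 1)):
            # renumber to consecutive class ids, preserving order
            remap = {old: i + 1 for i, old in enumerate(present)}
            M = np.vectorize(lambda x: remap.get(x, 0))(M)
        self.classes = M

    @property
    def n_states(self) -> int:
        return self.classes.shape[0]

    @property
    def n_free(self) -> int:
        return int(self.classes.max())

    def build_q(self, rates: np.ndarray, alphabet=None) -> RateMatrix:
        rates = np.asarray(rates, dtype=float)
        if rates.shape != (self.n_free,):
            raise ValueError(f"expected {self.n_free} rates, got {rates.shape}")
        off = np.zeros_like(self.classes, dtype=float)
        mask = self.classes > 0
        off[mask] = rates[self.classes[mask] - 1]
        if alphabet is None:
            alphabet = [f"s{i}" for i in range(self.n_states)]
        return RateMatrix.from_rates(off, alphabet)

    def drop_class(self, class_id: int) -> "ConstraintPattern":
        M = self.classes.copy()
        M[M == class_id] = 0
        return ConstraintPattern(M, kind=f"{self.kind}-simplified")

    def class_cells(self, class_id: int):
        return list(zip(*np.where(self.classes == class_id)))


#: 5-state analysis alphabet index convention used by the stepwise pattern
SW_ALPHABET = (
    "freshwater specialist",
    "marine specialist",
    "land specialist",
    "freshwater + land generalist",
    "marine generalist",
)


def make_model(kind: str, S: int, mask: np.ndarray | None = None) -> ConstraintPattern:
    """Standard rate-constraint patterns.

    ER: one shared rate. SYM: one rate per unordered pair. ARD: one rate per
    ordered pair. SW: ARD restricted to the stepping-stone adjacency of the
    5-state biome-preference alphabet (no direct specialist<->specialist
    moves; marine specialist <-> freshwater+land generalist disallowed).
    """
    kind = kind.upper()
    M = np.zeros((S, S), dtype=np.int64)
    if kind == "ER":
        M[:] = 1
    elif kind == "SYM":
        c = 0
        for i in range(S):
            for j in range(i + 1, S):
                c += 1
                M[i, j] = M[j, i] = c
    elif kind == "ARD":
        c = 0
        for i in range(S):
            for j in range(S):
                if i != j:
                    c += 1
                    M[i, j] = c
    elif kind == "SW":
        if S != 5:
            raise ValueError("the stepwise model is defined for the 5-state alphabet")
        # indices follow SW_ALPHABET; 0..2 specialists, 3 fw+land gen, 4 marine gen
        forbidden = {(0, 1), (0, 2), (1, 2), (1, 3)}
        forbidden |= {(j, i) for i, j in forbidden}
        c = 0
        for i in range(S):
            for j in range(S):
                if i != j and (i, j) not in forbidden:
                    c += 1
                    M[i, j] = c
    elif kind == "CUSTOM":
        if mask is None:
            raise ValueError("custom pattern needs a mask")
        return ConstraintPattern(np.asarray(mask), kind="custom")
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    np.fill_diagonal(M, 0)
    return ConstraintPattern(M, kind=kind)


# ---------------------------------------------------------------------------
# likelihood


@njit(cache=True)
def _prune_kernel(post, left, right, P, tipstate, n_tips, prior):
    n_nodes = left.shape[0]
    S = P.shape[1]
    L = np.zeros((n_nodes, S))
    for i in range(n_tips):
        L[i, tipstate[i]] = 1.0
    logscale = 0.0
    for idx in range(post.shape[0]):
        node = post[idx]
        l = left[node]
        r = right[node]
        v = np.empty(S)
        for a in range(S):
            acc = 0.0
            for b in range(S):
                acc += P[l, a, b] * L[l, b]
            v[a] = acc
        if r >= 0:
            for a in range(S):
                acc = 0.0
                for b in range(S):
                    acc += P[r, a, b] * L[r, b]
                v[a] *= acc
        s = v.sum()
        if not np.isfinite(s) or s <= 0.0:
            return -np.inf
        for j in range(S):
            L[node, j] = v[j] / s
        logscale += np.log(s)
    root = post[-1]
    tot = 0.0
    for j in range(S):
        tot += prior[j] * L[root, j]
    if tot <= 0.0:
        return -np.inf
    return np.log(tot) + logscale


def _transition_matrices(Q: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """P(t) = exp(Q t) for every branch length, via eigendecomposition with a
    Pade fallback for ill-conditioned eigenbases."""
    S = Q.shape[0]
    try:
        w, V = np.linalg.eig(Q)
        cond = np.linalg.cond(V)
    except np.linalg.LinAlgError:
        cond = np.inf
    if np.isfinite(cond) and cond < 1e8:
        Vinv = np.linalg.inv(V)
        E = np.exp(np.multiply.outer(lengths, w))  # (n, S)
        P = np.ascontiguousarray((V @ (E[:, :, None] * Vinv[None, :, :])).real)
    else:
        P = np.empty((len(lengths), S, S))
        uniq, inv = np.unique(lengths, return_inverse=True)
        mats = np.array([expm(Q * t) for t in uniq])
        P = mats[inv]
    np.clip(P, 0.0, None, out=P)
    if np.isnan(P).any():
        raise FloatingPointError("NaN in exp(Qt); offending branch lengths: "
                                 f"{lengths[np.isnan(P).any(axis=(1, 2))][:5]}")
    return P


def _root_prior_vector(root_prior, Q: RateMatrix) -> np.ndarray:
    S = Q.n_states
    if isinstance(root_prior, str):
        if root_prior == "uniform":
            return np.full(S, 1.0 / S)
        if root_prior == "stationary":
            return Q.stationary()
        raise ValueError(f"unknown root prior {root_prior!r}")
    v = np.asarray(root_prior, dtype=float)
    if v.shape != (S,) or v.min() < 0 or abs(v.sum() - 1) > 1e-8:
        raise ValueError("custom root prior must be a length-S probability vector")
    return v


def _prep(tree: PhyloTree, states: TipStateVector):
    if tree.n_tips < 2:
        raise ValueError("likelihoods need >= 2 tips")
    tree.assert_ultrametric()
    if not tree.is_binary():
        tree = tree.resolve_polytomies()
    flat = tree.flat()
    tipstate = states.as_array(flat.tip_labels)
    return flat, tipstate


def mk_loglik(
    tree: PhyloTree,
    states: TipStateVector,
    Q: RateMatrix,
    root_prior="uniform",
) -> float:
    flat, tipstate = _prep(tree, states)
    P = _transition_matrices(Q.matrix, flat.length)
    prior = _root_prior_vector(root_prior, Q)
    return float(
        _prune_kernel(flat.postorder, flat.left, flat.right, P, tipstate, flat.n_tips, prior)
    )


# ---------------------------------------------------------------------------
# fitting


@dataclass
class MkModel:
    pattern: ConstraintPattern
    rates: np.ndarray
    Q: RateMatrix
    logL: float
    root_prior: str = "uniform"
    converged: bool = True
    name: str = ""

    @property
    def k(self) -> int:
        return self.pattern.n_free

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.logL


def _parsimony_changes(flat, tipstate) -> int:
    """Fitch parsimony score (minimum number of state changes)."""
    n_nodes = flat.left.shape[0]
    sets = [set() for _ in range(n_nodes)]
    for i in range(flat.n_tips):
        sets[i] = {int(tipstate[i])}
    changes = 0
    for node in flat.postorder:
        l, r = flat.left[node], flat.right[node]
        if r < 0:
            sets[node] = sets[l]
            continue
        inter = sets[l] & sets[r]
        if inter:
            sets[node] = inter
        else:
            sets[node] = sets[l] | sets[r]
            changes += 1
    return changes


def fit_mk(
    tree: PhyloTree,
    states: TipStateVector,
    pattern: ConstraintPattern,
    root_prior: str = "uniform",
    n_starts: int = 5,
    seed: int = 0,
    warm_start: np.ndarray | None = None,
    gtol: float = 1e-6,
) -> MkModel:
    """ML fit of the free rate classes (log-rate parameterization, bounds
    RATE_BOUNDS, multi-start: one parsimony-informed start plus seeded random
    perturbations; optional warm start is tried first)."""
    if pattern.n_free == 0:
        raise ValueError("pattern has no free rates")
    flat, tipstate = _prep(tree, states)
    observed = np.bincount(tipstate, minlength=states.n_states)
    if (observed == 0).any():
        import warnings

        warnings.warn(
            f"states never observed at tips: "
            f"{[states.alphabet[i] for i in np.where(observed == 0)[0]]}; kept in alphabet"
        )

    alphabet = states.alphabet
    m = pattern.n_free
    lo, hi = np.log(RATE_BOUNDS[0]), np.log(RATE_BOUNDS[1])

    prior_cache = {}

    def neg_loglik(log_rates):
        Q = pattern.build_q(np.exp(log_rates), alphabet)
        try:
            P = _transition_matrices(Q.matrix, flat.length)
        except FloatingPointError:
            return 1e10
        key = root_prior if isinstance(root_prior, str) else "custom"
        if key == "stationary" or key not in prior_cache:
            prior_cache[key] = _root_prior_vector(root_prior, Q)
        ll = _prune_kernel(
            flat.postorder, flat.left, flat.right, P, tipstate, flat.n_tips, prior_cache[key]
        )
        if not np.isfinite(ll):
            return 1e10
        return -ll

    total_len = flat.length.sum()
    q0 = max(_parsimony_changes(flat, tipstate), 1) / max(total_len, 1e-12)
    q0 = float(np.clip(q0, RATE_BOUNDS[0] * 10, RATE_BOUNDS[1] / 10))
    rng = np.random.default_rng(seed)
    starts = []
    if warm_start is not None:
        starts.append(np.log(np.clip(warm_start, RATE_BOUNDS[0], RATE_BOUNDS[1])))
    starts.append(np.full(m, np.log(q0)))
    while len(starts) < n_starts + (warm_start is not None):
        starts.append(np.log(q0) + rng.uniform(-2.3, 2.3, size=m))

    best = None
    for x0 in starts:
        res = minimize(
            neg_loglik,
            np.clip(x0, lo, hi),
            method="L-BFGS-B",
            bounds=[(lo, hi)] * m,
            options={"maxiter": 500, "ftol": 1e-10, "gtol": gtol},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or best.fun >= 1e10:
        raise RuntimeError(f"Mk optimization failed from all starts: {best}")
    rates = np.exp(best.x)
    Q = pattern.build_q(rates, alphabet)
    return MkModel(
        pattern=pattern,
        rates=rates,
        Q=Q,
        logL=-float(best.fun),
        root_prior=root_prior if isinstance(root_prior, str) else "custom",
        converged=bool(best.success),
        name=pattern.kind,
    )


# ---------------------------------------------------------------------------
# model simplification and comparison


def _smallest_class(model: MkModel):
    """Free class with the smallest fitted rate; ties broken by the earliest
    (from-state, to-state) cell in row-major order."""
    order = []
    for cid in range(1, model.pattern.n_free + 1):
        cells = model.pattern.class_cells(cid)
        order.append((model.rates[cid - 1], min(cells), cid))
    order.sort()
    return order[0][2]


def simplify_ard(
    tree: PhyloTree,
    states: TipStateVector,
    start: MkModel,
    prune_threshold: float = 1e-3,
    root_prior: str = "uniform",
    seed: int = 0,
    n_starts: int = 1,
):
    """Iterative simplification of a fitted ARD-like model.

    Step 0 zeroes every fitted rate below `prune_threshold` at once and
    refits; each later step zeroes the single smallest remaining rate and
    refits; the loop stops as soon as AIC strictly increases (equal AIC keeps
    the simpler model and continues). Returns (best model by AIC, model table).
    """
    visited = [start]
    current = start

    small = [c + 1 for c in range(start.pattern.n_free) if start.rates[c] < prune_threshold]
    if small:
        patt = current.pattern
        rates = current.rates
        keep = [c for c in range(1, patt.n_free + 1) if c not in small]
        M = patt.classes.copy()
        for c in small:
            M[M == c] = 0
        patt2 = ConstraintPattern(M, kind=f"{patt.kind}-pruned")
        warm = np.array([rates[c - 1] for c in keep])
        current = fit_mk(
            tree, states, patt2, root_prior=root_prior, n_starts=n_starts, seed=seed,
            warm_start=warm,
        )
        current.name = f"{patt.kind}-{patt2.n_free}rates"
        visited.append(current)

    step = 0
    while current.pattern.n_free > 1:
        step += 1
        drop = _smallest_class(current)
        patt2 = current.pattern.drop_class(drop)
        warm = np.array(
            [current.rates[c - 1] for c in range(1, current.pattern.n_free + 1) if c != drop]
        )
        cand = fit_mk(
            tree, states, patt2, root_prior=root_prior, n_starts=n_starts,
            seed=seed + step, warm_start=warm,
        )
        cand.name = f"{start.pattern.kind}-{patt2.n_free}rates"
        visited.append(cand)
        if cand.aic > current.aic + 1e-6:
            break
        current = cand

    best = min(visited, key=lambda m: m.aic)
    table = model_table(visited)
    return best, table


def akaike_weights(aic_values) -> np.ndarray:
    a = np.asarray(aic_values, dtype=float)
    d = a - a.min()
    w = np.exp(-d / 2.0)
    return w / w.sum()


def aic_weights(models):
    """AIC, delta-AIC and Akaike weights from (k, logL) pairs."""
    ks = np.array([m[0] for m in models], dtype=float)
    lls = np.array([m[1] for m in models], dtype=float)
    aic = 2.0 * ks - 2.0 * lls
    return aic, aic - aic.min(), akaike_weights(aic)


def model_table(models: list) -> pd.DataFrame:
    aic = np.array([m.aic for m in models])
    w = akaike_weights(aic)
    return pd.DataFrame(
        {
            "model": [m.name or m.pattern.kind for m in models],
            "k": [m.k for m in models],
            "logL": [m.logL for m in models],
            "AIC": aic,
            "AIC_weight": w,
        }
    ).sort_values("AIC", ignore_index=True)


def source_sink_ratios(Q: RateMatrix) -> pd.DataFrame:
    """Per-state totals of rates away from and into the state, and the
    away/into ratio (>1 marks an evolutionary source; into = 0 gives inf)."""
    M = Q.matrix.copy()
    np.fill_diagonal(M, 0.0)
    away = M.sum(axis=1)
    into = M.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(into > 0, away / np.where(into > 0, into, 1.0), np.inf)
    return pd.DataFrame({"away": away, "into": into, "ratio": ratio}, index=Q.alphabet)


# ---------------------------------------------------------------------------
# bootstrap uncertainty


def bootstrap_rates(
    tree: PhyloTree,
    states: TipStateVector,
    pattern: ConstraintPattern,
    mode: str = "tree80",
    n_iter: int = 1000,
    fraction: float = 0.8,
    seed: int = 0,
    root_prior: str = "uniform",
    fitted: MkModel | None = None,
):
    """Refit `pattern` on subsampled trees and report percentile 95% CIs for
    each free rate and each state's source-sink ratio.

    mode="tree80": drop to `fraction` of the tips uniformly at random.
    mode="equal_n": subsample to the same number of tips per state (the size
    of the smallest state class).
    """
    from .trees import subsample_tree

    if mode not in ("tree80", "equal_n"):
        raise ValueError(f"unknown bootstrap mode {mode!r}")
    if fitted is None:
        fitted = fit_mk(tree, states, pattern, root_prior=root_prior, seed=seed)
    target = None
    if mode == "equal_n":
        counts = states.counts()
        counts = counts[counts > 0]
        target = int(counts.min())

    rate_draws, ratio_draws = [], []
    failures = 0
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_iter)
    for it in range(n_iter):
        child = children[it]
        try:
            if mode == "tree80":
                sub = subsample_tree(tree, "fraction", fraction, seed=child)
            else:
                sub = subsample_tree(tree, "equal_per_state", target, states=states, seed=child)
            sub_states = TipStateVector(
                {t: states.states[t] for t in sub.tip_labels}, states.alphabet
            )
            m = fit_mk(
                sub, sub_states, pattern, root_prior=root_prior, n_starts=1,
                seed=int(child.generate_state(1)[0] % 2**31), warm_start=fitted.rates,
            )
            rate_draws.append(m.rates)
            ratio_draws.append(source_sink_ratios(m.Q)["ratio"].values)
        except Exception:
            failures += 1
    if failures > 0.1 * n_iter:
        raise RuntimeError(f"{failures}/{n_iter} bootstrap iterations failed")
    R = np.array(rate_draws)
    G = np.array(ratio_draws)
    rates = pd.DataFrame(
        {
            "mean": R.mean(axis=0),
            "ci_lo": np.quantile(R, 0.025, axis=0),
            "ci_hi": np.quantile(R, 0.975, axis=0),
        },
        index=[f"class_{c}" for c in range(1, pattern.n_free + 1)],
    )
    with np.errstate(invalid="ignore"):
        ratios = pd.DataFrame(
            {
                "mean": np.nanmean(np.where(np.isfinite(G), G, np.nan), axis=0),
                "ci_lo": np.nanquantile(np.where(np.isfinite(G), G, np.nan), 0.025, axis=0),
                "ci_hi": np.nanquantile(np.where(np.isfinite(G), G, np.nan), 0.975, axis=0),
            },
            index=states.alphabet,
        )
    return {"rates": rates, "ratios": ratios, "n_failed": failures, "full_fit": fitted}
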