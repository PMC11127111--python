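"""Community composition: distances, ordination, group tests, clustering.

Samples are clustered into biomes from community data alone: weighted UniFrac
distances between samples (phylogeny-aware, abundance-weighted), classical
PCoA restricted to positive eigenvalues, PERMANOVA for group effects (global
and pairwise with Benjamini-Hochberg FDR), and k-medoid (PAM) clustering with
the gap statistic and Tibshirani's 1-SE rule to choose the number of clusters.

UniFrac is delegated to scikit-bio; PERMANOVA is computed in-package (the
partition is needed with R^2 and a seeded permutation stream) and PAM/gap are
implemented here. The PAM BUILD initialization is deterministic, so
clustering results depend on a seed only through the gap-statistic reference
draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from .tables import OccupancyTable
from .trees import PhyloTree

__all__ = [
    "weighted_unifrac",
    "pcoa",
    "PCoAResult",
    "permanova",
    "pairwise_permanova",
    "pam",
    "kmedoid_gap",
    "ClusteringResult",
]


# ---------------------------------------------------------------------------
# distances


def weighted_unifrac(
    table: OccupancyTable, tree: PhyloTree, normalized: bool = True
) -> DistanceMatrix:
    """Weighted UniFrac distances between samples.

    Abundances are converted to per-sample relative abundances first; each
    branch then carries the absolute difference in the relative-abundance
    mass of the taxa descending from it, weighted by its length. The
    normalized variant (default) divides by the abundance-weighted total
    branch length and is bounded in [0, 1]; the raw variant is the plain
    weighted sum. (Computed in-package on per-sample relative abundances;
    external counts-based implementations serve as cross-checks on integer
    tables.)
    """
    taxa = table.taxa
    tree_tips = set(tree.tip_labels)
    missing = sorted(set(taxa) - tree_tips)
    if missing:
        raise ValueError(f"table taxa missing from tree: {missing[:20]}")
    rel = table.relative_abundance()
    samples = list(rel.index)
    n = len(samples)

    # postorder accumulation of per-branch abundance mass for all samples
    nodes = list(tree.iter_postorder())
    mass = {}
    lengths = []
    masses = []
    for node in nodes:
        if not node.children:
            m = rel[node.label].to_numpy() if node.label in rel.columns else np.zeros(n)
        else:
            m = np.zeros(n)
            for c in node.children:
                m = m + mass[id(c)]
        mass[id(node)] = m
        if node is not tree.root:
            lengths.append(node.length)
            masses.append(m)
    L = np.asarray(lengths)  # (branches,)
    M = np.asarray(masses)  # (branches, samples)

    raw = np.einsum("b,bij->ij", L, np.abs(M[:, :, None] - M[:, None, :]))
    if normalized:
        w = L @ M  # abundance-weighted branch length per sample
        denom = w[:, None] + w[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(denom > 0, raw / np.where(denom > 0, denom, 1.0), 0.0)
    else:
        out = raw
    np.fill_diagonal(out, 0.0)
    out = (out + out.T) / 2.0
    return DistanceMatrix(out, ids=samples)


def distance_to_tsv(dm: DistanceMatrix, path):
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(path, sep="\t")


def distance_from_tsv(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.values, ids=list(df.columns))


# ---------------------------------------------------------------------------
# principal coordinates


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame  # samples x retained axes
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    n_dropped: int  # axes with eigenvalue <= 0 discarded
    proportion_explained: np.ndarray


def pcoa(dm: DistanceMatrix) -> PCoAResult:
    """Classical scaling of a distance matrix, keeping only axes with
    strictly positive eigenvalues (negative axes arise for non-Euclidean
    distances and are discarded, their count reported)."""
    D = np.asarray(dm.data, dtype=float)
    n = D.shape[0]
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    B = (B + B.T) / 2.0
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    tol = max(np.abs(w).max(), 1.0) * 1e-12
    pos = w > tol
    if not pos.any():
        raise ValueError("degenerate input: no positive eigenvalues")
    wp = w[pos]
    coords = V[:, pos] * np.sqrt(wp)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return PCoAResult(
        coordinates=pd.DataFrame(coords, index=list(dm.ids), columns=cols),
        eigenvalues=wp,
        n_dropped=int((~pos).sum()),
        proportion_explained=wp / wp.sum(),
    )


# ---------------------------------------------------------------------------
# PERMANOVA


def _ss_partition(d2: np.ndarray, codes: np.ndarray, n_groups: int):
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.where(codes == g)[0]
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss_total, ss_within


def permanova(dm: DistanceMatrix, groups, n_perm: int = 9999, seed=None):
    """Permutational multivariate ANOVA on a distance matrix.

    Returns a dict with pseudo-F, R^2 = SS_between / SS_total, and the
    permutation p-value (1 + exceedances) / (1 + n_perm).
    """
    groups = pd.Series(np.asarray(groups), index=list(dm.ids))
    levels = sorted(groups.unique())
    a = len(levels)
    n = len(groups)
    if a < 2:
        raise ValueError("need >= 2 groups")
    counts = groups.value_counts()
    if counts.max() == n:
        raise ValueError("a group equals the whole sample set")
    codes = groups.map({g: i for i, g in enumerate(levels)}).to_numpy()
    d2 = np.asarray(dm.data, dtype=float) ** 2

    ss_total, ss_within = _ss_partition(d2, codes, a)
    ss_between = ss_total - ss_within
    df_b, df_w = a - 1, n - a
    f_obs = (ss_between / df_b) / (ss_within / df_w) if ss_within > 0 else np.inf

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        sst, ssw = _ss_partition(d2, perm, a)
        f_p = ((sst - ssw) / df_b) / (ssw / df_w) if ssw > 0 else np.inf
        if f_p >= f_obs:
            exceed += 1
    return {
        "pseudo_F": float(f_obs),
        "R2": float(ss_between / ss_total),
        "p": (1 + exceed) / (1 + n_perm),
        "n_perm": n_perm,
        "df": (df_b, df_w),
    }


def pairwise_permanova(dm: DistanceMatrix, groups, n_perm: int = 9999, seed=None) -> pd.DataFrame:
    """PERMANOVA on every pair of groups, with Benjamini-Hochberg adjustment
    of p-values across pairs."""
    groups = pd.Series(np.asarray(groups), index=list(dm.ids))
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(levels) * (len(levels) - 1) // 2)
    rows = []
    ci = 0
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            ids = list(groups.index[groups.isin([levels[i], levels[j]])])
            sub = dm.filter(ids)
            res = permanova(sub, groups.loc[ids], n_perm=n_perm, seed=children[ci])
            ci += 1
            rows.append(
                {
                    "group_a": levels[i],
                    "group_b": levels[j],
                    "pseudo_F": res["pseudo_F"],
                    "R2": res["R2"],
                    "p": res["p"],
                }
            )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# PAM + gap statistic


def _pam_assign(D, medoids):
    return np.asarray(medoids)[np.argmin(D[:, medoids], axis=1)]


def _pam_cost(D, medoids):
    return D[:, medoids].min(axis=1).sum()


def pam(D: np.ndarray, k: int):
    """Partitioning Around Medoids with the classic deterministic BUILD
    initialization followed by greedy SWAP; the objective (sum of distances
    to the nearest medoid) never increases. Medoids always belong to their
    own cluster, so clusters cannot empty."""
    n = D.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k={k} outside [1, {n}]")
    medoids = [int(np.argmin(D.sum(axis=0)))]
    while len(medoids) < k:
        cur = D[:, medoids].min(axis=1)
        gains = np.array(
            [np.maximum(cur - D[:, j], 0).sum() if j not in medoids else -1.0 for j in range(n)]
        )
        medoids.append(int(np.argmax(gains)))
    # SWAP
    improved = True
    while improved:
        improved = False
        cost = _pam_cost(D, medoids)
        best = (0.0, None)
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = h
                delta = _pam_cost(D, trial) - cost
                if delta < best[0] - 1e-12:
                    best = (delta, (mi, h))
        if best[1] is not None:
            mi, h = best[1]
            medoids[mi] = h
            improved = True
    medoids = sorted(medoids)
    return medoids, _pam_assign(D, medoids)


def _pooled_dispersion(d2: np.ndarray, assign: np.ndarray) -> float:
    """Tibshirani's W: sum over clusters of (within-cluster sum of pairwise
    squared distances) / (2 n_r)."""
    W = 0.0
    for g in np.unique(assign):
        idx = np.where(assign == g)[0]
        W += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return W


@dataclass
class ClusteringResult:
    k: int
    medoids: list
    assignments: np.ndarray
    gap_curve: pd.DataFrame  # columns: k, gap, s_k, logW


def kmedoid_gap(X: np.ndarray, k_range, B: int = 100, seed=None) -> ClusteringResult:
    """PAM clustering with the gap statistic over `k_range`.

    Gap(k) compares log W_k with its expectation under B uniform reference
    draws over the per-axis bounding box of X; the chosen k is the smallest k
    with Gap(k) >= Gap(k+1) - s_{k+1} (the 1-SE rule).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    k_range = sorted(set(int(k) for k in k_range))
    if k_range[0] < 1 or k_range[-1] > n - 1:
        raise ValueError(f"k_range must lie within [1, {n - 1}]")
    if B < 10:
        raise ValueError("need B >= 10 reference draws")
    rng = np.random.default_rng(seed)

    def disp_for(data):
        diff = data[:, None, :] - data[None, :, :]
        d2 = (diff**2).sum(axis=2)
        D = np.sqrt(d2)
        out = {}
        for k in k_range:
            if k == 1:
                out[k] = _pooled_dispersion(d2, np.zeros(len(data), dtype=int))
            else:
                _, assign = pam(D, k)
                out[k] = _pooled_dispersion(d2, assign)
        return out

    logW = {k: np.log(v) for k, v in disp_for(X).items()}
    lo, hi = X.min(axis=0), X.max(axis=0)
    ref_logW = {k: [] for k in k_range}
    for _ in range(B):
        ref = rng.uniform(lo, hi, size=X.shape)
        for k, v in disp_for(ref).items():
            ref_logW[k].append(np.log(v))
    gap, s_k = {}, {}
    for k in k_range:
        arr = np.asarray(ref_logW[k])
        gap[k] = arr.mean() - logW[k]
        s_k[k] = arr.std(ddof=0) * np.sqrt(1.0 + 1.0 / B)

    chosen = k_range[-1]
    for i, k in enumerate(k_range[:-1]):
        k2 = k_range[i + 1]
        if gap[k] >= gap[k2] - s_k[k2]:
            chosen = k
            break

    diff = X[:, None, :] - X[None, :, :]
    D = np.sqrt((diff**2).sum(axis=2))
    if chosen == 1:
        medoids = [int(np.argmin(D.sum(axis=0)))]
        assign = np.full(n, medoids[0])
    else:
        medoids, assign = pam(D, chosen)
    curve = pd.DataFrame(
        {
            "k": k_range,
            "gap": [gap[k] for k in k_range],
            "s_k": [s_k[k] for k in k_range],
            "logW": [logW[k] for k in k_range],
        }
    )
    return ClusteringResult(k=chosen, medoids=medoids, assignments=assign, gap_curve=curve)
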