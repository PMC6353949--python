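"""Module detection, merging, and permutation-based preservation.

Modules of co-expressed genes are found in the control (reference) group:
the most connected genes are clustered by average linkage on topological-
overlap dissimilarity, the tree is cut at a fixed height, small clusters
fall into the unassigned "grey" bin, and modules whose eigengenes correlate
at or above 0.9 are merged.  Preservation of each module in the treated
group is scored by a permutation Z composite (Zsummary = mean of a density
Z and a connectivity Z) interpreted on the conventional bins: Zsummary > 10
highly preserved, 2-10 weak-to-moderate, < 2 not preserved.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .network import AdjacencyParams, adjacency_connectivity, correlation_matrix

__all__ = [
    "MODULE_COLORS",
    "GREY",
    "select_top_connected",
    "tom_similarity",
    "detect_modules",
    "module_eigengenes",
    "merge_modules",
    "preservation_zsummary",
    "zsummary_bin",
]

GREY = "grey"
# WGCNA-style ordered palette; assigned to modules by decreasing size
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta", "sienna",
    "yellowgreen", "orangered", "plum", "ivory", "lavender",
]


def select_top_connected(
    k_control: pd.DataFrame, k_treated: pd.DataFrame, m: int = 3000
) -> list[str]:
    """Union of the top-m most connected genes (by raw k) of each group.

    Ties at rank m break by gene-id lexicographic order; when fewer than m
    genes exist all are taken.  Returns a sorted gene list.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if set(k_control.index) != set(k_treated.index):
        raise ValueError("connectivity tables must cover the same genes")

    def top(table: pd.DataFrame) -> set[str]:
        order = sorted(table.index, key=lambda g: (-table.at[g, "k_raw"], g))
        return set(order[:m])

    return sorted(top(k_control) | top(k_treated))


def tom_similarity(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap: shared-neighbour-weighted similarity in [0, 1].

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), TOM_ii = 1.
    """
    a = adjacency.to_numpy(float).copy()
    if np.any(a < 0) or np.any(a > 1):
        raise ValueError("adjacency entries must lie in [0, 1]")
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    np.clip(tom, 0.0, 1.0, out=tom)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def detect_modules(
    tom: pd.DataFrame,
    min_module_size: int = 20,
    cut_height: float = 0.995,
) -> pd.Series:
    """Average-linkage clustering of 1 - TOM with a static tree cut.

    Clusters smaller than ``min_module_size`` are labelled grey; surviving
    clusters get palette colours by decreasing size (ties by smallest
    member gene id, so runs are deterministic).
    """
    genes = list(tom.index)
    if len(genes) < min_module_size:
        warnings.warn("fewer genes than min_module_size; all grey", stacklevel=2)
        return pd.Series(GREY, index=genes, name="module")
    diss = 1.0 - tom.to_numpy(float)
    np.fill_diagonal(diss, 0.0)
    diss = (diss + diss.T) / 2.0
    link = average(squareform(diss, checks=False))
    flat = fcluster(link, t=cut_height, criterion="distance")

    clusters: dict[int, list[str]] = {}
    for gene, c in zip(genes, flat):
        clusters.setdefault(int(c), []).append(gene)
    sized = [
        (len(members), min(members), members)
        for members in clusters.values()
        if len(members) >= min_module_size
    ]
    sized.sort(key=lambda t: (-t[0], t[1]))
    labels = pd.Series(GREY, index=genes, name="module")
    for rank, (_, _, members) in enumerate(sized):
        color = (
            MODULE_COLORS[rank]
            if rank < len(MODULE_COLORS)
            else f"module{rank + 1}"
        )
        labels.loc[members] = color
    return labels


def module_eigengenes(
    expr: pd.DataFrame, modules: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """First principal component of each module's standardized expression.

    Eigengenes are unit-norm sample profiles oriented so their average
    correlation with member genes is positive; the second return value is
    the variance explained by the first component, in (0, 1].
    """
    eigengenes = {}
    var_explained = {}
    for label in sorted(set(modules) - {GREY}):
        members = modules.index[modules == label]
        if len(members) < 2:
            raise ValueError(f"module {label!r} has fewer than 2 genes")
        x = expr.loc[members].to_numpy(float)
        sd = x.std(axis=1, ddof=0)
        if np.any(sd == 0):
            raise ValueError(f"constant gene in module {label!r}")
        z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        eig = vt[0]
        if np.mean(z @ eig) < 0:
            eig = -eig
        eigengenes[label] = eig
        var_explained[label] = float(s[0] ** 2 / (s**2).sum())
    frame = pd.DataFrame(eigengenes, index=expr.columns)
    return frame, pd.Series(var_explained, name="var_explained")


def merge_modules(
    modules: pd.Series,
    expr: pd.DataFrame,
    r_min: float = 0.9,
) -> pd.Series:
    """Iteratively merge the most-correlated eigengene pair while r >= r_min.

    After each merge eigengenes are recomputed, so chains of mutually
    similar modules coalesce; grey never participates.  The merged module
    keeps the label of the larger partner.
    """
    labels = modules.copy()
    while True:
        active = sorted(set(labels) - {GREY})
        if len(active) < 2:
            return labels
        eig, _ = module_eigengenes(expr, labels)
        cor = np.corrcoef(eig.to_numpy(float).T)
        best, best_r = None, r_min
        for i in range(len(active)):
            for j in range(i + 1, len(active)):
                if cor[i, j] >= best_r:
                    best_r = cor[i, j]
                    best = (active[i], active[j])
        if best is None:
            return labels
        a, b = best
        size_a, size_b = (labels == a).sum(), (labels == b).sum()
        # larger module keeps its label; ties keep the lexicographically first
        keep, drop = (a, b) if size_a >= size_b else (b, a)
        labels[labels == drop] = keep


def zsummary_bin(zsummary: float) -> str:
    """Interpretation bin: >10 HIGH, <2 NOT_PRESERVED, else WEAK_MODERATE."""
    if zsummary > 10:
        return "HIGH"
    if zsummary < 2:
        return "NOT_PRESERVED"
    return "WEAK_MODERATE"


def _module_stats(
    idx: np.ndarray, adj_ref: np.ndarray, adj_test: np.ndarray
) -> tuple[float, float]:
    """(density in test network, ref/test intramodular-connectivity correlation)."""
    sub_t = adj_test[np.ix_(idx, idx)]
    m = len(idx)
    density = sub_t.sum() / (m * (m - 1))
    sub_r = adj_ref[np.ix_(idx, idx)]
    k_r = sub_r.sum(axis=1)
    k_t = sub_t.sum(axis=1)
    if k_r.std() == 0 or k_t.std() == 0:
        cor = 0.0
    else:
        cor = float(np.corrcoef(k_r, k_t)[0, 1])
    return float(density), cor


def preservation_zsummary(
    expr_ref: pd.DataFrame,
    expr_test: pd.DataFrame,
    modules: pd.Series,
    params: AdjacencyParams | None = None,
    n_perm: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation Zsummary of module preservation in the test group.

    For each non-grey module the observed statistics are the mean
    within-module adjacency in the test network (density) and the
    correlation between the module's intramodular connectivity vectors in
    the reference and test networks.  The null re-evaluates both on
    ``n_perm`` random gene sets of the same size drawn from the analyzed
    genes; Z = (obs - null mean) / null sd and Zsummary is the mean of the
    two Z scores.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    params = params or AdjacencyParams()
    genes = list(modules.index)
    missing = [g for g in genes if g not in expr_ref.index or g not in expr_test.index]
    if missing:
        raise ValueError(f"expression matrices missing module genes: {missing[:10]}")
    adj_ref, _ = adjacency_connectivity(
        correlation_matrix(expr_ref.loc[genes]), params
    )
    adj_test, _ = adjacency_connectivity(
        correlation_matrix(expr_test.loc[genes]), params
    )
    ar = adj_ref.to_numpy(float)
    at = adj_test.to_numpy(float)
    pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    rows = []
    for label in sorted(set(modules) - {GREY}):
        members = np.array([pos[g] for g in modules.index[modules == label]])
        if len(members) < 2:
            continue
        obs_d, obs_c = _module_stats(members, ar, at)
        null_d = np.empty(n_perm)
        null_c = np.empty(n_perm)
        for b in range(n_perm):
            rand = rng.choice(len(genes), size=len(members), replace=False)
            null_d[b], null_c[b] = _module_stats(rand, ar, at)
        zs = []
        for obs, null in ((obs_d, null_d), (obs_c, null_c)):
            sd = null.std(ddof=1)
            if sd == 0:
                warnings.warn(
                    f"null sd = 0 for module {label!r}; Z reported as inf",
                    stacklevel=2,
                )
                zs.append(np.inf if obs > null.mean() else -np.inf)
            else:
                zs.append((obs - null.mean()) / sd)
        z_density, z_connectivity = zs
        z_summary = (z_density + z_connectivity) / 2.0
        rows.append(
            {
                "module": label,
                "size": int(len(members)),
                "Zdensity": z_density,
                "Zconnectivity": z_connectivity,
                "Zsummary": z_summary,
                "bin": zsummary_bin(z_summary),
            }
        )
    columns = ["module", "size", "Zdensity", "Zconnectivity", "Zsummary", "bin"]
    return pd.DataFrame(rows, columns=columns).set_index("module")
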