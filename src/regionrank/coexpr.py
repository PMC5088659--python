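"""Weighted co-expression network construction and module detection.

Pipeline per region: Pearson correlations between all probeset pairs are
soft-thresholded into a weighted adjacency ``a_ij = |cor(x_i, x_j)|^beta``
(beta = 6 by default, chosen so the network is approximately scale-free);
adjacency is transformed into the topological overlap matrix (TOM), which
credits both direct connection and shared-neighbor mass; probesets are
clustered by average-linkage hierarchical clustering on 1 - TOM; a dynamic
tree cut extracts tight, sufficiently large dendrogram branches as modules
(unassigned probesets are labelled "grey"); each module is summarized by its
eigengene, the first principal component of the standardized module
expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

__all__ = [
    "MODULE_COLORS",
    "ModuleAssignment",
    "soft_threshold_adjacency",
    "scale_free_fit_index",
    "topological_overlap",
    "cluster_modules",
    "module_eigengene",
    "build_network_modules",
]

#: size-ordered module color palette (grey reserved for unassigned)
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
)

UNASSIGNED = "grey"

#: deep_split level -> fraction of the dendrogram height range required as the
#: gap between a branch's core scatter and its attachment height (higher
#: deep_split = more aggressive splitting = smaller required gap)
_GAP_FRACTION = {0: 0.20, 1: 0.15, 2: 0.10, 3: 0.07, 4: 0.05}
_MIN_ABS_GAP = 0.02


@dataclass
class ModuleAssignment:
    """Probeset -> module labels for one region, with clustering metadata."""

    labels: pd.Series  # probeset-indexed module color ("grey" = unassigned)
    region: str = ""
    min_module_size: int = 30
    deep_split: int = 2

    def module_sets(self, include_grey: bool = False) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for mod, genes in self.labels.groupby(self.labels):
            if mod == UNASSIGNED and not include_grey:
                continue
            out[str(mod)] = list(genes.index)
        return out

    @property
    def assigned_fraction(self) -> float:
        return float((self.labels != UNASSIGNED).mean())


def soft_threshold_adjacency(
    m: pd.DataFrame, beta: int = 6, network_type: str = "unsigned"
) -> pd.DataFrame:
    """Soft-threshold adjacency ``|cor|^beta`` (or ``((1+cor)/2)^beta`` signed).

    Constant probesets have all their correlations set to 0 with a warning.
    The diagonal is set to 1.
    """
    if m.shape[1] < 4:
        raise ValueError("need >= 4 samples to estimate correlations")
    if beta < 1:
        raise ValueError("beta must be >= 1")
    x = m.to_numpy(dtype=float)
    sd = x.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant probeset(s): correlations set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        cor = np.corrcoef(x)
    cor[np.isnan(cor)] = 0.0
    cor = np.clip(cor, -1.0, 1.0)
    if network_type == "unsigned":
        a = np.abs(cor) ** beta
    elif network_type == "signed":
        a = ((1.0 + cor) / 2.0) ** beta
    else:
        raise ValueError("network_type must be 'unsigned' or 'signed'")
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=m.index, columns=m.index)


def scale_free_fit_index(a: pd.DataFrame | np.ndarray, n_bins: int = 10) -> float:
    """R-squared of the truncated-exponential power-law fit to the degree distribution.

    Connectivities ``k_i = sum_j a_ij (j != i)`` are binned into ``n_bins``
    equal-width bins; ``log10 p(k)`` is regressed on ``log10 k_bin`` AND
    ``k_bin`` (the truncated scale-free model); the model R-squared is
    returned.
    """
    arr = a.to_numpy(dtype=float) if isinstance(a, pd.DataFrame) else np.asarray(a, float)
    if arr.shape[0] < 10:
        raise ValueError("need >= 10 nodes for a degree-distribution fit")
    k = arr.sum(axis=1) - np.diag(arr)
    if np.ptp(k) == 0:
        raise ValueError("all connectivities equal: scale-free index undefined")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    kmean = np.array([k[idx == b].mean() if (idx == b).any() else np.nan for b in range(n_bins)])
    freq = np.array([(idx == b).mean() for b in range(n_bins)])
    ok = (freq > 0) & np.isfinite(kmean) & (kmean > 0)
    if ok.sum() < 3:
        raise ValueError("too few occupied bins for the regression")
    y = np.log10(freq[ok])
    X = np.column_stack([np.ones(ok.sum()), np.log10(kmean[ok]), kmean[ok]])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ss_tot = ((y - y.mean()) ** 2).sum()
    if ss_tot == 0:
        return 1.0
    return float(1.0 - (resid**2).sum() / ss_tot)


def topological_overlap(a: pd.DataFrame) -> pd.DataFrame:
    """Unsigned topological overlap matrix.

    ``tom_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    ``l_ij = sum_u a_iu * a_uj`` over u distinct from i and j, and
    ``k_i = sum_u a_iu`` over u != i; the diagonal is 1.
    """
    b = a.to_numpy(dtype=float).copy()
    np.fill_diagonal(b, 0.0)
    l = b @ b
    k = b.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (l + b) / (kmin + 1.0 - b)
    tom = np.clip(np.nan_to_num(tom, nan=0.0), 0.0, 1.0)
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=a.index, columns=a.columns)


def _branch_statistics(Z: np.ndarray, n: int):
    """Per-merge-node member lists, core scatter, and attachment heights.

    For average linkage the merge height IS the mean dissimilarity between the
    two merged clusters, so the within-cluster pairwise sum accumulates
    exactly: sum(new) = sum(c1) + sum(c2) + h * |c1| * |c2|.
    """
    size = np.ones(2 * n - 1, dtype=int)
    pair_sum = np.zeros(2 * n - 1)
    members: list[list[int] | None] = [[i] for i in range(n)] + [None] * (n - 1)
    parent_height = np.full(2 * n - 1, np.inf)
    for i in range(n - 1):
        c1, c2, h, _ = Z[i]
        c1, c2 = int(c1), int(c2)
        node = n + i
        size[node] = size[c1] + size[c2]
        pair_sum[node] = pair_sum[c1] + pair_sum[c2] + h * size[c1] * size[c2]
        members[node] = members[c1] + members[c2]  # type: ignore[operator]
        parent_height[c1] = parent_height[c2] = h
    npairs = size * (size - 1) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        scatter = np.where(npairs > 0, pair_sum / np.maximum(npairs, 1), 0.0)
    return members, size, scatter, parent_height


def cluster_modules(
    tom: pd.DataFrame,
    min_module_size: int = 30,
    deep_split: int = 2,
    expression: pd.DataFrame | None = None,
    kme_threshold: float = 0.5,
) -> ModuleAssignment:
    """Detect co-expression modules by dynamic cutting of the average-linkage tree.

    A dendrogram branch qualifies as a module when (a) it holds at least
    ``min_module_size`` probesets and (b) its core scatter (mean within-branch
    dissimilarity) sits sufficiently far below the height at which the branch
    attaches to the rest of the tree — the required gap is a ``deep_split``-
    controlled fraction of the dendrogram height range.  A qualifying branch
    is taken whole unless it separates into two or more qualifying
    sub-branches; all other probesets are labelled grey.  When ``expression``
    is supplied, module membership is refined: members whose correlation with
    the module eigengene falls below ``kme_threshold`` in absolute value are
    demoted to grey (trimming loosely attached probesets), and modules
    shrinking below the size floor are dissolved.  Modules are named by
    descending size from a fixed color palette.
    """
    if deep_split not in _GAP_FRACTION:
        raise ValueError(f"deep_split must be one of {sorted(_GAP_FRACTION)}")
    probesets = list(tom.index)
    n = len(probesets)
    labels = pd.Series(UNASSIGNED, index=probesets, name="module")
    if n < max(min_module_size, 2):
        warnings.warn("fewer probesets than min_module_size: all grey", stacklevel=2)
        return ModuleAssignment(labels, min_module_size=min_module_size, deep_split=deep_split)

    d = 1.0 - tom.to_numpy(dtype=float)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    Z = linkage(squareform(d, checks=False), method="average")
    members, size, scatter, parent_h = _branch_statistics(Z, n)

    heights = Z[:, 2]
    h_lo, h_hi = np.quantile(heights, 0.05), heights.max()
    min_gap = max(_GAP_FRACTION[deep_split] * (h_hi - h_lo), _MIN_ABS_GAP)

    qualifies = (size >= min_module_size) & (parent_h - scatter >= min_gap)
    # leaves never qualify on their own (size 1 < min_module_size >= 2);
    # the root is not a branch (it attaches to nothing), so it cannot be a
    # module by itself — this is what sends pure-noise input to grey.
    qualifies[2 * n - 2] = False

    # n_sep[v]: maximum number of disjoint qualifying branches inside v's subtree
    n_sep = np.zeros(2 * n - 1, dtype=int)
    for i in range(n - 1):  # children precede parents in merge order
        c1, c2 = int(Z[i, 0]), int(Z[i, 1])
        n_sep[n + i] = max(int(qualifies[n + i]), n_sep[c1] + n_sep[c2])

    # top-down: take a qualifying branch whole unless it splits into two or
    # more separable qualifying sub-branches, in which case descend
    module_nodes: list[int] = []
    stack = [2 * n - 2]
    while stack:
        v = stack.pop()
        if v < n:
            continue
        c1, c2 = int(Z[v - n, 0]), int(Z[v - n, 1])
        below = n_sep[c1] + n_sep[c2]
        if qualifies[v] and below <= 1:
            module_nodes.append(v)
        elif below >= 1:
            stack.extend((c1, c2))
    module_nodes.sort(key=lambda v: (-size[v], v))
    groups = [list(members[v]) for v in module_nodes]  # type: ignore[arg-type]
    if expression is not None:
        groups = _refine_by_membership(
            expression, groups, min_module_size, kme_threshold
        )
    groups.sort(key=lambda g: (-len(g), g[0] if g else 0))
    for rank, idxs in enumerate(groups):
        color = MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module{rank + 1}"
        labels.iloc[idxs] = color
    return ModuleAssignment(labels, min_module_size=min_module_size, deep_split=deep_split)


def _refine_by_membership(
    expression: pd.DataFrame,
    groups: list[list[int]],
    min_module_size: int,
    kme_threshold: float,
) -> list[list[int]]:
    """Trim module members whose eigengene correlation (kME) is too weak."""
    x = expression.to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=1)
    z = (x - x.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)[:, None]
    refined: list[list[int]] = []
    for idxs in groups:
        sub = z[idxs]
        _, _, vt = np.linalg.svd(sub, full_matrices=False)
        eig = vt[0]
        if np.dot(eig, sub.mean(axis=0)) < 0:
            eig = -eig
        kme = (sub @ eig) / (np.linalg.norm(sub, axis=1) * np.linalg.norm(eig))
        kept = [i for i, c in zip(idxs, kme) if abs(c) >= kme_threshold]
        if len(kept) >= min_module_size:
            refined.append(kept)
    return refined


def module_eigengene(
    m: pd.DataFrame, assignment: ModuleAssignment
) -> tuple[pd.DataFrame, pd.Series]:
    """Module eigengenes: first principal component of standardized module expression.

    Each module's genes are z-scored across samples; the first right singular
    vector of the genes x samples matrix is the eigengene (unit norm), with
    its sign oriented so it correlates positively with the module's average
    standardized expression.  Returns (eigengene frame: modules x samples,
    variance-explained series).
    """
    eg: dict[str, np.ndarray] = {}
    ve: dict[str, float] = {}
    for mod, genes in assignment.module_sets().items():
        if len(genes) < 2:
            raise ValueError(f"module {mod} has fewer than 2 genes")
        x = m.loc[genes].to_numpy(dtype=float)
        sd = x.std(axis=1, ddof=1)
        if (sd == 0).any():
            raise ValueError(f"module {mod} contains zero-variance genes")
        z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
        _, s, vt = np.linalg.svd(z, full_matrices=False)
        v = vt[0]
        mean_profile = z.mean(axis=0)
        if np.dot(v, mean_profile) < 0:
            v = -v
        eg[mod] = v
        ve[mod] = float(s[0] ** 2 / (s**2).sum())
    frame = pd.DataFrame(eg, index=m.columns).T
    frame.index.name = "module"
    return frame, pd.Series(ve, name="variance_explained")


@dataclass
class RegionNetwork:
    """Bundle of one region's network artifacts."""

    region: str
    assignment: ModuleAssignment
    eigengenes: pd.DataFrame
    variance_explained: pd.Series
    scale_free_r2: float
    beta: int = 6
    extras: dict = field(default_factory=dict)


def build_network_modules(
    m: pd.DataFrame,
    region: str = "",
    beta: int = 6,
    min_module_size: int = 30,
    deep_split: int = 2,
    network_type: str = "unsigned",
) -> RegionNetwork:
    """Full per-region network pipeline: adjacency -> TOM -> modules -> eigengenes."""
    adj = soft_threshold_adjacency(m, beta=beta, network_type=network_type)
    r2 = scale_free_fit_index(adj)
    tom = topological_overlap(adj)
    assignment = cluster_modules(
        tom, min_module_size=min_module_size, deep_split=deep_split, expression=m
    )
    assignment.region = region
    if assignment.module_sets():
        eigengenes, ve = module_eigengene(m, assignment)
    else:
        eigengenes = pd.DataFrame(columns=m.columns)
        ve = pd.Series(dtype=float)
    return RegionNetwork(
        region=region,
        assignment=assignment,
        eigengenes=eigengenes,
        variance_explained=ve,
        scale_free_r2=r2,
        beta=beta,
    )
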