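"""Meta-co-expression network over module eigengenes, module conservation,
and cross-region correlated probeset pairs.

The eigengenes of every region's modules, aligned on the donors the regions
share, form one matrix to which the same network pipeline (power adjacency,
TOM, dynamic tree cut) is applied; its clusters are meta-modules.  Module
conservation across regions is quantified by the Jaccard index of module
gene memberships, and region-region interaction by the number of probeset
pairs whose cross-region correlation is significant after BH adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .coexpr import ModuleAssignment, cluster_modules, soft_threshold_adjacency, topological_overlap

__all__ = [
    "MetaNetwork",
    "build_meta_network",
    "module_jaccard_conservation",
    "cross_region_pair_correlation",
]


@dataclass
class MetaNetwork:
    """Meta-module assignment of region-module eigengenes."""

    eigengenes: pd.DataFrame  # (region:module) x shared samples, re-standardized
    meta_modules: pd.Series  # per eigengene, meta-module label ("grey" = none)
    region_of: pd.Series  # per eigengene, region of origin

    def composition(self) -> pd.DataFrame:
        """Per-meta-module fraction of members contributed by each region."""
        rows = {}
        for meta, members in self.meta_modules.groupby(self.meta_modules):
            if meta == "grey":
                continue
            regions = self.region_of.loc[members.index]
            rows[meta] = regions.value_counts(normalize=True)
        return pd.DataFrame(rows).T.fillna(0.0)


def build_meta_network(
    eigengenes_by_region: dict[str, pd.DataFrame],
    beta: int = 6,
    min_module_size: int = 3,
    deep_split: int = 2,
    min_overlap: int = 10,
) -> MetaNetwork:
    """Cluster all regions' module eigengenes into meta-modules.

    Eigengenes are aligned on the intersection of donors present in every
    region, re-standardized on that shared subset, and run through the
    adjacency/TOM/tree-cut pipeline.  Meta-modules are small by nature, so the
    minimum module size defaults to 3 eigengenes.
    """
    shared: pd.Index | None = None
    for eg in eigengenes_by_region.values():
        shared = eg.columns if shared is None else shared.intersection(eg.columns)
    if shared is None or len(shared) < min_overlap:
        raise ValueError(
            f"shared donor overlap {0 if shared is None else len(shared)} "
            f"below minimum {min_overlap}"
        )
    blocks = []
    for region, eg in eigengenes_by_region.items():
        sub = eg[shared]
        mu = sub.mean(axis=1)
        sd = sub.std(axis=1).replace(0.0, 1.0)
        sub = sub.sub(mu, axis=0).div(sd, axis=0)
        sub.index = [f"{region}:{mod}" for mod in eg.index]
        blocks.append(sub)
    mat = pd.concat(blocks)
    adj = soft_threshold_adjacency(mat, beta=beta)
    tom = topological_overlap(adj)
    assignment = cluster_modules(tom, min_module_size=min_module_size, deep_split=deep_split)
    region_of = pd.Series([name.split(":", 1)[0] for name in mat.index], index=mat.index)
    return MetaNetwork(eigengenes=mat, meta_modules=assignment.labels, region_of=region_of)


def module_jaccard_conservation(
    assign_a: ModuleAssignment,
    assign_b: ModuleAssignment,
    threshold: float = 0.5,
) -> tuple[pd.DataFrame, int]:
    """Jaccard index |A∩B| / |A∪B| for all cross-region module pairs.

    Returns the pair table (module_a, module_b, jaccard) and the count of
    pairs strictly above ``threshold``.  Empty modules are skipped with a
    warning.
    """
    sets_a = {k: set(v) for k, v in assign_a.module_sets().items()}
    sets_b = {k: set(v) for k, v in assign_b.module_sets().items()}
    rows = []
    for ka, sa in sets_a.items():
        if not sa:
            warnings.warn(f"empty module {ka} skipped", stacklevel=2)
            continue
        for kb, sb in sets_b.items():
            if not sb:
                warnings.warn(f"empty module {kb} skipped", stacklevel=2)
                continue
            j = len(sa & sb) / len(sa | sb)
            rows.append({"module_a": ka, "module_b": kb, "jaccard": j})
    table = pd.DataFrame(rows, columns=["module_a", "module_b", "jaccard"])
    n_above = int((table["jaccard"] > threshold).sum()) if len(table) else 0
    return table, n_above


def cross_region_pair_correlation(
    ma: pd.DataFrame,
    mb: pd.DataFrame,
    fdr: float = 0.05,
    max_probesets: int | None = 500,
) -> tuple[int, float]:
    """Count significantly correlated probeset pairs between two regions.

    Pearson correlation of every (probeset in A) x (probeset in B) pair across
    the donors shared by the two regions; pair p-values (t approximation) are
    BH-adjusted; returns (significant count, fraction of all pairs).
    ``max_probesets`` caps each region's probeset universe (first rows kept).
    """
    shared = [s for s in ma.columns if s in set(mb.columns)]
    if len(shared) < 4:
        raise ValueError(f"only {len(shared)} shared donors; need >= 4")
    if max_probesets is not None:
        ma, mb = ma.iloc[:max_probesets], mb.iloc[:max_probesets]
    xa = ma[shared].to_numpy(dtype=float)
    xb = mb[shared].to_numpy(dtype=float)
    n = len(shared)
    za = (xa - xa.mean(axis=1, keepdims=True)) / np.maximum(xa.std(axis=1, keepdims=True), 1e-300)
    zb = (xb - xb.mean(axis=1, keepdims=True)) / np.maximum(xb.std(axis=1, keepdims=True), 1e-300)
    r = np.clip(za @ zb.T / n, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2).ravel()
    reject, *_ = multipletests(p, alpha=fdr, method="fdr_bh")
    count = int(reject.sum())
    return count, count / p.size
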