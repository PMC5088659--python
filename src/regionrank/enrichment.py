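"""Gene-set over-representation (Fisher's exact test) with BH control, and
validation of co-expression modules against gene perturbation signatures.

All tests are one-sided (over-representation): the query and target sets are
treated as samples from the probeset universe, and the p-value is the upper
hypergeometric tail of the observed overlap.  Module validation asks whether
a perturbation signature (e.g. a knock-down DEG list) is more enriched in the
modules harboring the perturbed target gene than in the remaining modules,
via a one-tailed Wilcoxon rank-sum test on -log10 enrichment p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .coexpr import ModuleAssignment

__all__ = [
    "EnrichmentResult",
    "fisher_enrichment",
    "enrichment_batch",
    "bh_adjust",
    "validate_perturbation",
]


@dataclass
class EnrichmentResult:
    """One Fisher over-representation test."""

    overlap: int
    query_size: int
    target_size: int
    universe_size: int
    fold_enrichment: float
    odds_ratio: float
    p: float
    fdr_bh: float | None = None


def fisher_enrichment(
    query: Iterable[str], target: Iterable[str], universe: Iterable[str]
) -> EnrichmentResult:
    """One-sided (enrichment) Fisher's exact test of two sets in a universe.

    ``p = P(overlap >= observed)`` under the hypergeometric null;
    ``fold_enrichment = (overlap/|query|) / (|target|/|universe|)``.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    q = set(query) & uni
    t = set(target) & uni
    k = len(q & t)
    n_u, n_q, n_t = len(uni), len(q), len(t)
    # upper tail: P(X >= k), X ~ Hypergeom(N=n_u, K=n_t, n=n_q)
    p = float(stats.hypergeom.sf(k - 1, n_u, n_t, n_q)) if n_q and n_t else 1.0
    p = min(max(p, np.finfo(float).tiny), 1.0)
    if n_q and n_t:
        fe = (k / n_q) / (n_t / n_u)
        table = [[k, n_q - k], [n_t - k, n_u - n_q - n_t + k]]
        odds = stats.contingency.odds_ratio(table, kind="sample").statistic
    else:
        fe, odds = 0.0, np.nan
    return EnrichmentResult(
        overlap=k,
        query_size=n_q,
        target_size=n_t,
        universe_size=n_u,
        fold_enrichment=float(fe),
        odds_ratio=float(odds),
        p=p,
    )


def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrichment_batch(
    queries: Mapping[str, Iterable[str]],
    target: Iterable[str],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Fisher enrichment of one target set in many query sets, BH-adjusted."""
    rows = {}
    for name, q in queries.items():
        r = fisher_enrichment(q, target, universe)
        rows[name] = {
            "overlap": r.overlap,
            "query_size": r.query_size,
            "target_size": r.target_size,
            "universe_size": r.universe_size,
            "fold_enrichment": r.fold_enrichment,
            "odds_ratio": r.odds_ratio,
            "p": r.p,
        }
    table = pd.DataFrame(rows).T
    table["fdr_bh"] = bh_adjust(table["p"])
    return table


def validate_perturbation(
    assignment: ModuleAssignment | Mapping[str, ModuleAssignment],
    target_gene: str,
    signature: Iterable[str],
    universe: Iterable[str],
) -> tuple[pd.DataFrame, float]:
    """Test whether a perturbation signature concentrates in target-harboring modules.

    Computes signature enrichment for every module, splits modules into those
    containing the perturbed target gene versus the rest, and returns the
    enrichment table plus the one-tailed Wilcoxon rank-sum p-value that
    -log10(p) is larger in the target-harboring modules.  Pass a mapping
    ``{region: assignment}`` to pool modules across regions (module keys
    become ``region:color``), which is how the comparison gains power.
    """
    if isinstance(assignment, ModuleAssignment):
        modules = assignment.module_sets()
    else:
        modules = {
            f"{region}:{mod}": genes
            for region, asg in assignment.items()
            for mod, genes in asg.module_sets().items()
        }
    harboring = [m for m, genes in modules.items() if target_gene in set(genes)]
    if not harboring:
        raise ValueError(f"target gene {target_gene!r} not assigned to any module")
    table = enrichment_batch(modules, signature, universe)
    table["harbors_target"] = [m in set(harboring) for m in table.index]
    score = -np.log10(table["p"].to_numpy(dtype=float))
    a = score[table["harbors_target"].to_numpy()]
    b = score[~table["harbors_target"].to_numpy()]
    if len(b) == 0:
        raise ValueError("all modules harbor the target; rank-sum undefined")
    stat = stats.mannwhitneyu(a, b, alternative="greater", method="auto")
    return table, float(stat.pvalue)
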