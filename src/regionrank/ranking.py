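"""Ensemble composite ranking of brain regions, modules, and genes.

Every item i (a region, module, or gene) carries a vector of ranking
variables K_i1..K_in — gene counts for regions, P-values for modules and
genes.  The composite importance score is the geometric mean of transformed
variables,

    S_i = (prod_j f(K_ij)) ** (1/n),

scaled to [0, 1] by division by the maximum score; rank 1 is the top item.
Counts use f(K) = ln(1 + K) (the +1 handles the zero counts that occur in
practice while preserving order); P-values use f(P) = -ln(P) with P floored
at 1e-300.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RankingResult", "composite_score", "rank_regions", "rank_modules", "rank_genes"]

P_FLOOR = 1e-300


@dataclass
class RankingResult:
    """Scores, ranks, and per-variable contributions of one ensemble ranking."""

    table: pd.DataFrame  # columns: score, rank (index = items)
    contributions: pd.DataFrame  # items x variables, transformed values f(K)
    transform: str

    @property
    def scores(self) -> pd.Series:
        return self.table["score"]

    @property
    def ranks(self) -> pd.Series:
        return self.table["rank"]


def _transform(K: pd.DataFrame, transform: str) -> pd.DataFrame:
    x = K.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("ranking variables must be non-negative")
    if transform == "log-count":
        f = np.log1p(x)
    elif transform == "minus-log-p":
        if (x > 1).any():
            raise ValueError("P-value variables must lie in [0, 1]")
        f = -np.log(np.maximum(x, P_FLOOR))
    else:
        raise ValueError("transform must be 'log-count' or 'minus-log-p'")
    return pd.DataFrame(f, index=K.index, columns=K.columns)


def composite_score(K: pd.DataFrame, transform: str = "log-count") -> RankingResult:
    """Geometric-mean composite score over ranking variables, scaled to [0, 1].

    ``S_i = (prod_j f(K_ij))^(1/n) / max_i S_i``; ties share the smallest
    rank of their group, with stable input order otherwise.
    """
    if K.shape[1] < 1:
        raise ValueError("need at least one ranking variable")
    if K.isna().any().any():
        raise ValueError("missing ranking variable values (no silent imputation)")
    f = _transform(K, transform)
    # geometric mean via log-sum; an all-usable-zero row scores exactly 0
    vals = f.to_numpy()
    any_zero = (vals == 0).any(axis=1)
    logs = np.log(np.where(vals > 0, vals, 1.0))
    score = np.exp(logs.mean(axis=1))
    score[any_zero] = 0.0  # a zero factor zeroes the product
    smax = score.max()
    if smax > 0:
        score = score / smax
    table = pd.DataFrame({"score": score}, index=K.index)
    table["rank"] = table["score"].rank(ascending=False, method="min").astype(int)
    return RankingResult(table=table, contributions=f, transform=transform)


def rank_regions(counts: pd.DataFrame) -> RankingResult:
    """Rank regions by DEG/TCG counts (columns = the 24 ranking variables
    by default: 3 contrasts x 6 traits of DEG counts + 6 TCG counts),
    with f(K) = ln(1 + K)."""
    return composite_score(counts, transform="log-count")


def rank_modules(pvalues: pd.DataFrame) -> RankingResult:
    """Rank modules by eigengene-trait correlation P-values and DEG/TCG
    enrichment P-values, with f(P) = -ln(P)."""
    return composite_score(pvalues, transform="minus-log-p")


def rank_genes(pvalues: pd.DataFrame, fill_missing: float = 1.0) -> RankingResult:
    """Rank genes by association P-values across regions and traits.

    Genes absent from a region contribute P = 1 (zero evidence) for that
    region's variables rather than being dropped.
    """
    filled = pvalues.fillna(fill_missing)
    return composite_score(filled, transform="minus-log-p")
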