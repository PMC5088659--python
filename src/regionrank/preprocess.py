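"""Expression-matrix preprocessing: platform merging, quantile normalization,
and covariate residualization.

The pipeline starts from log2-scale probesets x samples matrices (RMA-like
summaries).  Two-platform designs are merged by averaging common probesets;
matrices are quantile normalized so every sample shares one empirical
distribution; covariate effects (sex, PMI, pH, race) are then removed per
probeset by ordinary least squares, with the probeset mean restored so log2
fold changes stay interpretable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["merge_platforms", "quantile_normalize", "residualize_covariates"]


def merge_platforms(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Merge two platforms profiled on the same samples.

    The output holds the union of probesets; probesets present on both
    platforms get the arithmetic mean of the two signals, all others are
    carried through unchanged.
    """
    if set(a.columns) != set(b.columns):
        raise ValueError("platforms must share the same sample set")
    b = b[a.columns]
    shared = a.index.intersection(b.index)
    only_a = a.index.difference(b.index)
    only_b = b.index.difference(a.index)
    merged = pd.concat(
        [
            (a.loc[shared] + b.loc[shared]) / 2.0,
            a.loc[only_a],
            b.loc[only_b],
        ]
    )
    # Keep a's ordering first, then b's extras, for reproducible output.
    order = list(a.index) + [p for p in b.index if p not in set(a.index)]
    return merged.loc[order]


def quantile_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns so every sample has the same distribution.

    Each column's sorted values are replaced by the row means of the
    column-wise sorted matrix; ranks within a column are preserved, and ties
    receive the average of their tied ranks' reference values.
    """
    if m.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    x = m.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("expression matrix contains NaN or infinite values")
    ref = np.sort(x, axis=0).mean(axis=1)  # reference distribution
    cs = np.concatenate([[0.0], np.cumsum(ref)])
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        # a tie group occupying ranks [lo, hi] gets mean(ref[lo-1:hi])
        lo = rankdata(x[:, j], method="min")
        hi = rankdata(x[:, j], method="max")
        out[:, j] = (cs[hi] - cs[lo - 1]) / (hi - lo + 1)
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def _encode_design(cov: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Intercept + treatment-coded categoricals + numeric covariates."""
    cols: list[np.ndarray] = [np.ones(len(cov))]
    names = ["intercept"]
    for c in cov.columns:
        s = cov[c]
        if s.dtype.kind in "OUSb" or isinstance(s.dtype, pd.CategoricalDtype):
            levels = sorted(pd.unique(s.astype(str)))
            for lev in levels[1:]:  # first level is the reference
                cols.append((s.astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{c}[{lev}]")
        else:
            cols.append(s.to_numpy(dtype=float))
            names.append(c)
    return np.column_stack(cols), names


def residualize_covariates(m: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Remove linear covariate effects from every probeset by OLS.

    Covariates are subset and aligned to the matrix's samples (regions with
    uneven coverage simply use their own samples).  The fitted residuals are
    returned with each probeset's mean added back.
    """
    missing = [s for s in m.columns if s not in covariates.index]
    if missing:
        raise ValueError(f"covariates missing for samples: {missing[:5]}")
    cov = covariates.loc[list(m.columns)]
    X, names = _encode_design(cov)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns: those whose removal restores full rank
        bad = [
            names[j]
            for j in range(1, X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient covariate design; collinear columns: {bad}")
    y = m.to_numpy(dtype=float).T  # samples x probesets
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = (y - X @ beta).T
    resid += m.to_numpy(dtype=float).mean(axis=1, keepdims=True)
    return pd.DataFrame(resid, index=m.index, columns=m.columns)
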