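"""Association of expression with disease severity and traits.

Two complementary screens:

* Differential expression between severity groups (normal / low / high) using
  a per-probeset linear model with empirical-Bayes variance shrinkage (the
  moderated t of microarray practice), significance assessed by an empirical
  permutation FDR plus a fold-change filter.
* Trait-correlated genes (TCGs): Spearman rank correlation of each probeset
  with an ordinal or quantitative trait, with the same permutation-FDR
  machinery applied to the correlation statistics.

The empirical FDR at a cutoff is ``FDR = n * (FP/N) / P`` where ``n`` is the
number of tests, ``P`` the number of observed statistics passing the cutoff,
``FP`` the number of pooled permutation statistics passing it, and ``N`` the
total number of permutation statistics.  This is equivalent to computing
empirical permutation p-values and applying Benjamini-Hochberg step-up
control, and the per-probeset curve is made monotone the same way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "SEVERITY_LEVELS",
    "assign_severity_groups",
    "fit_scale_prior",
    "moderated_t_test",
    "permuted_moderated_t",
    "empirical_fdr",
    "empirical_fdr_curve",
    "differential_expression",
    "call_degs",
    "spearman_trait_correlation",
]

SEVERITY_LEVELS = ("normal", "low", "high")

#: the three two-group contrasts evaluated per trait, as (reference, test)
CONTRASTS = (("normal", "low"), ("low", "high"), ("normal", "high"))

_ORDINAL_RULES = {
    # trait -> (normal test, low test) on the numeric scale; rest is high
    "CDR": (lambda v: v == 0, lambda v: (v > 0) & (v <= 2)),
    "Braak": (lambda v: v <= 2, lambda v: (v >= 3) & (v <= 4)),
    # CERAD coded 0=normal, 1=possible AD, 2=probable AD, 3=definite AD
    "CERAD": (lambda v: v == 0, lambda v: (v >= 1) & (v <= 2)),
}

_QUANTITATIVE = ("PLQ_Mn", "NPrSum", "NTrSum")


def assign_severity_groups(traits: pd.DataFrame, trait: str) -> pd.Series:
    """Classify samples into normal / low / high severity for one trait.

    Ordinal rules: Braak 0-2 / 3-4 / 5-6; CDR 0 / 0.5-2 / 3-5; CERAD normal /
    possible-probable AD / definite AD.  Quantitative lesion traits: value 0
    (clean brain) is normal, the remaining samples are split at their median
    into low (<= median) and high (> median).
    """
    if trait not in traits.columns:
        raise KeyError(f"unknown trait {trait!r}; have {list(traits.columns)}")
    v = pd.to_numeric(traits[trait], errors="raise")
    v = v.dropna()
    out = pd.Series(index=v.index, dtype=object, name=f"{trait}_group")
    if trait in _ORDINAL_RULES:
        is_normal, is_low = _ORDINAL_RULES[trait]
        out[is_normal(v)] = "normal"
        out[is_low(v)] = "low"
        out[out.isna()] = "high"
    elif trait in _QUANTITATIVE:
        normal = v == 0
        rest = v[~normal]
        if len(rest) == 0:
            out[:] = "normal"
            return out
        med = rest.median()
        out[normal] = "normal"
        out[(~normal) & (v <= med)] = "low"
        out[(~normal) & (v > med)] = "high"
    else:
        raise KeyError(f"unknown trait {trait!r}")
    return out


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration on 1/trigamma)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if -dif / x < 1e-10:
            break
    return float(x)


def fit_scale_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square variance prior.

    Matches the mean and variance of log sample variances to the scaled
    F-distribution they follow under the hierarchical model, via the digamma /
    trigamma identities; returns (d0, s0_squared).  d0 = inf means complete
    shrinkage (all true variances equal).
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = np.maximum(s2, 1e-300)
    n = s2.size
    if n < 2:
        return np.inf, float(s2.mean())
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = ((e - emean) ** 2).sum() / (n - 1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_sq = np.exp(emean)
    return float(d0), float(s0_sq)


@dataclass
class ModeratedTResult:
    """Per-probeset differential-expression statistics for one contrast."""

    table: pd.DataFrame  # columns: log2_fc, t, p (index = probesets)
    d0: float
    s0_sq: float
    contrast: tuple[str, str]

    def __getitem__(self, col: str) -> pd.Series:
        return self.table[col]


def _group_matrices(
    m: pd.DataFrame, grouping: pd.Series, contrast: tuple[str, str]
) -> tuple[np.ndarray, np.ndarray]:
    ga, gb = contrast
    a_cols = [s for s in m.columns if grouping.get(s) == ga]
    b_cols = [s for s in m.columns if grouping.get(s) == gb]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError(
            f"contrast {contrast} needs >=2 samples per group "
            f"(got {len(a_cols)} and {len(b_cols)})"
        )
    return m[a_cols].to_numpy(dtype=float), m[b_cols].to_numpy(dtype=float)


def _moderated_t_from_arrays(
    xa: np.ndarray, xb: np.ndarray, prior_df: float | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, float]:
    n1, n2 = xa.shape[1], xb.shape[1]
    df = n1 + n2 - 2
    if df <= 0:
        raise ValueError("zero residual degrees of freedom")
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    ss = ((xa - ma[:, None]) ** 2).sum(axis=1) + ((xb - mb[:, None]) ** 2).sum(axis=1)
    s2 = ss / df
    if prior_df is None:
        d0, s0_sq = fit_scale_prior(s2, df)
    elif prior_df == 0:
        d0, s0_sq = 0.0, 1.0  # s0 irrelevant at zero prior weight
    else:
        d0 = float(prior_df)
        _, s0_sq = fit_scale_prior(s2, df)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    delta = mb - ma
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, delta / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return delta, t, p, d0, s0_sq


def moderated_t_test(
    m: pd.DataFrame,
    grouping: pd.Series,
    contrast: tuple[str, str] = ("normal", "high"),
    prior_df: float | None = None,
) -> ModeratedTResult:
    """Empirical-Bayes moderated two-group t-test per probeset.

    The pooled per-probeset variance ``s2_g`` (df_g = n1 + n2 - 2) is shrunk
    toward a prior value ``s0^2`` with prior degrees of freedom ``d0``
    estimated by method of moments on the log sample variances:
    ``s2_post = (d0 * s0^2 + df_g * s2_g) / (d0 + df_g)``.  The moderated t is
    ``(mean_B - mean_A) / (s_post * sqrt(1/n1 + 1/n2))`` with d0 + df_g degrees
    of freedom.  ``log2_fc`` is the mean difference on the log2 data.
    ``prior_df`` overrides the estimated d0 (0 gives the ordinary t-test).
    """
    xa, xb = _group_matrices(m, grouping, contrast)
    delta, t, p, d0, s0_sq = _moderated_t_from_arrays(xa, xb, prior_df)
    table = pd.DataFrame({"log2_fc": delta, "t": t, "p": p}, index=m.index)
    return ModeratedTResult(table=table, d0=d0, s0_sq=s0_sq, contrast=contrast)


def permuted_moderated_t(
    m: pd.DataFrame,
    grouping: pd.Series,
    contrast: tuple[str, str],
    n_perm: int = 5,
    rng: np.random.Generator | int = 0,
) -> np.ndarray:
    """Pooled null moderated-t statistics from reshuffled group labels.

    Sample labels are permuted jointly for all probesets (preserving gene-gene
    correlation) within the union of the two contrast groups, and the full
    moderated-t fit (including the variance-prior estimation) is repeated each
    time.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    ga, gb = contrast
    cols = [s for s in m.columns if grouping.get(s) in (ga, gb)]
    x = m[cols].to_numpy(dtype=float)
    n1 = sum(grouping.get(s) == ga for s in cols)
    pooled = []
    for _ in range(n_perm):
        perm = rng.permutation(x.shape[1])
        xa, xb = x[:, perm[:n1]], x[:, perm[n1:]]
        _, t, _, _, _ = _moderated_t_from_arrays(xa, xb)
        pooled.append(t)
    return np.concatenate(pooled)


def empirical_fdr(
    observed_stats: np.ndarray, permuted_stats: np.ndarray, cutoff: float
) -> float:
    """Empirical FDR at a |statistic| cutoff: ``n * (FP/N) / P``, capped at 1.

    Returns 1 when no observed statistic passes the cutoff (P = 0).
    """
    obs = np.abs(np.asarray(observed_stats, dtype=float))
    perm = np.abs(np.asarray(permuted_stats, dtype=float))
    if obs.size == 0:
        raise ValueError("no observed statistics")
    if perm.size == 0:
        raise ValueError("no permutation statistics (N = 0)")
    n = obs.size
    P = int((obs >= cutoff).sum())
    if P == 0:
        return 1.0
    FP = int((perm >= cutoff).sum())
    return float(min(n * (FP / perm.size) / P, 1.0))


def empirical_fdr_curve(observed_stats: np.ndarray, permuted_stats: np.ndarray) -> np.ndarray:
    """Per-observation empirical FDR with each |statistic| as its own cutoff.

    After evaluating ``n * (FP/N) / P`` at every observed statistic, the curve
    is made monotone non-increasing in |stat| by a step-up cumulative minimum
    (from the least to the most extreme statistic), exactly mirroring BH
    step-up adjustment of the empirical permutation p-values.
    """
    obs = np.abs(np.asarray(observed_stats, dtype=float))
    perm = np.abs(np.asarray(permuted_stats, dtype=float))
    if obs.size == 0:
        raise ValueError("no observed statistics")
    n = obs.size
    order = np.argsort(-obs, kind="stable")  # descending |stat|
    sorted_obs = obs[order]
    # P at cutoff sorted_obs[k]: number of observed >= cutoff (ties included)
    P = np.searchsorted(-sorted_obs, -sorted_obs, side="right")
    FP = perm.size - np.searchsorted(np.sort(perm), sorted_obs, side="left")
    raw = n * (FP / perm.size) / P
    adj = np.minimum(np.minimum.accumulate(raw[::-1])[::-1], 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def differential_expression(
    m: pd.DataFrame,
    traits: pd.DataFrame,
    trait: str,
    contrast: tuple[str, str] = ("normal", "high"),
    n_perm: int = 5,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Moderated-t DE for one trait contrast with empirical permutation FDR.

    Returns a frame with columns log2_fc, t, p, fdr indexed by probeset.
    """
    grouping = assign_severity_groups(traits, trait)
    grouping = grouping.reindex(m.columns).dropna()
    m = m[grouping.index]
    res = moderated_t_test(m, grouping, contrast)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    null = permuted_moderated_t(m, grouping, contrast, n_perm=n_perm, rng=rng)
    table = res.table.copy()
    table["fdr"] = empirical_fdr_curve(table["t"].to_numpy(), null)
    table.attrs["contrast"] = contrast
    table.attrs["trait"] = trait
    return table


def call_degs(
    de: pd.DataFrame, fdr_threshold: float = 0.05, fc_threshold: float = 1.5
) -> dict[str, list[str]]:
    """Significant probesets: FDR < 0.05 and fold change > 1.5, split by direction.

    The fold change is the anti-log of the mean log2 difference:
    ``2 ** |log2_fc| > fc_threshold``.
    """
    sig = (de["fdr"] < fdr_threshold) & (2.0 ** de["log2_fc"].abs() > fc_threshold)
    up = de.index[sig & (de["log2_fc"] > 0)].tolist()
    down = de.index[sig & (de["log2_fc"] < 0)].tolist()
    return {"up": sorted(up), "down": sorted(down)}


def _spearman_rho_matrix(x: np.ndarray, trait_ranks: np.ndarray) -> np.ndarray:
    """Spearman rho of every row of x against a pre-ranked trait vector."""
    rx = stats.rankdata(x, axis=1)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ty = trait_ranks - trait_ranks.mean()
    denom = np.sqrt((rx**2).sum(axis=1) * (ty**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(denom > 0, rx @ ty / denom, 0.0)
    return rho


def spearman_trait_correlation(
    m: pd.DataFrame,
    trait_values: pd.Series,
    n_perm: int = 5,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Spearman correlation of every probeset with a trait + permutation FDR.

    Ties are average-ranked; the p-value uses the t approximation
    ``t = rho * sqrt((n-2)/(1-rho^2))``; the empirical FDR uses a null built by
    permuting the trait vector ``n_perm`` times.
    """
    trait_values = trait_values.dropna()
    shared = [s for s in m.columns if s in trait_values.index]
    if len(shared) < 4:
        raise ValueError("need >= 4 paired observations")
    y = trait_values.loc[shared].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("constant trait vector: Spearman rho undefined")
    x = m[shared].to_numpy(dtype=float)
    n = len(shared)
    ty = stats.rankdata(y)
    rho = _spearman_rho_matrix(x, ty)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    null = np.concatenate(
        [_spearman_rho_matrix(x, rng.permutation(ty)) for _ in range(n_perm)]
    )
    fdr = empirical_fdr_curve(rho, null)
    out = pd.DataFrame({"rho": rho, "p": p, "fdr": fdr}, index=m.index)
    out.attrs["trait"] = trait_values.name
    return out
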