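"""Synthetic multi-region cohorts, single-cell counts, and perturbation signatures.

The generators emulate the statistical structure the downstream stages assume:

* ``simulate_cohort`` — per-region log2 expression matrices containing planted
  co-expressed modules.  Each module m is driven by a latent factor; the genes
  of m are ``loading_g * latent_m + noise``.  A subset of modules ("disease
  modules") have latents correlated with a per-subject Gaussian severity
  variable, from which ordinal traits (CDR-, Braak-, CERAD-like) and
  zero-inflated quantitative lesion traits (PLQ_Mn, NPrSum, NTrSum) are derived.
  Covariates (sex, PMI, pH, race) add linear effects.
* ``simulate_single_cell_counts`` — negative-binomial read counts with planted
  cell-type marker genes, library-size offsets, and subject effects.
* ``simulate_perturbation_signature`` — a gene set concentrated in one module
  at a chosen purity, mimicking an experimental knock-down/mutation signature.
* ``simulate_two_group`` — a direct two-group design with planted fold changes,
  used for differential-expression calibration studies.

All randomness flows through one :class:`numpy.random.Generator` seeded from
the config, so identical seeds give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfigError",
    "CohortConfig",
    "SingleCellConfig",
    "CohortData",
    "SingleCellData",
    "simulate_cohort",
    "simulate_single_cell_counts",
    "simulate_perturbation_signature",
    "simulate_two_group",
]

CELL_TYPES = ("astrocyte", "endothelial", "microglia", "neuron", "oligodendrocyte")

ORDINAL_TRAITS = ("CDR", "Braak", "CERAD")
QUANTITATIVE_TRAITS = ("PLQ_Mn", "NPrSum", "NTrSum")
TRAITS = ORDINAL_TRAITS + QUANTITATIVE_TRAITS
COVARIATES = ("sex", "PMI", "pH", "race")


class ConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of a synthetic multi-region cohort.

    ``trait_effect`` is the target Pearson correlation between each disease
    module's latent factor and the severity latent; ``noise_sd`` controls the
    within-module gene-gene correlation (r = load^2 var(latent) /
    (load^2 var(latent) + noise_sd^2), roughly 0.7 at the default 0.65).
    """

    n_regions: int = 4
    n_samples_per_region: int = 60
    n_probesets: int = 500
    n_modules: int = 6
    module_size: int = 50
    n_disease_modules: int = 2
    trait_effect: float = 0.8
    trait_effect_by_region: tuple[float, ...] | None = None
    covariate_effect: float = 0.3
    noise_sd: float = 0.65
    missing_fraction: float = 0.2
    clean_fraction: float = 0.3
    module_overlap: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules * self.module_size > self.n_probesets:
            raise ConfigError(
                f"module capacity exceeded: {self.n_modules} modules x "
                f"{self.module_size} genes > {self.n_probesets} probesets"
            )
        if not 0.0 <= self.trait_effect <= 1.0:
            raise ConfigError("trait_effect must lie in [0, 1]")
        if not 0 <= self.n_disease_modules <= self.n_modules:
            raise ConfigError("n_disease_modules must lie in [0, n_modules]")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ConfigError("missing_fraction must lie in [0, 1)")
        if self.trait_effect_by_region is not None and len(
            self.trait_effect_by_region
        ) != self.n_regions:
            raise ConfigError("trait_effect_by_region must have one entry per region")
        if not 0.0 < self.module_overlap <= 1.0:
            raise ConfigError("module_overlap must lie in (0, 1]")
        extra = self.n_modules * (
            self.module_size - int(round(self.module_overlap * self.module_size))
        )
        if self.n_modules * self.module_size + extra > self.n_probesets:
            raise ConfigError(
                "module capacity exceeded: background too small for the "
                "region-specific membership draw"
            )

    def region_effects(self) -> np.ndarray:
        if self.trait_effect_by_region is not None:
            return np.asarray(self.trait_effect_by_region, dtype=float)
        return np.full(self.n_regions, self.trait_effect)


@dataclass(frozen=True)
class SingleCellConfig:
    """Configuration of a synthetic single-cell read-count matrix."""

    n_genes: int = 300
    n_cells_per_type: int = 60
    n_types: int = 5
    n_subjects: int = 3
    marker_fraction: float = 0.1
    marker_fold: float = 8.0
    dispersion: float = 0.25
    subject_sd: float = 0.2
    libsize_range: tuple[int, int] = (20_000, 60_000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.marker_fold <= 1.0:
            raise ConfigError("marker_fold must be > 1")
        if not 1 <= self.n_types <= len(CELL_TYPES):
            raise ConfigError(f"n_types must be in [1, {len(CELL_TYPES)}]")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        if self.libsize_range[0] > self.libsize_range[1] or self.libsize_range[0] <= 0:
            raise ConfigError("libsize_range must be a positive increasing pair")
        if not 0.0 <= self.marker_fraction <= 1.0:
            raise ConfigError("marker_fraction must lie in [0, 1]")


@dataclass
class CohortData:
    """Output bundle of :func:`simulate_cohort`."""

    expression: dict[str, pd.DataFrame]  # region -> probesets x samples (log2)
    traits: pd.DataFrame  # subject-indexed traits + covariates
    truth: dict = field(default_factory=dict)

    @property
    def regions(self) -> list[str]:
        return list(self.expression)


@dataclass
class SingleCellData:
    """Output bundle of :func:`simulate_single_cell_counts`."""

    counts: pd.DataFrame  # genes x cells, integer
    cell_type: pd.Series  # per-cell label
    subject: pd.Series  # per-cell label
    truth: dict = field(default_factory=dict)

    @property
    def libsize(self) -> pd.Series:
        return self.counts.sum(axis=0)


def _ordinal_from_latent(z: np.ndarray, values: Sequence[float], quantiles: Sequence[float]) -> np.ndarray:
    """Map a Gaussian latent to ordinal trait values by thresholding at quantiles."""
    edges = np.quantile(z, quantiles)
    idx = np.searchsorted(edges, z, side="right")
    return np.asarray(values, dtype=float)[idx]


def _make_traits(z: np.ndarray, clean_fraction: float, rng: np.random.Generator) -> pd.DataFrame:
    """Derive the six disease traits from the severity latent z.

    Ordinal traits threshold z at fixed quantiles (three-group severity design:
    the lowest ~30% are 'clean').  Quantitative lesion traits are zero for clean
    brains and exp(scale * z + noise) otherwise (a zero atom plus a skewed
    positive part, supporting the zero=normal / median-split grouping rule).
    """
    n = z.size
    cf = clean_fraction
    traits = pd.DataFrame(index=pd.Index([f"S{i:04d}" for i in range(n)], name="subject"))
    # CDR scale values 0, 0.5, 1, 2, 3, 4, 5
    traits["CDR"] = _ordinal_from_latent(
        z, [0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0], [cf, cf + 0.12, cf + 0.24, cf + 0.36, 0.78, 0.9]
    )
    traits["Braak"] = _ordinal_from_latent(
        z, [0, 1, 2, 3, 4, 5, 6], [0.12, 0.22, cf, 0.5, 0.66, 0.84]
    )
    # CERAD coded 0=normal, 1=possible AD, 2=probable AD, 3=definite AD
    traits["CERAD"] = _ordinal_from_latent(z, [0, 1, 2, 3], [cf, 0.5, 0.72])
    for trait, scale in zip(QUANTITATIVE_TRAITS, (0.9, 1.0, 1.1)):
        clean = z <= np.quantile(z, cf)
        vals = np.exp(scale * z + 0.3 * rng.standard_normal(n))
        vals = np.round(np.maximum(vals, 0.0), 3)
        vals[clean] = 0.0
        traits[trait] = vals
    return traits


def _make_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    cov = pd.DataFrame(index=pd.Index([f"S{i:04d}" for i in range(n)], name="subject"))
    cov["sex"] = rng.choice(["F", "M"], size=n)
    cov["PMI"] = np.round(np.clip(rng.normal(8.0, 3.0, size=n), 0.5, None), 2)
    cov["pH"] = np.round(rng.normal(6.5, 0.3, size=n), 2)
    cov["race"] = rng.choice(["A", "B", "W"], size=n, p=[0.1, 0.25, 0.65])
    return cov


def _covariate_design(cov: pd.DataFrame) -> np.ndarray:
    """Standardized numeric design used to inject covariate effects (no intercept)."""
    cols = [
        (cov["sex"] == "M").astype(float) - 0.5,
        (cov["PMI"] - cov["PMI"].mean()) / max(cov["PMI"].std(), 1e-9),
        (cov["pH"] - cov["pH"].mean()) / max(cov["pH"].std(), 1e-9),
        (cov["race"] == "B").astype(float) - (cov["race"] == "B").mean(),
        (cov["race"] == "W").astype(float) - (cov["race"] == "W").mean(),
    ]
    return np.column_stack([np.asarray(c, dtype=float) for c in cols])


def simulate_cohort(config: CohortConfig) -> CohortData:
    """Generate a synthetic multi-region cohort with planted co-expression modules.

    Returns per-region expression matrices (log2 scale), a subject trait table
    (six disease traits + four covariates), and a ground-truth record of every
    planted membership and effect.
    """
    rng = np.random.default_rng(config.seed)
    pool = int(np.ceil(config.n_samples_per_region / (1.0 - config.missing_fraction)))
    pool = max(pool, config.n_samples_per_region)
    subjects = [f"S{i:04d}" for i in range(pool)]

    severity = rng.standard_normal(pool)
    traits = _make_traits(severity, config.clean_fraction, rng)
    cov = _make_covariates(pool, rng)
    traits = pd.concat([traits, cov], axis=1)
    design = _covariate_design(cov)

    probesets = [f"PS{i:05d}" for i in range(config.n_probesets)]
    module_names = [f"M{m + 1}" for m in range(config.n_modules)]
    membership = {
        name: probesets[m * config.module_size : (m + 1) * config.module_size]
        for m, name in enumerate(module_names)
    }
    disease_modules = module_names[: config.n_disease_modules]
    background = list(range(config.n_modules * config.module_size, config.n_probesets))
    core_n = int(round(config.module_overlap * config.module_size))
    baseline = rng.normal(8.0, 1.5, size=config.n_probesets)
    loadings = rng.uniform(0.7, 1.3, size=config.n_probesets)
    cov_betas = rng.normal(0.0, config.covariate_effect, size=(config.n_probesets, design.shape[1]))

    effects = config.region_effects()
    expression: dict[str, pd.DataFrame] = {}
    latents: dict[str, pd.DataFrame] = {}
    region_subjects: dict[str, list[str]] = {}
    region_modules: dict[str, dict[str, list[str]]] = {}
    for r in range(config.n_regions):
        region = f"R{r + 1}"
        keep = np.sort(rng.choice(pool, size=config.n_samples_per_region, replace=False))
        samp = [subjects[i] for i in keep]
        region_subjects[region] = samp
        n = len(samp)
        te = float(np.clip(effects[r], 0.0, 1.0))

        lat = np.empty((config.n_modules, n))
        for m, name in enumerate(module_names):
            eps = rng.standard_normal(n)
            if name in disease_modules:
                lat[m] = te * severity[keep] + np.sqrt(max(1.0 - te**2, 0.0)) * eps
            else:
                lat[m] = eps
        latents[region] = pd.DataFrame(lat, index=module_names, columns=samp)

        # region-specific membership: each module keeps a shared core of
        # round(module_overlap * module_size) genes; the remainder is drawn
        # from the background pool per region (consensus-with-variation)
        n_extra = config.module_size - core_n
        extra_pool = rng.permutation(background)
        reg_members: dict[str, list[int]] = {}
        for m, name in enumerate(module_names):
            core = list(range(m * config.module_size, m * config.module_size + core_n))
            extra = list(extra_pool[m * n_extra : (m + 1) * n_extra])
            reg_members[name] = core + extra

        x = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(config.n_probesets, n))
        for m, name in enumerate(module_names):
            rows = np.asarray(reg_members[name])
            x[rows] += loadings[rows, None] * lat[m][None, :]
        x += cov_betas @ design[keep].T
        expression[region] = pd.DataFrame(x, index=probesets, columns=samp)
        region_modules[region] = {
            name: [probesets[i] for i in sorted(idx)] for name, idx in reg_members.items()
        }

    truth = {
        "modules": membership,
        "region_modules": region_modules,
        "disease_modules": disease_modules,
        "severity": pd.Series(severity, index=subjects, name="severity"),
        "latents": latents,
        "loadings": pd.Series(loadings, index=probesets),
        "covariate_betas": cov_betas,
        "region_subjects": region_subjects,
        "trait_effect_by_region": {f"R{r + 1}": float(effects[r]) for r in range(config.n_regions)},
    }
    return CohortData(expression=expression, traits=traits, truth=truth)


def simulate_single_cell_counts(config: SingleCellConfig) -> SingleCellData:
    """Generate NB-distributed single-cell counts with planted cell-type markers.

    Counts follow NB(mu, dispersion) with
    ``log mu = log(libsize) + baseline_g + log(marker_fold) * 1[g marker of
    type(c)] + subject_effect`` and ``var = mu + dispersion * mu^2``.
    """
    rng = np.random.default_rng(config.seed)
    types = list(CELL_TYPES[: config.n_types])
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    n_cells = config.n_cells_per_type * config.n_types
    cells = [f"C{i:04d}" for i in range(n_cells)]

    cell_type = np.repeat(types, config.n_cells_per_type)
    subject = rng.choice([f"D{j + 1}" for j in range(config.n_subjects)], size=n_cells)

    n_markers = int(round(config.marker_fraction * config.n_genes))
    marker_genes = list(rng.choice(config.n_genes, size=n_markers, replace=False))
    markers: dict[str, list[str]] = {t: [] for t in types}
    for i, g in enumerate(marker_genes):
        markers[types[i % config.n_types]].append(genes[g])

    # Baselines on the log-proportion scale so counts scale with library size.
    baseline = np.log(1.0 / config.n_genes) + rng.normal(0.0, 1.0, size=config.n_genes)
    gamma = {
        f"D{j + 1}": rng.normal(0.0, config.subject_sd) for j in range(config.n_subjects)
    }
    libsize = rng.integers(config.libsize_range[0], config.libsize_range[1] + 1, size=n_cells)

    marker_of = {g: t for t, gs in markers.items() for g in gs}
    log_fold = np.zeros((config.n_genes, n_cells))
    for gi, g in enumerate(genes):
        t = marker_of.get(g)
        if t is not None:
            log_fold[gi, cell_type == t] = np.log(config.marker_fold)

    log_mu = (
        np.log(libsize)[None, :]
        + baseline[:, None]
        + log_fold
        + np.array([gamma[s] for s in subject])[None, :]
    )
    mu = np.exp(log_mu)
    if config.dispersion > 0:
        r = 1.0 / config.dispersion
        lam = rng.gamma(shape=r, scale=mu / r)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mu)

    truth = {
        "markers": markers,
        "marker_fold": config.marker_fold,
        "baseline": pd.Series(baseline, index=genes),
        "subject_effects": gamma,
        "dispersion": config.dispersion,
    }
    return SingleCellData(
        counts=pd.DataFrame(counts, index=genes, columns=cells),
        cell_type=pd.Series(cell_type, index=cells, name="cell_type"),
        subject=pd.Series(subject, index=cells, name="subject"),
        truth=truth,
    )


def simulate_perturbation_signature(
    module: Sequence[str],
    background: Sequence[str],
    purity: float,
    size: int,
    seed: int | np.random.Generator = 0,
) -> list[str]:
    """Draw a perturbation signature: ``round(purity * size)`` genes from the
    target module, the remainder uniformly from the background minus the module.
    """
    if not 0.0 <= purity <= 1.0:
        raise ConfigError("purity must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    module = list(dict.fromkeys(module))
    off_module = [g for g in dict.fromkeys(background) if g not in set(module)]
    n_in = int(round(purity * size))
    n_out = size - n_in
    if n_in > len(module):
        raise ConfigError(f"module has {len(module)} genes; cannot draw {n_in}")
    if n_out > len(off_module):
        raise ConfigError(
            f"background minus module has {len(off_module)} genes; cannot draw {n_out}"
        )
    sig = list(rng.choice(module, size=n_in, replace=False)) + list(
        rng.choice(off_module, size=n_out, replace=False)
    )
    return sorted(sig)


def simulate_two_group(
    n_probesets: int = 5000,
    n_per_group: int = 20,
    de_fraction: float = 0.0,
    log2_fc: float = 1.0,
    noise_sd: float = 0.65,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Two-group log2 expression with a planted fraction of DE probesets.

    Returns (matrix, group labels 'A'/'B', list of planted DE probesets).
    Planted probesets shift by ``log2_fc`` in group B, sign random per probeset.
    """
    rng = np.random.default_rng(seed)
    probesets = [f"PS{i:05d}" for i in range(n_probesets)]
    n = 2 * n_per_group
    samples = [f"X{i:03d}" for i in range(n)]
    groups = pd.Series(["A"] * n_per_group + ["B"] * n_per_group, index=samples, name="group")
    baseline = rng.normal(8.0, 1.5, size=n_probesets)
    x = baseline[:, None] + rng.normal(0.0, noise_sd, size=(n_probesets, n))
    n_de = int(round(de_fraction * n_probesets))
    de_idx = rng.choice(n_probesets, size=n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    for i, s in zip(de_idx, signs):
        x[i, n_per_group:] += s * log2_fc
    de_genes = sorted(probesets[i] for i in de_idx)
    return pd.DataFrame(x, index=probesets, columns=samples), groups, de_genes
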