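"""End-to-end orchestration: simulate -> preprocess -> associate -> network ->
meta-network -> enrich -> rank, with a JSON manifest recording parameters,
seeds, and output-file hashes.

The pipeline is the library's stages glued together on a synthetic cohort (or
user-supplied TSV inputs); every stage writes its tables under the output
directory and any failure aborts with the failing stage named.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import spearmanr

from . import association, coexpr, enrichment, io, metanet, ranking, synthdata
from .association import CONTRASTS
from .preprocess import quantile_normalize, residualize_covariates
from .synthdata import COVARIATES, TRAITS, CohortConfig

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("regionrank")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


_SCHEMA: dict[str, type] = {
    "out_dir": str,
    "seed": int,
    "expression_dir": (str, type(None)),
    "traits_file": (str, type(None)),
    "beta": int,
    "min_module_size": int,
    "deep_split": int,
    "n_permutations": int,
    "fdr_threshold": float,
    "fc_threshold": float,
    "cohort": dict,
}


@dataclass
class RunConfig:
    """Validated run configuration (YAML-loadable)."""

    out_dir: str = "regionrank_out"
    seed: int = 0
    expression_dir: str | None = None  # pre-existing inputs; None = simulate
    traits_file: str | None = None
    beta: int = 6
    min_module_size: int = 30
    deep_split: int = 2
    n_permutations: int = 5
    fdr_threshold: float = 0.05
    fc_threshold: float = 1.5
    cohort: dict = field(default_factory=dict)  # CohortConfig overrides

    def __post_init__(self) -> None:
        for name in ("beta", "min_module_size", "n_permutations"):
            if getattr(self, name) <= 0:
                raise PipelineError(f"config: {name} must be positive")
        for name in ("fdr_threshold", "fc_threshold"):
            if getattr(self, name) <= 0:
                raise PipelineError(f"config: {name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(_SCHEMA)
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        for key, val in raw.items():
            if not isinstance(val, _SCHEMA[key]):
                raise PipelineError(f"config: key {key!r} has wrong type")
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name: str):
    def wrap(fn):
        def run(*args, **kwargs):
            t0 = time.time()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - named-stage contract
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s done in %.1fs", name, time.time() - t0)
            return out

        return run

    return wrap


@_stage("simulate")
def _simulate(cfg: RunConfig) -> synthdata.CohortData:
    cohort_cfg = CohortConfig(**{"seed": cfg.seed, **cfg.cohort})
    return synthdata.simulate_cohort(cohort_cfg)


@_stage("load")
def _load(cfg: RunConfig) -> synthdata.CohortData:
    exp_dir = Path(cfg.expression_dir)
    if cfg.traits_file is None or not Path(cfg.traits_file).exists():
        raise FileNotFoundError(f"traits file {cfg.traits_file!r} not found")
    traits = io.read_table_tsv(cfg.traits_file)
    expression = {
        p.stem.replace("expression_", ""): io.read_expression_tsv(p)
        for p in sorted(exp_dir.glob("expression_*.tsv"))
    }
    if not expression:
        raise FileNotFoundError(f"no expression_*.tsv under {exp_dir}")
    return synthdata.CohortData(expression=expression, traits=traits)


@_stage("preprocess")
def _preprocess(cohort: synthdata.CohortData) -> dict[str, pd.DataFrame]:
    cov = cohort.traits[list(COVARIATES)]
    out = {}
    for region, m in cohort.expression.items():
        out[region] = residualize_covariates(quantile_normalize(m), cov)
    return out


@_stage("associate")
def _associate(cfg: RunConfig, expr: dict[str, pd.DataFrame], traits: pd.DataFrame):
    if traits is None:
        raise ValueError("no trait table available")
    rng = np.random.default_rng(cfg.seed + 1)
    de_tables, tcg_tables = {}, {}
    deg_sets, tcg_sets = {}, {}
    for region, m in expr.items():
        for trait in TRAITS:
            for contrast in CONTRASTS:
                de = association.differential_expression(
                    m, traits, trait, contrast, n_perm=cfg.n_permutations, seed=rng
                )
                de_tables[(region, trait, contrast)] = de
                degs = association.call_degs(de, cfg.fdr_threshold, cfg.fc_threshold)
                deg_sets[(region, trait, contrast)] = degs
            tv = pd.to_numeric(traits[trait], errors="coerce").dropna()
            tcg = association.spearman_trait_correlation(
                m, tv.rename(trait), n_perm=cfg.n_permutations, seed=rng
            )
            tcg_tables[(region, trait)] = tcg
            tcg_sets[(region, trait)] = sorted(tcg.index[tcg["fdr"] < cfg.fdr_threshold])
    return de_tables, tcg_tables, deg_sets, tcg_sets


@_stage("network")
def _network(cfg: RunConfig, expr: dict[str, pd.DataFrame]):
    return {
        region: coexpr.build_network_modules(
            m,
            region=region,
            beta=cfg.beta,
            min_module_size=cfg.min_module_size,
            deep_split=cfg.deep_split,
        )
        for region, m in expr.items()
    }


@_stage("meta")
def _meta(cfg: RunConfig, networks: dict[str, coexpr.RegionNetwork]):
    eg = {r: net.eigengenes for r, net in networks.items() if len(net.eigengenes)}
    meta = (
        metanet.build_meta_network(eg, beta=cfg.beta, min_overlap=4) if len(eg) >= 2 else None
    )
    jaccard_tables = []
    n_conserved = 0
    regions = sorted(networks)
    for i, ra in enumerate(regions):
        for rb in regions[i + 1 :]:
            tab, cnt = metanet.module_jaccard_conservation(
                networks[ra].assignment, networks[rb].assignment
            )
            tab.insert(0, "region_a", ra)
            tab.insert(2, "region_b", rb)
            jaccard_tables.append(tab)
            n_conserved += cnt
    jaccard = (
        pd.concat(jaccard_tables, ignore_index=True) if jaccard_tables else pd.DataFrame()
    )
    return meta, jaccard, n_conserved


@_stage("rank")
def _rank(cfg: RunConfig, expr, traits, networks, deg_sets, tcg_sets, de_tables, tcg_tables):
    regions = sorted(expr)
    # regions: 18 DEG-count + 6 TCG-count variables
    cols = {}
    for trait in TRAITS:
        for contrast in CONTRASTS:
            cols[f"DEG_{trait}_{contrast[0]}-{contrast[1]}"] = [
                len(deg_sets[(r, trait, contrast)]["up"])
                + len(deg_sets[(r, trait, contrast)]["down"])
                for r in regions
            ]
        cols[f"TCG_{trait}"] = [len(tcg_sets[(r, trait)]) for r in regions]
    region_K = pd.DataFrame(cols, index=regions)
    region_ranking = ranking.rank_regions(region_K)

    # modules: 6 eigengene-trait P + 18 DEG enrichment P + 6 TCG enrichment P
    rows = {}
    for r in regions:
        net = networks[r]
        universe = list(expr[r].index)
        mods = net.assignment.module_sets()
        for mod, genes in mods.items():
            key = f"{r}:{mod}"
            rec = {}
            eg = net.eigengenes.loc[mod]
            for trait in TRAITS:
                tv = pd.to_numeric(traits[trait], errors="coerce").reindex(eg.index).dropna()
                if tv.nunique() > 1:
                    rec[f"eig_{trait}_p"] = float(
                        spearmanr(eg.loc[tv.index], tv).pvalue
                    )
                else:
                    rec[f"eig_{trait}_p"] = 1.0
                for contrast in CONTRASTS:
                    dset = deg_sets[(r, trait, contrast)]
                    degs = dset["up"] + dset["down"]
                    rec[f"deg_{trait}_{contrast[0]}-{contrast[1]}_p"] = enrichment.fisher_enrichment(
                        genes, degs, universe
                    ).p
                rec[f"tcg_{trait}_p"] = enrichment.fisher_enrichment(
                    genes, tcg_sets[(r, trait)], universe
                ).p
            rows[key] = rec
    module_ranking = (
        ranking.rank_modules(pd.DataFrame(rows).T) if rows else None
    )

    # genes: DE p (normal vs high) and Spearman p per region x trait
    gene_cols = {}
    for r in regions:
        for trait in TRAITS:
            gene_cols[f"{r}_{trait}_de_p"] = de_tables[(r, trait, ("normal", "high"))]["p"]
            gene_cols[f"{r}_{trait}_tcg_p"] = tcg_tables[(r, trait)]["p"]
    gene_ranking = ranking.rank_genes(pd.DataFrame(gene_cols))
    return region_ranking, module_ranking, gene_ranking


def run_pipeline(config: RunConfig | str | Path) -> dict:
    """Execute every stage in dependency order; returns the manifest dict.

    The manifest (also written to ``<out_dir>/manifest.json``) records the
    configuration, the seed, per-stage status, and a sha256 hash of every
    output file.
    """
    cfg = RunConfig.from_yaml(config) if not isinstance(config, RunConfig) else config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = {"seed": cfg.seed, "beta": cfg.beta, "min_module_size": cfg.min_module_size}
    manifest: dict = {"config": asdict(cfg), "stages": [], "outputs": {}}

    cohort = _load(cfg) if cfg.expression_dir else _simulate(cfg)
    manifest["stages"].append("simulate" if not cfg.expression_dir else "load")
    for region, m in cohort.expression.items():
        io.write_expression_tsv(m, out / f"expression_{region}.tsv", params)
    io.write_table_tsv(cohort.traits, out / "traits.tsv", params)

    has_cov = all(c in cohort.traits.columns for c in COVARIATES)
    expr = _preprocess(cohort) if has_cov else dict(cohort.expression)
    manifest["stages"].append("preprocess")
    for region, m in expr.items():
        io.write_expression_tsv(m, out / f"normalized_{region}.tsv", params)

    de_tables, tcg_tables, deg_sets, tcg_sets = _associate(cfg, expr, cohort.traits)
    manifest["stages"].append("associate")
    deg_gmt = {
        f"{r}_{t}_{c[0]}-{c[1]}_{d}": genes
        for (r, t, c), dd in deg_sets.items()
        for d, genes in dd.items()
        if genes
    }
    io.write_gmt(deg_gmt, out / "degs.gmt")
    io.write_gmt(
        {f"{r}_{t}": g for (r, t), g in tcg_sets.items() if g}, out / "tcgs.gmt"
    )

    networks = _network(cfg, expr)
    manifest["stages"].append("network")
    for region, net in networks.items():
        io.write_table_tsv(
            net.assignment.labels.to_frame(), out / f"modules_{region}.tsv", params
        )
        if len(net.eigengenes):
            io.write_table_tsv(net.eigengenes, out / f"eigengenes_{region}.tsv", params)

    meta, jaccard, n_conserved = _meta(cfg, networks)
    manifest["stages"].append("meta")
    if meta is not None:
        io.write_table_tsv(
            pd.DataFrame(
                {"meta_module": meta.meta_modules, "region": meta.region_of}
            ),
            out / "meta_modules.tsv",
            params,
        )
    if len(jaccard):
        io.write_table_tsv(jaccard, out / "jaccard.tsv", params, index=False)
    manifest["n_conserved_module_pairs"] = n_conserved

    region_ranking, module_ranking, gene_ranking = _rank(
        cfg, expr, cohort.traits, networks, deg_sets, tcg_sets, de_tables, tcg_tables
    )
    manifest["stages"].append("rank")
    io.write_table_tsv(region_ranking.table, out / "region_ranking.tsv", params)
    if module_ranking is not None:
        io.write_table_tsv(module_ranking.table, out / "module_ranking.tsv", params)
    io.write_table_tsv(gene_ranking.table, out / "gene_ranking.tsv", params)

    for p in sorted(out.glob("*.tsv")):
        manifest["outputs"][p.name] = _sha256(p)
    io.write_json(manifest, out / "manifest.json")
    return manifest
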