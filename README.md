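# regionrank

Multi-region transcriptomic association, weighted co-expression network, and
ensemble ranking analysis.

## The problem

In progressive neurodegeneration — Alzheimer's disease being the canonical
case — different brain regions are affected at different times and to
different degrees. Given expression matrices from many regions of the same
post-mortem cohort, plus per-subject cognitive and neuropathological traits
(CDR, Braak stage, CERAD rating, plaque and tangle density summaries), the
analytical question is: *which regions, which gene modules, and which genes
are most strongly tied to disease severity?*

`regionrank` implements the full analysis chain for this question, driven by
a synthetic-cohort generator so every stage is testable against planted
ground truth:

1. **Preprocessing** — platform merging, quantile normalization, OLS removal
   of covariates (sex, PMI, pH, race).
2. **Association** — differential expression between severity groups with an
   empirical-Bayes moderated t, empirical permutation FDR
   (FDR = n·(FP/N)/P), and a fold-change filter; Spearman trait-correlated
   genes under the same permutation FDR.
3. **Cell-type markers** — Bayesian negative-binomial regression of
   single-cell counts (own MCMC sampler); a gene is type-specific when
   enriched at 99.9% posterior probability in exactly one type with > 5-fold
   expression over basal.
4. **Co-expression networks** — soft-threshold adjacency |cor|^β (β = 6),
   topological overlap matrix, average-linkage clustering with a dynamic
   tree cut, module eigengenes (first PC of standardized module expression).
5. **Meta-network** — the same network machinery over all regions' module
   eigengenes; module conservation by Jaccard index; cross-region correlated
   probeset-pair counts.
6. **Validation** — Fisher over-representation with BH control, and
   perturbation-signature validation of modules via one-tailed rank-sum
   comparison of target-harboring vs other modules.
7. **Ensemble ranking** — the composite importance score
   S_i = (∏_j f(K_ij))^{1/n}, scaled to [0, 1], with f(K) = ln(1+K) for gene
   counts (regions) and f(P) = −ln P for P-values (modules, genes).

See `docs/methods.md` for the models, priors, and numerical choices.

## Worked example

```python
from regionrank import (CohortConfig, simulate_cohort, differential_expression,
                        call_degs, build_network_modules,
                        module_jaccard_conservation)

cohort = simulate_cohort(CohortConfig(seed=1))      # 4 regions, 500 probesets
m = cohort.expression["R1"]

de = differential_expression(m, cohort.traits, "CDR", ("normal", "high"),
                             n_perm=20, seed=1)
degs = call_degs(de)                                # FDR < 0.05 and FC > 1.5
print(f"CDR high vs normal in R1: {len(degs['up'])} up, {len(degs['down'])} down")

net = build_network_modules(m, region="R1")
print(f"{len(net.assignment.module_sets())} modules, "
      f"{net.assignment.assigned_fraction:.0%} of probesets assigned, "
      f"scale-free R2 = {net.scale_free_r2:.2f}")

net2 = build_network_modules(cohort.expression["R2"], region="R2")
_, n = module_jaccard_conservation(net.assignment, net2.assignment)
print(f"{n} cross-region module pairs with Jaccard > 0.5")
```

Output:

```
CDR high vs normal in R1: 89 up, 1 down
6 modules, 60% of probesets assigned, scale-free R2 = 0.89
6 cross-region module pairs with Jaccard > 0.5
```

The cohort plants six 50-gene modules, two of them driven by a latent
severity variable at correlation 0.8. The DE screen finds the disease-module
genes (two modules × ~50 genes, minus fold-change censoring); the network
stage recovers all six planted modules (the remaining 40% of probesets are
unstructured background, correctly left grey); and all six modules are
conserved between regions at Jaccard > 0.5, reflecting the generator's 80%
shared module cores.

The same stages are available from the shell:

```bash
regionrank simulate cohort --out sim/ --seed 1
regionrank de --expr sim/expression_R1.tsv --traits sim/traits.tsv \
          --trait CDR --contrast normal:high --out de.tsv --seed 1
regionrank network --expr sim/expression_R1.tsv --out-prefix R1
regionrank run --config pipeline.yaml     # full end-to-end with manifest
```

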