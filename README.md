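# netpharm

Network-pharmacology inference for multi-compound drugs. Given a background
protein–protein interactome, a set of drug targets and a set of disease
genes, the package asks: *does this drug act on the same network
neighbourhood as the disease?* — and surrounds that core statistic with the
standard companions of a network-pharmacology study: drug-similarity
fingerprints with hierarchical clustering, gene-set enrichment, and a
clinical meta-analysis engine. A synthetic-data module generates every input
with planted, tunable structure, so the whole chain runs and is tested
without any external database.

## The statistics at the core

**Propagation association.** Drug targets and disease genes are each used as
seeds of a Random Walk with Restart on the interactome (restart probability
r = 0.75, column-stochastic transitions W = A·D⁻¹). The stationary
distributions p = r·e + (1−r)·W·p are the *influence score vectors* of the
two seed sets. Their Pearson correlation `Cor` is standardized against a
permutation null built from random contrast disease sets (uniformly drawn
node sets of the same size, 1,000 by default):

    Z = (Cor − E(Cor)) / δ(Cor),    significant when Z > 3.

**Drug similarity.** Three fingerprints over a compound panel:
Tanimoto |a∧b|/|a∨b| on structure bitsets; the interactome separation
measure S_AB = ⟨d_AB⟩ − (⟨d_AA⟩+⟨d_BB⟩)/2 on target modules (smaller =
closer); and PathSim along the compound→target→function→target→compound
metapath, s(x,y) = 2·M_xy/(M_xx+M_yy) with M = (CF)(CF)ᵀ. Each N×N matrix is
clustered by average-linkage agglomeration with deterministic tie-breaks.

**Enrichment.** Preranked GSEA (weighted Kolmogorov–Smirnov running sum,
random gene-set null, NES/p/q), hypergeometric over-representation with
Benjamini–Hochberg correction, strict DEG thresholding (FDR < 0.05,
|log2FC| > 1.5) and unique-ortholog collapse.

**Meta-analysis.** Per-study MD / log-RR / log-OR effects, Cochran's Q and
I², inverse-variance fixed-effect and DerSimonian–Laird random-effects
pooling, with the conventional I² ≥ 50% rule selecting the model, 95% normal
CIs and forest tables.

## Worked example

The numbered drivers under `analysis/` run the full synthetic experiment
(simulate → associate → similarity → cluster → enrich → meta); every stage
communicates through files under `results/pipeline/`:

```sh
python analysis/01_simulate.py
python analysis/02_association.py
python analysis/03_similarity_clustering.py
python analysis/04_enrichment.py
python analysis/05_meta_analysis.py
```

Output of `02_association.py`:

```
drug_positive: z = 5.02 (significant at Z>3)
drug_negative: z = -1.62 (not significant at Z>3)
finding: planted proximity drives the association statistic (z_pos - z_neg = 6.64)
```

The positive-control drug has 90% of its targets planted in the 1-hop
neighbourhood of the disease module and clears the Z > 3 rule; the
negative-control drug (all targets remote) does not — the synthetic analogue
of testing an active drug against an unrelated one. `03` reports that all
three fingerprints recover the three planted compound groups exactly
(ARI = 1.0), `04` recovers the planted gene set by GSEA (NES = 3.19,
p ≈ 0.0013) and over-representation, and `05` pools 30 synthetic studies
(`pooled MD = 5.11 [95% CI 4.74, 5.49]`, I² = 49.0% → fixed-effects model).

The same stages are exposed as a CLI (`netpharm run --config run.json`, plus
`rwr`, `associate`, `similarity`, `cluster`, `enrich`, `meta` subcommands)
and as plain library calls (see `netpharm.pipeline.run_pipeline`).

## Layout

- `src/netpharm/` — library: `synthetic_data`, `graph_io`, `propagation`,
  `association`, `similarity`, `clustering`, `enrichment`, `meta_analysis`,
  `pipeline`, `cli`.
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — pytest suite including property tests and oracle cross-checks.
- `docs/methods.md` — models, assumptions, parameter defaults, limitations.
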