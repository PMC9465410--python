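# Methods

## Scope and design

The package implements the inference chain of a network-pharmacology study as
a reusable, tested pipeline: network-propagation association between a drug's
targets and a disease's genes; three drug-similarity fingerprints with
hierarchical clustering; gene-set enrichment; and a fixed/random-effects
meta-analysis engine. Real studies of this kind run on a curated interactome
(~16,000 proteins), database-mined target and disease gene sets,
transcriptome-derived ranked lists and dozens of extracted clinical trials.
None of those inputs are redistributable here, so a synthetic-data module
generates all of them with planted, tunable structure, and validation is
property-based: calibration of the statistics under their own null, and
recovery of planted signal as the generator's effect knobs are turned.

## Network propagation and the association Z-score

The walk operates on the largest connected component (scores on other
components are identically determined; distances across components are
infinite), with column-stochastic transitions W = A·D⁻¹ — each step moves to
a neighbour with probability proportional to edge weight. Symmetric
normalization was rejected to preserve the probabilistic reading of the
influence vector. The restart probability defaults to 0.75, the conventional
value of the propagation tooling this follows; it is exposed as a flag
everywhere. The seed vector is uniform over the seeds present in the graph
(absent seeds are dropped with a logged count and recorded in the result);
degree-weighted seeding was rejected for lack of a principled weight.

The power iteration stops when the L1 change between iterates falls below
`tol` (default 1e-10, max 10,000 iterations); every returned vector satisfies
the fixed-point equation to within 10·tol, sums to one and is non-negative.
For workloads needing many vectors on one graph (the permutation null), an
LU factorization of I − (1−r)W turns each seed set into a triangular solve —
the exact same fixed point, computed directly; tests assert the two routes
agree to 1e-8.

The association statistic correlates (Pearson, raw scores) the drug and
disease influence vectors over *all* nodes of the component, seeds included:
excluding seeds would change the vector length per null replicate, and the
statistic's definition does not call for exclusion. The null randomizes the
disease side only — random contrast disease sets of the same size, drawn
uniformly without replacement (1,000 replicates by default) — and
Z = (Cor − mean)/sd of that null, with Z > 3 the significance call.
Degree-matched null sampling is a known alternative; uniform sampling is the
stated design here and the calibration tests show Z is close to standard normal
under it. Calibration: drug sets drawn by the same uniform mechanism yield
Z with mean ≈ 0 and sd ≈ 1 (asserted to [−0.2, 0.2] and [0.8, 1.2] over 200
replicates).

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of an integer seed (bit-identical reruns;
no global RNG state).

* **Interactome** — Barabási–Albert preferential attachment, 500 nodes with
  2 edges per new node by default. Preferential attachment is used because
  the association statistic's behaviour depends on hubs; a stochastic-block
  alternative was rejected as needless structure. The reduced scale keeps the
  *path-length geometry* of a large interactome (mean shortest path ≈ 4–5,
  heavy-tailed degrees) rather than its mean degree: a dense 500-node graph
  would have diameter ≈ 2 and planted proximity would be meaningless.
* **Seed sets** — the disease module is a BFS ball of 25 nodes around a
  random root (disease genes cluster in interactomes; a connected module is
  the cleanest embodiment). The drug-target set has the same size;
  round(proximity·25) members come from the ball's 1-hop closure and the
  rest are uniform outside it. Near-targets are sampled by picking a random
  ball member and then a uniform member of its closed neighbourhood. The
  alternative — uniform over the whole closure — makes the planted signal
  strength depend on whether the ball happens to contain a hub (hub balls
  have closures of hundreds of nodes, so uniform draws scatter to the
  periphery); that is an artifact of the generator, not a property of the
  method under test, so the member-then-neighbour scheme is used. The default
  proximity 0.9 defines the positive-control drug; the negative control uses
  proximity 0.
* **Annotations and fingerprints** — 12 compounds in 3 planted groups;
  targets and GO-like functions are partitioned into per-group blocks, with
  dense (0.9) in-block and sparse (0.05) out-of-block incidence. Structure
  fingerprints are 256-bit vectors: one Bernoulli(0.2) prototype per group,
  members mutated at flip rate 0.02 (0.05 in the recovery stress tests). For
  independent prototypes of density d the expected between-group Tanimoto is
  d/(2−d), which the tests check. For the separation fingerprint the
  annotation targets are placed on interactome nodes, one BFS ball per group
  around greedily-far-apart roots, so all three fingerprints share the same
  planted truth.
* **Ranked lists** — standard-normal scores with a planted set shifted by
  +3 (50 of 1,000 genes); shift 0 gives the exchangeable null used for
  p-value calibration.
* **Study tables** — study-level true effects θᵢ ~ N(4.89, τ²) with 30
  studies by default, emulating a synthesis of blood-flow-velocity mean
  differences at that scale; τ² defaults to 1. Arm sizes are uniform on
  [30, 100], the common SD uniform on [4, 8], observed means are normal
  around the truth and observed SDs follow the χ² sampling distribution, so
  the study MD is an unbiased estimate of θᵢ and Q is calibrated (mean ≈ df
  at τ² = 0). The binary variant links the risk ratio to θᵢ on the log scale
  with baseline risk 0.3.

What the generator does **not** emulate: real interactome topology beyond
degree heavy tails (no modules-within-modules, no edge confidence
structure), real compound chemistry (no SMILES; fingerprints are abstract
bitsets), correlated gene scores, or non-normal study-level effects.
Passing tests therefore demonstrate calibration and recovery of the
*statistics*, not performance on any particular real dataset.

## Similarity and clustering

Separation S_AB uses unweighted hop counts (the measure is topological; using
confidence-weighted distances is a different statistic) and the
closest-member convention: ⟨d_AA⟩ averages each member's distance to its
nearest *other* member (0 for singletons — the "no other member" case;
callers can opt into NaN propagation by checking set sizes), and ⟨d_AB⟩
averages, over all nodes of both sets, the distance to the nearest member of
the opposite set, shared nodes contributing 0. This convention makes
S_AA ≤ 0, which is what lets S_AB read as a separation. Tanimoto defines two
all-zero vectors as identical (similarity 1) and an all-zero against a
nonzero vector as 0, keeping the matrix total for clustering. PathSim uses
0/1 incidences; term-evidence weighting is out of scope.

Clustering maps similarity to distance by 1 − s for the bounded kinds and by
the affine shift s − min(s) for separation (order-preserving; a rank
transform would discard the geometry), then runs a native O(N³)
agglomerative merge with Lance–Williams updates. Average linkage is the
default (robust for similarity profiles); complete and single are available.
Ties break deterministically on the lexicographically smallest cluster-id
pair, so runs are exactly reproducible; the scipy implementation serves as
an independent oracle in the tests, not as the implementation. Newick export
hangs children at half the merge height (ultrametric).

## Enrichment

The preranked enrichment score is the signed maximum deviation of the
weighted running sum (hits add |score|ᵖ normalized by total hit weight,
p = 1 by default, p = 0 giving the classic KS statistic; misses subtract
1/(N − N_hit)). It is computed in closed form at the only candidate extrema
(just after each hit, just before each hit), which also vectorizes over
permutations; a literal per-gene loop is the test oracle. The null permutes
gene labels (random same-size sets): sample-level phenotype permutation
requires per-sample data that a preranked analysis does not have. NES
divides ES by the mean |null ES| of matching sign; p is the one-sided
add-one permutation fraction among sign-matched nulls (hence conservative,
never exactly zero); for a single queried set the permutation FDR q equals
p, and `gsea_fdr` implements the across-set q with sign-stratified pooling
and a monotonicity pass. DEG thresholds are strict inequalities
(FDR < 0.05, |log2FC| > 1.5) exactly as conventionally printed; boundary
records are excluded. Ortholog collapse keeps only 1:1 mappings — dropping
multi-mapped genes is order-independent, "keep first" is not.

## Meta-analysis

Inverse-variance pooling for both continuous and binary effects (one engine;
Mantel–Haenszel is a known alternative for sparse binary data and is out of
scope). DerSimonian–Laird τ² = max(0, (Q − df)/(Σw − Σw²/Σw)) with
fixed-effect weights, re-weighting by 1/(vᵢ + τ²); when Q ≤ df the
random-effects result equals the fixed-effect result exactly. Model
selection under `auto` follows the conventional rule: I² ≥ 50% → random
effects. Zero binary cells get the 0.5 continuity correction applied to the
affected study's four cells; double-zero studies carry no ratio information
and are excluded with a warning. CIs are normal-approximation ±1.96·se,
matching the reporting style of the synthesis tools this mirrors. The
statsmodels implementation is the independent oracle in tests. Validation is
by estimation properties: fixed-model 95% CI coverage 93–97% at τ² = 0
(1,000 replicates), median τ̂² within a factor-2 band on 30-study tables
generated at τ² = 4 (100 replicates), and correct firing of the I² rule on
homogeneous vs heterogeneous generators.

## Numerical and interface choices

* Node identifiers are opaque strings; ortholog maps are explicit two-column
  files — no species logic in the IO layer.
* Duplicate edges collapse to max weight; self-loops are dropped and
  counted; parsers never silently discard a record without logging it.
* Ranked lists are strictly ordered, ties broken by gene name, so every
  enrichment walk is well defined.
* The pipeline communicates between stages only via files and writes a
  manifest with per-stage summaries and content hashes; manifests are
  bit-identical across reruns of the same config.
* Problem sizes in the test-suite simulations (300–500-node graphs, 200–1,000
  replicates, 200–1,000 permutations) were chosen as the smallest scales at
  which the calibration bands above are stable; the package's own default
  conditions are stated in the synthetic-data section.

## Known limitations

* The restart-probability phrasing in the source methodology is ambiguous
  ("0.75 % of the restart probability"); 0.75 — the standard value of the
  cited propagation package — is the default, and the flag accepts any value
  in (0,1), including a literal 0.0075.
* Whether real analyses of this kind correlate over all network nodes or a
  subset is typically unstated; all-node correlation is the documented
  assumption here.
* Uniform (not degree-matched) null sampling follows the stated design;
  hub-heavy disease sets will have slightly conservative Z under
  degree-matched alternatives.
* No significance testing of S_AB (no degree-preserving permutation
  z-scores); raw similarities are clustered, as in the study design this
  follows.
* Headline numbers of any particular real study (specific NES values, pooled
  MDs/RRs) require that study's data and are out of numeric scope; the
  acceptance machinery reports the synthetic analogues instead.
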