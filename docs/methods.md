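# Methods

## Model

A binary HTS-PPI dataset is an undirected graph G = (V, E) over proteins V.
The interactome weight (IW) matrix Y ∈ {0,1}^{|V|×|V|} has y_ij = 1 iff
(i,j) ∈ E or i = j. The unit diagonal folds each protein into its own
neighborhood — the standard closed-neighborhood device that lets two
adjacent proteins support each other even without third-party common
partners, and the reason any observed edge has support n_ij ≥ 2. Rows of Y
are the protein feature vectors; every score in the package is a function
of two rows.

The mapping indicator between proteins i and j is an inter-neighborhood
similarity. The benchmark is the cosine ⟨y_i,y_j⟩/(‖y_i‖‖y_j‖). Its failure
mode on sparse noisy networks is norm instability: one hub endpoint
deflates the score of a pair regardless of how well it is supported. The
rescaled cosine coefficient (RCC) addresses this with two saturations:

**Denominator.** g(x₁,x₂; C_Y) = C_Y·(1 − exp(−x₁x₂/C_Y)) replaces the norm
product ‖y_i‖‖y_j‖. The prose constraints on this transform are (a)
monotone non-decreasing in each norm, so the relative order of scores at
equal support is preserved, and (b) bounded above, so the numerical gap
caused by extreme norms shrinks. The exponential-saturation form used here
satisfies both, is strictly below the norm product (so all scores are
enlarged relative to cosine), saturates at C_Y, and is C¹-smooth; it is
isolated behind `saturated_denominator` so an alternative form satisfying
the same contract can be swapped in without touching callers.

**Numerator.** The support n_ij = ⟨y_i,y_j⟩ counts the common
closed-neighborhood members backing a pair. All nonzero supports of the
matrix {n_ij : i < j, n_ij > 0} are fitted with a normal distribution
(maximum-likelihood mean μ and population variance σ²; self-pairs are
excluded because a self-support is just degree + 1, a diagonal artifact).
The rescaling coefficient r_ij = Φ((n_ij − μ)/σ) estimates the probability
that a pair's support is at least as large as a typical one. The final
score is

    rcc_ij = r_ij^d · n_ij / g(‖y_i‖, ‖y_j‖; C_Y).

Both tasks only use the ranking of scores, so the systematic enlargement
introduced by the saturated denominator is immaterial.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| C_Y | denominator saturation ceiling (dimensionless, on the scale of a norm product) | 30 | larger → closer to plain cosine; the benchmark setting for all test cases |
| d | rescaling exponent | 5 | d = 0 disables rescaling exactly; scores decrease monotonically in d since r ∈ (0,1), while the *relative* spread induced by r grows |
| K | prediction list size | 20,000 | the benchmark protocol's missing-interactome budget |
| candidate strategy | which pairs to score | common-neighbor-pairs | pairs with n_ij > 0, enumerated from the sparse Gram pattern Y·Yᵀ; zero-support pairs score exactly 0 under every metric here, so omitting them is lossless. `all-pairs` is available behind a pair-count cap |

## Numerical choices

* The normal CDF is evaluated exactly through the error function
  (scipy). A truncated Maclaurin-series mode exists solely as a
  cross-check of the exact route.
* r_ij is clipped to the open unit interval at machine precision: for
  |z| ≳ 8 the float64 CDF rounds to exactly 0 or 1 even though the
  mathematical value is strictly interior, and downstream contracts
  (zero score iff zero support; r ∈ (0,1)) rely on openness.
* σ² = 0 (all nonzero supports equal — realistic only for degenerate
  inputs like a single edge) falls back to the limiting step-function CDF
  (0 below μ, 1 above, ½ at μ) and logs a loud warning.
* All rankings break score ties by lexicographic pair order, making every
  output deterministic and permutation-equivariant (relabeling proteins
  relabels, but never reorders, the result).
* Sparse scoring is vectorized over the upper triangle of Y·Yᵀ and is
  checked against a naive dense per-pair re-evaluation to 1e-12 relative
  tolerance on hundreds of random networks.

## Baselines

Formulas follow the original publications of each index, since the
benchmark design requires them as comparators:

* **IG** (interaction generality): 1 + the number of degree-1 third-party
  proteins adjacent to either endpoint — spokes hanging off an edge are the
  signature of screening artifacts. Lower is better; the scoring interface
  negates it so every method is higher-is-better. Defined on observed edges
  only, and excluded from prediction benchmarking (it assigns missing pairs
  no usable ranking); in prediction rank tables it is placed last by
  convention.
* **CD**: 1 − |N_iΔN_j|/(|N_i|+|N_j|) on closed neighborhoods.
* **FW**: product of the two asymmetric overlap ratios
  2|N_u∩N_v| / (|N_u\N_v| + 2|N_u∩N_v| + λ_uv), with pseudo-count
  λ_uv = max(0, n_avg − |N_u|) (n_avg = mean closed-neighborhood size)
  penalizing proteins with fewer partners than average. Whether published
  FW benchmarks used the pseudo-count is not always stated, so both the
  λ-pseudo-count and the simplified λ = 0 form are provided.

## Evaluation protocol

GO annotations (GAF 2.x; NOT-qualified rows skipped) are split by ontology
branch. "Localization in common" means ≥ 1 shared cellular-component term;
"function in common" means ≥ 1 shared term in the union of biological
process and molecular function — the sharing predicate of the
guilt-by-association validation lineage. Before rating, the top 1% of
terms per branch by protein count are removed (ceil(0.01·T) terms,
frequency ties broken by term identifier): near-root terms annotate huge
protein sets and would trivially inflate coherence. This frequency filter
is the sole operationalization of "middle-level" terms; no ontology-graph
traversal is performed. Whether the removal should pool branches instead of
acting per branch is an open protocol question; per-branch is implemented
and is the variant a sensitivity analysis should toggle first.

A pair enters the coherence denominator only if both proteins carry at
least one term in the relevant branch set; the evaluable-pair count is
always reported alongside the rate so this exclusion is auditable. Zero
evaluable pairs yield NaN, never 0.

## Significance machinery

Methods are compared with the Friedman test over per-case ranks (ties get
average ranks), its Iman–Davenport F-form F_F = (N−1)χ²_F/(N(k−1)−χ²_F)
with F(k−1, (k−1)(N−1)) reference distribution, and the Nemenyi critical
difference CD = q_α·√(k(k+1)/6N). q_α is available both from the embedded
conventional table (α ∈ {0.05, 0.10}, k ≤ 10 — authoritative for matching
published critical differences, e.g. q_0.10 = 2.291 at k = 4) and
recomputed from the Studentized-range quantile at infinite degrees of
freedom divided by √2; the two agree to the table's printed 3-decimal
precision.

Null calibration of the F-form is checked on random rank tables at
k = 4 methods × N = 10 cases, where its empirical size sits well inside
the binomial 95% band around α = 0.05. At very small case counts (N ≈ 6)
the approximation is mildly anti-conservative (size ≈ 0.059 at α = 0.05 in
a 20,000-replicate probe) — a known limitation of the F approximation, not
of the implementation.

## Synthetic data

The generator plants a block model: proteins are assigned round-robin to
equal blocks; within-block pairs interact with probability `p_within`,
cross-block pairs with `p_between`. This directly plants the
common-neighbor structure the method's core assumption requires, which
makes recovery tests interpretable: a metric that exploits shared
neighborhoods must separate within-block signal from injected noise. The
observation process withholds a fraction `fn_rate` of true edges and
injects uniform random non-edges until they constitute `fp_rate` of the
observed edge set. Annotations give every protein its block's terms in
each GO branch, plus (with probability `annotation_noise`) one random
off-block term.

Defaults — 3,000 proteins, 100 blocks, p_within = 0.15,
p_between = 0.0002, fp_rate = 0.15, fn_rate = 0.10 — were chosen to land
the observed network in the sparse regime of real human HTS screens:
measured density ≈ 0.17% and ≈ 2.6 interactions per protein. Density and
mean degree cannot both match a 4,500-protein dataset at a different
network size; density (the quantity that controls common-neighbor
sparsity, hence problem hardness) was matched and degree allowed to land
where it falls. A single master seed derives independent per-stage streams
(topology, false-negative sampling, false-positive injection, annotations),
so each stage is individually reproducible.

What the generator does **not** emulate: heavy-tailed (scale-free) degree
distributions, bait/prey asymmetry of real screens, correlated (non-uniform)
false positives, overlapping protein complexes, or the hierarchical
structure of real GO. Passing recovery tests therefore demonstrates that
the implementation exploits common-neighbor signal correctly under
controlled noise — not that any particular AUC will be attained on a real
interactome.

## Problem sizes

The test suite and the acceptance script run sparse-vs-dense equivalence on
200 random networks of ≤ 50 nodes, recovery comparisons over 20 scenario
seeds at 3,000 proteins, and 2,000-replicate null calibration — sizes at
which every quantity they measure is stable to well within the asserted
tolerances.

## Known limitations

* Zero-support pairs are unreachable: RCC (like CD and FW) carries no
  information for pairs without shared closed-neighborhood members, so
  prediction draws only from common-neighbor candidates.
* The method inherits the common-neighbor assumption; interactions between
  modules (or true edges whose neighborhoods were unsampled) are
  systematically down-ranked.
* Scores are ranking devices, not calibrated probabilities; no
  accept/reject threshold is provided.
* The IW matrix is strictly binary; affinity- or evidence-weighted
  variants, and latent-factor/EM formulations of the same
  collaborative-filtering framing, are out of scope.
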