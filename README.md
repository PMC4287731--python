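# rcf — collaborative-filtering interactome mapping

High-throughput screens (yeast two-hybrid, AP-MS, protein-fragment
complementation) produce binary protein–protein interaction (PPI) networks
that are both noisy (false-positive interactions) and incomplete (most true
interactions unobserved). **Binary interactome mapping (BIM)** is the twin
task of *assessing* the reliability of each reported interaction and
*predicting* the most probable missing ones, using nothing but the network
itself.

`rcf` treats BIM as a collaborative-filtering problem. The network
G = (V, E) is encoded as an **interactome weight matrix** Y — symmetric,
binary, with unit diagonal:

    y_ij = 1  if (i,j) ∈ E or i = j,   else 0

so row *y_i* is protein *i*'s closed neighborhood, used as its feature
vector. Pairs are scored with the **rescaled cosine coefficient (RCC)**:

    rcc_ij = r_ij^d · ⟨y_i, y_j⟩ / g(‖y_i‖, ‖y_j‖; C_Y)

where

* ⟨y_i, y_j⟩ = n_ij is the **support**: the number of shared
  closed-neighborhood members backing the pair;
* g(x₁, x₂; C_Y) = C_Y·(1 − exp(−x₁x₂/C_Y)) is a **saturated denominator**
  replacing the plain cosine's norm product — monotone non-decreasing in
  each norm and bounded by C_Y, so hub proteins no longer crush the scores
  of their interactions while relative order at equal support is preserved;
* r_ij = Φ((n_ij − μ)/σ) is a **rescaling coefficient** in (0, 1): the
  normal CDF of the pair's support under a normal distribution fitted to
  all nonzero supports of the network, sharpening separation between
  frequently- and rarely-supported pairs. The exponent *d* controls its
  strength (d = 0 recovers the saturated cosine).

Defaults C_Y = 30, d = 5. Interactions ranked high are reliable; the
highest-scoring non-edges are predicted interactomes. The package also
ships the classical topology baselines (interaction generality IG,
Czekanowski–Dice CD, functional-similarity weight FW), a GO-annotation
coherence evaluation protocol (GAF 2.x reader, top-1% frequent-term
removal, functional-homogeneity and localization-coherence curves),
Friedman/Nemenyi significance machinery for multi-method comparison, and a
planted-block synthetic-data generator with ground-truth labels.

It is aimed at computational/systems biologists who need a fast,
annotation-free reliability score for sparse binary PPI networks
(densities around 0.1%, a handful of interactions per protein).

## Worked example

```python
from rcf import (RCCParams, assess, build_iw_matrix, predict,
                 score_all_pairs)
from rcf.synthetic import SyntheticScenario, generate, recovery_metrics

# simulate a sparse noisy screen: 3,000 proteins, ~0.17% density,
# 15% injected false positives, 10% of true edges withheld
data = generate(SyntheticScenario(seed=42))
net = data.observed_network
print(f"observed: {net.n_edges} interactions among {net.n_proteins} proteins "
      f"(density {100 * net.density():.2f}%)")

iw = build_iw_matrix(net)
scores = score_all_pairs(iw, RCCParams(c_y=30, d=5))

ranked = assess(net, scores)              # reliability ranking of edges
(a, b), s, _ = ranked.entries[0]
print(f"most reliable observed PPI: {a}-{b} (rcc = {s:.4f})")

missing = predict(net, scores, k=20_000)  # top missing interactomes
(a, b), s, _ = missing.entries[0]
print(f"top predicted missing interactome: {a}-{b} (rcc = {s:.4f})")

m = recovery_metrics(scores, data.labels, k=20_000)
print(f"assessment AUC vs planted noise: {m['assessment_auc']:.3f}")
print(f"recall of withheld true edges:   {m['prediction_recall_at_k']:.3f}")
```

Output:

```
observed: 7724 interactions among 3000 proteins (density 0.17%)
most reliable observed PPI: P00083-P01883 (rcc = 0.8848)
top predicted missing interactome: P00145-P01445 (rcc = 0.6987)
assessment AUC vs planted noise: 0.725
recall of withheld true edges:   0.258
```

The AUC is the probability that a randomly chosen genuine observed
interaction outscores a randomly chosen injected false positive — 0.725
means the score cleanly separates planted noise from signal in a network
this sparse. The recall is the fraction of deliberately withheld true
interactions recovered among the top 20,000 predictions.

The same pipeline is available from the shell:

```bash
rcf simulate --seed 42 -o sim/
rcf assess  --edges sim/observed.tsv --cy 30 --d 5 -o ranked.tsv
rcf predict --edges sim/observed.tsv -K 20000 -o predicted.tsv
rcf benchmark --edges sim/observed.tsv --gaf sim/annotations.gaf \
    --task assessment -o bench/
```

`rcf benchmark` scores the network with RCC, CD, FW (and IG for
assessment), evaluates GO functional-homogeneity and
localization-coherence curves, ranks the methods per testing point, and
reports the Friedman χ², its F-form, the F critical value and the Nemenyi
critical difference with the pairwise significance matrix.

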