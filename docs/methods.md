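# Methods

## Problem setting

A peripheral-blood-smear slide is represented as a *bag* of per-cell feature
embeddings: a frozen single-cell image encoder maps each detected white
blood cell crop to a D-dimensional vector (the clinical deployment this
package targets uses 1000-dimensional encoder features and roughly 2,000
cells per slide). Only the slide carries a diagnosis label (acute leukemia
AL, myelodysplastic syndromes MDS, hairy cell leukemia HCL, or normal NL);
no cell-level supervision exists. This is the multiple-instance-learning
(MIL) setting, and the package implements, trains, and interrogates two MIL
aggregators over such bags.

## The CAREMIL model

For a bag X ∈ R^{N×D}:

1. **Aggregator network** f_a: R^D → R^H, a one-hidden-layer perceptron
   (tanh hidden activation), applied per cell.
2. **Summary class tokens.** Over the N aggregator outputs we compute
   order-free statistics — coordinate-wise mean, population variance
   (divide by N, so single-cell bags are defined), and optionally
   generalized (power) means ((1/N) Σ x^p)^{1/p} for configured p ≠ 0.
   Each statistic is one H-dimensional *class token*; the default is
   mean + variance (K = 2). When any power mean is configured the
   aggregator network ends in a rectifier so its outputs are nonnegative
   (the power mean's domain); otherwise the output is unconstrained.
3. **Parallel network** f_p: R^D → R^H, an independent perceptron of the
   same shape, produces the per-cell tokens.
4. **Self-attention.** The sequence [K class tokens ; N cell tokens] passes
   through one multi-head scaled-dot-product self-attention layer
   (full attention, H split over n_heads, learned Q/K/V and output
   projections). There is **no residual connection**: a token's output is
   exactly its attention-weighted value mixture. This is a deliberate
   design choice — with a residual, the classifier head can read the
   summary statistics directly, gradient pressure never shapes the
   class-token → cell attention, and the extracted attention scores stop
   reflecting the prediction. Without the residual the only route from
   the cells to the head is through the attention weights, which makes
   the per-cell scores faithful explanations; empirically it also trains
   at least as well.
5. **Head.** The K post-attention class-token outputs are concatenated and
   fed to an MLP emitting class logits; probabilities are their softmax.

Because the class tokens are symmetric statistics and self-attention is
permutation-equivariant over cell positions, logits are invariant to cell
order and per-cell attention scores are equivariant — both are tested
properties, not implementation accidents.

**Attention extraction.** From the (K+N)×(K+N) softmax attention (averaged
over heads) we take the K×N block of class-token queries against cell keys
and renormalize each row to sum to 1 over cells; the mass a token spends on
other tokens is discarded. A cell's scalar score is the mean of the K
renormalized rows. The renormalization choice is recorded in the
`AttentionReport.normalization` metadata. Ranking ties are broken by
ascending cell index.

## Gated-attention MIL baseline

Instances are transformed D → H by a perceptron matching the CAREMIL
parallel network's capacity (so the comparison isolates the aggregation
mechanism), then scored by w·(tanh(V h) ⊙ σ(U h)) with gate dimension
L = H/2 by default; softmax over instances yields weights, the bag vector
is the weighted sum, and an MLP head emits logits.

## Training

Cross-entropy on slide labels with inverse-frequency class weights
(cohorts in this domain are heavily imbalanced). Bags have unequal N, so a
"batch" is gradient accumulation over bags processed one at a time — no
padding, exact gradients. Optimizer: Adam (β = 0.9/0.999), weight decay
1e-5, dropout on hidden layers during training only. Model selection keeps
the checkpoint with the best validation macro AUROC, using validation loss
as a tie-break: on small validation sets the AUROC saturates within a few
epochs and the loss keeps discriminating between checkpoints with identical
rankings. Early stopping waits `early_stop_patience` epochs without
improvement. Training is deterministic given the config seed (one numpy
generator drives shuffling and dropout).

All network code runs on a small in-package reverse-mode automatic
differentiation engine over numpy arrays (`caremil._tensor`). The models
here are small (tens of thousands of parameters, one attention layer), and
the engine is gradient-checked against central finite differences in the
test suite.

## Evaluation

* **AUROC** via the Mann–Whitney rank statistic (ties count 1/2); one-vs-rest
  per class plus macro average for multiclass. Tests cross-check it against
  exhaustive pair enumeration and scikit-learn.
* **Sensitivity by blast bin** at probability cutoff 0.5, over the
  deliberately overlapping bins high (≥20%), low (<20%), very low (≤10%),
  extremely low (≤5%) and invisible (≤1%); empty bins are flagged, not
  dropped.
* **Cytometry baseline**: multinomial logistic regression on the slide's
  cell-type fraction vector (the blood differential), with regularization
  strength chosen on validation AUROC. It sees counts and nothing of
  morphology, which is exactly why it anchors the central comparison.

## Explainability statistics

Per slide, cells are ranked by attention score; review panels take the
top-k, a seeded random k, and the bottom-k cells (k = 10 by default). The
top fraction f of a slide is the ⌈fN⌉ highest-ranked cells (ceiling keeps
the set nonempty). Enrichment pools the top-10% cells over the correctly
classified slides of one disease category and, per cell type, tests the
2×2 table (in top set vs not) × (is type vs not) with Pearson chi-squared
(no continuity correction, 1 df; expected counts < 5 are flagged).
Bonferroni correction uses α = 0.05 and m = number of cell types observed
in the pooled population. Log-odds of top-fraction vs overall composition
use Haldane–Anscombe +0.5 smoothing on degenerate cells so rare types
remain reportable. Marker overlap reports precision and recall of the
top-25% attention set against externally flagged diagnostic cells.

## Synthetic cohorts

The generator emulates what a frozen encoder produces on real smears, not
the images themselves. Each cell type has a unit-norm prototype in R^D with
a guaranteed minimum pairwise distance (0.5); cells are prototype +
isotropic Gaussian noise (σ = 0.25). A slide's composition is drawn from a
Dirichlet centered on a typical circulating differential (~50% neutrophils,
30% lymphocytes, ...; total concentration 150, giving realistic
slide-to-slide variation), and cell counts from a Poisson with mean 2,000
by default. Disease classes plant marker cells in one of two modes:

* **additive** — extra cells of a diagnostic type (circulating blasts) on
  top of the background differential; with `shift_scale = 0` the markers
  are morphologically identical to normal blasts, giving a
  *composition-only* signal.
* **in_type** — a fraction of an existing type's cells move to a shifted
  sub-cluster while keeping their recorded label (dysplastic neutrophils,
  hairy lymphocytes), leaving the differential untouched: a
  *morphology-only* signal that count-based classifiers cannot see.
  The default morphology-only task morphs 5–15% of cells — the rare
  sub-population regime the attention analyses are about.

Marker shifts are fixed random directions of norm `shift_scale` (default
1.0, i.e. comparable to the inter-prototype scale — encoder embeddings of
genuinely distinct morphologies separate well). `mislabel_as` records a
wrong type for marker cells, emulating an encoder that has never seen the
abnormal variant. Planted markers are flagged in `cell_refs`, giving
ground truth for overlap statistics. The default four-class miniature
cohort is 60 AL / 30 MDS / 20 HCL / 40 NL slides, one per patient.

What the generator does **not** model: staining and scanner variation,
spatially correlated crops, heavy-tailed or manifold-structured embedding
clouds, label noise at the slide level, and cell-detection errors. Passing
tests therefore demonstrate that the machinery recovers planted signals of
the two clinically relevant kinds under controlled conditions — not
clinical performance.

**Synthetic-patient mixing.** The limit-of-detection study samples
round(f·n) marker ("blast") cells and n − round(f·n) normal cells without
replacement from pools built from held-out slides, shuffles them into one
bag, and records the achieved fraction. The default grid is
f ∈ {0, 0.01, 0.02, 0.05, 0.10, 0.15, 0.20} with 30 replicates per
fraction and call cutoff 0.5.

## Study problem sizes

The training-based tests and `scripts/acceptance.py` run a scaled-down
version of the study: two-class (disease vs normal) cohorts of 25 + 25
patients, one slide per patient, ~250 cells per slide, D = 32 embeddings;
model H = 32 with 4 heads and one 32-unit hidden layer per network;
training for up to 60 epochs at learning rate 3e-3, batch accumulation 8,
early-stop patience 15. Five independent cohort/model seeds are used for
every reported quantity. These sizes were chosen as the smallest
configuration at which the planted signals are comfortably inside the
detectable regime for all three classifier families.

## Patient-level splits

Splitting is by patient: a patient's slides never straddle partitions.
Patients are sorted by id, shuffled by the seed, and apportioned by
largest-remainder rounding (remainder ties resolved in train → validation
→ test order). Unstratified by default; per-label stratification is a flag.
Blast fractions are stored as reals in [0,1]; percent strings in manifests
are rejected rather than converted, to avoid silent unit ambiguity.

## Numerical and degenerate-input choices

* Population (1/N) variance so N = 1 bags are defined; a single-cell bag
  receives all cell-directed attention by construction.
* Generalized mean adds 1e-12 inside the power only in the differentiable
  path, keeping the p < 1 gradient finite at exact zeros; the inference
  path treats zeros exactly. p = 0 (geometric mean) is unsupported.
* Softmax subtracts the (detached) row maximum — exact and overflow-safe.
* Checkpoints round-trip bit-identically (float64 `.npz` plus a JSON
  config record).
* Chi-squared on a table with a zero margin returns statistic 0, p = 1.
* AUROC raises on single-class inputs instead of returning a default.

## Known limitations

* The CPU training loop is exact but sequential; it is sized for cohorts of
  hundreds of slides with hundreds to thousands of cells, not for
  foundation-scale sweeps.
* The cytometry baseline is one regularized logistic model, a stand-in for
  a full model-family grid search; it is the appropriate comparator for
  count-only information but not a tuned clinical classifier.
* Attention faithfulness is demonstrated on planted Gaussian sub-clusters;
  real encoder embeddings have richer geometry, and the no-residual design
  choice, while necessary for faithful attention here, has only synthetic
  evidence behind its performance neutrality.
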