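# Methods

`graphsurv` implements a graph-based deep-learning survival pipeline for
whole-slide histopathology images (WSIs), together with the survival and
contingency statistics used to validate the resulting risk stratification.
This note records the model, its assumptions, the tunable parameters, and the
design choices made where the design was genuinely open.

## Pipeline model

**Tissue masking.** Stained tissue is saturated against near-white glass, so
segmentation runs on the HSV saturation channel of the slide image
downsampled to the x5 working magnification: median filter (kernel 7 px) →
Otsu threshold (foreground = high-saturation side) → morphological closing
(4x4 square) → removal of connected components smaller than 100 px (area
threshold defined at the x5 segmentation level and scaled quadratically if
the mask is computed elsewhere) → per-component hole handling: interior
holes are filled except holes larger than 16 px, of which at most the 8
largest are preserved as tissue cavities. Components use 8-connectivity and
holes 4-connectivity (the standard duality). Hole-size ties break toward the
larger hole, then scanline order. An all-background result is a warning, not
an error. The hole rule is one reading of an ambiguous convention (fill
small holes, cap preserved large ones); it is isolated in
`filter_components` so the opposite reading is a one-line change.

**Patch graph.** The masked tissue is tiled into non-overlapping 256x256
patches at x5 (grid anchored at the origin, row-major; patches with at least
50% of pixels in-mask are kept — the fraction is configurable, the cutoff
being a choice the underlying procedure leaves open). Each patch is encoded
to a 512-dim vector by a pluggable encoder. The default encoder is a
deterministic stand-in for a pretrained histopathology foundation encoder:
per-channel 64-bin histograms plus channel means/stds, projected to 512 dims
by a fixed seeded Gaussian matrix. It honours the same interface contract
(deterministic, 512-dim, per-patch) so a real pretrained encoder can be
plugged in without touching anything downstream. Patch centers are joined by
k-nearest-neighbour (k = 8) Euclidean edges computed on spatial coordinates
(features live on nodes, not in the metric); the directed k-NN is
symmetrized by union so every node keeps at least k neighbours, distance
ties break toward the lower node index, and k is capped at N-1. Whether
corners or centers feed the metric is immaterial for a fixed grid (a global
translation); centers are used.

**GNN + Cox head.** Two message-passing layers (GCN with symmetric
normalization D^-1/2 (A+I) D^-1/2, or multi-head additive-attention GAT with
heads concatenated on hidden layers and averaged on the last), a linear map
to 64-dim node embeddings, and one of four poolings to a 64-dim graph
embedding h: mean, max, gated attention (score_i = w^T tanh(V h_i), softmax
weights), or KDE. The risk score is the Cox linear predictor h . beta with
no intercept (absorbed by the baseline hazard). All parameters, including
beta, are trained jointly by full-batch Adam on the negative Cox partial
log-likelihood with the Breslow convention for ties (risk sets use
t_j >= t_i; events at t are in their own risk set). Full batch is deliberate:
the partial likelihood couples subjects through risk sets, and the cohorts
this tool targets are small. Each WSI is a training sample carrying its
patient's outcome; the per-patient max over slide scores applies at
inference only.

**KDE pooling** is specified here concretely since it is usually cited only
by name: for each of the 64 embedding dimensions, a Gaussian KDE of the N
node values is evaluated at 16 equally spaced points spanning that
dimension's [min, max] (bandwidth: Scott's rule per dimension, floored at
1e-3; a degenerate span collapses to a bump at the constant); the 64x16
density image is flattened and linearly projected back to 64 dims by a
learned map. Grid placement and bandwidth are treated as constants of the
current embedding (no gradient through them) — gradients flow through the
kernel arguments, which is what moves node embeddings during training.

**Backpropagation** runs on a small in-package reverse-mode autodiff engine
over numpy arrays (float64), written for exactly the operations this model
needs; every operation is gradient-checked against central finite
differences in the test suite, and the Cox-loss gradient check is part of
the acceptance script.

**Risk stratification.** After cross-validated training, each test patient's
risk is the max over slide scores. Raw scores are standardized (z-scored)
against the training fold before the baseline is estimated: a deep Cox head
that separates its training cohort keeps inflating the score spread (tens of
log-hazard units), and on the raw scale every predicted probability
collapses to 0 or 1; standardization preserves ranks (so the C-index is
untouched) while keeping exp(risk) in a meaningful range. The Breslow
estimator
H0(t) = sum_{t_i <= t} d_i / sum_{j in risk set} exp(s_j) is fitted on
training-set patient scores; S(t|risk) = exp(-H0(t))^exp(risk) gives the
predicted survival probability at the 18-month (1.5-year) horizon, and
patients with probability strictly below a threshold are called high-risk.
The threshold has no published value; the default is 0.9 (at typical event
rates a 0.5 cutoff is vacuous) and it must be set deliberately for any real
deployment. Cross-validation is patient-level: patient ids are shuffled with
the run seed and dealt round-robin into 4 folds, so all of a patient's
slides share a fold; folds whose test split has no comparable pairs are
excluded from the mean C-index with a warning rather than imputed.

**Explainability.** A GNNExplainer-style soft mask is optimized to keep the
masked graph's risk close to the full graph's (|delta risk| — a regression
fidelity, since the model emits a scalar, replacing the classifier's
cross-entropy) plus a per-element sparsity penalty (applied to the mask sum,
so the pressure per element does not shrink with graph size) and an element
entropy penalty pushing weights toward 0/1. The default mask acts on node
features and importance is the node's mask weight: because message passing
retains each node's self-connection, deleting a node's edges leaves its own
contribution to the pooled readout intact, so an edge mask is structurally
unable to attribute importance to signal-carrying nodes (we measured planted
signal nodes ranking last under edge masks). The classical edge mask
(importance = max incident edge weight) remains available as
`mask_mode="edge"`. Heatmaps alpha-blend a blue→red colormap over patch
footprints on the downsampled slide (default x1.25).

## Slide I/O

Magnification, not pyramid level, is the public coordinate: reading a x40
slide at x5 is a linear downsample of 8. Bounding boxes are level-0, 0-based,
half-open pixels. When no pyramid level matches, the nearest finer level is
read and area-averaged down (exact block mean with a single rounding for
integer factors, PIL's BOX filter otherwise) — deterministic, constant-
preserving, and associative to within one gray level. Pyramidal TIFF (the
container used by SVS) is read via tifffile; plain PNG/TIFF rasters are
first-class single-level slides whose magnification comes from an explicit
override or a `<path>.meta.json` sidecar.

## Statistics

Group comparisons: Pearson chi-square with Yates continuity correction for
2x2 tables only (larger tables uncorrected), all-zero rows/columns dropped
first since zero expected counts are undefined; Fisher's exact test;
Mann-Whitney U (normal approximation, tie and continuity corrections; all
values tied returns p = 1). Survival: Kaplan-Meier and the log-rank test
(via lifelines), and Cox proportional-hazards regression implemented
directly — Newton-Raphson on the Breslow partial likelihood (tol 1e-8, max
100 iterations), Wald SEs from the inverse observed information,
HR = exp(coef) with 95% CIs — because the tie convention must match the
training loss exactly; lifelines is the independent cross-check on tie-free
data in the tests, where both agree to ~1e-5. Monotone likelihoods (perfect
separation) are flagged with the coefficient capped at ±20 rather than
raised. L1-penalized fits use proximal gradient (ISTA with backtracking) on
the mean negative partial likelihood; no SEs are reported in penalized mode.

## Synthetic data

`simulate_slide` paints smooth Gaussian-bump "stain" blobs (saturated
H&E-like hue) on a near-white background, adds sub-threshold specks (area
9-25 px << 100) and carves holes of configurable area, and emits the
ground-truth mask (blobs minus holes large enough to be preserved). It
exercises exactly the decisions the masking stage makes — threshold between
saturated and unsaturated pixels, area filtering, hole handling — but not
stain variability, pen marks, blur, or tissue texture, so a passing IoU
says the procedure is implemented correctly, not that it is robust to real
staining artifacts.

`simulate_cohort` draws, per patient, an "aggressive fraction"
rho ~ U(0.05, 0.95); each slide gets 20-60 nodes with uniform 2D coordinates
(k-NN graphs, k = 8) and standard-Gaussian 512-dim features, except that a
rho-fraction of nodes is shifted by +2 on 16 designated signal dimensions.
The true linear predictor is eta = beta_true * rho (default beta_true = 2);
event times are Exponential(rate = 0.01 * exp(eta)) months with independent
Exponential(0.012) censoring (observed time = min, event indicator
accordingly), giving roughly 55-70% events and a median follow-up of a few
years — event-richer than typical early-stage clinical cohorts by design,
since 80 patients with very few events cannot support a learnability check.
A Weibull event-time option sits behind `weibull_shape`. Patients have 1-3
slides (all slides share the patient's outcome and fold). The signal lives
in feature means, not coordinates, so pooling has to aggregate node content
— mirroring how graph pooling summarizes patch morphology — and the truth
table (rho, eta per patient) supports oracle comparisons.

**A structural limit worth stating.** Under any proportional-hazards law the
probability that the higher-risk member of a pair fails first is
HR/(1+HR), independent of the baseline. With eta = beta_true * rho,
beta_true = 2 and rho in [0,1], pairwise hazard ratios are at most e^2, and
the concordance of the *true* predictor — the information ceiling no model
can beat — is about 0.65 (seed-dependent, roughly 0.55-0.71 at n = 80). The
cross-validated C-index of the trained pipeline must therefore be judged
against this oracle ceiling, which the acceptance script reports alongside
it, not against concordances reported for clinical cohorts whose effect
sizes are far larger. Raising beta_true (e.g. to 6, ceiling ≈ 0.78) makes
the planted ranking clearly learnable and is used in the learnability test.

## Study configuration and problem sizes

The cross-validation studies in the tests and the acceptance script use the
GCN+KDE model with hidden widths 512→32→16, 64-dim embedding, dropout 0,
Adam lr 3e-3, weight decay 0.1, 40 epochs (20 for null cohorts), chosen as
the package's standard synthetic-study configuration: with ~60 training
slides of 512-dim features the model memorizes the training partial
likelihood easily (training C ≈ 1), and strong weight decay with a compact
backbone is what lets the weak planted signal survive to held-out folds.
Feature dropout is off because it interacts poorly with KDE pooling's
density estimates at these widths. Library defaults for real use remain
wider (256/128 hidden, dropout 0.25, lr 1e-4, 200 epochs), all configurable.

## Numerical choices

- Float64 throughout the engine; risk-set log-sum-exp is max-shifted.
- k-NN ties: (distance, index) lexicographic; max-pool subgradient goes to
  the first argmax; stratification uses strict inequality (p = threshold is
  low-risk).
- Cox Newton steps falling outside |coef| <= 20 flag separation; singular
  information matrices yield NaN SEs with `converged=False` rather than an
  exception.
- Seeds: every random operation (init, dropout, folds, simulation,
  explainer) derives from explicit integer seeds; identical seeds reproduce
  results bit-for-bit.

## Known limitations

- The stand-in encoder carries color/intensity statistics only; it cannot
  represent the semantic content a pretrained histopathology encoder would,
  so synthetic results say nothing about real-slide discriminative power.
- Breslow (not Efron) ties throughout; with heavily tied event times both
  the loss and the statistics are coarser than Efron-based tools.
- Harrell's C without IPCW weighting; no competing risks; no time-dependent
  covariates.
- The explainer optimizes a local, seeded objective; importances are
  comparable within a slide, not across slides.
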