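# graphsurv

Graph-based deep-learning survival analysis for whole-slide histopathology
images (WSIs), built for prognostic risk stratification in small clinical
cohorts such as rare-tumor studies (the motivating setting is primary
mucinous ovarian carcinoma, where reliable prognostic markers are scarce).

The pipeline turns each slide into a spatial patch graph and trains a graph
neural network jointly with a Cox proportional-hazards head:

1. **Tissue masking** — HSV saturation channel at x5 magnification: median
   filter (k=7) → Otsu threshold → morphological closing (4x4) → drop
   components < 100 px → fill interior holes except the ≤ 8 largest holes
   over 16 px.
2. **Patch graph** — non-overlapping 256x256 patches at x5, encoded to
   512-dim feature vectors (pluggable encoder; a deterministic
   histogram-projection stand-in ships for testing), patch centers linked by
   k-NN (k=8) Euclidean edges.
3. **GNN survival model** — GCN or GAT backbone with mean / max / gated
   attention / KDE pooling into a 64-dim graph embedding h; risk score
   s = h·β. All parameters are optimized jointly by minimizing the negative
   Cox partial log-likelihood (Breslow ties)

   L(θ, β) = − Σ_{i: δ_i=1} [ s_i − log Σ_{j: t_j ≥ t_i} exp(s_j) ].

4. **Risk stratification** — patient risk = max over slide scores; Breslow
   baseline hazard H₀(t) from the training folds; predicted 1.5-year
   survival S(18 mo | s) = exp(−H₀)^{exp(s)}; patients below a probability
   threshold (default 0.9) are called high-risk. Patient-level 4-fold
   cross-validation reports Harrell's C.
5. **Explainability** — GNNExplainer-style soft masks yield per-patch
   importances rendered as blue→red heatmaps on the slide.
6. **Statistics** — Kaplan-Meier + log-rank, chi-square/Fisher/Mann-Whitney
   group comparisons, and univariable/multivariable/L1-penalized Cox
   regression for validating the stratification.

Everything runs on CPU with numpy (the GNN uses an in-package autodiff
engine); synthetic slide and cohort generators make the full pipeline
testable with no external data. See `docs/methods.md` for the model details
and design choices.

## Worked example

```python
import numpy as np
from graphsurv.simulate import CohortSimConfig, simulate_cohort
from graphsurv.model import BackboneConfig, TrainConfig
from graphsurv.risk import cross_validate, stratify

# synthetic cohort: 80 patients, 1-3 slide graphs each, survival driven by a
# planted "aggressive fraction" of shifted patch features (beta_true = 2)
cohort, survival, truth = simulate_cohort(CohortSimConfig(n_patients=80, seed=0))

res = cross_validate(
    cohort,
    BackboneConfig(arch="gcn", pooling="kde", hidden_dims=[32, 16], dropout=0.0),
    TrainConfig(epochs=40, learning_rate=3e-3, weight_decay=0.1, seed=0),
    n_folds=4, seed=0,
)
print("fold C-indices:", [round(c, 3) for c in res.fold_cindices])
print("mean C-index:  ", round(res.mean_cindex, 3))

strat = stratify(res.probabilities, threshold=0.5)
n_high = sum(1 for g in strat.assignments.values() if g == "high")
print("high-risk patients:", n_high, "of", len(strat.assignments))
```

Output:

```
fold C-indices: [0.731, 0.61, 0.527, 0.372]
mean C-index:   0.56
high-risk patients: 45 of 80
```

The mean C-index of 0.56 should be read against the generator's information
ceiling: with proportional hazards, the concordance of the *true* risk is
HR/(1+HR) per pair, which caps even a perfect model near 0.65-0.70 at this
effect size (the true-predictor oracle for this cohort scores 0.685). The
example thresholds at 0.5 rather than the default 0.9 because this synthetic
cohort is deliberately event-rich (most predicted 18-month survival
probabilities sit well below 0.9); for low-event clinical cohorts the
default is the sensible starting point.

The same study runs from the shell:

```bash
graphsurv simulate cohort --out runs/cohort --n-patients 80 --seed 0
graphsurv evaluate --graphs runs/cohort/graphs --survival runs/cohort/survival.csv \
    --out runs/eval --pool kde --epochs 40 --folds 4
graphsurv report --cohort-csv runs/cohort/survival.csv \
    --stratification runs/eval/stratification.csv --out runs/report
```

or end-to-end from a YAML config with `graphsurv run --config pipeline.yaml`
(artifacts plus a manifest with config hash, seed and per-stage timings).

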