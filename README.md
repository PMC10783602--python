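# slidefactors

Cross-linking tumor transcriptomic state and tissue histology: `slidefactors`
compresses a bulk tumor transcriptome into a small number of binary
**gene-group latent factors** and predicts those factor statuses — per slide
and per tissue region — directly from whole-slide-image (WSI) graphs.

It is written for computational-pathology and cancer-genomics researchers
who want a self-contained, CPU-friendly implementation of the full pipeline:

1. **Gene-group discovery** (total-correlation explanation).  Given a log2
   z-scored expression matrix `M` (m samples × n genes), find d binary
   latent factors G₁…G_d such that the mutual information between gene
   expression levels is minimised after conditioning on the factors.  Each
   factor is a ranked (by mutual information, in nats) overlapping group of
   genes, with an explained total correlation TC_k and a per-sample binary
   status; a patient's expression state becomes d bits instead of n reals.
2. **WSI graphs.**  A slide is tiled into 512 px patches at 0.50
   microns/pixel, patches with under 40% informative tissue are discarded,
   per-patch features h_i ∈ ℝ¹⁰²⁴ are extracted, and patches become nodes of
   a graph 𝒢 = (V, E) whose edges are the Delaunay triangulation of patch
   centroids pruned at 4,000 px.
3. **Slide-graph network.**  L = 3 EdgeConv layers,
   `h_m^l = Σ_{k∈N(m)} H^l([h_m^{l-1} ‖ h_k^{l-1} − h_m^{l-1}])`,
   with per-layer heads f_l; node score `f(v_m) = Σ_l f_l(h_m^l)` and slide
   score `F(𝒢) = Σ_m f(v_m)`.  Training uses the pairwise hinge ranking
   loss `L = Σ_k Σ_{(a,b)∈P_k} max(0, 1 − (F_k(a) − F_k(b)))` so status-1
   slides outrank status-0 slides for every factor, with Adam, early
   stopping, a queue of the 10 best checkpoints, and 5-fold
   cross-validation; ensembles average queued models.
4. **Spatial profiling.**  Node-score heatmaps (blue = status-0 evidence,
   red = status-1), exemplar-patient selection, 1% top/bottom patch
   harvesting, 25-medoid motif mining, and sub-patch aggregation geometry
   for pluggable cell-composition/mitosis annotators.
5. **Downstream predictors.**  The predicted factor scores act as a latent
   representation from which receptor status, molecular subtypes, mutation
   and copy-number status are predicted by perceptrons under the same
   ranking-loss protocol, evaluated by 1,000× bootstrap AUROC at 67%
   resampling.

The neural network, its backpropagation, and the k-medoid (PAM) clustering
are implemented in NumPy; everything is deterministic given seeds.
A synthetic-cohort module generates coupled expression + slide data with
planted ground truth, so the whole pipeline is testable offline.

## Worked example

Discover factors in a synthetic cohort, check recovery, and train the slide
model:

```python
import numpy as np
from sklearn.metrics import roc_auc_score
from slidefactors import (ModelConfig, TrainConfig, discover_groups,
                          infer_status, match_statuses, normalize_expression,
                          predict_ensemble, train)
from slidefactors.profiling import localization_auc
from slidefactors.synthetic import (SynthExpressionConfig, SynthSlideConfig,
                                    generate_cohort, generate_expression)

expr = generate_expression(SynthExpressionConfig(seed=0))   # 300 x 480, 10 factors
mat = normalize_expression(expr.matrix.to_frame(), already_log2=True)
model = discover_groups(mat, n_groups=10, n_iterations=100, seed=0)
_, agreement, _ = match_statuses(model.statuses, expr.statuses)
print("factor recovery:", agreement.min())

cohort = generate_cohort(SynthExpressionConfig(n_samples=200, n_factors=8, seed=0),
                         SynthSlideConfig(seed=0))
result = train(cohort.graphs[:160], cohort.statuses[:160].astype(float),
               model_config=ModelConfig(n_outputs=8, seed=0),
               train_config=TrainConfig(seed=0))
preds = predict_ensemble(result, cohort.graphs[160:])
scores = np.stack([p.slide_scores for p in preds])
aurocs = [roc_auc_score(cohort.statuses[160:, k], scores[:, k]) for k in range(8)]
print("held-out slide AUROC (min):", round(min(aurocs), 3))
print("localization AUC (min):",
      round(min(localization_auc(preds, cohort.masks[160:], k) for k in range(8)), 3))
```

prints

```
factor recovery: 1.0
held-out slide AUROC (min): 0.972
localization AUC (min): 0.85
```

— every planted factor's status is recovered exactly from expression, each
factor's status is predicted from the held-out slide graphs with AUROC
≥ 0.97, and the node scores rank the planted signal regions above background
tissue with AUC ≥ 0.85.

The same steps are available from the shell:

```bash
slidefactors simulate --n-samples 200 --n-factors 8 --out fixtures/
slidefactors discover-groups --expr fixtures/expression.tsv --n-groups 10 \
    --already-log2 --out model/
slidefactors infer-status --model model/ --expr fixtures/expression.tsv \
    --already-log2 --out statuses.tsv
slidefactors build-graph --slide slide.png --mpp 0.5 --out graph/
slidefactors train --graphs fixtures/ --labels fixtures/statuses.tsv --out run/
slidefactors predict --run run/ --graphs fixtures/ --out pred/
slidefactors profile --run run/ --graphs fixtures/ --factors 0,3 --out maps/
```

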