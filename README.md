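# beetlesieve

Disaggregate multi-specimen composite photographs into single-specimen
crops, classify the crops with a pluggable fine-tuned image classifier, and
score every prediction with an unknown-class (out-of-class) probability —
plus the full leave-one-class-out ROC evaluation harness.

## What it does

1. **Segmentation** (`beetlesieve.segmentation`) — an eight-step pipeline:
   load the colour composite, convert to grayscale (BT.601), binarize with
   a 256-bin Otsu threshold (dark specimens = foreground), remove objects
   touching the image border, label 8-connected components, keep the larger
   of two size clusters (exact 1-D 2-means on pixel areas), and extract the
   kept bounding boxes from the original colour image. Crops that overlap
   another kept box or have an outlier aspect ratio are flagged for human
   review instead of being silently dropped.

2. **Open-set scoring** (`beetlesieve.openset`) — from an n-class
   probability vector `P` and a decision boundary `t ∈ (0, 1)`:

   ```
   d_i = P_i ^ (1 − |P_i − t|)
   Pu  = 1 − Σ_{i,j} |d_i − d_j| / (2 (n − 1) Σ_j d_j)
   ```

   `Pu` is exactly 0 for a one-hot vector, exactly 1 for a uniform vector,
   and always in [0, 1]. The conventional `max(P) < t` decision-boundary
   baseline is provided alongside; both expose a shared `unknown_score`
   (higher = more unknown).

3. **Splits** (`beetlesieve.splits`) — leakage-free, class-stratified
   test split (largest-remainder allocation) and k-fold cross-validation,
   always assigning whole replicate groups (one physical batch = one dish =
   its agitation replicates) to one side of a split.

4. **Training** (`beetlesieve.training`) — a classifier with a
   `linear → tanh → softmax` head (one node per class, pre-softmax bounded
   to [−1, 1]), label-smoothing cross-entropy, Adam, a one-epoch warm-up
   with the backbone frozen, and the full augmentation set (blur, noise
   patches, rotation, flip, brightness, contrast, zoom, warp, crop) applied
   with probability 0.8 by default. The offline backbone is a tiny numpy
   CNN with hand-written backprop so everything trains on one CPU with no
   downloads; large pretrained backbones can be plugged in behind the same
   head.

5. **Evaluation** (`beetlesieve.evaluation`) — one-vs-rest ROC with
   "unknown" as the positive class, Mann–Whitney-consistent AUC, vertical
   fold averaging on a 101-point FPR grid, the optimal operating point
   (closest to TPR 1 / FPR 0), support-weighted F1 with "unknown" as an
   ordinary label, and the leave-one-class-out (LOCO) harness that trains
   one model per (excluded class × fold) and scores both methods from the
   same prediction table.

6. **Synthetic data** (`beetlesieve.synthetic`) — ground-truthed composite
   generator (dark textured elliptical blobs on a near-white background,
   edge-touching objects, debris specks, per-class size/intensity/texture/
   colour signatures, agitation replicates) and Dirichlet probability-vector
   generators (confident / ambiguous / ood regimes), so every stage is
   testable offline.

## CLI

All stages are subcommands of `beetlesieve`; every source of randomness
flows from an explicit `--seed`, and each stage is byte-reproducible.

```bash
# generate a synthetic dataset with ground truth
beetlesieve simulate --out data/sim --seed 1 --classes 4 --batches 4 --replicates 10

# split composites into single-specimen crops (+ crop manifest and reports)
beetlesieve split-composite --input data/sim --manifest data/sim/manifest.csv \
    --out data/crops --margin 0

# assign leakage-free test/fold splits
beetlesieve make-splits --manifest data/crops/crops.csv \
    --test-frac 0.2 --k 5 --seed 1 --out data/crops/crops_split.csv

# fine-tune the classifier
beetlesieve train --manifest data/crops/crops_split.csv \
    --config config.yaml --out models/run1

# per-crop predictions with class probabilities, Pu, and a decision
beetlesieve predict --model models/run1 --manifest data/crops/crops.csv \
    --out predictions.jsonl --t 0.8 --method formula

# leave-one-class-out open-set evaluation with fold-averaged ROC curves
beetlesieve evaluate-openset --manifest data/crops/crops_split.csv \
    --config config.yaml --out eval/
```

Configuration is a strict YAML schema (`beetlesieve.config.PipelineConfig`);
every pipeline constant (test fraction 0.2, k = 5, batch 64 / 5 epochs /
learning rate 0.003, augmentation probability 0.8, 224 px inputs, t = 0.8)
is a named, overridable default. Unknown keys are rejected.

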