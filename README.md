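# epla

Slide-level prediction of microsatellite status (MSI vs MSS) from
histopathology, by **Ensemble Patch Likelihood Aggregation**.

Microsatellite instability is a hypermutator phenotype caused by
mismatch-repair deficiency. It selects colorectal-cancer patients for
immunotherapy, but the reference assays (tumor/normal sequencing, multiplex
PCR) are not universally available — while H&E slides are. This package
implements a two-stage pipeline that reads MSI status off the slide:

1. **Patch level.** The annotated carcinoma region of a whole-slide image is
   tiled into patches; a convolutional classifier is trained under multiple
   instance learning (every patch inherits its slide's label, binary
   cross-entropy, mini-batch SGD) and emits a per-patch MSI likelihood
   p ∈ [0, 1].
2. **Slide level.** The bag of patch likelihoods {p₁, …, p_n} is aggregated
   two ways:
   * **PALHI** — the occurrence histogram h ∈ Δ⁹⁹ of the likelihoods over
     100 equal bins, classified by gradient-boosted trees (xgboost);
   * **BoW** — likelihoods quantized to words w = ⌈100·p⌉, the slide
     represented by an L2-normalized TF-IDF vector, classified by Gaussian
     Naive Bayes.

   The slide score is the convex ensemble
   `s = α·s_PALHI + (1 − α)·s_BoW`, with α chosen by a grid scan on
   out-of-fold training scores and the operating cutoff by the Youden index.

The 200 slide-level features (100 histogram bins ∥ 100 TF-IDF weights) are
named FEA#001–FEA#200 and double as interpretable *pathological signatures*:
permutation importance ranks them, and the omics module relates them to
tumor mutation burden, INDEL load, mismatch-repair/DDR/HRD deficiency calls,
and immune expression scores (CYT, CD8⁺ T-effector).

Also included: a deep-learning majority-voting baseline, ROC machinery with
DeLong confidence intervals and the Wald AUC-difference test, cross-cohort
transfer learning (weight reuse + fine-tuning on a fraction of a new
cohort), and synthetic-cohort generators (likelihood bags, textured tile
images with ROI XML, correlated omics tables) so the whole pipeline runs
end-to-end with no external data.

## Worked example

```sh
epla simulate --mode likelihood --n-slides 120 --seed 11 --out run
epla aggregate-train --manifest run/manifest.tsv \
    --likelihoods run/likelihoods.tsv --seed 11 --out run
epla predict --model run/epla_model.pkl \
    --likelihoods run/likelihoods.tsv --out run
epla evaluate --predictions run/predictions.tsv \
    --manifest run/manifest.tsv --partition run/partition.tsv --out run
```

prints (stderr shows stage progress, stdout the final report):

```
wrote 120 slides to run
alpha=0.50 cutoff=0.5090
scored 120 slides
{"auc": 1.0, "cutoff": 0.534, "sensitivity": 1.0, "specificity": 1.0,
 "n_pos": 6, "n_neg": 30, "ci": [1.0, 1.0]}
```

`alpha=0.50` is the ensemble weight (both aggregators carry equal signal
here), `cutoff` the Youden operating point on the ensemble score, and the
report is the held-out test-split ROC summary: at this synthetic
separability the 6 MSI and 30 MSS test slides are ranked perfectly, so the
AUC is 1.0 and the DeLong interval degenerates. Library use mirrors the
CLI: see `epla.synthetic`, `epla.aggregation.fit_epla`,
`epla.evaluation.evaluate_scores`.

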