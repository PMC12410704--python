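# morfse

Mixture of radiological-finding-specific experts for mammographic patch
classification, with repeated out-of-fold evaluation and from-scratch
DeLong ROC statistics.

## The problem

Radiologists read mammograms differently depending on the finding type:
calcifications are judged by the shape of each deposit and the tightness of
the cluster, masses by their shape and margins. Most CNN classifiers ignore
this distinction and train one network on everything. This package
implements a mixture-of-experts alternative for 3-class patch diagnosis
(cancer / benign / normal):

* a **gate network** (gNet, 2-class) scores whether a patch is
  calcification- or mass-dominant, emitting weights `(wc, wm)` with
  `wc + wm = 1` (enforced structurally by a two-class softmax head);
* a **calcification expert** (cExp) and a **mass expert** (mExp), each a
  3-class classifier trained only on its own finding type plus normals;
* the final prediction is the convex combination

  ```
  y = wc · cExp(x) + wm · mExp(x)
  ```

Two baselines share the machinery: **No-gNet** (the same experts with fixed
weights `wc = wm = 0.5`) and **Conventional** (a single 3-class network
trained on all patches).

Evaluation follows a repeated out-of-fold protocol: one patient-grouped,
diagnosis-stratified 5-fold partition; R repetitions of the full K-fold
cycle with fresh initialisation seeds; per-patch predictions averaged over
repetitions; cancer-vs-rest AUC on the integrated out-of-fold set, overall
and per finding type; paired DeLong tests between variants.

The statistics layer (`morfse.stats`) implements midrank AUC, the DeLong
structural-components variance, normal-approximation CIs and the paired
DeLong test for correlated ROC curves from first principles.

Because full-scale mammography archives need a large download and GPU
training, the package ships a synthetic patch generator
(`morfse.synth`) whose malignancy cues are *finding-specific by
construction* — dot morphology and cluster tightness for calcifications,
margin blur and spiculation for masses — so the benefit of gating is
genuinely testable on a laptop. An I/O layer (`morfse.io`) applies the
patch-construction rules for real DICOM/PNG archives with lesion masks:
512 px centroid-centred crops, per-lesion extraction, distortion exclusion,
FAD-to-mass relabelling, and Otsu-based normal-patch sampling.

## Worked example

```python
from morfse import SynthConfig, TrainConfig, MorfseExperiment

synth = SynthConfig(seed=7, n_per_cell=20)          # 100 patches, 64 px
cfg = TrainConfig(fast_mode=True, repetitions=2, folds=5)
res = MorfseExperiment.from_synthetic(synth, cfg).fit(master_seed=7)
print(res.summary())
```

```
Mixture-of-experts evaluation
================================================================
patches: 100   folds: 5   repetitions: 2
variant            AUC                95% CI       n+/n-
morfse          0.9729   (0.9484-0.9974)         40/60
nognet          0.8371   (0.7613-0.9128)         40/60
conventional    0.9725   (0.9450-1.0000)         40/60
----------------------------------------------------------------
DeLong morfse vs conventional: z = +0.027, p = 0.9783
DeLong morfse vs nognet: z = +3.359, p = 0.0007818
DeLong conventional vs nognet: z = +3.768, p = 0.0001647
gate finding accuracy: 0.988
```

The gated mixture (`morfse`) clearly beats the equal-weight ensemble
(`nognet`, p < 0.001): when each expert is reliable only on its own finding
type, fixed averaging lets the off-specialty expert dilute the prediction,
while the gate — which recovers the true finding label for 98.8% of lesion
patches here — routes each patch to the right specialist. The conventional
single network is competitive on this synthetic task; the mixture's
advantage over it is the focus of full-scale studies.

`res.oof` holds the per-repetition out-of-fold table (persistable as CSV),
`res.auc(variant)`, `res.per_finding_auc(variant, finding)` and
`res.compare(a, b)` expose the individual statistics, and `res.plot_roc()`
overlays the ROC curves.

The same pipeline is scriptable via the `morfse` CLI (`synth`, `extract`,
`run`, `compare`, `report` subcommands; exit codes 0/2/3/4 for
ok/config/data/training errors).

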