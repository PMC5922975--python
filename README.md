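# hydramotion

Automatic recognition and unsupervised discovery of behaviors in videos of
*Hydra* — a freshwater polyp whose body deforms so freely that
skeleton- or pose-based trackers do not apply.  The package is for
quantitative ethologists and neuroscientists who need per-window behavior
labels (ethograms), repertoire statistics, and data-driven behavioral maps
from long grayscale recordings of a bright animal on a dark background.

## The method

Each 5-s window of video (at 5 Hz) is treated as one *behavior element* and
passes through a bag-of-words pipeline:

1. **Registration.** Background (morphological opening) is subtracted; the
   animal is segmented by 3-cluster intensity k-means; the bright body
   column is isolated by a two-pass Otsu threshold and fitted with an
   ellipse by image moments; head/foot polarity comes from the tentacle
   area at the two major-axis ends.  One similarity transform per window
   maps the animal to a canonical frame (body vertical, head up, 100 px
   long in a 300×300 image) and the mask splits into tentacle / upper /
   lower body parts.
2. **Dense trajectories.** Interest points on a 5-px grid are tracked for
   15 frames by median-filtered dense optical flow; static, erratic and
   teleporting tracks are filtered out.  Each trajectory carries four
   single-cell histograms over its 32×32 px patch: HOG (8 bins), HOF
   (8 orientation bins + a zero-motion bin), MBHx and MBHy (8 bins each).
3. **Fisher vectors.** Per descriptor type: per-part centering, PCA to half
   dimension, whitening, and a K-component diagonal GMM codebook
   (K = 128 by default).  A window is encoded by the Fisher vector — the
   Fisher-information-normalized gradients of the GMM log-likelihood,

       G_mu(i,d)    = 1/(T sqrt(w_i))   Σ_t γ_t(i) (x_td − μ_id)/σ_id
       G_sigma(i,d) = 1/(T sqrt(2 w_i)) Σ_t γ_t(i) [((x_td − μ_id)/σ_id)² − 1]

   power-normalized (sign(z)|z|^0.5) and l2-normalized, concatenated over
   3 body parts × 4 descriptor types.
4. **Supervised classification.** Class-weighted RBF SVM
   (w_i = ΣN_j / N_i) on 90%-variance PCA features, 5-fold CV over
   log₂C, log₂γ ∈ {−5, −3, …, 15}, probability outputs; hard labels by
   argmax, soft labels attach up to three classes while each next
   probability exceeds 50% of the previous.
5. **Unsupervised motif discovery.** t-SNE (perplexity 16) of the reduced
   Fisher vectors; Gaussian density map (σ = 1/40 of the map extent);
   watershed regions seeded at dilated density peaks; regions named by the
   majority manual label they contain; new windows placed into the frozen
   map by per-point KL minimization.
6. **Egestion detection.** The body-width (ellipse minor axis) trace is
   filtered by mean(15 min before) − mean(15 min after); significant peaks
   mark the sub-second radial contractions that empty the body cavity.

A first-class synthetic generator (`hydramotion.fixtures`) renders
deformable ellipse-plus-tentacles animals executing scripted behaviors
(silent, elongation, tentacle sway, body sway, bending, contraction,
egestion) with exact per-frame ground truth, so the whole pipeline is
testable without the recorded dataset.

## Worked example

`examples/05_egestion_events.py` builds a 3.7-hour synthetic width trace
with five egestion events 40 minutes apart (40% width drops with 5% noise)
and runs the detector:

```
5 injected events, 5 detected:
  frame   9000 (  30.0 min)  height  7.57 px  nearest truth 9000 (interior)
  frame  21000 (  70.0 min)  height  7.48 px  nearest truth 21000 (interior)
  frame  33000 ( 110.0 min)  height  7.48 px  nearest truth 33000 (interior)
  frame  45000 ( 150.0 min)  height  7.50 px  nearest truth 45000 (interior)
  frame  57000 ( 190.0 min)  height  7.47 px  nearest truth 57000 (interior)
```

Every event is recovered at its exact frame; the ~7.5 px heights estimate
the lasting width drop (the 12 px instantaneous drop, partially re-inflated
over the 15-min averaging window).  The other example scripts each exercise
one capability — synthetic rendering, registration, supervised
classification, motif discovery — and print what the numbers mean as they
go.

The same pipeline is scriptable from a shell via the thin `hydramotion`
CLI (`simulate`, `preprocess`, `features`, `fit-codebook`, `encode`,
`train`, `predict`, `evaluate`, `embed`, `egestion`), with artifacts and
run manifests in a working directory.

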