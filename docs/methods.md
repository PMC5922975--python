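# Methods

`hydramotion` implements a bag-of-words (BoW) video pipeline for recognizing
and discovering behaviors of *Hydra*, a freshwater polyp whose body is so
deformable that pose-graph or skeleton trackers do not apply.  The pipeline
treats each fixed-length window of video (a *behavior element*, 5 s at 5 Hz
by default) as an unordered collection of local motion/appearance
descriptors, summarizes the collection as a Fisher vector against learned
Gaussian-mixture codebooks, and feeds that representation to a supervised
classifier and to an unsupervised embedding.

## Preprocessing and registration

The animal is bright on a dark background.  Per frame:

1. **Background estimation.** Grayscale morphological opening of the
   per-pixel temporal minimum frame, with a disk structuring element whose
   radius (default 60 px; `opening_radius_px`) exceeds the body width so
   the animal is removed.  Opening is anti-extensive, so the background is
   a pixelwise lower bound and subtraction leaves the animal bright.
2. **Animal segmentation.** After a 1–99% linear contrast stretch, pixel
   intensities are clustered into three groups by 1-D k-means (background /
   weak tentacles / bright body; deterministic initialization spanning the
   intensity range).  The largest cluster is background; connected
   foreground components below 0.25% of the image area are dropped; the
   mask is dilated by 3 px.
3. **Body-column fit.** The background-subtracted image is smoothed with a
   3×3 Gaussian (σ = 1 px) and thresholded twice with Otsu's method — first
   globally (background vs animal), then within the surviving region
   (tentacles vs body column).  An ellipse is fitted to the body column by
   second-order central moments; full axis lengths are 4·√eigenvalue, the
   solid-ellipse relation.
4. **Polarity.** Square probes (side = minor-axis length) at both
   major-axis endpoints; the end with the larger animal-minus-body-column
   area underneath is the tentacle/mouth (head) end.  If both probes are
   empty, the previous frame's polarity is reused.
5. **Body parts.** Tentacles = animal minus body column under the head
   probe; the remainder splits at the minor axis into upper (head side) and
   lower body.

Each window is registered with a single similarity transform built from
the window-average centroid, head direction (vector mean, so there is no
angle wraparound) and major-axis length: body vertical with the head toward
the top of the image, body length `canonical_body_px` (default 100 px),
output `canonical_size`² (default 300²), bilinear interpolation, pixels
outside the animal mask zeroed.  Frames where segmentation fails reuse the
previous frame's geometry and are flagged.

Conventions: 0-based pixel coordinates, x right / y down, angles in degrees
from +x toward +y restricted to (−90°, 90°] for the undirected axis.

## Dense trajectories and descriptors

Interest points are seeded every 5 px inside the animal mask, skipped where
the Shi–Tomasi corner response is below 1% of the frame maximum, and
advected for 15 frames by dense iterative Lucas–Kanade optical flow
(median-filtered 3×3 before advection; three warp iterations, sufficient
for the few-px/frame motions of a registered window).  Trajectories are
discarded when their coordinate spread is < 0.1 px (static) or > 50 px
(erratic) or any single step exceeds 50 px (tracking failure).

Each trajectory accumulates four single-cell histograms over the 32×32 px
patch around the tracked point across its span:

* **HOG** — 8 bins of unsigned (180°) image-gradient orientation,
  magnitude-weighted (appearance);
* **HOF** — 8 bins of signed (360°) optical-flow orientation plus an
  explicit zero bin for flow magnitudes below 0.4 px/frame
  (`hof_zero_thresh`): 9 bins total;
* **MBHx / MBHy** — 8 bins of signed orientation of the spatial gradient of
  each flow component ("motion boundaries", insensitive to uniform drift).
  Vanishing flow gradients contribute vanishing magnitude, so a uniformly
  translating patch yields an all-zero MBH histogram, which normalization
  leaves all-zero.

Histograms are l2-normalized per descriptor.  The single-cell layout (no
2×2×3 spatio-temporal grid) is deliberate: it gives the 9/8/8/8
dimensionalities this pipeline is built around.  Descriptors are grouped by
the body part containing the trajectory's mean position (nearest part as a
fallback), which injects coarse spatial structure into the otherwise
orderless BoW representation.

## Codebooks and Fisher vectors

Per descriptor type: descriptors are centered per body part, projected by a
PCA shared across parts to ⌈D/2⌉ components (5 for HOF, 4 for the others),
and whitened (xᵢ/√λᵢ — unit variance per retained component).  A
K-component diagonal-covariance GMM (default K = 128; K = 16 in the
reduced-scale studies, see below) is fitted by EM on a seeded subset of at
most 256 000 whitened descriptors (variances floored at 1e−6).

A window's descriptor set X = {x_t, t = 1…T} is encoded by the gradients of
the GMM log-likelihood with respect to means and standard deviations,
normalized by the closed-form diagonal Fisher-information factors, with
γ_t(i) the posterior responsibility (computed in log space):

    G_μ(i,d)  = 1/(T√w_i)   Σ_t γ_t(i) (x_td − μ_id)/σ_id
    G_σ(i,d)  = 1/(T√(2w_i)) Σ_t γ_t(i) [((x_td − μ_id)/σ_id)² − 1]

Weight gradients are omitted.  Components with total responsibility below
1e−10 contribute zero blocks.  Each block is power-normalized,
f(z) = sign(z)|z|^α with α = 0.5 (reduces the dominance of sparse bursty
components), then l2-normalized.  Blocks concatenate in the fixed order
(tentacle, upper, lower) × (HOF, HOG, MBHx, MBHy), mean gradients before
variance gradients within a block, and the concatenated vector is
l2-normalized once more, so every encoded window has unit norm — unless no
trajectory survived anywhere, in which case it is all-zero.

The correctness anchor is a finite-difference oracle: on random small
GMMs, the closed form must match the numeric gradient of the log-likelihood
(scaled by the same Fisher factors) to 1e−5, and a large sample drawn from
the codebook's own GMM must give a near-zero vector (the expected score
vanishes at the true parameters).

## Classification

Per-frame manual labels (codes 0–10; 0 = none, larger codes = more
prominent behaviors) aggregate to one window label: with L1/L2 the two most
frequent labels, L2 wins when it is the more prominent behavior and
count(L1) ≤ 3·count(L2); none-class frames are ignored unless the window is
all none.  This lets a 1-s contraction outvote 4 s of stillness.

The classifier is an RBF-kernel SVM on PCA-reduced Fisher vectors (90%
retained variance), with class weights w_i = (Σ_j N_j)/N_i and a 5-fold
cross-validated grid search over log₂C, log₂γ ∈ {−5, −3, …, 15}.  Because
the deployed prediction rule is the argmax of the calibrated (Platt)
probabilities, candidates are scored by cross-validated log loss rather
than decision accuracy: on small training sets the Platt sigmoid can
collapse to near-uniform probabilities at hyperparameters whose raw
decision function is nevertheless accurate, and accuracy-based selection
can pick exactly those.  Soft predictions attach up to three labels per
window while the next probability strictly exceeds 50% of the previous one.
Ties in the argmax break toward the more prominent behavior.

Evaluation is one-vs-rest per class — accuracy (TP+TN)/(TP+TN+FP+FN),
precision TP/(TP+FP), recall TP/(TP+FN), ROC by score sorting, AUC by
trapezoid — with soft predictions credited when the true label is anywhere
in the predicted set.  Ethograms are summarized as per-behavior time
fractions plus the standard deviation of those fractions over consecutive
30-min blocks.

## Motif discovery

PCA-reduced Fisher vectors are embedded in 2-D by t-SNE (Euclidean
distances, perplexity 16, PCA initialization, fixed seed; exact gradient
below 1500 points).  A density map on a 501² grid is the sum of Gaussians
of width σ = `sigma_frac` × the maximum absolute embedding coordinate
(default 1/40; 1/60 reveals finer structure on long recordings), padded 10%
and normalized to integrate to 1.  Local maxima above 1% of the peak
density are dilated by 3 px — merging near-duplicate peaks — and a
watershed on the inverted distance-to-peak transform assigns every grid
cell to a region, so the region grid partitions the plane.  Regions take
the majority manual label of the training windows they contain (ties to
the more prominent behavior; empty regions are labeled none) — the labels
play no part in forming the regions, only in naming them.

New windows are placed into the frozen map per point: the window's
similarity distribution over the training vectors is calibrated to the map
perplexity by binary search on the Gaussian bandwidth, and its 2-D
coordinate minimizes the KL divergence against the Student-t similarities
to the fixed training embedding (L-BFGS from two starts: the
similarity-weighted mean and the nearest neighbor's position).

## Egestion detection

Egestion (radial contraction) empties the body cavity within a second —
too brief for reliable frame-wise annotation but visible as a sharp drop in
the ellipse minor axis followed by slow re-inflation.  The width trace
(missing frames linearly interpolated and flagged) is filtered by
mean(15 min before t) − mean(15 min after t), windows truncated at the
trace ends; a lasting drop yields a positive peak at the drop.  Events are
peaks with prominence ≥ 3× a robust noise scale (MAD of the first
differences of the filtered trace, so the slow event bumps do not inflate
the threshold), separated by at least one half window.  Because truncated
windows raise the filtered value's standard error near the trace ends,
peaks below 3× their pointwise standard error (from the raw trace's
frame-to-frame noise) are discarded; surviving end-region events are
edge-flagged.  Detection counts are non-increasing in the prominence
threshold, and the filter is linear with zero response to constants.

## The synthetic generator

`hydramotion.fixtures` renders the scene statistics the pipeline assumes —
not a photorealistic polyp.  A capsule-shaped body (midline arc with an
elliptic half-width profile) carries longitudinal intensity banding
(body ≈ 200 ± 15 gray levels) so optical flow and corner detection have
texture; 3-px tentacle strokes at a distinctly weaker level (≈ 110) fan
out from the head so the three-cluster segmentation, the second Otsu pass
and the polarity probes are all genuinely exercised; the background is
dark (≈ 10).  Seven behaviors are scripted: silent, elongation (major axis
grows monotonically), contraction (body and tentacles shorten rapidly),
tentacle sway (only tentacles oscillate), body sway (rigid rocking),
bending (midline curvature ramps up), and egestion (≥ 30% width drop
within 1 s, then recovery).  Every clip carries per-frame ground truth:
the behavior code, the body ellipse measured from the noise-free body mask
by an implementation (scikit-image regionprops) independent of the
preprocessor's own moment fit, and egestion event times.

Two realism details matter downstream.  First, all motion includes a
baseline micro-motility — a smooth centroid random walk and slight
orientation jitter scaled by the sensor-noise level — because a live
animal is never perfectly still; without it, silent windows produce zero
surviving trajectories and hence bit-identical all-zero Fisher vectors,
whose stacked density spike distorts the embedding's peak detection in a
way real data cannot.  Noise-free clips (noise_sd = 0) remain exactly
static, preserving the clean-geometry contracts.  Second, synthetic width
traces re-inflate over ~20 min by default, matching the slow fluid
reaccumulation that makes the before/after mean filter peak at the drop;
with fast recovery the filter's response plateaus ahead of the event and
localization degrades — a property of the filter, not of the generator.

What passing on this generator does **not** show: robustness to occlusion,
contrast drift, debris, multi-animal scenes, buds, feeding interactions, or
real tentacle morphology.  The synthetic behaviors are also cleaner and
more stereotyped than real repertoires, so synthetic accuracies should be
read as a correctness check of the machinery, not as expected field
performance.

## Problem sizes and numerical choices

The end-to-end evaluation studies run at a reduced scale chosen once:
144-px videos with a 52-px body registered to 50 px in a 144-px canonical
frame, K = 16 mixture components, six behaviors, 5 training and 2 held-out
animals with 6 / 3 clips per behavior respectively (180 training windows,
36 test windows).  Thirty training windows per class keeps class
neighborhoods above the fixed t-SNE perplexity of 16 — with fewer windows
per class than the perplexity, t-SNE cannot form class-coherent
neighborhoods regardless of feature quality.  Ellipse-recovery checks run
at full scale (300-px frames, 100-px body).  K-means and GMM fits use
deterministic or seeded initialization; responsibilities are computed in
log space; GMM variances are floored (reg_covar 1e−6); whitening
eigenvalues are floored at 1e−12; the t-SNE seed, all generator seeds and
all subset draws derive from the configured seed, and every study is
bit-reproducible for a fixed seed.

## Known limitations

* The trajectory-shape descriptor of classic dense-trajectory pipelines is
  intentionally absent; only HOF/HOG/MBH are used.
* No temporal model links consecutive windows; ethograms are per-window
  decisions and transition structure is out of scope.
* Optical flow is iterative Lucas–Kanade; very fast whole-body contractions
  (> ~8 px/frame at the registered scale) can exceed its pull-in range and
  lose trajectories to the maximum-step filter, which in practice still
  yields a distinctive (sparse) signature for contraction windows.
* The out-of-sample embedding optimizes each point independently; dense
  batches of novel behavior would be better served by rebuilding the map.
* AVI I/O requires an imageio backend with a video codec; TIFF is the
  primary format and is always lossless.
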