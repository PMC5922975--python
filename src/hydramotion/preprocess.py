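"""Segmentation, body-ellipse fitting and window registration.

The animal is bright on a dark background.  Preprocessing proceeds per frame:

1.  the background is estimated by a grayscale morphological opening (with a
    structuring element larger than the animal, so the animal is removed) and
    subtracted;
2.  the animal is segmented by 3-cluster 1-D k-means on pixel intensities
    (body / weak tentacles / background), small connected components are
    removed (< 0.25% of image area) and the mask dilated by 3 px;
3.  the bright body column is isolated by a two-pass Otsu threshold on the
    Gaussian-smoothed image and fitted with an ellipse by second-order
    moments;
4.  head/foot polarity is resolved by comparing the non-body-column animal
    area under square probes at the two major-axis ends (the tentacle crown
    makes the head end win);
5.  the animal is split into tentacle / upper body / lower body masks.

Each analysis window (default 25 frames = 5 s at 5 Hz) is then registered by
one similarity transform — built from the window-average centroid,
orientation and major-axis length — into a canonical frame: body vertical
with the head up, body length ``canonical_body_px`` (default 100 px), output
``canonical_size`` squared (default 300), pixels outside the animal zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.morphology import dilation, disk, opening
from skimage.transform import SimilarityTransform, warp
from sklearn.cluster import KMeans

from .config import PipelineConfig
from .geometry import BodyEllipse, ellipse_from_moments
from .video import VideoClip


class NoAnimalError(RuntimeError):
    """Raised when segmentation finds no foreground object."""


class PolarityError(RuntimeError):
    """Raised when head/foot polarity cannot be resolved."""


@dataclass
class BodyParts:
    """Disjoint binary masks for the three body parts."""

    tentacle_mask: np.ndarray
    upper_mask: np.ndarray
    lower_mask: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"tentacle": self.tentacle_mask, "upper": self.upper_mask,
                "lower": self.lower_mask}


@dataclass
class RegisteredWindow:
    """One analysis window in canonical coordinates."""

    frames: np.ndarray                 # (T, S, S) float
    transform: SimilarityTransform
    parts: BodyParts
    mask: np.ndarray                   # canonical animal mask (majority vote)
    frame_rate_hz: float


def estimate_background(frames: np.ndarray, opening_radius: int = 60) -> np.ndarray:
    """Background image via grayscale opening of the temporal minimum frame.

    The opening removes any bright object narrower than the structuring
    element, and is anti-extensive, so the result is <= every input frame
    pixelwise and subtracting it leaves the animal bright.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.shape[0] == 0:
        raise ValueError("need at least one frame")
    if 2 * opening_radius + 1 > min(frames.shape[1:]):
        raise ValueError("structuring element larger than image")
    floor = frames.min(axis=0)
    return opening(floor, disk(opening_radius))


def _contrast_stretch(img: np.ndarray, pct: float = 1.0) -> np.ndarray:
    lo, hi = np.percentile(img, [pct, 100.0 - pct])
    if hi <= lo:
        return np.zeros_like(img)
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0)


def segment_animal(frame: np.ndarray, background: np.ndarray,
                   min_component_frac: float = 0.0025,
                   dilate_px: int = 3) -> np.ndarray:
    """Foreground mask of the animal (body + tentacles).

    Background subtraction, 1-99% contrast stretch, 3-cluster 1-D k-means on
    intensity (largest cluster = background), removal of connected
    components below ``min_component_frac`` of the image area, then dilation
    by ``dilate_px``.
    """
    if frame.shape != background.shape:
        raise ValueError("frame and background must have the same shape")
    sub = np.clip(np.asarray(frame, float) - background, 0.0, None)
    stretched = _contrast_stretch(sub)
    vals = stretched.reshape(-1, 1)
    # deterministic init spanning the intensity range (background, weak
    # tentacles, bright body) avoids k-means seeding variance
    init = np.linspace(vals.min(), vals.max(), 3).reshape(-1, 1)
    km = KMeans(n_clusters=3, init=init, n_init=1, max_iter=100).fit(vals)
    counts = np.bincount(km.labels_, minlength=3)
    bg_cluster = int(np.argmax(counts))
    mask = (km.labels_ != bg_cluster).reshape(frame.shape)

    lab = sk_label(mask, connectivity=2)
    min_area = min_component_frac * mask.size
    keep = np.zeros_like(mask)
    for region_id in range(1, lab.max() + 1):
        component = lab == region_id
        if component.sum() >= min_area:
            keep |= component
    if not keep.any():
        raise NoAnimalError("no foreground component above the area threshold")
    return dilation(keep, disk(dilate_px))


def fit_body_column(frame: np.ndarray, mask: np.ndarray
                    ) -> tuple[BodyEllipse, np.ndarray]:
    """Two-pass Otsu body-column isolation and moment ellipse fit.

    ``frame`` should be the background-subtracted image.  Returns the fitted
    ellipse (polarity unresolved) and the body-column mask.
    """
    if not mask.any():
        raise NoAnimalError("empty animal mask")
    smooth = gaussian_filter(np.asarray(frame, float), sigma=1.0, truncate=1.0)
    t1 = threshold_otsu(smooth)          # background vs animal
    region1 = mask & (smooth > t1)
    if not region1.any():
        raise NoAnimalError("first Otsu pass removed everything")
    t2 = threshold_otsu(smooth[region1])
    body = region1 & (smooth > t2)
    if not body.any():            # degenerate second pass; keep first region
        body = region1
    lab = sk_label(body, connectivity=2)
    largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
    body = lab == largest
    return ellipse_from_moments(body), body


def resolve_polarity(animal_mask: np.ndarray, body_mask: np.ndarray,
                     ellipse: BodyEllipse,
                     previous_head: tuple[float, float] | None = None
                     ) -> BodyEllipse:
    """Decide which major-axis end is the tentacle/mouth (head) end.

    Square probes with side equal to the minor-axis length are centered on
    both major-axis endpoints; the end with the larger animal-minus-body
    area underneath is the head.  If both probe areas are zero the previous
    frame's polarity is reused.
    """
    end_a, end_b = ellipse.endpoints()
    fringe = animal_mask & ~body_mask
    side = max(ellipse.minor_axis, 4.0)

    def probe_area(end):
        h, w = animal_mask.shape
        x0 = int(round(end[0] - side / 2)); x1 = int(round(end[0] + side / 2))
        y0 = int(round(end[1] - side / 2)); y1 = int(round(end[1] + side / 2))
        x0, x1 = max(x0, 0), min(x1, w)
        y0, y1 = max(y0, 0), min(y1, h)
        if x0 >= x1 or y0 >= y1:
            return 0
        return int(fringe[y0:y1, x0:x1].sum())

    area_a, area_b = probe_area(end_a), probe_area(end_b)
    centroid = np.asarray(ellipse.centroid)
    if area_a == area_b == 0:
        if previous_head is None:
            raise PolarityError("no tentacle signal at either end and no prior")
        head_vec = np.asarray(previous_head, float)
        # snap the prior onto the current axis
        axis = ellipse.axis_vector
        head_vec = axis if head_vec @ axis >= 0 else -axis
    else:
        end = end_a if area_a >= area_b else end_b
        head_vec = (end - centroid) / np.linalg.norm(end - centroid)
    return BodyEllipse(ellipse.centroid, ellipse.major_axis, ellipse.minor_axis,
                       ellipse.orientation, (float(head_vec[0]), float(head_vec[1])))


def split_body_parts(animal_mask: np.ndarray, body_mask: np.ndarray,
                     ellipse: BodyEllipse) -> BodyParts:
    """Tentacle / upper / lower masks from the polarity-resolved ellipse.

    The tentacle region is the animal minus body column under the head-end
    probe square; the remainder is split at the minor axis (the line through
    the centroid perpendicular to the body axis), head side = upper.
    """
    if ellipse.head_end is None:
        raise ValueError("polarity must be resolved first")
    h, w = animal_mask.shape
    head = np.asarray(ellipse.head_end)
    centroid = np.asarray(ellipse.centroid)
    head_pt = centroid + 0.5 * ellipse.major_axis * head
    side = max(ellipse.minor_axis, 4.0)

    ys, xs = np.mgrid[0:h, 0:w]
    in_probe = (np.abs(xs - head_pt[0]) <= side / 2) & \
               (np.abs(ys - head_pt[1]) <= side / 2)
    tentacle = animal_mask & ~body_mask & in_probe

    rest = animal_mask & ~tentacle
    along = (xs - centroid[0]) * head[0] + (ys - centroid[1]) * head[1]
    upper = rest & (along >= 0)
    lower = rest & (along < 0)
    return BodyParts(tentacle, upper, lower)


@dataclass
class FrameGeometry:
    """Per-frame segmentation products."""

    ellipse: BodyEllipse
    animal_mask: np.ndarray
    body_mask: np.ndarray
    flagged: bool = False


def process_clip(clip: VideoClip, config: PipelineConfig | None = None
                 ) -> list[FrameGeometry]:
    """Segment and fit every frame; failed frames reuse the previous fit."""
    config = config or PipelineConfig()
    background = estimate_background(clip.frames, config.opening_radius_px)
    out: list[FrameGeometry] = []
    prev: FrameGeometry | None = None
    for i in range(clip.n_frames):
        frame = clip.frames[i].astype(float)
        try:
            animal = segment_animal(frame, background,
                                    config.min_component_frac,
                                    config.mask_dilate_px)
            sub = np.clip(frame - background, 0.0, None)
            ellipse, body = fit_body_column(sub, animal)
            ellipse = resolve_polarity(
                animal, body, ellipse,
                prev.ellipse.head_end if prev is not None else None)
            geo = FrameGeometry(ellipse, animal, body)
        except (NoAnimalError, PolarityError):
            if prev is None:
                raise
            geo = FrameGeometry(prev.ellipse, prev.animal_mask,
                                prev.body_mask, flagged=True)
        out.append(geo)
        prev = geo
    return out


def geometry_table(geometries: list[FrameGeometry]) -> pd.DataFrame:
    """Per-frame geometry as the standard CSV-ready table."""
    rows = []
    for i, g in enumerate(geometries):
        e = g.ellipse
        hx, hy = e.head_end if e.head_end is not None else (np.nan, np.nan)
        rows.append(dict(frame=i, cx=e.centroid[0], cy=e.centroid[1],
                         major=e.major_axis, minor=e.minor_axis,
                         angle_deg=e.orientation, head_x=hx, head_y=hy,
                         flagged=g.flagged))
    return pd.DataFrame(rows)


def register_window(clip: VideoClip, geometries: list[FrameGeometry],
                    config: PipelineConfig | None = None) -> RegisteredWindow:
    """Register one window with a single window-average similarity transform.

    The average head direction (vector mean, so no angle wraparound), average
    centroid and average major-axis length define a transform that maps the
    centroid to the canvas center, rotates the head direction to point
    toward the top of the image, and scales the body to
    ``canonical_body_px``.  Bilinear interpolation; pixels outside the
    (warped) animal mask are zeroed.
    """
    config = config or PipelineConfig()
    if clip.n_frames != config.window_frames:
        raise ValueError(
            f"window has {clip.n_frames} frames, expected {config.window_frames}")
    if len(geometries) != clip.n_frames:
        raise ValueError("one geometry per frame required")

    centroids = np.array([g.ellipse.centroid for g in geometries])
    heads = np.array([g.ellipse.head_end for g in geometries])
    majors = np.array([g.ellipse.major_axis for g in geometries])
    center_in = centroids.mean(axis=0)
    head_mean = heads.mean(axis=0)
    head_mean /= np.linalg.norm(head_mean)
    scale = config.canonical_body_px / majors.mean()

    size = config.canonical_size
    # rotate head_mean to (0, -1): toward the top of the canvas
    rot = np.arctan2(head_mean[1], head_mean[0]) - np.arctan2(-1.0, 0.0)
    tform = SimilarityTransform(translation=-center_in) \
        + SimilarityTransform(rotation=-rot, scale=scale) \
        + SimilarityTransform(translation=(size / 2.0, size / 2.0))

    inv = tform.inverse
    out_frames = np.empty((clip.n_frames, size, size), dtype=np.float32)
    part_votes = {"tentacle": np.zeros((size, size)),
                  "upper": np.zeros((size, size)),
                  "lower": np.zeros((size, size))}
    mask_votes = np.zeros((size, size))
    for i, g in enumerate(geometries):
        warped = warp(clip.frames[i].astype(float), inv, output_shape=(size, size),
                      order=1, preserve_range=True)
        wmask = warp(g.animal_mask.astype(float), inv, output_shape=(size, size),
                     order=0, preserve_range=True) > 0.5
        warped[~wmask] = 0.0
        out_frames[i] = warped
        mask_votes += wmask
        parts = split_body_parts(g.animal_mask, g.body_mask, g.ellipse)
        for name, m in parts.as_dict().items():
            part_votes[name] += warp(m.astype(float), inv,
                                     output_shape=(size, size), order=0,
                                     preserve_range=True) > 0.5

    half = clip.n_frames / 2.0
    mask = mask_votes >= half
    tent = (part_votes["tentacle"] >= half)
    upper = (part_votes["upper"] >= half) & ~tent
    lower = (part_votes["lower"] >= half) & ~tent & ~upper
    parts = BodyParts(tent, upper, lower)
    return RegisteredWindow(out_frames, tform, parts, mask, clip.frame_rate_hz)


def iter_windows(clip: VideoClip, config: PipelineConfig | None = None,
                 stride: int | None = None):
    """Yield (start_frame, sub-clip) for consecutive full windows.

    Non-overlapping by default; a smaller ``stride`` gives the overlapping
    continuous-window variant.  A trailing partial window is dropped.
    """
    config = config or PipelineConfig()
    length = config.window_frames
    stride = stride or length
    for start in range(0, clip.n_frames - length + 1, stride):
        yield start, clip.window(start, length)
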