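"""Synthetic Hydra videos with known ground truth.

Real recordings show a bright, highly deformable tubular animal on a dark
background: a body column that elongates, contracts, sways and bends, with a
crown of weaker-intensity tentacles at the oral end.  This module renders a
parameterized caricature of that scene — a capsule-shaped body with
longitudinal intensity banding (so optical flow has texture to grip) plus
thin curved tentacle strokes at lower intensity — executing one of seven
scripted behaviors per clip:

* ``silent`` — no motion, only sensor noise;
* ``elongation`` — the major axis grows monotonically;
* ``contraction`` — the body and tentacles shorten rapidly;
* ``tentacle_sway`` — only the tentacle strokes oscillate;
* ``body_sway`` — the whole animal rigidly rocks about its centroid;
* ``bending`` — the midline curvature increases over the clip;
* ``egestion`` — the body width drops by >= 30% within <= 1 s and recovers.

Every clip comes with per-frame ground truth: the behavior label, the true
body ellipse (measured from the noise-free body mask, so it is exactly the
quantity the preprocessor tries to recover), and any egestion event times.
Output is bit-identical for identical specs including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.measure import label as sk_label
from skimage.measure import regionprops

from .classes import CODE_TO_CLASS, NAME_TO_CLASS, validate_codes
from .geometry import wrap_angle_deg
from .video import VideoClip, read_video, write_video  # noqa: F401  (re-export)

BEHAVIORS = (
    "silent",
    "elongation",
    "tentacle_sway",
    "body_sway",
    "bending",
    "contraction",
    "egestion",
)

BACKGROUND_LEVEL = 10.0
TENTACLE_LEVEL = 110.0
BODY_LEVEL = 200.0
BODY_BAND_AMPLITUDE = 15.0
BODY_BAND_CYCLES = 3.0


class UnknownBehaviorError(ValueError):
    """Raised for a behavior tag outside the supported set."""


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic behavior clip."""

    behavior: str
    duration_s: float = 5.0
    frame_rate_hz: float = 5.0
    image_size: int = 300
    body_length_px: float = 100.0
    n_tentacles: int = 6
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.behavior not in BEHAVIORS:
            raise UnknownBehaviorError(
                f"unknown behavior {self.behavior!r}; expected one of {BEHAVIORS}"
            )
        if self.duration_s <= 0 or self.frame_rate_hz <= 0:
            raise ValueError("duration_s and frame_rate_hz must be positive")
        if self.n_tentacles < 0:
            raise ValueError("n_tentacles must be >= 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))


@dataclass
class GroundTruth:
    """Per-frame truth accompanying a synthetic clip."""

    per_frame_label: np.ndarray
    ellipse_track: pd.DataFrame  # frame,cx,cy,major,minor,angle_deg,head_x,head_y
    egestion_times: list[int] = field(default_factory=list)


def _arc_points(start: np.ndarray, angle0: float, length: float,
                total_bend: float, n: int) -> np.ndarray:
    """Polyline of a constant-curvature arc; angles in radians, (x, y) rows."""
    s = np.linspace(0.0, 1.0, n)
    angles = angle0 + total_bend * s
    step = length / (n - 1)
    dx = np.cos(angles[:-1]) * step
    dy = np.sin(angles[:-1]) * step
    pts = np.empty((n, 2))
    pts[0] = start
    pts[1:, 0] = start[0] + np.cumsum(dx)
    pts[1:, 1] = start[1] + np.cumsum(dy)
    return pts


def _stamp_disks(img: np.ndarray, centers: np.ndarray, radii: np.ndarray,
                 values: np.ndarray) -> None:
    """Paint filled disks into ``img`` (later disks overwrite earlier)."""
    h, w = img.shape
    for (cx, cy), r, v in zip(centers, radii, values):
        if r <= 0:
            continue
        x0, x1 = int(np.floor(cx - r)), int(np.ceil(cx + r)) + 1
        y0, y1 = int(np.floor(cy - r)), int(np.ceil(cy + r)) + 1
        x0, x1 = max(x0, 0), min(x1, w)
        y0, y1 = max(y0, 0), min(y1, h)
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
        img[y0:y1, x0:x1][inside] = v


class _Pose:
    """Per-frame scene parameters."""

    def __init__(self, length, width, angle_deg, bend_rad, tent_scale,
                 tent_offsets_deg, center_offset=(0.0, 0.0)):
        self.length = length
        self.width = width
        self.angle_deg = angle_deg
        self.bend_rad = bend_rad
        self.tent_scale = tent_scale
        self.tent_offsets_deg = tent_offsets_deg
        self.center_offset = np.asarray(center_offset, float)


def _behavior_schedule(spec: SyntheticSpec, rng: np.random.Generator) -> list[_Pose]:
    n = spec.n_frames
    t = np.arange(n) / spec.frame_rate_hz          # seconds
    frac = np.arange(n) / max(n - 1, 1)            # 0..1 through the clip
    L0 = spec.body_length_px
    w0 = 0.30 * L0
    theta0 = rng.uniform(-60.0, 60.0)
    n_t = spec.n_tentacles
    zeros = np.zeros(n_t)

    length = np.full(n, L0)
    width = np.full(n, w0)
    angle = np.full(n, theta0)
    bend = np.full(n, 0.05)
    tent_scale = np.ones(n)
    tent_offsets = [zeros.copy() for _ in range(n)]

    if spec.behavior == "elongation":
        length = L0 * (0.75 + 0.45 * frac)
        width = w0 * np.sqrt(L0 / length)          # rough volume conservation
    elif spec.behavior == "contraction":
        ramp = np.minimum(frac / 0.6, 1.0)
        length = L0 * (1.0 - 0.50 * ramp)
        width = w0 * (1.0 + 0.25 * ramp)
        tent_scale = 1.0 - 0.6 * ramp
    elif spec.behavior == "tentacle_sway":
        phases = 1.3 * np.arange(n_t)
        tent_offsets = [
            28.0 * np.sin(2 * np.pi * 0.5 * ti + phases) for ti in t
        ]
    elif spec.behavior == "body_sway":
        angle = theta0 + 12.0 * np.sin(2 * np.pi * 0.4 * t)
    elif spec.behavior == "bending":
        bend = 0.08 + 1.3 * frac
    elif spec.behavior == "egestion":
        event = n // 2
        dip = np.zeros(n)
        down = max(1, int(round(0.6 * spec.frame_rate_hz)))   # <= 1 s drop
        rec = max(2, int(round(2.0 * spec.frame_rate_hz)))
        for i in range(n):
            if event <= i < event + down:
                dip[i] = 0.35 * (i - event + 1) / down
            elif event + down <= i < event + down + rec:
                dip[i] = 0.35 * (1.0 - (i - event - down) / rec)
        width = w0 * (1.0 - dip)

    # baseline micro-motility: a live animal is never perfectly still.  A
    # smooth centroid random walk plus slight orientation jitter, scaled by
    # the noise level so noise-free clips remain exactly static.
    drift = rng.normal(0.0, 0.15 * spec.noise_sd, (n, 2)).cumsum(axis=0)
    wobble = rng.normal(0.0, 0.05 * spec.noise_sd, n).cumsum()

    return [
        _Pose(length[i], width[i], angle[i] + wobble[i], bend[i],
              tent_scale[i], np.asarray(tent_offsets[i]), drift[i])
        for i in range(n)
    ]


def _render_frame(spec: SyntheticSpec, pose: _Pose, band_phase: float,
                  tent_curves: np.ndarray, tent_fan_deg: np.ndarray):
    """Render one noise-free frame; returns (float image, body-only mask)."""
    size = spec.image_size
    center = np.array([size / 2.0, size / 2.0])
    n_mid = max(48, int(pose.length))
    theta = np.deg2rad(pose.angle_deg)
    mid = _arc_points(np.zeros(2), theta - pose.bend_rad / 2.0, pose.length,
                      pose.bend_rad, n_mid)
    mid = (mid - mid.mean(axis=0) + center
           + pose.center_offset)            # foot = mid[0], head = mid[-1]

    s = np.linspace(0.0, 1.0, n_mid)
    radii = 0.5 * pose.width * np.sqrt(np.clip(1.0 - (2 * s - 1.0) ** 2, 0, None))
    bands = BODY_LEVEL + BODY_BAND_AMPLITUDE * np.sin(
        2 * np.pi * BODY_BAND_CYCLES * s + band_phase
    )

    img = np.full((size, size), BACKGROUND_LEVEL, dtype=np.float64)

    # tentacles first so the body overwrites their bases
    head = mid[-1]
    head_dir = np.arctan2(mid[-1, 1] - mid[-2, 1], mid[-1, 0] - mid[-2, 0])
    for k in range(spec.n_tentacles):
        ang = head_dir + np.deg2rad(tent_fan_deg[k] + pose.tent_offsets_deg[k])
        t_len = 0.5 * pose.length * pose.tent_scale
        if t_len < 2:
            continue
        n_pts = max(12, int(t_len))
        pts = _arc_points(head, ang, t_len, tent_curves[k], n_pts)
        _stamp_disks(img, pts, np.full(n_pts, 2.5), np.full(n_pts, TENTACLE_LEVEL))

    body = np.zeros((size, size), dtype=np.float64)
    _stamp_disks(body, mid, radii, bands)
    body_mask = body > 0
    img[body_mask] = body[body_mask]
    return img, body_mask, mid


def _truth_ellipse(body_mask: np.ndarray, head_xy: np.ndarray) -> dict:
    """Measure the true body ellipse from the noise-free mask.

    Uses skimage regionprops (an implementation independent of the
    preprocessor's own moment fit).  regionprops' ``orientation`` is the
    angle between the row axis and the major axis, counterclockwise; the
    major-axis direction in (x=col, y=row) coordinates is (sin o, cos o).
    """
    props = regionprops(sk_label(body_mask))[0]
    cy, cx = props.centroid
    o = props.orientation
    vx, vy = np.sin(o), np.cos(o)
    angle = wrap_angle_deg(np.rad2deg(np.arctan2(vy, vx)))
    hv = head_xy - np.array([cx, cy])
    sign = np.sign(hv @ np.array([vx, vy])) or 1.0
    hx, hy = sign * vx, sign * vy
    return dict(cx=cx, cy=cy, major=props.axis_major_length,
                minor=props.axis_minor_length, angle_deg=angle,
                head_x=hx, head_y=hy)


def make_behavior_clip(spec: SyntheticSpec) -> tuple[VideoClip, GroundTruth]:
    """Render a synthetic behavior clip and its ground truth."""
    rng = np.random.default_rng(spec.seed)
    poses = _behavior_schedule(spec, rng)
    band_phase = rng.uniform(0, 2 * np.pi)
    tent_fan = np.linspace(-65.0, 65.0, max(spec.n_tentacles, 1))
    tent_curves = rng.uniform(-0.8, 0.8, size=max(spec.n_tentacles, 1))
    noise = rng.normal(0.0, spec.noise_sd, size=(spec.n_frames, spec.image_size,
                                                 spec.image_size))

    frames = np.empty((spec.n_frames, spec.image_size, spec.image_size),
                      dtype=np.uint8)
    rows = []
    for i, pose in enumerate(poses):
        img, body_mask, mid = _render_frame(spec, pose, band_phase,
                                            tent_curves, tent_fan)
        rows.append({"frame": i, **_truth_ellipse(body_mask, mid[-1])})
        if spec.noise_sd > 0:
            img = img + noise[i]
        frames[i] = np.clip(img, 0, 255).astype(np.uint8)

    code = 0 if spec.behavior == "egestion" else NAME_TO_CLASS[spec.behavior].code
    labels = np.full(spec.n_frames, code, dtype=int)
    egestion_times = [spec.n_frames // 2] if spec.behavior == "egestion" else []
    clip = VideoClip(frames, spec.frame_rate_hz,
                     {"synthetic": True, "behavior": spec.behavior,
                      "seed": spec.seed})
    truth = GroundTruth(labels, pd.DataFrame(rows), egestion_times)
    return clip, truth


def make_width_trace(n_frames: int, egestion_times, baseline_px: float,
                     drop_frac: float, noise_sd: float, seed: int,
                     frame_rate_hz: float = 5.0,
                     recovery_s: float = 1200.0) -> np.ndarray:
    """Body-width time series with step drops at known egestion times.

    Each event drops the width by ``baseline_px * drop_frac`` within one
    frame; the width then relaxes linearly back to baseline over
    ``recovery_s`` seconds (default 20 min — the expelled cavity fluid is
    reaccumulated slowly, so the deflation outlasts the detection filter's
    mean-width windows).  Gaussian noise of ``noise_sd`` px is added.
    """
    if not (0.0 < drop_frac < 1.0):
        raise ValueError("drop_frac must lie in (0, 1)")
    times = sorted(int(t) for t in egestion_times)
    for t in times:
        if not (0 <= t < n_frames):
            raise ValueError(f"egestion time {t} outside [0, {n_frames})")
    rng = np.random.default_rng(seed)
    trace = np.full(n_frames, float(baseline_px))
    n_rec = max(1, int(round(recovery_s * frame_rate_hz)))
    drop = baseline_px * drop_frac
    for t in times:
        end = min(n_frames, t + n_rec)
        ramp = drop * (1.0 - np.arange(end - t) / n_rec)
        trace[t:end] -= np.maximum(ramp, 0.0)
    if noise_sd > 0:
        trace = trace + rng.normal(0.0, noise_sd, size=n_frames)
    return trace


# ---------------------------------------------------------------------------
# ground-truth JSON sidecar


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Serialize a GroundTruth record as a JSON sidecar file."""
    import json

    payload = {
        "per_frame_label": truth.per_frame_label.tolist(),
        "ellipse_track": truth.ellipse_track.to_dict(orient="list"),
        "egestion_times": list(truth.egestion_times),
    }
    Path(path).write_text(json.dumps(payload))


def read_ground_truth(path: str | Path) -> GroundTruth:
    import json

    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        np.asarray(payload["per_frame_label"], dtype=int),
        pd.DataFrame(payload["ellipse_track"]),
        [int(t) for t in payload["egestion_times"]],
    )


# ---------------------------------------------------------------------------
# label CSV I/O


def write_labels(labels, path: str | Path) -> None:
    """Write per-frame behavior codes as a ``frame_index,label_code`` CSV."""
    labels = np.asarray(labels, dtype=int)
    validate_codes(labels)
    pd.DataFrame({"frame_index": np.arange(labels.size),
                  "label_code": labels}).to_csv(path, index=False)


def read_labels(path: str | Path) -> np.ndarray:
    """Read a per-frame label CSV, validating codes against the class table."""
    df = pd.read_csv(path)
    for col in ("frame_index", "label_code"):
        if col not in df.columns:
            raise ValueError(f"label CSV missing column {col!r}")
    bad = df[~df["label_code"].isin(CODE_TO_CLASS)]
    if len(bad):
        raise ValueError(
            "unknown label codes at rows "
            f"{bad.index.tolist()}: {sorted(bad['label_code'].unique())}"
        )
    df = df.sort_values("frame_index")
    return df["label_code"].to_numpy(dtype=int)
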