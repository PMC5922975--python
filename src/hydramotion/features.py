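"""Dense-trajectory interest points and local motion/appearance descriptors.

Interest points are seeded on a 5-px grid inside the animal mask, skipped in
low-texture regions (corner response below 1% of the frame maximum), and
advected for 15 frames by median-filtered dense optical flow.  Trajectories
that are effectively static (coordinate standard deviation < 0.1 px),
erratic (std > 50 px) or teleporting (any single step > 50 px) are
discarded — the standard static/erratic filters of dense-trajectory
pipelines.

Each surviving trajectory carries four descriptors accumulated over the
32x32 px patch around the tracked point across its 15-frame span, each a
single-cell orientation histogram:

* HOG  — 8 bins of unsigned (180 deg) image-gradient orientation,
  magnitude-weighted;
* HOF  — 8 bins of signed (360 deg) optical-flow orientation plus one
  explicit zero bin collecting flow magnitudes below a threshold
  (default 0.4 px/frame): 9 bins total;
* MBHx / MBHy — 8 bins of signed orientation of the spatial gradient of the
  horizontal / vertical flow component, magnitude-weighted.  A locally
  constant flow has vanishing gradients, so its MBH histograms carry
  (near-)zero mass and stay all-zero after normalization.

Histograms are l2-normalized per descriptor (all-zero stays all-zero).
Descriptor computation uses per-bin integral images, so each patch histogram
is a handful of lookups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt, map_coordinates, median_filter
from skimage.feature import corner_shi_tomasi
from skimage.registration import optical_flow_ilk

from .config import PipelineConfig
from .preprocess import BodyParts, RegisteredWindow

HOF_BINS = 9   # 8 orientations + zero bin
HOG_BINS = 8
MBH_BINS = 8

PART_ORDER = ("tentacle", "upper", "lower")
DESC_ORDER = ("hof", "hog", "mbhx", "mbhy")
DESC_DIMS = {"hof": HOF_BINS, "hog": HOG_BINS, "mbhx": MBH_BINS, "mbhy": MBH_BINS}


@dataclass
class Trajectory:
    """One tracked interest point."""

    points: np.ndarray          # (L, 2) (x, y) per frame of the span
    start_frame: int
    body_part: str | None = None


@dataclass
class DescriptorSet:
    """The four histograms of one trajectory."""

    hof: np.ndarray
    hog: np.ndarray
    mbhx: np.ndarray
    mbhy: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"hof": self.hof, "hog": self.hog, "mbhx": self.mbhx,
                "mbhy": self.mbhy}


def sample_points(mask: np.ndarray, spacing: int = 5) -> np.ndarray:
    """Grid points at ``spacing`` px restricted to the mask; (N, 2) (x, y)."""
    h, w = mask.shape
    ys = np.arange(0, h, spacing)
    xs = np.arange(0, w, spacing)
    gy, gx = np.meshgrid(ys, xs, indexing="ij")
    keep = mask[gy, gx]
    return np.stack([gx[keep], gy[keep]], axis=1).astype(float)


def compute_flows(frames: np.ndarray, radius: int = 8,
                  num_warp: int = 3) -> np.ndarray:
    """Dense optical flow between consecutive frames.

    Iterative Lucas-Kanade flow; returns (T-1, 2, H, W) with components
    (u=dx, v=dy), median-filtered with a 3x3 kernel before use, matching
    the smoothing applied before point advection in dense-trajectory
    tracking.  Three warp iterations suffice for the few-px/frame motions
    of a registered window.
    """
    T = frames.shape[0]
    flows = np.empty((T - 1, 2) + frames.shape[1:], dtype=np.float32)
    for t in range(T - 1):
        v, u = optical_flow_ilk(frames[t], frames[t + 1], radius=radius,
                                num_warp=num_warp)
        flows[t, 0] = median_filter(u, size=3)
        flows[t, 1] = median_filter(v, size=3)
    return flows


def _sample_flow(flow: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Bilinear flow lookup at (x, y) points; returns (N, 2) (dx, dy)."""
    coords = np.stack([pts[:, 1], pts[:, 0]])  # (row, col)
    dx = map_coordinates(flow[0], coords, order=1, mode="nearest")
    dy = map_coordinates(flow[1], coords, order=1, mode="nearest")
    return np.stack([dx, dy], axis=1)


def track_trajectories(window: RegisteredWindow,
                       config: PipelineConfig | None = None,
                       flows: np.ndarray | None = None) -> list[Trajectory]:
    """Seed, advect and filter dense trajectories in a registered window."""
    config = config or PipelineConfig()
    frames = window.frames
    T = frames.shape[0]
    L = config.track_length
    if T < L:
        raise ValueError(f"window of {T} frames shorter than track length {L}")
    if flows is None:
        flows = compute_flows(frames)

    spacing = config.sample_spacing_px
    h, w = frames.shape[1:]
    occupied = np.zeros((T, h // spacing + 1, w // spacing + 1), dtype=bool)

    raw: list[Trajectory] = []
    for start in range(0, T - L + 1):
        response = corner_shi_tomasi(frames[start])
        thresh = config.quality_frac * response.max() if response.max() > 0 else np.inf
        pts = sample_points(window.mask, spacing)
        if pts.size == 0:
            continue
        quality = map_coordinates(response, np.stack([pts[:, 1], pts[:, 0]]),
                                  order=1)
        pts = pts[quality >= thresh]
        fresh = []
        for p in pts:
            gx, gy = int(p[0] // spacing), int(p[1] // spacing)
            if not occupied[start, gy, gx]:
                fresh.append(p)
        if not fresh:
            continue
        track = np.empty((len(fresh), L, 2))
        track[:, 0] = np.asarray(fresh)
        cur = np.asarray(fresh, dtype=float)
        for step in range(L - 1):
            cur = cur + _sample_flow(flows[start + step], cur)
            cur[:, 0] = np.clip(cur[:, 0], 0, w - 1)
            cur[:, 1] = np.clip(cur[:, 1], 0, h - 1)
            track[:, step + 1] = cur
        for i in range(len(fresh)):
            traj = Trajectory(track[i], start)
            raw.append(traj)
            for step in range(L):
                px, py = track[i, step]
                occupied[start + step, int(py // spacing), int(px // spacing)] = True

    kept = []
    for traj in raw:
        pts = traj.points
        spread = float(np.sqrt(pts[:, 0].var() + pts[:, 1].var()))
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if spread < config.min_displacement_std:
            continue
        if spread > config.max_displacement_std:
            continue
        if steps.size and steps.max() > config.max_step_px:
            continue
        kept.append(traj)
    return kept


def filter_trajectory(points: np.ndarray, min_std: float = 0.1,
                      max_std: float = 50.0, max_step: float = 50.0) -> bool:
    """Displacement filters as a standalone predicate (True = keep)."""
    pts = np.asarray(points, float)
    spread = float(np.sqrt(pts[:, 0].var() + pts[:, 1].var()))
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if spread < min_std or spread > max_std:
        return False
    return not (steps.size and steps.max() > max_step)


# ---------------------------------------------------------------------------
# descriptor maps


def _integral(maps: np.ndarray) -> np.ndarray:
    """Per-bin 2-D integral images with a zero top/left border."""
    nbin, h, w = maps.shape
    out = np.zeros((nbin, h + 1, w + 1), dtype=np.float64)
    np.cumsum(maps, axis=1, out=out[:, 1:, 1:])
    np.cumsum(out[:, 1:, 1:], axis=2, out=out[:, 1:, 1:])
    return out


def _box_sum(integral: np.ndarray, x0, y0, x1, y1) -> np.ndarray:
    return (integral[:, y1, x1] - integral[:, y0, x1]
            - integral[:, y1, x0] + integral[:, y0, x0])


def _orientation_hist_maps(gx: np.ndarray, gy: np.ndarray, nbins: int,
                           full_circle: bool) -> np.ndarray:
    """(nbins, H, W) magnitude-weighted hard-assigned orientation maps."""
    mag = np.hypot(gx, gy)
    ang = np.arctan2(gy, gx)
    if full_circle:
        frac = (ang + np.pi) / (2 * np.pi)
    else:
        frac = (ang % np.pi) / np.pi
    idx = np.minimum((frac * nbins).astype(int), nbins - 1)
    maps = np.zeros((nbins,) + gx.shape)
    for b in range(nbins):
        maps[b][idx == b] = mag[idx == b]
    return maps


def _hof_maps(flow: np.ndarray, zero_thresh: float) -> np.ndarray:
    """(9, H, W): 8 signed flow-orientation bins + zero bin (index 8)."""
    u, v = flow
    mag = np.hypot(u, v)
    maps = np.zeros((HOF_BINS,) + u.shape)
    moving = mag >= zero_thresh
    ang = np.arctan2(v, u)
    frac = (ang + np.pi) / (2 * np.pi)
    idx = np.minimum((frac * 8).astype(int), 7)
    for b in range(8):
        sel = moving & (idx == b)
        maps[b][sel] = mag[sel]
    maps[8][~moving] = 1.0
    return maps


class WindowDescriptorMaps:
    """Precomputed per-frame integral histogram maps for one window."""

    def __init__(self, window: RegisteredWindow, flows: np.ndarray,
                 config: PipelineConfig):
        self.config = config
        frames = window.frames
        T = frames.shape[0]
        self.shape = frames.shape[1:]
        self.hog = []
        self.hof = []
        self.mbhx = []
        self.mbhy = []
        for t in range(T):
            gy, gx = np.gradient(frames[t].astype(np.float64))
            self.hog.append(_integral(_orientation_hist_maps(gx, gy, HOG_BINS,
                                                             full_circle=False)))
        for t in range(T - 1):
            self.hof.append(_integral(_hof_maps(flows[t],
                                                config.hof_zero_thresh)))
            uy, ux = np.gradient(flows[t, 0].astype(np.float64))
            vy, vx = np.gradient(flows[t, 1].astype(np.float64))
            self.mbhx.append(_integral(_orientation_hist_maps(ux, uy, MBH_BINS,
                                                              full_circle=True)))
            self.mbhy.append(_integral(_orientation_hist_maps(vx, vy, MBH_BINS,
                                                              full_circle=True)))

    def _accumulate(self, integrals, times, pts, nbins) -> np.ndarray:
        h, w = self.shape
        half = self.config.patch_px // 2
        out = np.zeros(nbins)
        for t, (x, y) in zip(times, pts):
            x0 = int(np.clip(x - half, 0, w)); x1 = int(np.clip(x + half, 0, w))
            y0 = int(np.clip(y - half, 0, h)); y1 = int(np.clip(y + half, 0, h))
            if x0 >= x1 or y0 >= y1:
                continue
            out += _box_sum(integrals[t], x0, y0, x1, y1)
        return out


def _l2(h: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(h)
    return h / n if n > 0 else h


def compute_descriptors(maps: WindowDescriptorMaps,
                        trajectory: Trajectory) -> DescriptorSet:
    """Accumulate the four patch histograms along one trajectory."""
    pts = trajectory.points
    L = pts.shape[0]
    t0 = trajectory.start_frame
    hog_times = range(t0, t0 + L)
    flow_times = range(t0, t0 + L - 1)
    hog = maps._accumulate(maps.hog, hog_times, pts, HOG_BINS)
    hof = maps._accumulate(maps.hof, flow_times, pts[:-1], HOF_BINS)
    mbhx = maps._accumulate(maps.mbhx, flow_times, pts[:-1], MBH_BINS)
    mbhy = maps._accumulate(maps.mbhy, flow_times, pts[:-1], MBH_BINS)
    return DescriptorSet(_l2(hof), _l2(hog), _l2(mbhx), _l2(mbhy))


def assign_body_part(trajectory: Trajectory, parts: BodyParts) -> str:
    """Part containing the trajectory's mean position; else nearest part."""
    mean = trajectory.points.mean(axis=0)
    x, y = int(round(mean[0])), int(round(mean[1]))
    h, w = parts.tentacle_mask.shape
    x = int(np.clip(x, 0, w - 1)); y = int(np.clip(y, 0, h - 1))
    for name, mask in parts.as_dict().items():
        if mask[y, x]:
            return name
    best, best_d = "upper", np.inf
    for name, mask in parts.as_dict().items():
        if not mask.any():
            continue
        d = distance_transform_edt(~mask)[y, x]
        if d < best_d:
            best, best_d = name, d
    return best


def window_descriptors(window: RegisteredWindow,
                       config: PipelineConfig | None = None
                       ) -> dict[str, dict[str, np.ndarray]]:
    """All descriptors of a window grouped as {part: {type: (N, d) array}}.

    Parts or types with no surviving trajectories get empty (0, d) arrays.
    """
    config = config or PipelineConfig()
    flows = compute_flows(window.frames)
    trajectories = track_trajectories(window, config, flows=flows)
    maps = WindowDescriptorMaps(window, flows, config)
    grouped: dict[str, dict[str, list[np.ndarray]]] = {
        p: {d: [] for d in DESC_ORDER} for p in PART_ORDER}
    for traj in trajectories:
        traj.body_part = assign_body_part(traj, window.parts)
        desc = compute_descriptors(maps, traj)
        for name, hist in desc.as_dict().items():
            grouped[traj.body_part][name].append(hist)
    return {
        p: {d: (np.array(v) if v else np.empty((0, DESC_DIMS[d])))
            for d, v in by_type.items()}
        for p, by_type in grouped.items()
    }
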