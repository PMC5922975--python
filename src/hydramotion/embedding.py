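"""Unsupervised behavioral-motif discovery in a 2-D embedding space.

PCA-reduced Fisher vectors are embedded in 2-D with t-SNE (Euclidean
distances, perplexity 16, PCA initialization with a fixed seed).  A
probability density over the embedding plane is obtained by convolving the
embedded points with a Gaussian kernel whose sigma is a fraction (default
1/40) of the maximum absolute coordinate.  Density peaks are dilated by 3 px
(merging near-duplicate peaks), and a watershed on the inverted distance
transform of the peak mask partitions the plane into motif regions — in
effect each grid cell drains to its nearest peak cluster.  Regions are
annotated with the majority manual label of the training points they
contain; new windows are placed into the frozen map by minimizing their
t-SNE mismatch (KL divergence of perplexity-calibrated input similarities
vs Student-t map similarities) over their 2-D coordinate only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt
from scipy.optimize import minimize
from skimage.feature import peak_local_max
from skimage.measure import label as sk_label
from skimage.morphology import dilation, disk
from skimage.segmentation import watershed
from sklearn.manifold import TSNE

from .classes import NONE_CODE, prominence
from .config import PipelineConfig


def embed(vectors: np.ndarray, perplexity: float = 16.0, seed: int = 0
          ) -> np.ndarray:
    """2-D t-SNE embedding of (PCA-reduced) window vectors."""
    X = np.asarray(vectors, float)
    n = X.shape[0]
    if n < 3 * perplexity:
        raise ValueError(
            f"{n} points is too few for perplexity {perplexity} "
            f"(need >= {int(3 * perplexity)})")
    tsne = TSNE(n_components=2, perplexity=perplexity, metric="euclidean",
                init="pca", random_state=seed, method="exact" if n < 1500
                else "barnes_hut")
    return tsne.fit_transform(X)


@dataclass
class DensityGrid:
    """Gaussian-kernel density on a square grid over the embedding plane."""

    values: np.ndarray      # (G, G), rows = y, cols = x
    x_axis: np.ndarray
    y_axis: np.ndarray
    sigma: float

    def cell_area(self) -> float:
        return float((self.x_axis[1] - self.x_axis[0])
                     * (self.y_axis[1] - self.y_axis[0]))

    def integral(self) -> float:
        return float(self.values.sum() * self.cell_area())

    def locate(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Grid (row, col) indices of (x, y) points, clipped to the grid."""
        pts = np.atleast_2d(points)
        col = np.searchsorted(self.x_axis, pts[:, 0])
        row = np.searchsorted(self.y_axis, pts[:, 1])
        col = np.clip(col, 0, self.x_axis.size - 1)
        row = np.clip(row, 0, self.y_axis.size - 1)
        return row, col


def density_map(points: np.ndarray, sigma_frac: float = 1.0 / 40.0,
                grid_n: int = 501, padding: float = 0.10) -> DensityGrid:
    """Gaussian-kernel density of the embedded points.

    Sigma is ``sigma_frac`` of the maximum absolute coordinate in the
    embedding (the map extent); the grid covers the data with fractional
    ``padding`` and the density integrates to ~1.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    extent = np.abs(pts).max()
    if extent == 0:
        extent = 1.0
    sigma = sigma_frac * extent
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    span = np.maximum(hi - lo, 1e-6)
    lo = lo - padding * span - 3 * sigma
    hi = hi + padding * span + 3 * sigma
    x_axis = np.linspace(lo[0], hi[0], grid_n)
    y_axis = np.linspace(lo[1], hi[1], grid_n)
    gx, gy = np.meshgrid(x_axis, y_axis)
    dens = np.zeros((grid_n, grid_n))
    # direct summation; point counts here are small
    for px, py in pts:
        dens += np.exp(-((gx - px) ** 2 + (gy - py) ** 2) / (2 * sigma**2))
    dens /= pts.shape[0] * 2 * np.pi * sigma**2
    return DensityGrid(dens, x_axis, y_axis, sigma)


def segment_density(density: DensityGrid, peak_threshold_frac: float = 0.01,
                    dilate_px: int = 3) -> np.ndarray:
    """Watershed motif regions seeded at dilated density peaks.

    Local maxima above ``peak_threshold_frac`` of the maximum density are
    dilated by ``dilate_px`` (so peaks closer than the dilation merge into
    one seed); the watershed of the inverted distance-to-peak map assigns
    every grid cell to a region.  Returns an integer region grid (labels
    from 1).
    """
    vals = density.values
    if vals.max() <= vals.min():
        raise ValueError("density map is constant")
    peaks = peak_local_max(vals, threshold_abs=peak_threshold_frac * vals.max(),
                           exclude_border=False)
    if peaks.shape[0] == 0:
        return np.ones(vals.shape, dtype=int)
    peak_mask = np.zeros(vals.shape, dtype=bool)
    peak_mask[peaks[:, 0], peaks[:, 1]] = True
    peak_mask = dilation(peak_mask, disk(dilate_px))
    markers = sk_label(peak_mask, connectivity=2)
    dist = distance_transform_edt(~peak_mask)
    return watershed(dist, markers=markers)


def label_regions(region_grid: np.ndarray, density: DensityGrid,
                  points: np.ndarray, labels) -> pd.DataFrame:
    """Majority manual label per region.

    Ties go to the more prominent behavior; regions containing no training
    points are labeled none.  Returns rows
    ``region_id, n_points, majority_label, fraction``.
    """
    labels = np.asarray(labels, int)
    rows_idx, cols_idx = density.locate(np.asarray(points))
    point_regions = region_grid[rows_idx, cols_idx]
    out = []
    for region_id in range(1, int(region_grid.max()) + 1):
        in_region = labels[point_regions == region_id]
        if in_region.size == 0:
            out.append({"region_id": region_id, "n_points": 0,
                        "majority_label": NONE_CODE, "fraction": np.nan})
            continue
        codes, counts = np.unique(in_region, return_counts=True)
        best = max(zip(counts, [prominence(int(c)) for c in codes], codes))
        out.append({"region_id": region_id, "n_points": int(in_region.size),
                    "majority_label": int(best[2]),
                    "fraction": float(best[0] / in_region.size)})
    return pd.DataFrame(out)


@dataclass
class MotifMap:
    """Frozen embedding, density, segmentation and region annotation."""

    train_points: np.ndarray          # (N, 2)
    train_vectors: np.ndarray         # (N, D) PCA-reduced inputs
    density: DensityGrid
    region_grid: np.ndarray
    region_table: pd.DataFrame
    sigma_frac: float
    perplexity: float

    def region_of_points(self, points: np.ndarray) -> np.ndarray:
        r, c = self.density.locate(np.asarray(points))
        return self.region_grid[r, c]


def build_motif_map(vectors: np.ndarray, labels,
                    config: PipelineConfig | None = None,
                    seed: int | None = None) -> MotifMap:
    """Embed, estimate density, segment and annotate in one call."""
    config = config or PipelineConfig()
    seed = config.seed if seed is None else seed
    pts = embed(vectors, config.perplexity, seed)
    dens = density_map(pts, config.sigma_frac, config.density_grid_n,
                       config.density_padding)
    regions = segment_density(dens, config.peak_threshold_frac,
                              config.peak_dilate_px)
    table = label_regions(regions, dens, pts, labels)
    return MotifMap(pts, np.asarray(vectors, float), dens, regions, table,
                    config.sigma_frac, config.perplexity)


def _perplexity_probs(d2: np.ndarray, perplexity: float) -> np.ndarray:
    """Binary-search a Gaussian bandwidth to the target perplexity."""
    beta_lo, beta_hi = 1e-12, 1e12
    beta = 1.0
    target = np.log(perplexity)
    d2 = d2 - d2.min()
    for _ in range(64):
        w = np.exp(-beta * d2)
        s = w.sum()
        if s <= 0:
            beta_hi = beta
            beta = (beta_lo + beta_hi) / 2
            continue
        p = w / s
        h = -np.sum(p[p > 0] * np.log(p[p > 0]))
        if abs(h - target) < 1e-6:
            break
        if h > target:
            beta_lo = beta
        else:
            beta_hi = beta
        beta = (beta_lo + beta_hi) / 2 if beta_hi < 1e12 else beta * 2
    return np.exp(-beta * d2) / np.exp(-beta * d2).sum()


def embed_new(vectors: np.ndarray, motif_map: MotifMap
              ) -> tuple[np.ndarray, np.ndarray]:
    """Place new windows into a frozen motif map.

    Each new point's similarity distribution to the training vectors is
    calibrated to the map's perplexity; its 2-D coordinate is chosen to
    minimize the KL divergence between that distribution and the Student-t
    similarities to the frozen embedded points.  Returns (coordinates,
    region ids).
    """
    X = np.atleast_2d(np.asarray(vectors, float))
    Y = motif_map.train_points
    out = np.empty((X.shape[0], 2))
    for i, x in enumerate(X):
        d2 = np.sum((motif_map.train_vectors - x) ** 2, axis=1)
        p = _perplexity_probs(d2, motif_map.perplexity)

        def kl(y):
            w = 1.0 / (1.0 + np.sum((Y - y) ** 2, axis=1))
            q = w / w.sum()
            mask = p > 0
            return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))

        def grad(y):
            diff = y - Y
            w = 1.0 / (1.0 + np.sum(diff**2, axis=1))
            q = w / w.sum()
            return 2.0 * np.sum(((p - q) * w)[:, None] * diff, axis=0)

        starts = [p @ Y, Y[np.argmax(p)]]
        best, best_val = None, np.inf
        for y0 in starts:
            res = minimize(kl, y0, jac=grad, method="L-BFGS-B")
            if res.fun < best_val:
                best, best_val = res.x, res.fun
        out[i] = best
    return out, motif_map.region_of_points(out)
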