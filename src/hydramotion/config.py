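"""Pipeline configuration.

All defaults are the published operating point of the pipeline: 5 s analysis
windows at 5 Hz, dense sampling every 5 px, 15-frame trajectories, a K=128
diagonal-covariance GMM codebook per descriptor type, power normalization
with alpha=0.5, t-SNE perplexity 16 and a density kernel of 1/40 of the map
extent.  Every field can be overridden from a YAML file or CLI flags.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .classes import BASIC_SIX


@dataclass
class PipelineConfig:
    # windowing
    window_s: float = 5.0
    frame_rate_hz: float = 5.0

    # preprocessing / registration
    canonical_size: int = 300           # output frame side, px
    canonical_body_px: float = 100.0    # registered body (major-axis) length
    opening_radius_px: int = 60         # background opening; > body width
    min_component_frac: float = 0.0025  # connected-component area filter
    mask_dilate_px: int = 3

    # dense trajectories
    sample_spacing_px: int = 5
    track_length: int = 15
    quality_frac: float = 0.01          # corner response, fraction of max
    min_displacement_std: float = 0.1
    max_displacement_std: float = 50.0
    max_step_px: float = 50.0
    patch_px: int = 32
    hof_zero_thresh: float = 0.4        # px/frame; below -> HOF zero bin

    # codebook / encoding
    gmm_k: int = 128
    gmm_subset: int = 256_000
    fv_alpha: float = 0.5

    # classification
    classes: tuple[str, ...] = tuple(BASIC_SIX)
    pca_variance: float = 0.90
    cv_folds: int = 5
    log2_c_grid: tuple[int, ...] = tuple(range(-5, 16, 2))
    log2_g_grid: tuple[int, ...] = tuple(range(-5, 16, 2))

    # embedding
    perplexity: float = 16.0
    sigma_frac: float = 1.0 / 40.0
    density_grid_n: int = 501
    density_padding: float = 0.10
    peak_threshold_frac: float = 0.01
    peak_dilate_px: int = 3

    # egestion
    egestion_half_window_min: float = 15.0

    # reproducibility
    seed: int = 0

    @property
    def window_frames(self) -> int:
        return int(round(self.window_s * self.frame_rate_hz))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(d) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for k, v in d.items():
            if isinstance(v, list):
                v = tuple(v)
            kwargs[k] = v
        return cls(**kwargs)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        """Stable hash of the full configuration, for run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
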