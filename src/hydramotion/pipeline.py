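"""End-to-end orchestration: synthetic animals through features, codebooks,
classification and motif discovery.

These functions chain the per-module operations in pipeline order
(preprocess -> features -> codebook -> encode -> classify / embed) and are
what the CLI subcommands, the example scripts and the evaluation harness
call.  A synthetic "animal" is a set of behavior clips rendered from one
per-animal seed, emulating one recorded individual that performs every
behavior several times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import aggregate_window_label
from .config import PipelineConfig
from .encoding import FisherWindow, GmmCodebook, encode_window, fit_codebooks
from .features import window_descriptors
from .fixtures import BEHAVIORS, GroundTruth, SyntheticSpec, make_behavior_clip
from .preprocess import iter_windows, process_clip, register_window
from .video import VideoClip


@dataclass
class WindowRecord:
    """One analysis window after feature extraction."""

    window_id: str
    descriptors: dict          # {part: {type: (N, d) array}}
    label: int | None = None


def simulate_animal(animal_seed: int, behaviors=None, clips_per_behavior: int = 1,
                    **spec_overrides) -> list[tuple[VideoClip, GroundTruth]]:
    """Render one synthetic animal: clips of each behavior with known truth."""
    behaviors = list(behaviors) if behaviors is not None else list(BEHAVIORS)
    out = []
    for b_idx, behavior in enumerate(behaviors):
        for rep in range(clips_per_behavior):
            seed = animal_seed * 10_000 + b_idx * 100 + rep
            spec = SyntheticSpec(behavior, seed=seed, **spec_overrides)
            out.append(make_behavior_clip(spec))
    return out


def extract_clip_windows(clip: VideoClip, config: PipelineConfig,
                         truth: GroundTruth | None = None,
                         clip_id: str = "clip") -> list[WindowRecord]:
    """Preprocess a clip and extract per-window descriptors (and labels)."""
    geometries = process_clip(clip, config)
    records = []
    for start, sub in iter_windows(clip, config):
        window = register_window(sub, geometries[start:start + config.window_frames],
                                 config)
        desc = window_descriptors(window, config)
        label = None
        if truth is not None:
            label = aggregate_window_label(
                truth.per_frame_label[start:start + config.window_frames])
        records.append(WindowRecord(f"{clip_id}:{start}", desc, label))
    return records


def extract_dataset(animals: dict[str, list[tuple[VideoClip, GroundTruth]]],
                    config: PipelineConfig) -> list[WindowRecord]:
    """Feature extraction over a {animal_id: [(clip, truth), ...]} dataset."""
    records = []
    for animal_id, clips in animals.items():
        for i, (clip, truth) in enumerate(clips):
            behavior = clip.provenance.get("behavior", "clip")
            records.extend(extract_clip_windows(
                clip, config, truth, f"{animal_id}/{behavior}{i}"))
    return records


def encode_records(records: list[WindowRecord],
                   codebooks: dict[str, GmmCodebook],
                   config: PipelineConfig) -> list[FisherWindow]:
    return [
        encode_window(r.descriptors, codebooks, config.fv_alpha,
                      r.window_id, r.label)
        for r in records
    ]


def fisher_matrix(windows: list[FisherWindow]
                  ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stack encoded windows into (X, labels, window_ids)."""
    X = np.vstack([w.vector for w in windows])
    y = np.array([w.label if w.label is not None else -1 for w in windows])
    ids = [w.window_id for w in windows]
    return X, y, ids


def synthetic_study(n_train_animals: int = 5, n_test_animals: int = 2,
                    clips_per_behavior: int = 3, behaviors=None,
                    config: PipelineConfig | None = None,
                    seed: int = 0, test_clips_per_behavior: int | None = None,
                    **spec_overrides):
    """Generate, extract and encode a multi-animal synthetic study.

    Returns (train_windows, test_windows, codebooks): Fisher-encoded
    labeled windows for ``n_train_animals`` training and ``n_test_animals``
    held-out animals, with codebooks fitted on the training descriptors
    only.
    """
    config = config or PipelineConfig()
    if behaviors is None:
        behaviors = [b for b in BEHAVIORS if b != "egestion"]
    if test_clips_per_behavior is None:
        test_clips_per_behavior = clips_per_behavior
    spec_overrides.setdefault("frame_rate_hz", config.frame_rate_hz)
    spec_overrides.setdefault("duration_s", config.window_s)

    def build(n_animals, tag, base, n_clips):
        animals = {}
        for a in range(n_animals):
            animals[f"{tag}{a}"] = simulate_animal(
                base + a, behaviors, n_clips, **spec_overrides)
        return animals

    train_records = extract_dataset(
        build(n_train_animals, "train", seed + 1, clips_per_behavior), config)
    test_records = extract_dataset(
        build(n_test_animals, "test", seed + 1 + n_train_animals,
              test_clips_per_behavior), config)
    codebooks = fit_codebooks([r.descriptors for r in train_records],
                              config, seed=seed)
    train_windows = encode_records(train_records, codebooks, config)
    test_windows = encode_records(test_records, codebooks, config)
    return train_windows, test_windows, codebooks
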