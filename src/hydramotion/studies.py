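"""Self-contained evaluation studies on synthetic data.

Each function generates its own inputs from a seed, runs the relevant part
of the pipeline, and returns the measured quantities.  They power both the
acceptance harness and the example scripts; problem sizes are chosen so a
full run fits comfortably on one CPU (see the methods note).
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp
from sklearn.decomposition import PCA

from .classify import evaluate, predict_hard, predict_soft, train
from .config import PipelineConfig
from .egestion import WidthTrace, detect_events, filter_width
from .embedding import build_motif_map, embed_new
from .encoding import GmmCodebook, fisher_vector, fit_pca_whiten
from .fixtures import SyntheticSpec, make_behavior_clip, make_width_trace
from .geometry import angle_difference_deg
from .classify import auc_trapezoid, roc_curve_points
from .pipeline import fisher_matrix, synthetic_study
from .preprocess import (
    fit_body_column,
    geometry_table,
    iter_windows,
    process_clip,
    register_window,
)

#: Reduced-scale study conditions used by the end-to-end evaluations:
#: 144-px synthetic videos with a 52-px body registered into a 144-px
#: canonical frame (52 -> 50 px body length), K=16 GMM components, six
#: behaviors, 6 training / 3 held-out clips per behavior per animal.
STUDY_CONFIG = dict(canonical_size=144, canonical_body_px=50.0,
                    opening_radius_px=22, gmm_k=16)
STUDY_SPEC = dict(image_size=144, body_length_px=52.0)
STUDY_BEHAVIORS = ("silent", "elongation", "tentacle_sway", "body_sway",
                   "bending", "contraction")


def _gmm_loglik(X, w, mu, var):
    d = X.shape[1]
    comp = []
    for i in range(len(w)):
        diff = X - mu[i]
        comp.append(np.log(w[i]) - 0.5 * (np.sum(diff**2 / var[i], axis=1)
                                          + np.sum(np.log(var[i]))
                                          + d * np.log(2 * np.pi)))
    return logsumexp(np.array(comp), axis=0).sum()


def fv_oracle_study(seed: int = 0, n_instances: int = 20) -> dict:
    """Closed-form Fisher vector vs a finite-difference gradient oracle.

    Random small GMMs (K=2, d<=3, T<=10); returns the worst absolute
    element-wise difference across instances.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        K, d = 2, int(rng.integers(1, 4))
        T = int(rng.integers(2, 11))
        w = rng.dirichlet(np.full(K, 5.0))
        mu = rng.normal(0, 1, (K, d))
        var = rng.uniform(0.5, 2.0, (K, d))
        X = rng.normal(0, 1.5, (T, d))
        fv = fisher_vector(X, GmmCodebook(None, w, mu, var))
        sigma = np.sqrt(var)
        eps = 1e-5
        oracle = []
        for i in range(K):
            for j in range(d):
                m1, m2 = mu.copy(), mu.copy()
                m1[i, j] += eps
                m2[i, j] -= eps
                g = (_gmm_loglik(X, w, m1, var)
                     - _gmm_loglik(X, w, m2, var)) / (2 * eps)
                oracle.append(sigma[i, j] / (T * np.sqrt(w[i])) * g)
        for i in range(K):
            for j in range(d):
                s1, s2 = sigma.copy(), sigma.copy()
                s1[i, j] += eps
                s2[i, j] -= eps
                g = (_gmm_loglik(X, w, mu, s1**2)
                     - _gmm_loglik(X, w, mu, s2**2)) / (2 * eps)
                oracle.append(sigma[i, j] / (T * np.sqrt(2 * w[i])) * g)
        worst = max(worst, float(np.abs(fv - np.array(oracle)).max()))
    return {"max_abs_diff": worst, "n": n_instances}


def classification_study(seed: int = 0) -> dict:
    """Train on 5 synthetic animals, test on 2 held-out animals.

    Returns hard/soft accuracies plus the encoded matrices so the motif
    study can reuse the same windows.
    """
    config = PipelineConfig(seed=seed, **STUDY_CONFIG)
    train_w, test_w, _ = synthetic_study(
        n_train_animals=5, n_test_animals=2, clips_per_behavior=6,
        test_clips_per_behavior=3, behaviors=STUDY_BEHAVIORS, config=config,
        seed=seed + 2, **STUDY_SPEC)
    X_train, y_train, _ = fisher_matrix(train_w)
    X_test, y_test, _ = fisher_matrix(test_w)
    model = train(X_train, y_train, config, seed=seed)
    hard = predict_hard(model, X_test, config=config)
    soft = predict_soft(model, X_test, config=config)
    hard_acc = float(np.mean(hard.hard_labels() == y_test))
    soft_acc = evaluate(soft, y_test)["overall_accuracy"]
    return {
        "hard_accuracy": hard_acc, "soft_accuracy": float(soft_acc),
        "n_train": int(y_train.size), "n_test": int(y_test.size),
        "config": config, "model": model,
        "X_train": X_train, "y_train": y_train,
        "X_test": X_test, "y_test": y_test,
    }


def motif_study(classification: dict, seed: int = 0) -> dict:
    """t-SNE density/watershed motif discovery on the study windows."""
    config = classification["config"]
    pca = PCA(n_components=config.pca_variance, svd_solver="full")
    Z_train = pca.fit_transform(classification["X_train"])
    Z_test = pca.transform(classification["X_test"])
    y_train = classification["y_train"]
    y_test = classification["y_test"]
    motif_map = build_motif_map(Z_train, y_train, config, seed=seed)
    populated = motif_map.region_table[motif_map.region_table.n_points > 0]
    discovered = set(populated.majority_label) - {0}
    _, regions = embed_new(Z_test, motif_map)
    lookup = dict(zip(motif_map.region_table.region_id,
                      motif_map.region_table.majority_label))
    match = float(np.mean([lookup.get(r, 0) == t
                           for r, t in zip(regions, y_test)]))
    return {
        "n_regions": int(motif_map.region_grid.max()),
        "behaviors_discovered": len(discovered),
        "holdout_match": match,
        "n_test": int(y_test.size),
        "motif_map": motif_map,
    }


def preprocessing_recovery_study(seed: int = 0, n_frames: int = 50) -> dict:
    """Ellipse recovery and registration scale on noise-free frames.

    Full-resolution conditions (300-px frames, 100-px body).  Clips of all
    behaviors are processed until ``n_frames`` frames are measured.
    """
    config = PipelineConfig(seed=seed)
    rng = np.random.default_rng(seed)
    behaviors = list(STUDY_BEHAVIORS)
    axis_errors, angle_errors, reg_lengths = [], [], []
    measured = 0
    b = 0
    while measured < n_frames:
        behavior = behaviors[b % len(behaviors)]
        spec = SyntheticSpec(behavior, noise_sd=0.0,
                             seed=int(rng.integers(2**31)))
        clip, truth = make_behavior_clip(spec)
        geos = process_clip(clip, config)
        table = geometry_table(geos)
        tt = truth.ellipse_track
        axis_errors.extend(np.abs(table["major"] - tt["major"]))
        axis_errors.extend(np.abs(table["minor"] - tt["minor"]))
        angle_errors.extend(
            angle_difference_deg(a, t)
            for a, t in zip(table["angle_deg"], tt["angle_deg"]))
        start, sub = next(iter_windows(clip, config))
        window = register_window(sub, geos[:config.window_frames], config)
        # one similarity transform serves the whole window, so the scale
        # contract holds for the window-average body length
        frame_lengths = []
        for frame in window.frames:
            ell, _ = fit_body_column(frame, frame > 30)
            frame_lengths.append(ell.major_axis)
        reg_lengths.append(float(np.mean(frame_lengths)))
        measured += clip.n_frames
        b += 1
    return {
        "max_axis_error_px": float(np.max(axis_errors)),
        "max_angle_error_deg": float(np.max(angle_errors)),
        "registered_body_length_px": float(np.mean(reg_lengths)),
        "n": measured,
    }


def egestion_study(seed: int = 0, n_events: int = 5) -> dict:
    """Detector precision/recall: drop 0.4, noise 5% of baseline width."""
    frame_rate = 5.0
    spacing = int(40 * 60 * frame_rate)            # 40 min apart
    truth = [(i + 1) * spacing for i in range(n_events)]
    n_frames = (n_events + 1) * spacing + spacing // 2
    baseline = 30.0
    w = make_width_trace(n_frames, truth, baseline, drop_frac=0.4,
                         noise_sd=0.05 * baseline, seed=seed,
                         frame_rate_hz=frame_rate)
    trace = WidthTrace(w, frame_rate)
    filtered = filter_width(trace, 15.0)
    events = detect_events(filtered, frame_rate, 15.0, raw_trace=trace)
    tol = int(15 * 60 * frame_rate) // 4
    recall = (sum(any(abs(e.frame - t) <= tol for e in events)
                  for t in truth) / len(truth))
    precision = (sum(any(abs(e.frame - t) <= tol for t in truth)
                     for e in events) / len(events)) if events else 0.0
    return {"precision": float(precision), "recall": float(recall),
            "n_events": n_events, "n_detected": len(events)}


def chance_auc_study(seed: int = 0, n: int = 10_000) -> dict:
    """Label-independent scores give AUC ~ 0.5 on the package's own ROC."""
    rng = np.random.default_rng(seed)
    truth = rng.integers(0, 2, n).astype(bool)
    scores = rng.uniform(0, 1, n)
    fpr, tpr = roc_curve_points(scores, truth)
    return {"auc": auc_trapezoid(fpr, tpr), "n": n}


def pca_halving_study(seed: int = 0, n_descriptors: int = 400) -> dict:
    """HOF descriptors (9 bins) keep ceil(9/2) = 5 PCA components."""
    rng = np.random.default_rng(seed)
    by_part = {p: rng.uniform(0, 1, (n_descriptors, 9))
               for p in ("tentacle", "upper", "lower")}
    whitener = fit_pca_whiten(by_part)
    return {"n_components": int(whitener.n_components),
            "n": 3 * n_descriptors}
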