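"""Trace classification into neuron / glia / silent.

Each normalized trace is summarized by a fixed, versioned 8-feature vector
(moments, threshold-crossing statistics, low-frequency power fraction, peak
amplitude) and classified by an AdaBoost ensemble of depth-1 decision trees.
A default model is built deterministically from seeded generator data the
first time it is needed, so the pipeline runs end-to-end without manual
labels; user-supplied label files override it by retraining.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats as sps
from sklearn.ensemble import AdaBoostClassifier
from sklearn.tree import DecisionTreeClassifier

FEATURE_NAMES = (
    "mean",
    "variance",
    "skewness",
    "excess_kurtosis",
    "n_crossings",
    "frac_above",
    "lowfreq_power_frac",
    "max_df_f",
)
FEATURE_SCHEMA_VERSION = 1

CLASSES = ("glia", "neuron", "silent")

__all__ = [
    "FEATURE_NAMES",
    "FEATURE_SCHEMA_VERSION",
    "CLASSES",
    "featurize_traces",
    "train_trace_classifier",
    "classify_traces",
    "default_classifier",
    "robust_noise_sd",
]


def robust_noise_sd(r: np.ndarray) -> np.ndarray:
    """Per-trace noise SD: 1.4826 * MAD of the frame difference / sqrt(2).

    Insensitive to calcium transients, which occupy few frame-to-frame
    differences relative to the baseline.
    """
    r = np.atleast_2d(r)
    d = np.diff(r, axis=1)
    mad = np.median(np.abs(d - np.median(d, axis=1, keepdims=True)), axis=1)
    return 1.4826 * mad / np.sqrt(2.0)


def featurize_traces(
    r: np.ndarray, frame_rate: float, lowfreq_cutoff_hz: float = 0.1
) -> np.ndarray:
    """Deterministic 8-feature vector per normalized trace (rows)."""
    r = np.atleast_2d(np.asarray(r, dtype=np.float64))
    n, T = r.shape
    mean = r.mean(axis=1)
    var = r.var(axis=1)
    with np.errstate(invalid="ignore"):
        skew = sps.skew(r, axis=1)
        kurt = sps.kurtosis(r, axis=1)
    skew = np.where(var > 0, np.nan_to_num(skew), 0.0)
    kurt = np.where(var > 0, np.nan_to_num(kurt), 0.0)

    sd = robust_noise_sd(r)
    thr = 2.0 * np.where(sd > 0, sd, np.inf)
    above = r > thr[:, None]
    n_crossings = (above[:, 1:] & ~above[:, :-1]).sum(axis=1).astype(float)
    frac_above = above.mean(axis=1)

    spec = np.abs(np.fft.rfft(r - mean[:, None], axis=1)) ** 2
    freqs = np.fft.rfftfreq(T, d=1.0 / frame_rate)
    total = spec[:, 1:].sum(axis=1)
    low = spec[:, 1:][:, freqs[1:] < lowfreq_cutoff_hz].sum(axis=1)
    lowfreq = np.where(total > 0, low / np.where(total > 0, total, 1.0), 0.0)

    return np.column_stack(
        [mean, var, skew, kurt, n_crossings, frac_above, lowfreq, r.max(axis=1)]
    )


@dataclass
class TraceClassifier:
    model: AdaBoostClassifier
    schema_version: int = FEATURE_SCHEMA_VERSION


def train_trace_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    n_rounds: int = 50,
    max_depth: int = 1,
) -> TraceClassifier:
    """Adaptive boosting over shallow trees; retrain to refine labels."""
    features = np.atleast_2d(features)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("training labels must contain at least 2 classes")
    if features.shape[1] != len(FEATURE_NAMES):
        raise ValueError(
            f"expected {len(FEATURE_NAMES)} features, got {features.shape[1]}"
        )
    model = AdaBoostClassifier(
        estimator=DecisionTreeClassifier(max_depth=max_depth, random_state=seed),
        n_estimators=n_rounds,
        random_state=seed,
    )
    model.fit(features, labels)
    return TraceClassifier(model=model)


def classify_traces(
    classifier: TraceClassifier, features: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(labels, probabilities)``; probabilities follow model.classes_."""
    features = np.atleast_2d(features)
    if features.shape[1] != len(FEATURE_NAMES):
        raise ValueError("feature schema mismatch")
    labels = classifier.model.predict(features)
    proba = classifier.model.predict_proba(features)
    return labels, proba


@lru_cache(maxsize=4)
def default_classifier(
    duration: float = 600.0, frame_rate: float = 20.0, seed: int = 0
) -> TraceClassifier:
    """Deterministic default model trained on seeded generator data.

    Builds a balanced three-class training culture (equal parts spiking
    neurons, glia and silent ROIs) at the requested recording geometry and
    trains the boosted ensemble on it.
    """
    from dataclasses import replace

    from .imaging import normalize_traces
    from .params import get_preset
    from .synthetic import render_traces, simulate_raster

    base = get_preset("WT-STR")
    feats_all = []
    labels_all = []
    # two training cultures spanning sparse and regular firing, so the
    # neuron/silent boundary sits below the sparsest spiking cells
    for k, indep_rate in enumerate((0.02, 0.05)):
        params = replace(
            base,
            n_rois=240,
            frac_glia=1.0 / 3.0,
            frac_active=0.5,  # half of the non-glia cells spike
            independent_rate=indep_rate,
            duration=duration,
            frame_rate=frame_rate,
            seed=seed + 7919 * k,
        )
        culture = simulate_raster(params)
        rendered = render_traces(culture)
        # train through the same baseline-correction path the model sees
        tm = normalize_traces(rendered.raw, frame_rate)
        feats_all.append(featurize_traces(tm.r, frame_rate))
        labels_all.append(culture.roles.astype(str))
    feats = np.concatenate(feats_all)
    labels = np.concatenate(labels_all)
    return train_trace_classifier(feats, labels, seed=seed)
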