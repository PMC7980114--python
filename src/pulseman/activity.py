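"""Physical-activity recognition from wrist tri-axial acceleration.

The stream is low-pass filtered at 10 Hz to remove sensor noise; the
gravitational component is isolated with a 0.3 Hz low-pass of the
denoised signal, and the dynamic (body-motion) component is their
difference — equivalent to a 0.3-10 Hz band-pass.  The stream is then
cut into non-overlapping 2-second windows and each window is summarized
by a fixed feature vector covering signal intensity and shape (moments),
sensor orientation (gravity direction), physics-based quantities
(velocity change, kinetic-energy proxy) and expert-knowledge counts
(signal peaks, mean crossings), plus inter-axis correlations.  A random
forest maps windows to one of ten everyday activities; evaluation is
leave-one-subject-out with per-class precision/recall/F.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .errors import ContractError, InsufficientDataError, ParameterError
from .metrics import ClassificationEval, evaluate_classification
from .synth import ACTIVITY_LABELS

WINDOW_S = 2.0
NOISE_CUTOFF_HZ = 10.0
GRAVITY_CUTOFF_HZ = 0.3
PEAK_PROMINENCE_G = 0.05

_AXES = ("x", "y", "z")


def split_components(stream: pd.DataFrame, rate: float
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Separate the denoised signal into gravity and dynamic components.

    Returns ``(gravity, dynamic)`` arrays of shape (n, 3) in g; their sum
    reconstructs the 10 Hz-denoised signal exactly by construction.
    """
    if rate < 20.0:
        raise ParameterError("need a sampling rate of at least 20 Hz")
    xyz = stream[["ax_g", "ay_g", "az_g"]].to_numpy(dtype=float)
    sos_noise = sps.butter(4, NOISE_CUTOFF_HZ, btype="low", fs=rate, output="sos")
    sos_grav = sps.butter(2, GRAVITY_CUTOFF_HZ, btype="low", fs=rate, output="sos")
    denoised = sps.sosfiltfilt(sos_noise, xyz, axis=0)
    gravity = sps.sosfiltfilt(sos_grav, denoised, axis=0)
    return gravity, denoised - gravity


@dataclass(frozen=True)
class ActivityWindow:
    """One 2-s segment split into gravity and dynamic components."""

    gravity: np.ndarray     # (n, 3) g
    dynamic: np.ndarray     # (n, 3) g
    start_s: float
    rate: float
    label: str | None = None
    subject_id: str | None = None


def segment_windows(stream: pd.DataFrame, rate: float,
                    window_s: float = WINDOW_S) -> list[ActivityWindow]:
    """Consecutive non-overlapping windows; a trailing partial window is
    dropped.  If the stream has a ``label`` column, each window takes the
    majority label of its samples."""
    if window_s <= 0:
        raise ParameterError("window length must be positive")
    gravity, dynamic = split_components(stream, rate)
    n_per = int(round(window_s * rate))
    t0 = float(stream["time_s"].iloc[0])
    subject = str(stream["subject_id"].iloc[0]) if "subject_id" in stream else None
    labels = stream["label"].to_numpy() if "label" in stream else None
    windows = []
    for start in range(0, len(stream) - n_per + 1, n_per):
        sl = slice(start, start + n_per)
        label = None
        if labels is not None:
            vals, counts = np.unique(labels[sl], return_counts=True)
            label = str(vals[np.argmax(counts)])
        windows.append(ActivityWindow(gravity[sl], dynamic[sl],
                                      t0 + start / rate, rate, label, subject))
    return windows


def _moments(v: np.ndarray) -> tuple[float, float, float, float]:
    var = float(np.var(v))
    if var < 1e-16:
        return float(np.mean(v)), 0.0, 0.0, 0.0   # flat: skew/kurt set to 0
    return (float(np.mean(v)), var,
            float(stats.skew(v)), float(stats.kurtosis(v)))


def extract_activity_features(window: ActivityWindow) -> dict[str, float]:
    """Fixed 65-dimensional feature vector of one window (see module doc)."""
    dyn = window.dynamic
    mag = np.linalg.norm(dyn, axis=1)
    dt = 1.0 / window.rate
    out: dict[str, float] = {}

    channels = {**{a: dyn[:, i] for i, a in enumerate(_AXES)}, "mag": mag}
    for name, v in channels.items():
        mean, var, skew, kurt = _moments(v)
        out[f"dyn_mean_{name}"] = mean
        out[f"dyn_var_{name}"] = var
        out[f"dyn_skew_{name}"] = skew
        out[f"dyn_kurt_{name}"] = kurt
        out[f"dyn_min_{name}"] = float(v.min())
        out[f"dyn_max_{name}"] = float(v.max())
        out[f"dyn_range_{name}"] = float(np.ptp(v))
        out[f"dyn_rms_{name}"] = float(np.sqrt(np.mean(v ** 2)))
        out[f"dyn_iqr_{name}"] = float(np.subtract(*np.percentile(v, [75, 25])))
        out[f"dyn_mad_{name}"] = float(np.median(np.abs(v - np.median(v))))
        # physics: accumulated velocity change and kinetic-energy proxy
        out[f"vel_change_{name}"] = float(np.sum(np.abs(v)) * dt)
        out[f"energy_{name}"] = float(np.mean(v ** 2))

    # orientation from the gravity component
    gmean = window.gravity.mean(axis=0)
    gnorm = float(np.linalg.norm(gmean))
    for i, a in enumerate(_AXES):
        out[f"grav_mean_{a}"] = float(gmean[i])
        cosang = gmean[i] / gnorm if gnorm > 1e-9 else 0.0
        out[f"grav_incl_{a}"] = float(np.arccos(np.clip(cosang, -1.0, 1.0)))

    # expert-knowledge counts per axis and magnitude
    for name, v in channels.items():
        peaks, _ = sps.find_peaks(v, prominence=PEAK_PROMINENCE_G)
        out[f"peaks_{name}"] = float(peaks.size)
        centered = v - v.mean()
        out[f"crossings_{name}"] = float(np.sum(np.signbit(centered[:-1])
                                                != np.signbit(centered[1:])))

    # inter-axis correlations of the dynamic component
    for i, j in ((0, 1), (0, 2), (1, 2)):
        vi, vj = dyn[:, i], dyn[:, j]
        if vi.std() < 1e-9 or vj.std() < 1e-9:
            r = 0.0
        else:
            r = float(np.corrcoef(vi, vj)[0, 1])
        out[f"corr_{_AXES[i]}{_AXES[j]}"] = r
    return out


FEATURE_COUNT = 65  # fixed length of the vector above


def windows_to_table(windows: list[ActivityWindow]) -> pd.DataFrame:
    rows = []
    for w in windows:
        feats = extract_activity_features(w)
        feats["window_start_s"] = w.start_s
        if w.label is not None:
            feats["label"] = w.label
        if w.subject_id is not None:
            feats["subject_id"] = w.subject_id
        rows.append(feats)
    return pd.DataFrame(rows)


@dataclass
class ActivityModel:
    classifier: RandomForestClassifier
    feature_columns: tuple[str, ...]
    seed: int


def train_activity_model(table: pd.DataFrame, seed: int = 0,
                         n_estimators: int = 300) -> ActivityModel:
    """Random-forest classifier over the 10-activity label set."""
    labels = table["label"].astype(str)
    if labels.nunique() < 2:
        raise InsufficientDataError("training needs at least 2 activity classes")
    unknown = set(labels.unique()) - set(ACTIVITY_LABELS)
    if unknown:
        raise ContractError(f"labels outside the activity set: {sorted(unknown)}")
    cols = tuple(c for c in table.columns
                 if c not in ("label", "subject_id", "window_start_s"))
    clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed,
                                 n_jobs=1)
    clf.fit(table[list(cols)], labels)
    return ActivityModel(clf, cols, seed)


def classify_window(model: ActivityModel, features: pd.DataFrame) -> list[str]:
    missing = set(model.feature_columns) - set(features.columns)
    if missing:
        raise ContractError(f"feature schema mismatch, missing {sorted(missing)}")
    return list(model.classifier.predict(features[list(model.feature_columns)]))


def evaluate_activity_loso(table: pd.DataFrame, seed: int = 0,
                           n_estimators: int = 300) -> ClassificationEval:
    """Leave-one-subject-out evaluation aggregated into one confusion
    matrix over all folds."""
    subjects = sorted(table["subject_id"].astype(str).unique())
    if len(subjects) < 2:
        raise InsufficientDataError("LOSO needs at least 2 subjects")
    truth, predicted = [], []
    for subject in subjects:
        mask = table["subject_id"].astype(str) == subject
        model = train_activity_model(table[~mask], seed, n_estimators)
        predicted.extend(classify_window(model, table[mask]))
        truth.extend(table.loc[mask, "label"].astype(str))
    present = tuple(lab for lab in ACTIVITY_LABELS if lab in set(truth) | set(predicted))
    return evaluate_classification(truth, predicted, present)
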