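"""Psychophysiological profile recognition and CBT principle selection.

Weekly structured phone interviews provide short speech segments; the
wristband provides beat-to-beat intervals.  From speech we compute three
base features per 25 ms frame (10 ms hop): fundamental frequency (pitch,
autocorrelation method with a voicing threshold), 13 mel-frequency
cepstral coefficients, and smoothed log energy; each base feature is
summarized by mean, SD, range, maximum and minimum (75 values).  From
the cardiac side we take the mean heart rate and RMSSD (the root mean
square of successive inter-beat-interval differences, a short-term
vagal-tone index).  A classifier maps the fused feature vector to one of
three profiles — motivated, anxious, depressed — and each profile selects
the cognitive-dissonance principle used to phrase motivational messages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.fft import dct, rfft
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import (ContractError, DegenerateSignalError,
                     InsufficientDataError, ParameterError)
from .metrics import ClassificationEval, evaluate_classification
from .synth import PROFILE_LABELS

FRAME_S = 0.025
HOP_S = 0.010
N_MFCC = 13
N_MEL = 26
PITCH_MIN_HZ = 50.0
PITCH_MAX_HZ = 500.0
VOICING_THRESHOLD = 0.3
ENERGY_SMOOTH_FRAMES = 5
REFERENCE_RMS = 0.1

STAT_NAMES = ("mean", "sd", "range", "max", "min")
BASE_FEATURES = ("pitch", *[f"mfcc{i}" for i in range(1, N_MFCC + 1)], "energy")

# Festinger's cognitive-dissonance principles per profile: the phrasing
# strategy of motivational messages in cognitive behavioral therapy.
CBT_PRINCIPLES = {
    "motivated": "cognitive consequences of forced compliance",
    "anxious": "free choice",
    "depressed": "effort justification",
}

PROFILE_ALGORITHMS = ("naive_bayes", "mlp", "random_forest", "svm")


@dataclass(frozen=True)
class SpeechSegment:
    samples: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if not np.all(np.isfinite(samples)):
            raise ContractError("audio contains non-finite samples")
        if self.sampling_rate <= 0:
            raise ParameterError("sampling rate must be positive")
        if samples.size < self.sampling_rate:
            raise ContractError("segment must be at least 1 s long")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate


def preprocess_audio(segment: SpeechSegment,
                     reference_rms: float = REFERENCE_RMS) -> SpeechSegment:
    """Remove DC and normalize RMS level, so recording gain and offset do
    not influence the features."""
    x = segment.samples - segment.samples.mean()
    rms = np.sqrt(np.mean(x ** 2))
    if rms < 1e-12:
        raise DegenerateSignalError("silent audio segment")
    return SpeechSegment(x * (reference_rms / rms), segment.sampling_rate)


def _frames(x: np.ndarray, fs: float) -> np.ndarray:
    flen = int(round(FRAME_S * fs))
    hop = int(round(HOP_S * fs))
    n = 1 + max(0, (x.size - flen) // hop)
    idx = np.arange(flen)[None, :] + hop * np.arange(n)[:, None]
    return x[idx]


def _pitch_autocorr(frame: np.ndarray, fs: float) -> float:
    """F0 of one frame via the normalized autocorrelation peak in the
    50-500 Hz lag band; returns NaN for unvoiced frames."""
    frame = frame - frame.mean()
    energy = float(np.dot(frame, frame))
    if energy < 1e-12:
        return np.nan
    ac = np.correlate(frame, frame, mode="full")[frame.size - 1:]
    lo = max(2, int(fs / PITCH_MAX_HZ))
    hi = min(frame.size - 1, int(fs / PITCH_MIN_HZ))
    if hi <= lo:
        return np.nan
    lag = lo + int(np.argmax(ac[lo:hi + 1]))
    if ac[lag] / ac[0] < VOICING_THRESHOLD:
        return np.nan
    return fs / lag


def _mel_filterbank(fs: float, n_fft: int) -> np.ndarray:
    def hz_to_mel(f):
        return 2595.0 * np.log10(1.0 + f / 700.0)

    def mel_to_hz(m):
        return 700.0 * (10.0 ** (m / 2595.0) - 1.0)

    mels = np.linspace(hz_to_mel(0.0), hz_to_mel(fs / 2.0), N_MEL + 2)
    hz = mel_to_hz(mels)
    bins = np.floor((n_fft + 1) * hz / fs).astype(int)
    fb = np.zeros((N_MEL, n_fft // 2 + 1))
    for i in range(N_MEL):
        a, b, c = bins[i], bins[i + 1], bins[i + 2]
        if b > a:
            fb[i, a:b] = (np.arange(a, b) - a) / (b - a)
        if c > b:
            fb[i, b:c] = (c - np.arange(b, c)) / (c - b)
    return fb


@dataclass(frozen=True)
class SpeechFeatures:
    """75-value summary (5 statistics x 15 base features) of one segment."""

    values: dict[str, float]
    pitch_missing: bool

    def vector(self) -> np.ndarray:
        return np.array([self.values[f"{b}_{s}"]
                         for b in BASE_FEATURES for s in STAT_NAMES])


def extract_speech_features(segment: SpeechSegment) -> SpeechFeatures:
    """Frame-level pitch / MFCC / smoothed-energy tracks summarized by
    mean, SD, range, max and min.

    Unvoiced frames are excluded from the pitch statistics; if no frame
    is voiced the pitch statistics are NaN and flagged missing.
    """
    x, fs = segment.samples, segment.sampling_rate
    frames = _frames(x, fs)
    window = np.hanning(frames.shape[1])
    n_fft = int(2 ** np.ceil(np.log2(frames.shape[1])))

    spectra = np.abs(rfft(frames * window, n=n_fft, axis=1)) ** 2
    fb = _mel_filterbank(fs, n_fft)
    mel_energy = np.log(spectra @ fb.T + 1e-12)
    mfcc = dct(mel_energy, type=2, norm="ortho", axis=1)[:, 1:N_MFCC + 1]

    log_energy = 10.0 * np.log10(np.mean((frames * window) ** 2, axis=1) + 1e-12)
    # edge-replicating moving average: no spurious roll-off at segment ends
    from scipy.ndimage import uniform_filter1d
    smoothed = uniform_filter1d(log_energy, ENERGY_SMOOTH_FRAMES, mode="nearest")

    pitch = np.array([_pitch_autocorr(f, fs) for f in frames])
    voiced = pitch[np.isfinite(pitch)]

    def stats(v: np.ndarray) -> dict[str, float]:
        if v.size == 0:
            return dict.fromkeys(STAT_NAMES, np.nan)
        return {"mean": float(v.mean()), "sd": float(v.std()),
                "range": float(np.ptp(v)), "max": float(v.max()),
                "min": float(v.min())}

    values: dict[str, float] = {}
    for stat, val in stats(voiced).items():
        values[f"pitch_{stat}"] = val
    for i in range(N_MFCC):
        for stat, val in stats(mfcc[:, i]).items():
            values[f"mfcc{i + 1}_{stat}"] = val
    for stat, val in stats(smoothed).items():
        values[f"energy_{stat}"] = val
    return SpeechFeatures(values, pitch_missing=voiced.size == 0)


def compute_rmssd(intervals_ms) -> float:
    """RMSSD (ms): sqrt of the mean squared successive difference of
    beat-to-beat intervals.  Intervals outside the plausible 250-2400 ms
    band are rejected with a warning."""
    iv = np.asarray(list(intervals_ms), dtype=float)
    in_range = (iv >= 250.0) & (iv <= 2400.0)
    if not in_range.all():
        warnings.warn(f"rejected {int((~in_range).sum())} out-of-range intervals")
        iv = iv[in_range]
    if iv.size < 2:
        raise InsufficientDataError("RMSSD needs at least 2 intervals")
    return float(np.sqrt(np.mean(np.diff(iv) ** 2)))


def select_cbt_principle(profile: str) -> str:
    """Festinger principle used to phrase messages for a profile."""
    if profile not in CBT_PRINCIPLES:
        raise ParameterError(f"unknown profile {profile!r}")
    return CBT_PRINCIPLES[profile]


@dataclass
class ProfileModel:
    pipeline: Pipeline
    feature_columns: tuple[str, ...]
    algorithm: str
    seed: int


def _make_classifier(algorithm: str, seed: int):
    if algorithm == "naive_bayes":
        return GaussianNB()
    if algorithm == "mlp":
        return MLPClassifier(hidden_layer_sizes=(32,), max_iter=2000,
                             random_state=seed)
    if algorithm == "random_forest":
        return RandomForestClassifier(n_estimators=300, random_state=seed, n_jobs=1)
    if algorithm == "svm":
        return SVC(kernel="rbf", random_state=seed)
    raise ParameterError(f"unknown algorithm {algorithm!r}; "
                         f"choose from {PROFILE_ALGORITHMS}")


def train_profile_model(table: pd.DataFrame, algorithm: str = "svm",
                        seed: int = 0) -> ProfileModel:
    """Fit a 3-class profile classifier on fused speech + cardiac rows."""
    labels = set(table["label"].astype(str).unique())
    if labels != set(PROFILE_LABELS):
        raise InsufficientDataError(
            f"training requires all profiles {PROFILE_LABELS}, got {sorted(labels)}")
    cols = tuple(c for c in table.columns if c not in ("label", "subject_id"))
    pipe = Pipeline([("scale", StandardScaler()),
                     ("clf", _make_classifier(algorithm, seed))])
    pipe.fit(table[list(cols)], table["label"].astype(str))
    return ProfileModel(pipe, cols, algorithm, seed)


def classify_profile(model: ProfileModel, features: pd.DataFrame) -> list[str]:
    missing = set(model.feature_columns) - set(features.columns)
    if missing:
        raise ContractError(f"feature schema mismatch, missing {sorted(missing)}")
    return list(model.pipeline.predict(features[list(model.feature_columns)]))


def evaluate_profile_loso(table: pd.DataFrame, algorithm: str = "svm",
                          seed: int = 0
                          ) -> tuple[ClassificationEval, float]:
    """Leave-one-subject-out evaluation; returns the harness result and
    the majority-baseline accuracy (%): a dummy that always predicts the
    most frequent profile scores exactly the largest class share of the
    evaluated instances."""
    subjects = sorted(table["subject_id"].astype(str).unique())
    if len(subjects) < 2:
        raise InsufficientDataError("LOSO needs at least 2 subjects")
    truth, predicted = [], []
    for subject in subjects:
        mask = table["subject_id"].astype(str) == subject
        train = table[~mask]
        if set(train["label"].astype(str).unique()) != set(PROFILE_LABELS):
            continue
        model = train_profile_model(train, algorithm, seed)
        predicted.extend(classify_profile(model, table[mask]))
        truth.extend(table.loc[mask, "label"].astype(str))
    ev = evaluate_classification(truth, predicted, PROFILE_LABELS)
    counts = pd.Series(truth).value_counts()
    baseline_acc = float(counts.iloc[0] / counts.sum() * 100.0)
    return ev, baseline_acc
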