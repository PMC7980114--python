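"""Cuffless blood-pressure estimation from quality-screened PPG cycles.

Each kept cardiac cycle yields a feature vector combining

* temporal morphology (durations, amplitudes, widths, areas, derivative
  extrema) of the valley-to-valley segment,
* frequency-domain descriptors of a window extending 5 s before the
  cycle start and 5 s after its end (band powers, dominant frequency,
  spectral entropy, harmonic ratio) — more robust than per-cycle
  morphology on low-quality wrist signals,
* tri-axial accelerometer statistics over the same window, because the
  cardiovascular response differs during physical activity,
* the instantaneous heart rate.

Feature vectors are paired with cuff readings taken within a +/-30 s
tolerance and fed to regression models that estimate SBP and DBP
(mm Hg).  Two evaluation protocols are provided: leave-one-subject-out
for subject-independent models, and a chronological 70/30 split at
cuff-reading granularity for personalized models; both report MAE
against a dummy baseline that always predicts the training means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.integrate import trapezoid
from sklearn.dummy import DummyRegressor
from sklearn.ensemble import RandomForestRegressor
from sklearn.neighbors import KNeighborsRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

from .errors import (ContractError, InsufficientContextError,
                     InsufficientDataError, ParameterError,
                     UndefinedFeatureError)
from .signal_quality import CardiacCycle, RawSignal

TEMPORAL_FEATURES = (
    "duration", "upstroke_time", "diastolic_time", "peak_amplitude",
    "width_25", "width_50", "width_75", "area",
    "d1_max", "d1_min", "d2_max", "d2_min", "upstroke_ratio",
)
SPECTRAL_FEATURES = (
    "total_power", "relpow_0p5_1p5", "relpow_1p5_2p5", "relpow_2p5_4p0",
    "dominant_freq", "spectral_entropy", "harmonic_ratio",
)
ACCEL_FEATURES = (
    "acc_mean_x", "acc_mean_y", "acc_mean_z",
    "acc_sd_x", "acc_sd_y", "acc_sd_z",
    "acc_mag_mean", "acc_mag_sd", "acc_intensity", "acc_valid",
)
FEATURE_COLUMNS = TEMPORAL_FEATURES + SPECTRAL_FEATURES + ACCEL_FEATURES + ("heart_rate",)

BP_ALGORITHMS = ("dummy_mean", "decision_tree", "knn", "svr", "random_forest")

PAIRING_TOLERANCE_S = 30.0


def _width_at(seg: np.ndarray, dt: float, peak: int, level: float) -> float:
    """Width (s) of the pulse at a given amplitude level, by linear
    interpolation of the first up-crossing before the peak and the last
    down-crossing after it."""
    above = seg >= level
    # first crossing at or before the peak
    left = peak
    while left > 0 and above[left - 1]:
        left -= 1
    if left > 0:
        frac = (level - seg[left - 1]) / (seg[left] - seg[left - 1])
        t_left = (left - 1 + frac) * dt
    else:
        t_left = 0.0
    right = peak
    while right < seg.size - 1 and above[right + 1]:
        right += 1
    if right < seg.size - 1:
        frac = (seg[right] - level) / (seg[right] - seg[right + 1])
        t_right = (right + frac) * dt
    else:
        t_right = (seg.size - 1) * dt
    return t_right - t_left


def extract_temporal_features(cycle: CardiacCycle) -> dict[str, float]:
    """Morphology features of one valley-to-valley cycle (see module doc)."""
    seg = np.asarray(cycle.segment, dtype=float)
    dt = cycle.duration / (seg.size - 1)
    peak = cycle.systolic_peak - cycle.valley_start
    baseline = seg[0]
    amplitude = seg[peak] - baseline
    if amplitude <= 1e-9 or np.ptp(seg) <= 1e-9:
        raise UndefinedFeatureError("flat cycle: morphology undefined")

    d1 = np.gradient(seg, dt)
    d2 = np.gradient(d1, dt)
    out = {
        "duration": cycle.duration,
        "upstroke_time": peak * dt,
        "diastolic_time": (seg.size - 1 - peak) * dt,
        "peak_amplitude": amplitude,
        "area": float(trapezoid(seg - baseline, dx=dt)),
        "d1_max": float(d1.max()),
        "d1_min": float(d1.min()),
        "d2_max": float(d2.max()),
        "d2_min": float(d2.min()),
        "upstroke_ratio": peak * dt / cycle.duration,
    }
    for frac in (0.25, 0.50, 0.75):
        out[f"width_{int(frac * 100)}"] = _width_at(seg, dt, peak,
                                                    baseline + frac * amplitude)
    return out


def extract_frequency_features(signal: RawSignal, cycle: CardiacCycle,
                               margin_s: float = 5.0,
                               band: tuple[float, float] = (0.5, 4.0)
                               ) -> dict[str, float]:
    """Spectral descriptors of the 10-s context window around one cycle.

    The window extends ``margin_s`` before the cycle start and after its
    end, clipped at record boundaries; at least 2 s must remain.
    Relative band powers are normalized within the analysis band so the
    three sum to one.
    """
    fs = signal.sampling_rate
    lo = max(0, cycle.valley_start - int(round(margin_s * fs)))
    hi = min(signal.samples.size, cycle.valley_end + int(round(margin_s * fs)) + 1)
    window = signal.samples[lo:hi]
    if window.size < 2.0 * fs:
        raise InsufficientContextError(
            f"only {window.size / fs:.2f} s of context after clipping")

    freqs, psd = sps.periodogram(window, fs=fs, detrend="constant")
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    band_power = psd[in_band].sum()
    if band_power <= 0:
        raise UndefinedFeatureError("no power in the analysis band")

    def rel(lo_f, hi_f):
        m = (freqs >= lo_f) & (freqs < hi_f) & in_band
        return float(psd[m].sum() / band_power)

    p = psd[in_band] / band_power
    p = p[p > 0]
    f_band = freqs[in_band]
    f0 = float(f_band[np.argmax(psd[in_band])])
    df = freqs[1] - freqs[0]
    near = lambda f: psd[np.abs(freqs - f) <= max(0.15, df)].sum()
    return {
        "total_power": float(band_power * df),
        "relpow_0p5_1p5": rel(0.5, 1.5),
        "relpow_1p5_2p5": rel(1.5, 2.5),
        "relpow_2p5_4p0": rel(2.5, 4.0 + 1e-9),
        "dominant_freq": f0,
        "spectral_entropy": float(-(p * np.log2(p)).sum()),
        "harmonic_ratio": float(near(2 * f0) / near(f0)) if near(f0) > 0 else 0.0,
    }


def extract_accel_features(accel: pd.DataFrame | None) -> dict[str, float]:
    """Mean/SD per axis and of the magnitude, plus motion intensity
    (mean absolute derivative of the magnitude, g/s) over a slice
    co-temporal with the frequency window.  An empty slice yields
    all-zero sentinel features with ``acc_valid = 0``."""
    if accel is None or len(accel) == 0:
        return {k: 0.0 for k in ACCEL_FEATURES} | {"acc_valid": 0.0}
    xyz = accel[["ax_g", "ay_g", "az_g"]].to_numpy(dtype=float)
    mag = np.linalg.norm(xyz, axis=1)
    if len(accel) > 1:
        dt = float(np.median(np.diff(accel["time_s"].to_numpy())))
        intensity = float(np.mean(np.abs(np.diff(mag)))) / dt if dt > 0 else 0.0
    else:
        intensity = 0.0
    means, sds = xyz.mean(axis=0), xyz.std(axis=0)
    return {
        "acc_mean_x": means[0], "acc_mean_y": means[1], "acc_mean_z": means[2],
        "acc_sd_x": sds[0], "acc_sd_y": sds[1], "acc_sd_z": sds[2],
        "acc_mag_mean": float(mag.mean()), "acc_mag_sd": float(mag.std()),
        "acc_intensity": intensity, "acc_valid": 1.0,
    }


def build_feature_table(signal: RawSignal, cycles: list[CardiacCycle],
                        accel: pd.DataFrame | None = None,
                        subject_id: str = "s1",
                        margin_s: float = 5.0) -> pd.DataFrame:
    """Per-cycle feature rows (columns ``FEATURE_COLUMNS`` plus
    ``subject_id`` and ``timestamp_s``); cycles whose morphology or
    spectral context is undefined are silently skipped."""
    rows = []
    for cycle in cycles:
        try:
            feats = extract_temporal_features(cycle)
            feats |= extract_frequency_features(signal, cycle, margin_s)
        except (UndefinedFeatureError, InsufficientContextError):
            continue
        t0 = signal.start_time + cycle.valley_start / signal.sampling_rate
        t1 = signal.start_time + (cycle.valley_end + 1) / signal.sampling_rate
        if accel is not None:
            sl = accel[(accel["time_s"] >= t0 - margin_s)
                       & (accel["time_s"] <= t1 + margin_s)]
        else:
            sl = None
        feats |= extract_accel_features(sl)
        feats["heart_rate"] = 60.0 / cycle.duration
        feats["timestamp_s"] = signal.start_time + \
            cycle.systolic_peak / signal.sampling_rate
        feats["subject_id"] = subject_id
        rows.append(feats)
    df = pd.DataFrame(rows)
    if len(df):
        df = df[["subject_id", "timestamp_s", *FEATURE_COLUMNS]]
    return df


def pair_with_ground_truth(features: pd.DataFrame, readings: pd.DataFrame,
                           tolerance_s: float = PAIRING_TOLERANCE_S) -> pd.DataFrame:
    """Attach each cycle to the nearest cuff reading within tolerance.

    Both tables must be time-sorted.  Ties go to the earlier reading;
    cycles outside every reading's tolerance are dropped.  Output gains
    ``sbp``, ``dbp`` and ``reading_time_s`` columns.
    """
    if len(features) == 0 or len(readings) == 0:
        return features.iloc[0:0].assign(sbp=[], dbp=[], reading_time_s=[])
    rt = readings["timestamp_s"].to_numpy(dtype=float)
    ft = features["timestamp_s"].to_numpy(dtype=float)
    idx = np.searchsorted(rt, ft)
    left = np.clip(idx - 1, 0, rt.size - 1)
    right = np.clip(idx, 0, rt.size - 1)
    d_left = np.abs(ft - rt[left])
    d_right = np.abs(ft - rt[right])
    nearest = np.where(d_left <= d_right, left, right)   # earlier wins ties
    dist = np.minimum(d_left, d_right)
    keep = dist <= tolerance_s
    out = features.loc[keep].copy()
    sel = nearest[keep]
    out["sbp"] = readings["sbp"].to_numpy(dtype=float)[sel]
    out["dbp"] = readings["dbp"].to_numpy(dtype=float)[sel]
    out["reading_time_s"] = rt[sel]
    return out


def mean_absolute_error(predictions, truth) -> float:
    """MAE = mean |prediction - truth| (mm Hg)."""
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.shape != t.shape or p.size == 0:
        raise ContractError("predictions and truth must be equal-length, non-empty")
    return float(np.mean(np.abs(p - t)))


def _make_regressor(algorithm: str, seed: int, hyperparams: dict | None):
    hp = dict(hyperparams or {})
    if algorithm == "dummy_mean":
        return DummyRegressor(strategy="mean")
    if algorithm == "decision_tree":
        return DecisionTreeRegressor(random_state=seed, **hp)
    if algorithm == "knn":
        hp.setdefault("n_neighbors", 5)
        return KNeighborsRegressor(**hp)
    if algorithm == "svr":
        hp.setdefault("kernel", "rbf")
        return SVR(**hp)
    if algorithm == "random_forest":
        hp.setdefault("n_estimators", 500)
        return RandomForestRegressor(random_state=seed, n_jobs=1, **hp)
    raise ParameterError(f"unknown algorithm {algorithm!r}; "
                         f"choose from {BP_ALGORITHMS}")


@dataclass
class BPModel:
    """Fitted SBP+DBP regressor pair with its training metadata."""

    algorithm: str
    sbp_model: Pipeline
    dbp_model: Pipeline
    feature_columns: tuple[str, ...]
    subjects: tuple[str, ...]
    n_train: int
    seed: int

    def predict(self, features: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        return predict_bp(self, features)


def train_bp_model(instances: pd.DataFrame, algorithm: str = "random_forest",
                   seed: int = 0, hyperparams: dict | None = None) -> BPModel:
    """Fit SBP and DBP regressors on labelled cycle instances.

    Features are standardized inside the pipeline, so scaling statistics
    always come from the training data only.
    """
    if algorithm not in BP_ALGORITHMS:
        raise ParameterError(f"unknown algorithm {algorithm!r}")
    if len(instances) < 10:
        raise InsufficientDataError("need at least 10 training instances")
    X = instances[list(FEATURE_COLUMNS)]
    models = {}
    for target in ("sbp", "dbp"):
        pipe = Pipeline([("scale", StandardScaler()),
                         ("reg", _make_regressor(algorithm, seed, hyperparams))])
        models[target] = pipe.fit(X, instances[target].to_numpy(dtype=float))
    return BPModel(algorithm, models["sbp"], models["dbp"], FEATURE_COLUMNS,
                   tuple(sorted(instances["subject_id"].astype(str).unique())),
                   len(instances), seed)


def predict_bp(model: BPModel, features: pd.DataFrame
               ) -> tuple[np.ndarray, np.ndarray]:
    """Predict (SBP, DBP) in mm Hg, clipped to the plausible [30, 300] range."""
    missing = set(model.feature_columns) - set(features.columns)
    if missing:
        raise ContractError(f"feature schema mismatch, missing {sorted(missing)}")
    X = features[list(model.feature_columns)]
    sbp = np.clip(model.sbp_model.predict(X), 30.0, 300.0)
    dbp = np.clip(model.dbp_model.predict(X), 30.0, 300.0)
    return sbp, dbp


@dataclass
class EvalResult:
    """Per-fold and aggregate MAE (mm Hg) with the dummy baseline."""

    protocol: str
    algorithm: str
    folds: pd.DataFrame = field(repr=False)  # fold, n_test, mae_sbp, mae_dbp, dummy_*

    @property
    def mae_sbp(self) -> float:
        return float(self.folds["mae_sbp"].mean())

    @property
    def mae_dbp(self) -> float:
        return float(self.folds["mae_dbp"].mean())

    @property
    def dummy_mae_sbp(self) -> float:
        return float(self.folds["dummy_mae_sbp"].mean())

    @property
    def dummy_mae_dbp(self) -> float:
        return float(self.folds["dummy_mae_dbp"].mean())


def _fold_row(name, train, test, algorithm, seed, hyperparams):
    model = train_bp_model(train, algorithm, seed, hyperparams)
    dummy = train_bp_model(train, "dummy_mean", seed)
    sbp, dbp = predict_bp(model, test)
    dsbp, ddbp = predict_bp(dummy, test)
    return dict(
        fold=name, n_test=len(test),
        mae_sbp=mean_absolute_error(sbp, test["sbp"]),
        mae_dbp=mean_absolute_error(dbp, test["dbp"]),
        dummy_mae_sbp=mean_absolute_error(dsbp, test["sbp"]),
        dummy_mae_dbp=mean_absolute_error(ddbp, test["dbp"]),
        train_subjects=",".join(sorted(train["subject_id"].astype(str).unique())),
    )


def evaluate_loso(instances: pd.DataFrame, algorithm: str = "random_forest",
                  seed: int = 0, hyperparams: dict | None = None) -> EvalResult:
    """Leave-one-subject-out evaluation: one fold per subject, the
    held-out subject never contributes to training or scaling."""
    subjects = sorted(instances["subject_id"].astype(str).unique())
    if len(subjects) < 2:
        raise InsufficientDataError("LOSO needs at least 2 subjects")
    rows = []
    for subject in subjects:
        test = instances[instances["subject_id"].astype(str) == subject]
        train = instances[instances["subject_id"].astype(str) != subject]
        if len(test) == 0:
            import warnings
            warnings.warn(f"subject {subject} has no instances; fold skipped")
            continue
        rows.append(_fold_row(subject, train, test, algorithm, seed, hyperparams))
    return EvalResult("loso", algorithm, pd.DataFrame(rows))


def evaluate_personalized(instances: pd.DataFrame, train_frac: float = 0.7,
                          algorithm: str = "random_forest", seed: int = 0,
                          hyperparams: dict | None = None) -> EvalResult:
    """Chronological 70/30 split of one subject's data at cuff-reading
    granularity: all cycles paired to one reading stay on one side, and
    every training timestamp precedes every test timestamp (no leakage).
    """
    readings = np.sort(instances["reading_time_s"].unique())
    if readings.size < 4:
        raise InsufficientDataError("need at least 4 distinct cuff readings")
    n_train = int(train_frac * readings.size)
    if n_train < 1 or n_train >= readings.size:
        raise InsufficientDataError("split leaves an empty side")
    cutoff = readings[n_train - 1]
    train = instances[instances["reading_time_s"] <= cutoff]
    test = instances[instances["reading_time_s"] > cutoff]
    assert train["timestamp_s"].max() < test["timestamp_s"].min()
    row = _fold_row("personal", train, test, algorithm, seed, hyperparams)
    return EvalResult("personalized", algorithm, pd.DataFrame([row]))
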