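"""Seed-deterministic synthetic fixtures for every analysis module.

No public data accession exists for the monitoring methods this toolkit
implements, so each generator emits data with the statistical structure
the corresponding method assumes, together with the ground truth needed
to verify it:

* PPG sessions whose per-cycle morphology is a *documented* deterministic
  function of the underlying systolic/diastolic pressure (plus noise and
  motion artifacts), so waveform features provably carry BP information;
* tri-axial accelerometer sessions with per-activity generative regimes;
* well-being tables labelled by a declarative ground-truth rule;
* per-subject psychophysiological feature rows and beat-to-beat interval
  series whose distributions differ by psychological profile.

The morphology->BP mapping constants below are an invented stand-in for
real vascular physiology (no hemodynamic validity is claimed); they are
fixed so tests can invert them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SpecError
from .signal_quality import RawSignal

# ---------------------------------------------------------------------------
# PPG sessions
# ---------------------------------------------------------------------------

# Documented (invented) morphology mapping: the systolic upstroke occupies a
# fraction of the cycle that decreases affinely with SBP, and the diastolic
# decay constant (as a fraction of the cycle) decreases affinely with DBP.
UPSTROKE_AT_110 = 0.24        # upstroke fraction at SBP = 110 mm Hg
UPSTROKE_SLOPE = -0.0015      # per mm Hg of SBP
DECAY_AT_70 = 0.42            # decay constant (cycle fraction) at DBP = 70 mm Hg
DECAY_SLOPE = -0.003          # per mm Hg of DBP


def upstroke_fraction(sbp: float) -> float:
    """Systolic upstroke fraction of the cycle implied by SBP (mm Hg)."""
    return float(np.clip(UPSTROKE_AT_110 + UPSTROKE_SLOPE * (sbp - 110.0), 0.08, 0.45))


def decay_fraction(dbp: float) -> float:
    """Diastolic decay constant (cycle fraction) implied by DBP (mm Hg)."""
    return float(np.clip(DECAY_AT_70 + DECAY_SLOPE * (dbp - 70.0), 0.10, 0.80))


def pulse_waveform(phase: np.ndarray, u: float, tau: float) -> np.ndarray:
    """Two-lobe pulse: half-sine systolic rise over [0, u], exponential
    diastolic decay with constant ``tau`` plus a small dicrotic bump."""
    y = np.zeros_like(phase)
    rising = phase < u
    y[rising] = np.sin(np.pi * phase[rising] / (2.0 * u))
    t = phase[~rising] - u
    bump_c, bump_w = 0.25 * (1.0 - u), 0.07 * (1.0 - u)
    y[~rising] = np.exp(-t / tau) + 0.12 * np.exp(-((t - bump_c) / bump_w) ** 2)
    return y


@dataclass(frozen=True)
class PPGSessionSpec:
    """Conditions of one simulated wear session.

    ``hr_bpm`` is a constant or piecewise-constant profile
    ``[(start_s, bpm), ...]``; SBP/DBP trajectories are constants or
    piecewise-linear breakpoints ``[(t_s, mm Hg), ...]``.
    """

    duration_s: float = 14400.0          # 4 h of wear
    hr_bpm: float | list[tuple[float, float]] = 70.0
    # Default pressures swing through their full range twice in the first
    # half of the session and keep fluctuating inside it afterwards,
    # mimicking activity-driven BP excursions over a morning of wear.
    sbp: float | list[tuple[float, float]] = field(
        default_factory=lambda: [(0.0, 112.0), (1800.0, 150.0), (4500.0, 110.0),
                                 (7200.0, 150.0), (9000.0, 112.0), (10800.0, 148.0),
                                 (12600.0, 114.0), (14400.0, 146.0)])
    dbp: float | list[tuple[float, float]] = field(
        default_factory=lambda: [(0.0, 70.0), (1800.0, 92.0), (4500.0, 68.0),
                                 (7200.0, 92.0), (9000.0, 70.0), (10800.0, 90.0),
                                 (12600.0, 70.0), (14400.0, 88.0)])
    noise_sd: float = 0.05               # a.u., pulse amplitude is ~1
    artifact_rate: float = 2.0           # corrupted cycles per minute
    sampling_rate: float = 64.0          # Hz (wrist PPG)
    reading_cadence_s: float = 1800.0    # cuff BP reading every 30 min
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.sampling_rate <= 0:
            raise SpecError("duration and sampling rate must be positive")
        for t, bpm in self._profile(self.hr_bpm):
            if not 40.0 <= bpm <= 180.0:
                raise SpecError(f"heart rate {bpm} bpm outside [40, 180]")
        for t in np.arange(0.0, self.duration_s + 1e-9, 60.0):
            s, d = self.sbp_at(float(t)), self.dbp_at(float(t))
            if not 30.0 < d < s < 300.0:
                raise SpecError(f"require 30 < DBP < SBP < 300 mm Hg (violated at t={t})")

    @staticmethod
    def _profile(value) -> list[tuple[float, float]]:
        if np.isscalar(value):
            return [(0.0, float(value))]
        return [(float(t), float(v)) for t, v in value]

    def hr_at(self, t: float) -> float:
        prof = self._profile(self.hr_bpm)
        value = prof[0][1]
        for start, bpm in prof:
            if t >= start:
                value = bpm
        return value

    def _interp(self, traj, t):
        prof = self._profile(traj)
        ts = np.array([p[0] for p in prof])
        vs = np.array([p[1] for p in prof])
        return float(np.interp(t, ts, vs))

    def sbp_at(self, t: float) -> float:
        return self._interp(self.sbp, t)

    def dbp_at(self, t: float) -> float:
        return self._interp(self.dbp, t)


@dataclass(frozen=True)
class PPGGroundTruth:
    beat_times: np.ndarray               # onset (valley) time of each beat, s
    beat_sbp: np.ndarray
    beat_dbp: np.ndarray
    corrupted: np.ndarray                # bool per beat
    corruption_kind: list[str]           # '', 'noise_burst' or 'inversion'

    def match_kept(self, kept_peak_times: np.ndarray, period_s: float | None = None
                   ) -> np.ndarray:
        """For each generated beat, whether a kept cycle's systolic peak
        falls inside that beat's span (within half a period)."""
        if self.beat_times.size == 0:
            return np.zeros(0, dtype=bool)
        if period_s is None:
            period_s = float(np.median(np.diff(self.beat_times))) if \
                self.beat_times.size > 1 else 1.0
        kept = np.sort(np.asarray(kept_peak_times))
        centers = self.beat_times + period_s / 2.0
        idx = np.searchsorted(kept, centers)
        hit = np.zeros(self.beat_times.size, dtype=bool)
        for i, c in enumerate(centers):
            for j in (idx[i] - 1, idx[i]):
                if 0 <= j < kept.size and abs(kept[j] - c) <= period_s / 2.0:
                    hit[i] = True
        return hit


def gen_ppg_session(spec: PPGSessionSpec
                    ) -> tuple[RawSignal, pd.DataFrame, pd.DataFrame, PPGGroundTruth]:
    """Simulate one wear session.

    Returns the PPG record, a co-temporal tri-axial accelerometer stream
    (stationary wear: gravity on z plus sensor noise), the cuff BP
    readings taken every ``reading_cadence_s``, and the ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.sampling_rate
    n = int(round(spec.duration_s * fs))
    x = np.zeros(n)

    beat_times, beat_sbp, beat_dbp = [], [], []
    t = 0.0
    while t < spec.duration_s:
        period = 60.0 / spec.hr_at(t)
        i0, i1 = int(round(t * fs)), min(int(round((t + period) * fs)), n)
        if i1 <= i0:
            break
        sbp, dbp = spec.sbp_at(t), spec.dbp_at(t)
        phase = (np.arange(i0, i1) / fs - t) / period
        x[i0:i1] = pulse_waveform(phase, upstroke_fraction(sbp), decay_fraction(dbp))
        beat_times.append(t)
        beat_sbp.append(sbp)
        beat_dbp.append(dbp)
        t += period

    beat_times = np.array(beat_times)
    n_beats = beat_times.size
    corrupted = np.zeros(n_beats, dtype=bool)
    kinds = [""] * n_beats
    n_artifacts = min(n_beats, int(round(spec.artifact_rate * spec.duration_s / 60.0)))
    if n_artifacts > 0:
        hit = rng.choice(n_beats, size=n_artifacts, replace=False)
        for b in np.sort(hit):
            t0 = beat_times[b]
            t1 = beat_times[b + 1] if b + 1 < n_beats else spec.duration_s
            i0, i1 = int(round(t0 * fs)), min(int(round(t1 * fs)), n)
            if rng.random() < 0.5:
                x[i0:i1] = rng.normal(0.0, 1.5, i1 - i0)
                kinds[b] = "noise_burst"
            else:
                x[i0:i1] = -x[i0:i1]
                kinds[b] = "inversion"
            corrupted[b] = True

    x += rng.normal(0.0, spec.noise_sd, n)
    ppg = RawSignal(x, fs)

    accel_rate = 32.0
    m = int(round(spec.duration_s * accel_rate))
    accel = pd.DataFrame({
        "time_s": np.arange(m) / accel_rate,
        "ax_g": rng.normal(0.0, 0.01, m),
        "ay_g": rng.normal(0.0, 0.01, m),
        "az_g": 1.0 + rng.normal(0.0, 0.01, m),
    })

    read_times = np.arange(spec.reading_cadence_s, spec.duration_s + 1e-9,
                           spec.reading_cadence_s)
    readings = pd.DataFrame({
        "timestamp_s": read_times,
        "sbp": [spec.sbp_at(rt) for rt in read_times],
        "dbp": [spec.dbp_at(rt) for rt in read_times],
    })

    gt = PPGGroundTruth(beat_times, np.array(beat_sbp), np.array(beat_dbp),
                        corrupted, kinds)
    return ppg, accel, readings, gt


def gen_cycle_set(n: int = 200, corrupt_frac: float = 0.25, hr_bpm: float = 60.0,
                  sbp: float = 120.0, dbp: float = 80.0, noise_sd: float = 0.02,
                  sampling_rate: float = 64.0, seed: int = 42
                  ) -> tuple[list, np.ndarray]:
    """A sequence of segmented cardiac cycles with a known corruption mask.

    Clean cycles are the documented pulse shape with mild (2% SD)
    beat-to-beat duration jitter plus Gaussian noise; a ``corrupt_frac``
    subset is replaced by a noise burst (SD 1.5, dwarfing the unit pulse)
    or sign-inverted.  Returns ``(cycles, corrupted_mask)`` ready for
    template screening.
    """
    from .signal_quality import CardiacCycle

    rng = np.random.default_rng(seed)
    period = 60.0 / hr_bpm
    u, tau = upstroke_fraction(sbp), decay_fraction(dbp)
    n_bad = int(round(n * corrupt_frac))
    bad = np.zeros(n, dtype=bool)
    bad[rng.choice(n, size=n_bad, replace=False)] = True

    cycles, start = [], 0
    for i in range(n):
        dur = period * (1.0 + rng.normal(0.0, 0.02))
        m = max(8, int(round(dur * sampling_rate)))
        phase = np.arange(m) / m
        y = pulse_waveform(phase, u, tau) + rng.normal(0.0, noise_sd, m)
        if bad[i]:
            if rng.random() < 0.5:
                y = rng.normal(0.0, 1.5, m)
            else:
                y = -y
        peak = start + int(np.argmax(y))
        if peak == start:
            peak = start + 1
        elif peak == start + m - 1:
            peak = start + m - 2
        cycles.append(CardiacCycle(start, peak, start + m - 1, y, m / sampling_rate))
        start += m
    return cycles, bad


# ---------------------------------------------------------------------------
# Accelerometer activity sessions
# ---------------------------------------------------------------------------

ACTIVITY_LABELS = ("rest", "standing", "walking", "nordic_walking", "running",
                   "exercise", "eating", "washing", "chores", "hand_activities")

# Per-class generative regimes: wrist orientation (gravity unit vector),
# dominant oscillation frequency (Hz) and per-axis amplitudes (g), sensor
# noise SD (g), and the fraction of time the oscillation is active
# (intermittent gestures such as eating have duty < 1).
_REGIMES: dict[str, dict] = {
    "rest":            dict(g=(0.0, 0.0, 1.0), f=0.0, amp=(0.0, 0.0, 0.0), noise=0.010, duty=1.0),
    "standing":        dict(g=(0.0, 0.30, 0.95), f=0.3, amp=(0.02, 0.02, 0.01), noise=0.015, duty=1.0),
    "walking":         dict(g=(0.0, 0.7, 0.7), f=2.0, amp=(0.25, 0.15, 0.10), noise=0.030, duty=1.0),
    "nordic_walking":  dict(g=(0.2, 0.7, 0.7), f=2.2, amp=(0.40, 0.25, 0.20), noise=0.035, duty=1.0),
    "running":         dict(g=(0.1, 0.8, 0.6), f=3.0, amp=(0.80, 0.50, 0.40), noise=0.050, duty=1.0),
    "exercise":        dict(g=(0.5, 0.5, 0.7), f=1.2, amp=(0.60, 0.60, 0.30), noise=0.040, duty=1.0),
    "eating":          dict(g=(0.3, 0.5, 0.8), f=0.8, amp=(0.12, 0.10, 0.08), noise=0.020, duty=0.5),
    "washing":         dict(g=(0.0, 0.5, 0.87), f=4.0, amp=(0.30, 0.20, 0.10), noise=0.030, duty=0.8),
    "chores":          dict(g=(0.4, 0.4, 0.8), f=1.5, amp=(0.50, 0.35, 0.30), noise=0.060, duty=0.6),
    "hand_activities": dict(g=(0.2, 0.2, 0.95), f=4.5, amp=(0.05, 0.04, 0.02), noise=0.012, duty=0.9),
}


def gen_activity_session(script: list[tuple[str, float]], rate: float = 50.0,
                         seed: int = 0, subject_id: str = "s1") -> pd.DataFrame:
    """Simulate a labelled wrist accelerometer stream for a scripted
    sequence of ``(activity, duration_s)`` segments.

    Burst regimes (``duty < 1``) gate the oscillation with a 0.25 Hz
    on/off square wave; a small random phase decorrelates axes.
    """
    for label, _ in script:
        if label not in ACTIVITY_LABELS:
            raise SpecError(f"unknown activity label {label!r}")
    rng = np.random.default_rng(seed)
    frames = []
    t_offset = 0.0
    for label, dur in script:
        reg = _REGIMES[label]
        m = int(round(dur * rate))
        t = np.arange(m) / rate
        g = np.asarray(reg["g"], dtype=float)
        g = g / np.linalg.norm(g)
        data = np.tile(g, (m, 1))
        if reg["f"] > 0:
            gate = 1.0
            if reg["duty"] < 1.0:
                gate = (np.sin(2 * np.pi * 0.25 * t + rng.uniform(0, 2 * np.pi))
                        > np.cos(np.pi * reg["duty"])).astype(float)
            for ax in range(3):
                phase = rng.uniform(0, 2 * np.pi)
                data[:, ax] += reg["amp"][ax] * gate * np.sin(
                    2 * np.pi * reg["f"] * t + phase)
        data += rng.normal(0.0, reg["noise"], (m, 3))
        frames.append(pd.DataFrame({
            "time_s": t_offset + t,
            "ax_g": data[:, 0], "ay_g": data[:, 1], "az_g": data[:, 2],
            "label": label, "subject_id": subject_id,
        }))
        t_offset += dur
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Well-being tables
# ---------------------------------------------------------------------------

WELLBEING_SCHEMA = ("heart_rate", "sbp", "dbp", "weight", "temperature", "humidity")

DEFAULT_WELLBEING_RULE = "(temperature <= 25.5) & (humidity <= 62)"


@dataclass(frozen=True)
class WellbeingGroundTruth:
    rule: str
    flipped: np.ndarray     # bool per record: label inverted by noise
    humidity_temperature_r: float


def gen_wellbeing_dataset(n: int = 500, rule: str = DEFAULT_WELLBEING_RULE,
                          noise: float = 0.0, humidity_temperature_r: float = 0.7,
                          seed: int = 0) -> tuple[pd.DataFrame, WellbeingGroundTruth]:
    """Tabular well-being records labelled good/bad by a declarative rule.

    The rule is a boolean pandas expression over the schema features
    (``True`` -> good).  Environmental humidity is drawn with the
    configured correlation to temperature, and SBP is mildly (inversely)
    driven by temperature so the modifiable/correlated/uncorrelated
    partition has something to find.  Labels are flipped independently
    with probability ``noise``.
    """
    if not 0.0 <= noise < 0.5:
        raise SpecError("label-flip probability must be in [0, 0.5)")
    names = set(re.findall(r"[A-Za-z_][A-Za-z0-9_]*", rule)) - {"and", "or", "not"}
    unknown = names - set(WELLBEING_SCHEMA)
    if unknown:
        raise SpecError(f"rule references unknown features: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    r = humidity_temperature_r
    temperature = rng.normal(24.0, 4.0, n)
    z_t = (temperature - 24.0) / 4.0
    humidity = np.clip(55.0 + 12.0 * (r * z_t + np.sqrt(1 - r ** 2)
                                      * rng.normal(size=n)), 0.0, 100.0)
    sbp = 125.0 - 1.5 * (temperature - 24.0) + rng.normal(0.0, 13.0, n)
    dbp = 42.5 + 0.30 * sbp + rng.normal(0.0, 4.0, n)
    df = pd.DataFrame({
        "heart_rate": rng.normal(72.0, 10.0, n),
        "sbp": sbp,
        "dbp": dbp,
        "weight": rng.normal(80.0, 12.0, n),
        "temperature": temperature,
        "humidity": humidity,
    })
    good = df.eval(rule).to_numpy(dtype=bool)
    flipped = rng.random(n) < noise
    good = good ^ flipped
    df["label"] = np.where(good, "good", "bad")
    return df, WellbeingGroundTruth(rule, flipped, r)


# ---------------------------------------------------------------------------
# Psychophysiological profiles
# ---------------------------------------------------------------------------

PROFILE_LABELS = ("motivated", "anxious", "depressed")

# Class-conditional means; "depressed" shows flat low pitch and low energy,
# "anxious" elevated heart rate with suppressed vagal tone (low RMSSD).
_PROFILE_MEANS = {
    "motivated": dict(pitch_mean=185.0, pitch_sd=45.0, energy_mean=-18.0,
                      energy_sd=6.0, heart_rate=72.0, rmssd=42.0),
    "anxious":   dict(pitch_mean=205.0, pitch_sd=35.0, energy_mean=-20.0,
                      energy_sd=5.0, heart_rate=88.0, rmssd=20.0),
    "depressed": dict(pitch_mean=150.0, pitch_sd=18.0, energy_mean=-26.0,
                      energy_sd=3.0, heart_rate=76.0, rmssd=33.0),
}
_PROFILE_SDS = dict(pitch_mean=12.0, pitch_sd=6.0, energy_mean=1.5,
                    energy_sd=0.8, heart_rate=4.0, rmssd=4.0)
PROFILE_FEATURES = tuple(_PROFILE_SDS)


def gen_profile_dataset(n_per_class: int = 10, separation: float = 1.0, seed: int = 0,
                        n_intervals: int = 120
                        ) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Per-subject psychophysiological feature rows and interval series.

    One row per subject: speech-prosody summary features, mean heart
    rate, and RMSSD.  ``separation`` scales every class mean's offset
    from the grand mean (0 -> identical class distributions, no signal).
    Returns the table and a dict subject_id -> beat-to-beat interval
    series (ms) constructed so its RMSSD matches the row's target: with
    i.i.d. interval jitter of SD sigma, successive differences have SD
    ``sigma * sqrt(2)``, so sigma = rmssd / sqrt(2).
    """
    if n_per_class <= 0:
        raise SpecError("n_per_class must be positive")
    rng = np.random.default_rng(seed)
    grand = {k: float(np.mean([_PROFILE_MEANS[c][k] for c in PROFILE_LABELS]))
             for k in PROFILE_FEATURES}
    rows, intervals = [], {}
    sid = 0
    for label in PROFILE_LABELS:
        for _ in range(n_per_class):
            sid += 1
            subject = f"p{sid:03d}"
            row = {"subject_id": subject, "label": label}
            for k in PROFILE_FEATURES:
                mean = grand[k] + separation * (_PROFILE_MEANS[label][k] - grand[k])
                row[k] = mean + rng.normal(0.0, _PROFILE_SDS[k])
            row["heart_rate"] = float(np.clip(row["heart_rate"], 40.0, 180.0))
            row["rmssd"] = float(max(row["rmssd"], 5.0))
            base = 60000.0 / row["heart_rate"]
            sigma = row["rmssd"] / np.sqrt(2.0)
            series = np.clip(base + rng.normal(0.0, sigma, n_intervals), 250.0, 2400.0)
            intervals[subject] = series
            rows.append(row)
    return pd.DataFrame(rows), intervals
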