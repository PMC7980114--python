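"""PPG preprocessing and template-based signal-quality screening.

The chain turns a raw wrist photoplethysmogram into a set of
quality-screened cardiac cycles:

1. zero-mean / unit-variance normalization,
2. Hampel outlier replacement (local median, MAD-scaled threshold),
3. fourth-order Butterworth band-pass (0.5-4.0 Hz), applied
   forward-backward so cycle landmarks are not shifted in time,
4. derivative-based detection of systolic upslopes, peaks and the
   diastolic valleys between them,
5. sliding-window cycle templates (pointwise mean of resampled cycles)
   and per-cycle quality metrics against the window template.

Cycles that correlate poorly with their neighbourhood template, lie far
from it in normalized Euclidean distance, or deviate strongly from the
window's median beat duration are flagged for discard, so individual
bad cycles inside an otherwise good segment are dropped without
rejecting the whole segment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps

from .errors import ContractError, DegenerateSignalError, ParameterError

# consistency constant linking MAD to the SD of a Gaussian
MAD_SCALE = 1.4826

#: resampled length of every cycle template
TEMPLATE_LENGTH = 64

#: physiological valley-to-valley duration bound, seconds (30-240 bpm)
MIN_CYCLE_S = 0.25
MAX_CYCLE_S = 2.0


@dataclass(frozen=True)
class RawSignal:
    """Uniformly sampled 1-D signal."""

    samples: np.ndarray
    sampling_rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 2:
            raise ContractError("signal must be 1-D with length >= 2")
        if not np.all(np.isfinite(samples)):
            raise ContractError("signal contains non-finite samples")
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be > 0")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.sampling_rate


@dataclass(frozen=True)
class CardiacCycle:
    """One valley-to-valley PPG segment with its systolic peak."""

    valley_start: int
    systolic_peak: int
    valley_end: int
    segment: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        if not self.valley_start < self.systolic_peak < self.valley_end:
            raise ContractError("cycle landmarks must satisfy start < peak < end")
        if len(self.segment) != self.valley_end - self.valley_start + 1:
            raise ContractError("segment length inconsistent with landmarks")


@dataclass(frozen=True)
class CycleTemplate:
    """Average waveform of a window of resampled cycles."""

    waveform: np.ndarray
    window_span: tuple[int, int]
    n_cycles: int
    median_duration: float


@dataclass(frozen=True)
class QualityReport:
    correlation: float
    norm_distance: float
    duration_deviation: float
    keep: bool


@dataclass(frozen=True)
class QualityThresholds:
    """Per-cycle screening thresholds; a cycle is kept only if it passes all three."""

    min_correlation: float = 0.9
    max_norm_distance: float = 0.5
    max_duration_deviation: float = 0.25


def normalize_signal(sig: RawSignal) -> RawSignal:
    """Zero-mean, unit-variance (population SD) normalization."""
    x = sig.samples
    sd = x.std()
    if sd < 1e-12:
        raise DegenerateSignalError("cannot normalize a zero-variance signal")
    return replace(sig, samples=(x - x.mean()) / sd)


def hampel_filter(sig: RawSignal, half_window: int = 5, n_sigmas: float = 3.0) -> RawSignal:
    """Replace local outliers by the local median (Hampel identifier).

    A sample further than ``n_sigmas * 1.4826 * MAD`` from the median of
    its centered window (clipped at the signal edges) is replaced by
    that median; everything else passes through unchanged.  The default
    ``half_window=5`` gives the conventional 11-sample (~10-sample)
    neighbourhood.
    """
    if half_window < 1:
        raise ParameterError("half_window must be >= 1")
    x = sig.samples
    w = 2 * half_window + 1
    if w > x.size:
        raise ParameterError("Hampel window longer than the signal")

    out = x.copy()
    # full interior windows, vectorized
    views = sliding_window_view(x, w)
    med = np.median(views, axis=1)
    mad = np.median(np.abs(views - med[:, None]), axis=1)
    centers = np.arange(half_window, x.size - half_window)
    bad = np.abs(x[centers] - med) > n_sigmas * MAD_SCALE * mad
    out[centers[bad]] = med[bad]
    # clipped edge windows
    for i in list(range(half_window)) + list(range(x.size - half_window, x.size)):
        win = x[max(0, i - half_window): i + half_window + 1]
        m = np.median(win)
        s = np.median(np.abs(win - m))
        if abs(x[i] - m) > n_sigmas * MAD_SCALE * s:
            out[i] = m
    return replace(sig, samples=out)


def bandpass_filter(sig: RawSignal, low: float = 0.5, high: float = 4.0,
                    order: int = 4) -> RawSignal:
    """Zero-phase Butterworth band-pass (forward-backward)."""
    nyq = sig.sampling_rate / 2.0
    if not 0 < low < high:
        raise ParameterError("need 0 < low < high")
    if high >= nyq:
        raise ParameterError(f"high cutoff {high} Hz >= Nyquist {nyq} Hz")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=sig.sampling_rate,
                     output="sos")
    return replace(sig, samples=sps.sosfiltfilt(sos, sig.samples))


def detect_cycles(sig: RawSignal, refractory_s: float = 0.25,
                  upslope_frac: float = 0.33) -> list[CardiacCycle]:
    """Valley-to-valley cardiac cycles from a normalized, band-passed PPG.

    Systolic upslopes are located as maxima of the first derivative
    separated by a refractory period; the systolic peak is the signal
    maximum after each upslope, and the diastolic valley the minimum
    between consecutive peaks (plus the boundary minima before the
    first and after the last peak).  Cycles outside the physiological
    0.25-2.0 s duration band are discarded.
    """
    x = sig.samples
    fs = sig.sampling_rate
    d = np.diff(x)
    if d.size < 2 or d.max() <= 0:
        return []
    distance = max(1, round(refractory_s * fs))
    # Robust height threshold: motion artifacts can carry derivatives far
    # above the cardiac upslope, so scale by the MAD of the derivative
    # rather than its maximum (capped by the max for near-noiseless input).
    med = np.median(d)
    mad = np.median(np.abs(d - med))
    height = min(upslope_frac * d.max(), med + 2.0 * MAD_SCALE * mad)
    if height <= 0:
        return []
    upslopes, _ = sps.find_peaks(d, height=height, distance=distance)
    # a steep rise running into the record boundary has no interior
    # derivative maximum; recover it so the edge beats are usable
    if d[0] >= height and d[0] > d[1] and (upslopes.size == 0 or upslopes[0] >= distance):
        upslopes = np.insert(upslopes, 0, 0)
    if d[-1] >= height and d[-1] > d[-2] and \
            (upslopes.size == 0 or d.size - 1 - upslopes[-1] >= distance):
        upslopes = np.append(upslopes, d.size - 1)
    if upslopes.size < 2:
        return []

    # The diastolic valley immediately precedes the systolic upslope, so
    # anchor the valley search to a short window before each upslope
    # (rather than the global minimum between peaks, which an artifact in
    # the preceding beat would capture).
    med_gap = float(np.median(np.diff(upslopes)))
    lookback = max(2, int(round(0.35 * med_gap)))
    valleys = np.empty(upslopes.size, dtype=int)
    for i, u in enumerate(upslopes):
        lo = max(0, u - lookback)
        valleys[i] = lo + int(np.argmin(x[lo: u + 1]))

    # systolic peak = signal maximum between the upslope and the next valley
    cycles: list[CardiacCycle] = []
    for i in range(upslopes.size - 1):
        vs, ve = valleys[i], valleys[i + 1]
        if ve <= upslopes[i] + 1:
            continue
        peak = upslopes[i] + int(np.argmax(x[upslopes[i]: ve]))
        if not vs < peak < ve:
            continue
        duration = (ve - vs) / fs
        if not MIN_CYCLE_S <= duration <= MAX_CYCLE_S:
            continue
        cycles.append(CardiacCycle(int(vs), peak, int(ve), x[vs: ve + 1], duration))

    # Edge cycles sit where filtering transients distort the waveform;
    # keep them only if their duration is consistent (within 25%, the
    # same tolerance the quality screen applies) with the interior rhythm.
    if len(cycles) >= 3:
        med = float(np.median([c.duration for c in cycles[1:-1]]))
        cycles = [c for i, c in enumerate(cycles)
                  if 0 < i < len(cycles) - 1 or abs(c.duration - med) / med <= 0.25]
    return cycles


def resample_cycle(cycle: CardiacCycle, length: int = TEMPLATE_LENGTH) -> np.ndarray:
    """Linearly resample a cycle segment to a fixed length."""
    seg = np.asarray(cycle.segment, dtype=float)
    src = np.linspace(0.0, 1.0, seg.size)
    dst = np.linspace(0.0, 1.0, length)
    return np.interp(dst, src, seg)


def build_templates(cycles: list[CardiacCycle], window_size: int = 10,
                    template_length: int = TEMPLATE_LENGTH,
                    method: str = "mean") -> list[CycleTemplate]:
    """Non-overlapping sliding-window templates over resampled cycles.

    ``method='mean'`` is the plain pointwise average; ``method='median'``
    is its outlier-resistant counterpart used to bootstrap screening in
    artifact-heavy windows.  The trailing partial window, if any, also
    receives a template so every cycle has a neighbourhood to be
    screened against.
    """
    if window_size < 1:
        raise ParameterError("window_size must be >= 1")
    if method not in ("mean", "median"):
        raise ParameterError(f"unknown template method {method!r}")
    reduce = np.mean if method == "mean" else np.median
    templates: list[CycleTemplate] = []
    for start in range(0, len(cycles), window_size):
        members = cycles[start: start + window_size]
        stack = np.vstack([resample_cycle(c, template_length) for c in members])
        templates.append(CycleTemplate(
            waveform=reduce(stack, axis=0),
            window_span=(start, start + len(members) - 1),
            n_cycles=len(members),
            median_duration=float(np.median([c.duration for c in members])),
        ))
    return templates


def score_cycle_quality(cycle: CardiacCycle, template: CycleTemplate,
                        thresholds: QualityThresholds | None = None) -> QualityReport:
    """Compare one cycle against its window template.

    Metrics: Pearson correlation of the resampled cycle with the
    template; Euclidean distance between the two unit-norm waveforms
    (scale-invariant, 0 for identical shapes, bounded by 2); relative
    deviation of the cycle duration from the window's median duration.
    """
    thresholds = thresholds or QualityThresholds()
    t = template.waveform
    c = resample_cycle(cycle, len(t))
    if len(c) != len(t):
        raise ContractError("template length mismatch")

    cs, ts = c.std(), t.std()
    corr = 0.0 if cs < 1e-12 or ts < 1e-12 else float(np.corrcoef(c, t)[0, 1])
    cn, tn = np.linalg.norm(c), np.linalg.norm(t)
    if cn < 1e-12 or tn < 1e-12:
        dist = math.sqrt(2.0)
    else:
        dist = float(np.linalg.norm(c / cn - t / tn))
    dur_dev = abs(cycle.duration - template.median_duration) / template.median_duration

    keep = (corr >= thresholds.min_correlation
            and dist <= thresholds.max_norm_distance
            and dur_dev <= thresholds.max_duration_deviation)
    return QualityReport(corr, dist, float(dur_dev), keep)


def screen_cycles(cycles: list[CardiacCycle], window_size: int = 10,
                  thresholds: QualityThresholds | None = None
                  ) -> tuple[list[QualityReport], list[CycleTemplate]]:
    """Two-pass template screening of an ordered cycle sequence.

    Pass 1 builds a *consensus* template per window: the member with the
    highest mean correlation to its peers seeds the template, which is
    the average of all members correlating >= 0.8 with the seed.  Motion
    artifacts (noise bursts, inversions) do not cohere with each other,
    so the clean cycles form the winning cluster even in heavily
    corrupted windows.  Pass 2 rebuilds the template as the mean of the
    pass-1 survivors (when at least three survive) and re-scores, so the
    reported metrics refer to an average of plausible cycles.
    """
    if not cycles:
        return [], []
    reports: list[QualityReport] = []
    refined: list[CycleTemplate] = []
    for start in range(0, len(cycles), window_size):
        members = cycles[start: start + window_size]
        stack = np.vstack([resample_cycle(c) for c in members])
        if len(members) > 1:
            with np.errstate(invalid="ignore"):
                corr = np.corrcoef(stack)
            corr = np.nan_to_num(corr)
            np.fill_diagonal(corr, 0.0)
            seed = int(np.argmax(corr.sum(axis=1)))
            coherent = [i for i in range(len(members))
                        if i == seed or corr[seed, i] >= 0.8]
        else:
            coherent = [0]
        median_dur = float(np.median([members[i].duration for i in coherent]))
        template = CycleTemplate(stack[coherent].mean(axis=0),
                                 (start, start + len(members) - 1),
                                 len(coherent), median_dur)
        survivors = [c for c in members
                     if score_cycle_quality(c, template, thresholds).keep]
        if len(survivors) >= 3:
            template = build_templates(survivors, window_size=len(survivors))[0]
        refined.append(template)
        reports.extend(score_cycle_quality(c, template, thresholds) for c in members)
    return reports, refined


@dataclass(frozen=True)
class ScreenedPPG:
    """Output of the full preprocessing chain."""

    signal: RawSignal                       # normalized, Hampel-cleaned, band-passed
    cycles: list[CardiacCycle]
    reports: list[QualityReport]
    templates: list[CycleTemplate] = field(repr=False, default_factory=list)

    @property
    def kept_cycles(self) -> list[CardiacCycle]:
        return [c for c, r in zip(self.cycles, self.reports) if r.keep]


def preprocess_ppg(sig: RawSignal, half_window: int = 5, n_sigmas: float = 3.0,
                   low: float = 0.5, high: float = 4.0, order: int = 4,
                   window_size: int = 10,
                   thresholds: QualityThresholds | None = None) -> ScreenedPPG:
    """Run the complete normalization -> Hampel -> band-pass -> detection
    -> template screening chain on a raw PPG record.

    Screening follows :func:`screen_cycles` (median-initialized two-pass
    template comparison).
    """
    clean = bandpass_filter(hampel_filter(normalize_signal(sig), half_window, n_sigmas),
                            low, high, order)
    cycles = detect_cycles(clean)
    reports, templates = screen_cycles(cycles, window_size, thresholds)
    return ScreenedPPG(clean, cycles, reports, templates)
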