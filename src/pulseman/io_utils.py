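"""CSV/WAV/JSON readers and writers, configuration, and run manifests.

All exchange formats are plain text: comma-separated CSV with mandatory
header, UTF-8, ``.`` decimal, times in seconds as floats.  Every CLI run
writes a JSON manifest capturing the configuration hash, seeds, package
version and input/output digests, so any result can be reproduced from
its manifest alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError
from .signal_quality import RawSignal

PPG_COLUMNS = ("time_s", "ppg")
ACCEL_COLUMNS = ("time_s", "ax_g", "ay_g", "az_g")


def _check_time_axis(t: np.ndarray, tolerance: float = 0.01) -> float:
    """Validate strictly increasing, uniform (within 1%) timestamps and
    return the inferred sampling rate."""
    dt = np.diff(t)
    bad = np.flatnonzero(dt <= 0)
    if bad.size:
        raise FormatError(f"non-monotone timestamp at row {int(bad[0]) + 2}")
    med = float(np.median(dt))
    off = np.flatnonzero(np.abs(dt - med) > tolerance * med)
    if off.size:
        raise FormatError(f"non-uniform sampling at row {int(off[0]) + 2} "
                          f"(dt={dt[off[0]]:.6g} vs median {med:.6g})")
    return 1.0 / med


def read_signal_csv(path, columns=PPG_COLUMNS, rate: float | None = None):
    """Read a PPG (``time_s,ppg``) or accelerometer
    (``time_s,ax_g,ay_g,az_g``) CSV.

    Returns a :class:`RawSignal` for single-channel input, or the
    validated DataFrame for multi-channel input.  The sampling rate is
    taken from ``rate`` when given, otherwise inferred from timestamps.
    """
    df = pd.read_csv(path)
    missing = set(columns) - set(df.columns)
    if missing:
        raise FormatError(f"missing columns {sorted(missing)}; expected {columns}")
    inferred = _check_time_axis(df["time_s"].to_numpy(dtype=float))
    fs = rate if rate is not None else inferred
    if set(columns) == set(PPG_COLUMNS):
        return RawSignal(df["ppg"].to_numpy(dtype=float), fs,
                         float(df["time_s"].iloc[0]))
    return df


def write_cycles_csv(path, screened, sampling_rate: float) -> pd.DataFrame:
    """Emit the cycles table: one row per detected cycle with its
    landmarks (s), duration, quality metrics and keep verdict."""
    rows = []
    for i, (c, r) in enumerate(zip(screened.cycles, screened.reports)):
        rows.append(dict(
            cycle_id=i,
            start_s=c.valley_start / sampling_rate,
            peak_s=c.systolic_peak / sampling_rate,
            end_s=c.valley_end / sampling_rate,
            duration_s=c.duration,
            correlation=r.correlation,
            norm_distance=r.norm_distance,
            keep=r.keep,
        ))
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def read_wav(path) -> tuple[np.ndarray, float]:
    """Mono WAV as float samples in [-1, 1] plus sampling rate."""
    from scipy.io import wavfile

    fs, data = wavfile.read(path)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return np.asarray(data, dtype=float), float(fs)


def write_wav(path, samples: np.ndarray, rate: float) -> None:
    from scipy.io import wavfile

    scaled = np.clip(samples, -1.0, 1.0)
    wavfile.write(path, int(rate), (scaled * 32767).astype(np.int16))


def load_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError("config must be a mapping")
    return cfg


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, command: str, config: dict, seed: int | None,
                   inputs: list[str], outputs: list[str]) -> Path:
    """JSON manifest making a run reproducible: command, config (and its
    hash), seed, package version and content digests of every input and
    output file."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "command": command,
        "config": config,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": seed,
        "version": __version__,
        "inputs": {str(p): file_digest(p) for p in inputs},
        "outputs": {str(p): file_digest(p) for p in outputs},
    }
    path = out_dir / "manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return path
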