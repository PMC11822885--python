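"""Readers and writers for signals, events and pipeline configuration.

Signals travel as a flat little-endian binary of channel-major samples next
to a JSON sidecar holding channel names, anatomical labels, good flags,
sampling rate and units.  Events are a tab-separated table, one row per
trial, times in seconds from recording start at 6-decimal precision.
Both round-trip losslessly at their stated precision.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import EVENT_COLUMNS, ChannelInfo, Recording, TrialEvents
from .preprocess import BANDS, BandPowerEnvelope, EpochArray

__all__ = [
    "write_signals",
    "read_signals",
    "read_edf",
    "write_events",
    "read_events",
    "write_envelope",
    "read_envelope",
    "write_epochs",
    "exclude_artifacts",
    "PipelineConfig",
    "file_sha256",
]

SIDECAR_SUFFIX = ".json"


def write_signals(rec: Recording, path: str | Path, roles: list[str] | None = None) -> Path:
    """Write a Recording as raw binary plus a JSON sidecar.

    ``roles`` (synthetic ground-truth channel roles) are recorded in the
    sidecar when given; real recordings have none.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.ascontiguousarray(rec.samples, dtype="<f8")
    data.tofile(path)
    sidecar = {
        "format": "intentdecode-signals-v1",
        "dtype": "<f8",
        "order": "channel_major",
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "sampling_rate_hz": rec.sampling_rate,
        "units": "uV",
        "channels": [
            {"name": c.name, "anatomical_label": c.anatomical_label, "good": c.good}
            for c in rec.channels
        ],
    }
    if roles is not None:
        if len(roles) != rec.n_channels:
            raise ValueError("one role per channel required")
        sidecar["roles"] = list(roles)
    path.with_suffix(SIDECAR_SUFFIX).write_text(json.dumps(sidecar, indent=1))
    return path


def read_signals(path: str | Path) -> Recording:
    """Read a binary + sidecar signal container back into a Recording."""
    path = Path(path)
    sidecar_path = path.with_suffix(SIDECAR_SUFFIX)
    if not sidecar_path.exists():
        raise FileNotFoundError(f"sidecar {sidecar_path} not found")
    meta = json.loads(sidecar_path.read_text())
    if "sampling_rate_hz" not in meta:
        raise ValueError(f"{sidecar_path}: sidecar lacks sampling_rate_hz")
    n_ch, n_s = int(meta["n_channels"]), int(meta["n_samples"])
    raw = np.fromfile(path, dtype=meta.get("dtype", "<f8"))
    if raw.size != n_ch * n_s:
        raise ValueError(
            f"{path}: binary holds {raw.size} values, sidecar promises "
            f"{n_ch} x {n_s} = {n_ch * n_s}"
        )
    channels = [
        ChannelInfo(c["name"], c.get("anatomical_label", "unknown"), c.get("good", True))
        for c in meta["channels"]
    ]
    return Recording(
        samples=raw.reshape(n_ch, n_s).astype(np.float64),
        sampling_rate=float(meta["sampling_rate_hz"]),
        channels=channels,
    )


def read_edf(path: str | Path) -> Recording:
    """Import an EDF recording (optional; requires ``mne``)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF import requires the optional dependency 'mne'") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    samples = raw.get_data() * 1e6  # volts -> microvolts
    channels = [ChannelInfo(name) for name in raw.ch_names]
    return Recording(samples=samples, sampling_rate=float(raw.info["sfreq"]), channels=channels)


def write_envelope(env: BandPowerEnvelope, path: str | Path) -> Path:
    """Write a band-power envelope in the binary + sidecar container.

    Same layout as :func:`write_signals` with band metadata and the
    validity mask (stored as the first/last valid sample of its span).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.ascontiguousarray(env.power, dtype="<f8").tofile(path)
    valid_idx = np.flatnonzero(env.valid)
    sidecar = {
        "format": "intentdecode-envelope-v1",
        "dtype": "<f8",
        "order": "channel_major",
        "n_channels": env.n_channels,
        "n_samples": env.n_samples,
        "sampling_rate_hz": env.sampling_rate,
        "units": "uV^2",
        "band_hz": list(env.band),
        "band_name": env.band_name,
        "delay_corrected": env.delay_corrected,
        "valid_span": [int(valid_idx[0]), int(valid_idx[-1])] if valid_idx.size else None,
        "channels": [
            {"name": c.name, "anatomical_label": c.anatomical_label, "good": c.good}
            for c in env.channels
        ],
    }
    path.with_suffix(SIDECAR_SUFFIX).write_text(json.dumps(sidecar, indent=1))
    return path


def read_envelope(path: str | Path) -> BandPowerEnvelope:
    """Read a band-power envelope container written by :func:`write_envelope`."""
    path = Path(path)
    meta = json.loads(path.with_suffix(SIDECAR_SUFFIX).read_text())
    if meta.get("format") != "intentdecode-envelope-v1":
        raise ValueError(f"{path}: not an envelope container")
    n_ch, n_s = int(meta["n_channels"]), int(meta["n_samples"])
    raw = np.fromfile(path, dtype=meta["dtype"])
    if raw.size != n_ch * n_s:
        raise ValueError(
            f"{path}: binary holds {raw.size} values, sidecar promises {n_ch * n_s}"
        )
    valid = np.zeros(n_s, dtype=bool)
    if meta["valid_span"] is not None:
        lo, hi = meta["valid_span"]
        valid[lo: hi + 1] = True
    return BandPowerEnvelope(
        power=raw.reshape(n_ch, n_s),
        band=tuple(meta["band_hz"]),
        sampling_rate=float(meta["sampling_rate_hz"]),
        channels=[
            ChannelInfo(c["name"], c.get("anatomical_label", "unknown"), c.get("good", True))
            for c in meta["channels"]
        ],
        valid=valid,
        delay_corrected=bool(meta["delay_corrected"]),
        band_name=meta.get("band_name", ""),
    )


def write_epochs(epochs: EpochArray, path: str | Path) -> Path:
    """Write an epoch array (trials x channels x time) with a JSON shape
    descriptor."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.ascontiguousarray(epochs.data, dtype="<f8").tofile(path)
    sidecar = {
        "format": "intentdecode-epochs-v1",
        "dtype": "<f8",
        "shape": list(epochs.data.shape),
        "axes": ["trial", "channel", "time"],
        "alignment_event": epochs.alignment_event,
        "window_s": list(epochs.window),
        "sampling_rate_hz": epochs.sampling_rate,
        "z_scored": epochs.z_scored,
        "trial_ids": [int(t) for t in epochs.trial_ids],
        "dropped_trial_ids": [int(t) for t in epochs.dropped_trial_ids],
        "channels": [c.name for c in epochs.channels],
    }
    path.with_suffix(SIDECAR_SUFFIX).write_text(json.dumps(sidecar, indent=1))
    return path


def write_events(events: TrialEvents, path: str | Path) -> Path:
    """Write the trial-events table as TSV (seconds, 6-decimal fixed point)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    events.table.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return path


def read_events(path: str | Path) -> TrialEvents:
    """Read and validate a trial-events TSV.

    A missing stimulus-onset column is tolerated (stimulus-aligned
    analyses are then unavailable); missing required columns, negative
    times or mis-ordered times within a trial raise a descriptive error.
    """
    table = pd.read_csv(path, sep="\t")
    ev = TrialEvents(table)
    if not ev.has_stimulus_onsets:
        warnings.warn(
            f"{path}: stimulus onsets missing for some trials; "
            "stimulus-aligned analyses disabled",
            RuntimeWarning,
            stacklevel=2,
        )
    return ev


def exclude_artifacts(
    rec: Recording,
    epochs: EpochArray | None = None,
    amp_thresh: float = 10.0,
    var_thresh: float = 10.0,
) -> tuple[Recording, np.ndarray, dict]:
    """Threshold-based channel/trial exclusion.

    A channel is flagged bad when its peak absolute amplitude or variance
    exceeds ``thresh`` times the median over channels; likewise trials
    (within ``epochs``, if given) against the median over trials.  The
    conservative defaults exclude nothing on clean data.

    Returns the re-flagged Recording, a boolean keep-mask over trials
    (empty when ``epochs`` is None) and a report dict.
    """
    if amp_thresh <= 0 or var_thresh <= 0:
        raise ValueError("thresholds must be positive")
    peak = np.abs(rec.samples).max(axis=1)
    var = rec.samples.var(axis=1)
    bad = (peak > amp_thresh * np.median(peak)) | (var > var_thresh * np.median(var))
    if bad.all():
        raise ValueError("all channels excluded; thresholds too aggressive")
    out = rec.copy_with()
    for c, b in zip(out.channels, bad):
        if b:
            c.good = False

    if epochs is not None:
        tpeak = np.abs(epochs.data).max(axis=(1, 2))
        tvar = epochs.data.var(axis=(1, 2))
        trial_keep = ~(
            (tpeak > amp_thresh * np.median(tpeak))
            | (tvar > var_thresh * np.median(tvar))
        )
    else:
        trial_keep = np.ones(0, dtype=bool)
    report = {
        "bad_channels": [c.name for c, b in zip(rec.channels, bad) if b],
        "n_trials_excluded": int((~trial_keep).sum()) if epochs is not None else 0,
    }
    return out, trial_keep, report


@dataclass
class PipelineConfig:
    """Every tunable constant of the pipeline, with its standard default.

    Round-trips through YAML exactly; unknown keys in a config file are
    rejected rather than silently ignored.
    """

    # band power
    bands: dict = field(default_factory=lambda: {k: list(v) for k, v in BANDS.items()})
    transition_bandwidth_hz: float = 10.0
    notch_harmonics_hz: list = field(default_factory=lambda: [60.0, 120.0, 180.0])
    # class windows
    feature_window_s: float = 0.100
    n_feature_windows: int = 4
    silence_start_after_voice_offset_s: float = 1.5
    silence_start_auditory_s: float = 0.5
    delay_window_end_after_stimulus_offset_s: float = 1.0
    # offset sweep
    sweep_start_s: float = -1.5
    sweep_stop_s: float = 0.7
    sweep_step_s: float = 0.1
    delay_sweep_offsets_s: list = field(default_factory=lambda: [-0.2, -0.1, 0.0])
    # decoder
    outer_train_fraction: float = 0.8
    inner_folds: int = 5
    n_iterations: int = 20
    penalty_grid: list = field(default_factory=lambda: [0.1, 1.0, 10.0, 100.0])
    kernel_width_grid: list = field(default_factory=lambda: [0.01, 0.1, "1/d", 1.0, 10.0])
    n_shuffles: int = 500
    alpha: float = 0.05
    # state space
    savgol_order: int = 4
    savgol_length_s: float = 0.201
    dpca_regularization: float = 1e-6
    # clustering
    cluster_window_s: list = field(default_factory=lambda: [-1.0, 0.5])
    gaussian_width_s: float = 0.025
    k_range: list = field(default_factory=lambda: [2, 10])
    kmeans_restarts: int = 20
    # reproducibility
    seed: int = 0

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
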