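"""Synthetic intracranial recordings with planted speech-intent signals.

Real delayed-word-production recordings are not publicly distributable, so
this generator builds multichannel surrogates that carry the statistical
structure the downstream analysis assumes: a 1/f (pink) broadband
background, coherent line noise at 60/120/180 Hz, a shared common-mode
component, and — on designated channels — high-gamma-band amplitude
modulation time-locked to each trial's voice onset.  "Production" channels
ramp up a fixed lead *before* voice onset (mimicking pre-vocalization
motor-intent activity), "perception" channels ramp up a lag *after* it
(mimicking the response to hearing one's own voice), "silent" channels
carry background only.

Trials follow the instructed-delay word-production structure: a stimulus
(written word, picture, or audio), a silent delay, a go cue, a spoken word
with per-trial jittered reaction time, then an inter-trial interval.  The
reaction-time jitter makes voice-onset locking distinguishable from cue
locking, exactly the property the analysis exploits.

Everything is deterministic given the config seed: a single SeedSequence
fans out into per-channel and per-component substreams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .core import ChannelInfo, Recording, TrialEvents, EVENT_COLUMNS
from . import io as iio

__all__ = [
    "TrialTiming",
    "SimulationConfig",
    "GroundTruth",
    "generate_recording",
    "write_fixture_suite",
    "default_roles",
]

ROLES = ("production", "perception", "silent", "common_mode_only")

#: background broadband RMS in microvolts
BACKGROUND_RMS_UV = 10.0


@dataclass
class TrialTiming:
    """Interval durations (seconds) of one trial.

    ``reaction`` is the (low, high) of the uniform go-cue-to-voice-onset
    jitter.  The inter-trial interval runs from voice offset to the next
    stimulus onset and must leave room for the post-trial silence window
    (start 1.5 s after voice offset for visual tasks, 0.5 s for auditory)
    plus up to 0.4 s of feature windows.
    """

    stimulus: float = 1.5
    delay: float = 1.5
    reaction: tuple[float, float] = (0.3, 0.8)
    word: float = 0.6
    iti: float = 2.5
    lead_in: float = 2.0

    def max_trial_span(self) -> float:
        return self.stimulus + self.delay + self.reaction[1] + self.word + self.iti


def default_roles(n_channels: int) -> list[str]:
    """Half production, quarter perception, quarter silent (cyclic)."""
    pattern = ["production", "perception", "production", "silent"]
    return [pattern[i % 4] for i in range(n_channels)]


@dataclass
class SimulationConfig:
    """Parameters of one synthetic dataset.

    ``modulation_snr`` is the ratio of the planted high-gamma amplitude
    (at plateau) to the channel's background amplitude within the same
    band; 0 plants nothing.  ``production_lead`` is the time before voice
    onset at which production-channel modulation begins; ``perception_lag``
    the time after voice onset for perception channels.
    """

    n_channels: int = 8
    sampling_rate: float = 500.0
    n_trials: int = 40
    task: str = "visual_delay"
    channel_roles: list[str] | None = None
    production_lead: float = 0.300
    perception_lag: float = 0.100
    hg_band: tuple[float, float] = (70.0, 200.0)
    modulation_snr: float = 2.0
    ramp_duration: float = 0.200
    line_noise_amp: float = 1.0
    common_mode_amp: float = 1.0
    timing: TrialTiming = field(default_factory=TrialTiming)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.channel_roles is None:
            self.channel_roles = default_roles(self.n_channels)

    def validate(self) -> None:
        if self.sampling_rate not in (500.0, 1000.0, 2000.0):
            raise ValueError("sampling_rate must be one of 500, 1000, 2000 Hz")
        if self.production_lead <= 0:
            raise ValueError("production_lead must be positive")
        t = self.timing
        for name in ("stimulus", "delay", "word", "iti", "lead_in"):
            if getattr(t, name) <= 0 and not (name == "delay" and self.task == "visual_nodelay"):
                raise ValueError(f"timing.{name} must be positive")
        if not (0 < t.reaction[0] <= t.reaction[1]):
            raise ValueError("reaction window must satisfy 0 < low <= high")
        silence_start = 0.5 if self.task in ("auditory_repetition", "auditory_naming") else 1.5
        if t.iti < silence_start + 0.4:
            raise ValueError(
                "inter-trial interval too short: silence windows (start "
                f"{silence_start} s after voice offset plus 0.4 s of features) "
                f"would overlap the next stimulus (iti = {t.iti} s)"
            )
        if self.task == "visual_delay" and t.delay <= 1.0:
            raise ValueError(
                "instructed delay must exceed 1.0 s so the 0.9-1.0 s "
                "delay-control window exists"
            )
        if len(self.channel_roles) != self.n_channels:
            raise ValueError("one role per channel required")
        bad = set(self.channel_roles) - set(ROLES)
        if bad:
            raise ValueError(f"unknown channel roles: {sorted(bad)}")
        if self.hg_band[1] >= self.sampling_rate / 2:
            raise ValueError("hg_band upper edge must lie below Nyquist")


@dataclass
class GroundTruth:
    """What was planted where: the oracle for parameter-recovery tests."""

    channel_roles: list[str]
    voice_onset: np.ndarray  # (n_trials,)
    voice_offset: np.ndarray  # (n_trials,)
    modulation_start: np.ndarray  # (n_channels, n_trials); NaN where no modulation
    production_lead: float
    perception_lag: float
    ramp_duration: float

    def modulation_envelope(self, channel: int, n_samples: int, sampling_rate: float) -> np.ndarray:
        """Noiseless planted amplitude envelope (0..1) of one channel."""
        role = self.channel_roles[channel]
        env = np.zeros(n_samples)
        if role not in ("production", "perception"):
            return env
        t = np.arange(n_samples) / sampling_rate
        for start, voff in zip(self.modulation_start[channel], self.voice_offset):
            env = np.maximum(env, _ramp_envelope(t, start, voff, self.ramp_duration))
        return env


def _ramp_envelope(t: np.ndarray, start: float, sustain_until: float, ramp: float) -> np.ndarray:
    """Raised-cosine ramp 0->1 over [start, start+ramp], plateau until
    ``sustain_until``, then raised-cosine back to 0 over ``ramp`` seconds."""
    env = np.zeros_like(t)
    up = (t >= start) & (t < start + ramp)
    env[up] = 0.5 * (1 - np.cos(np.pi * (t[up] - start) / ramp))
    env[(t >= start + ramp) & (t < sustain_until)] = 1.0
    down = (t >= sustain_until) & (t < sustain_until + ramp)
    env[down] = 0.5 * (1 + np.cos(np.pi * (t[down] - sustain_until) / ramp))
    return env


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-RMS 1/f noise via spectral shaping of Gaussian white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    return x / x.std()


def _band_limited_noise(rng: np.random.Generator, n: int, band: tuple[float, float], fs: float) -> np.ndarray:
    """Unit-RMS zero-phase band-limited Gaussian noise (carrier)."""
    taps = signal.firwin(257, list(band), pass_zero=False, fs=fs)
    x = signal.filtfilt(taps, 1.0, rng.standard_normal(n))
    return x / x.std()


def _generate_events(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    t = config.timing
    rows = []
    clock = t.lead_in
    for i in range(config.n_trials):
        stim_on = clock
        stim_off = stim_on + t.stimulus
        if config.task == "visual_nodelay":
            go = stim_on
        else:
            go = stim_off + t.delay
        voice_on = go + rng.uniform(*t.reaction)
        voice_off = voice_on + t.word
        rows.append(
            dict(
                trial_id=i,
                task=config.task,
                stimulus_onset_s=stim_on,
                stimulus_offset_s=stim_off,
                go_cue_s=go,
                voice_onset_s=voice_on,
                voice_offset_s=voice_off,
            )
        )
        clock = voice_off + t.iti
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def generate_recording(config: SimulationConfig) -> tuple[Recording, TrialEvents, GroundTruth]:
    """Simulate a recording, its trial events and the planted ground truth.

    Each channel is built as ``pink background + line noise + common mode
    (+ role-specific high-gamma amplitude modulation)``.  The modulated
    component is band-limited noise whose plateau amplitude equals
    ``modulation_snr`` times the channel's background RMS within the same
    band, ramping up from ``voice_onset - production_lead`` (production
    role) or ``voice_onset + perception_lag`` (perception role) and
    sustained through the word.  Bit-identical for identical configs.
    """
    config.validate()
    fs = config.sampling_rate
    ss = np.random.SeedSequence(config.seed)
    ev_seed, common_seed, line_seed, *chan_seeds = ss.spawn(3 + config.n_channels)

    events_df = _generate_events(config, np.random.default_rng(ev_seed))
    duration = events_df["voice_offset_s"].iloc[-1] + config.timing.iti
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    # components shared across channels
    common = _pink_noise(np.random.default_rng(common_seed), n) * BACKGROUND_RMS_UV
    line_rng = np.random.default_rng(line_seed)
    line_phases = line_rng.uniform(0, 2 * np.pi, size=3)
    line_gains = line_rng.uniform(0.8, 1.2, size=config.n_channels)
    rel_amp = np.array([1.0, 0.5, 0.25])
    line = np.zeros(n)
    for f0, ph, a in zip((60.0, 120.0, 180.0), line_phases, rel_amp):
        line += a * np.sin(2 * np.pi * f0 * t + ph)
    line *= config.line_noise_amp * BACKGROUND_RMS_UV

    voice_on = events_df["voice_onset_s"].to_numpy()
    voice_off = events_df["voice_offset_s"].to_numpy()
    mod_start = np.full((config.n_channels, config.n_trials), np.nan)

    samples = np.empty((config.n_channels, n))
    for ch, (role, seed) in enumerate(zip(config.channel_roles, chan_seeds)):
        rng = np.random.default_rng(seed)
        if role == "common_mode_only":
            x = config.common_mode_amp * common + line_gains[ch] * line
            samples[ch] = x
            continue
        background = _pink_noise(rng, n) * BACKGROUND_RMS_UV
        x = background + config.common_mode_amp * common + line_gains[ch] * line
        if role in ("production", "perception") and config.modulation_snr > 0:
            if role == "production":
                starts = voice_on - config.production_lead
            else:
                starts = voice_on + config.perception_lag
            mod_start[ch] = starts
            env = np.zeros(n)
            ramp = config.ramp_duration
            for s0, v1 in zip(starts, voice_off):
                # the envelope is zero outside [s0, v1 + ramp]; only touch that slice
                i0 = max(0, int(s0 * fs) - 1)
                i1 = min(n, int((v1 + ramp) * fs) + 2)
                np.maximum(
                    env[i0:i1], _ramp_envelope(t[i0:i1], s0, v1, ramp), out=env[i0:i1]
                )
            carrier = _band_limited_noise(rng, n, config.hg_band, fs)
            # background amplitude inside the modulated band sets the scale
            sigma_bg = _band_rms(background, config.hg_band, fs)
            x = x + config.modulation_snr * sigma_bg * carrier * env
        elif role in ("production", "perception"):
            # snr = 0: record where modulation *would* start, plant nothing
            mod_start[ch] = (
                voice_on - config.production_lead
                if role == "production"
                else voice_on + config.perception_lag
            )
        samples[ch] = x

    channels = [
        ChannelInfo(name=f"ch{i:03d}", anatomical_label=f"synthetic_{role}")
        for i, role in enumerate(config.channel_roles)
    ]
    rec = Recording(samples=samples, sampling_rate=fs, channels=channels)
    events = TrialEvents(events_df)
    truth = GroundTruth(
        channel_roles=list(config.channel_roles),
        voice_onset=voice_on,
        voice_offset=voice_off,
        modulation_start=mod_start,
        production_lead=config.production_lead,
        perception_lag=config.perception_lag,
        ramp_duration=config.ramp_duration,
    )
    return rec, events, truth


def _band_rms(x: np.ndarray, band: tuple[float, float], fs: float) -> float:
    taps = signal.firwin(257, list(band), pass_zero=False, fs=fs)
    return float(signal.filtfilt(taps, 1.0, x).std())


# ---------------------------------------------------------------------------
# fixture suite


def _fixture_configs() -> dict[str, SimulationConfig]:
    """Canonical small fixtures used throughout the test suite."""
    return {
        "signal": SimulationConfig(n_channels=8, n_trials=40, modulation_snr=5.0, seed=101),
        "null": SimulationConfig(n_channels=8, n_trials=40, modulation_snr=0.0, seed=202),
        "auditory": SimulationConfig(
            n_channels=8,
            n_trials=40,
            modulation_snr=5.0,
            task="auditory_repetition",
            timing=TrialTiming(iti=1.5),
            seed=303,
        ),
    }


def write_fixture_suite(out_dir: str | Path) -> dict:
    """Write the canonical fixture recordings plus a manifest.

    Returns (and writes as ``manifest.json``) a manifest listing, per
    fixture, its seed, channel roles and file names — enough to regenerate
    the files bit-identically.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"format": "intentdecode-fixtures-v1", "fixtures": []}
    for name, cfg in _fixture_configs().items():
        rec, events, truth = generate_recording(cfg)
        sig_path = iio.write_signals(rec, out_dir / f"{name}.bin", roles=cfg.channel_roles)
        ev_path = iio.write_events(events, out_dir / f"{name}_events.tsv")
        manifest["fixtures"].append(
            {
                "name": name,
                "seed": cfg.seed,
                "task": cfg.task,
                "modulation_snr": cfg.modulation_snr,
                "channel_roles": list(cfg.channel_roles),
                "signals": sig_path.name,
                "events": ev_path.name,
                "signals_sha256": iio.file_sha256(sig_path),
            }
        )
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
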