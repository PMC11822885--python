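"""Shared data containers for intracranial recordings and trial events.

The containers here are deliberately thin: a :class:`Recording` is a
channels x time array of field potentials plus per-channel metadata, and a
:class:`TrialEvents` table carries the behavioral timestamps (stimulus,
go cue, voice onset/offset) that anchor every epoching and feature window
downstream.  All times are seconds from the start of the recording;
sample indices are obtained as ``floor(t * sampling_rate)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ChannelInfo",
    "Recording",
    "TrialEvents",
    "EVENT_COLUMNS",
    "time_to_sample",
]

#: canonical event-table columns, BIDS-flavored naming
EVENT_COLUMNS = [
    "trial_id",
    "task",
    "stimulus_onset_s",
    "stimulus_offset_s",
    "go_cue_s",
    "voice_onset_s",
    "voice_offset_s",
]

#: tasks cued through the auditory channel; these use the shorter
#: post-voice-offset washout before silence windows are taken
AUDITORY_TASKS = frozenset({"auditory_repetition", "auditory_naming"})

VALID_TASKS = frozenset(
    {
        "visual_delay",
        "visual_nodelay",
        "auditory_repetition",
        "picture_naming",
        "auditory_naming",
    }
)


def time_to_sample(t: float | np.ndarray, sampling_rate: float):
    """Convert seconds to a 0-based sample index (``floor(t * f_s)``).

    A one-microsample guard keeps boundaries that are exact in real
    arithmetic (e.g. multiples of the 100 ms feature window) from falling
    one sample short through floating-point rounding.
    """
    return np.floor(np.asarray(t) * sampling_rate + 1e-6).astype(int)


@dataclass
class ChannelInfo:
    """Name, anatomical label and quality flag of one electrode."""

    name: str
    anatomical_label: str = "unknown"
    good: bool = True


@dataclass
class Recording:
    """Multichannel raw intracranial signal in microvolts.

    Attributes
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Field potentials in microvolts.
    sampling_rate : float
        Sampling frequency in Hz.
    channels : list of ChannelInfo
        Per-channel metadata; ``good=False`` marks channels excluded from
        the common-average reference and from decoding.
    """

    samples: np.ndarray
    sampling_rate: float
    channels: list[ChannelInfo] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not self.channels:
            self.channels = [
                ChannelInfo(name=f"ch{i:03d}") for i in range(self.samples.shape[0])
            ]
        if len(self.channels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel entries for "
                f"{self.samples.shape[0]} signal rows"
            )
        if not any(c.good for c in self.channels):
            raise ValueError("at least one channel must be flagged good")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    @property
    def good_mask(self) -> np.ndarray:
        return np.array([c.good for c in self.channels], dtype=bool)

    def copy_with(self, samples: np.ndarray | None = None) -> "Recording":
        """Shallow metadata copy with (optionally) new sample data."""
        return Recording(
            samples=self.samples.copy() if samples is None else samples,
            sampling_rate=self.sampling_rate,
            channels=[replace(c) for c in self.channels],
        )


class TrialEvents:
    """Per-trial behavioral event times.

    Wraps a DataFrame with columns ``trial_id, task, stimulus_onset_s,
    stimulus_offset_s, go_cue_s, voice_onset_s, voice_offset_s`` (seconds
    from recording start).  The stimulus columns may be absent or NaN
    (some acquisitions fail to log stimulus onsets); in that case any
    stimulus-anchored analysis (the instructed-delay contrast) is disabled
    rather than guessed.
    """

    def __init__(self, table: pd.DataFrame, validate: bool = True):
        table = table.copy().reset_index(drop=True)
        missing = [
            c
            for c in EVENT_COLUMNS
            if c not in table.columns
            and c not in ("stimulus_onset_s", "stimulus_offset_s")
        ]
        if missing:
            raise ValueError(f"events table missing required columns: {missing}")
        for col in ("stimulus_onset_s", "stimulus_offset_s"):
            if col not in table.columns:
                table[col] = np.nan
        self.table = table[EVENT_COLUMNS]
        if validate:
            self._validate()

    def _validate(self) -> None:
        t = self.table
        bad_task = set(t["task"].unique()) - VALID_TASKS
        if bad_task:
            raise ValueError(f"unknown task labels: {sorted(bad_task)}")
        # required orderings; in no-go-cue tasks speech may legitimately
        # begin while the stimulus is still on screen, so stimulus offset
        # is only ordered against stimulus onset
        ordered_pairs = [
            ("stimulus_onset_s", "stimulus_offset_s"),
            ("stimulus_onset_s", "go_cue_s"),
            ("go_cue_s", "voice_onset_s"),
            ("voice_onset_s", "voice_offset_s"),
        ]
        for _, row in t.iterrows():
            times = [row[c] for c in EVENT_COLUMNS[2:] if np.isfinite(row[c])]
            if any(x < 0 for x in times):
                raise ValueError(
                    f"trial {row['trial_id']}: negative event time"
                )
            for a, b in ordered_pairs:
                if np.isfinite(row[a]) and np.isfinite(row[b]) and row[b] < row[a]:
                    raise ValueError(
                        f"trial {row['trial_id']}: event times not "
                        f"non-decreasing ({b} < {a})"
                    )

    @property
    def n_trials(self) -> int:
        return len(self.table)

    @property
    def has_stimulus_onsets(self) -> bool:
        return bool(np.isfinite(self.table["stimulus_onset_s"]).all())

    @property
    def tasks(self) -> pd.Series:
        return self.table["task"]

    def is_auditory(self) -> np.ndarray:
        """Per-trial mask of auditory-cued tasks (shorter silence washout)."""
        return self.table["task"].isin(AUDITORY_TASKS).to_numpy()

    def column(self, name: str) -> np.ndarray:
        return self.table[name].to_numpy(dtype=float)

    def select(self, mask: np.ndarray) -> "TrialEvents":
        return TrialEvents(self.table.loc[np.asarray(mask)], validate=False)

    def __len__(self) -> int:
        return self.n_trials

    def __repr__(self) -> str:
        tasks = ", ".join(sorted(self.table["task"].unique()))
        return f"<TrialEvents: {self.n_trials} trials ({tasks})>"
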