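"""Class-labeled feature windows for speech-intent decoding.

The decoding feature is mean band power in 100 ms non-overlapping windows,
one value per (electrode, window), concatenated across the good electrodes
in recorded channel order.  Speech-intent windows end at ``voice_onset +
offset`` (the offset is swept by the decoder); contrast windows are never
offset: silence windows start 1.5 s after voice offset (0.5 s for
auditory-cued tasks, whose inter-trial interval is shorter), and the
instructed-delay control window ends 1.0 s after the stimulus disappears
(i.e. the 0.9-1.0 s mid-delay period, preceded by up to three more
windows when four features are used).

Classes are balanced by seeded random subsampling of the majority class,
so a feature set is reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import TrialEvents, time_to_sample
from .preprocess import BandPowerEnvelope

__all__ = [
    "WINDOW_WIDTH_S",
    "ClassWindowSpec",
    "FeatureSet",
    "window_mean_power",
    "build_feature_set",
    "speech_window_spec",
    "silence_window_spec",
    "delay_window_spec",
]

#: feature window width in seconds
WINDOW_WIDTH_S = 0.100

#: silence windows start this long after voice offset
SILENCE_START_S = 1.5
SILENCE_START_AUDITORY_S = 0.5

#: the instructed-delay control window ends this long after stimulus offset
DELAY_WINDOW_END_S = 1.0

AUDITORY = ("auditory_repetition", "auditory_naming")


class WindowInvalidError(ValueError):
    """A requested feature window touches invalid or out-of-bounds samples."""


@dataclass
class ClassWindowSpec:
    """Where a class's feature windows sit relative to an anchor event.

    ``anchor_rule`` is the signed offset (seconds) of the *end* of the last
    feature window from the anchor event.  For the silence class the rule
    depends on the trial's task (shorter washout after auditory cues), so
    it is resolved per trial via :meth:`end_time`.
    """

    class_name: str
    anchor_event: str
    anchor_rule: float
    n_windows: int = 4
    window_width: float = WINDOW_WIDTH_S

    def __post_init__(self) -> None:
        if self.n_windows not in (1, 4):
            raise ValueError("n_windows must be 1 or 4")
        if self.window_width != WINDOW_WIDTH_S:
            raise ValueError(f"window width is fixed at {WINDOW_WIDTH_S} s")

    def end_time(self, row: pd.Series) -> float:
        anchor = float(row[f"{self.anchor_event}_s"])
        if self.class_name == "silence":
            start = (
                SILENCE_START_AUDITORY_S if row["task"] in AUDITORY else SILENCE_START_S
            )
            return anchor + start + self.n_windows * self.window_width
        return anchor + self.anchor_rule


def speech_window_spec(n_windows: int = 4) -> ClassWindowSpec:
    """Speech-intent windows: the last one ends at voice onset (+ sweep offset)."""
    return ClassWindowSpec("speech_intent", "voice_onset", 0.0, n_windows)


def silence_window_spec(n_windows: int = 4) -> ClassWindowSpec:
    """Resting-state windows in the inter-trial washout after voice offset."""
    return ClassWindowSpec("silence", "voice_offset", np.nan, n_windows)


def delay_window_spec() -> ClassWindowSpec:
    """Instructed-delay control: 4 windows ending 1 s after stimulus offset."""
    return ClassWindowSpec("delay", "stimulus_offset", DELAY_WINDOW_END_S, 4)


def window_mean_power(
    env: BandPowerEnvelope,
    end_time: float,
    n_windows: int,
    channel_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Mean power in consecutive 100 ms windows, the last ending at ``end_time``.

    Windows are half-open ``[start, end)``; a boundary sample belongs to
    the later window.  Raises :class:`WindowInvalidError` if any window
    touches masked or out-of-bounds samples (the caller drops that trial).

    Returns an array of shape (n_selected_channels, n_windows), earliest
    window first.
    """
    fs = env.sampling_rate
    bounds = [
        int(time_to_sample(end_time - WINDOW_WIDTH_S * k, fs))
        for k in range(n_windows, -1, -1)
    ]
    if bounds[0] < 0 or bounds[-1] > env.n_samples:
        raise WindowInvalidError(f"window ending at {end_time:.3f} s out of bounds")
    if not env.valid[bounds[0]: bounds[-1]].all():
        raise WindowInvalidError(
            f"window ending at {end_time:.3f} s touches invalid samples"
        )
    power = env.power if channel_mask is None else env.power[channel_mask]
    means = np.stack(
        [power[:, b0:b1].mean(axis=1) for b0, b1 in zip(bounds, bounds[1:])], axis=1
    )
    return means


@dataclass
class FeatureSet:
    """Trials x (electrodes x windows) decoding matrix with class labels."""

    matrix: np.ndarray
    labels: np.ndarray  # class-name strings, one per row
    trial_ids: np.ndarray
    offset: float
    band: str
    contrast: str
    column_names: list[str]
    channel_names: list[str]
    task_filter: str = "all"
    seed: int | None = None

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels))

    def select_columns(self, mask: np.ndarray) -> "FeatureSet":
        """Column-restricted copy (e.g. one electrode's windows)."""
        mask = np.asarray(mask)
        return FeatureSet(
            matrix=self.matrix[:, mask],
            labels=self.labels,
            trial_ids=self.trial_ids,
            offset=self.offset,
            band=self.band,
            contrast=self.contrast,
            column_names=[c for c, m in zip(self.column_names, mask) if m],
            channel_names=self.channel_names,
            task_filter=self.task_filter,
            seed=self.seed,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=self.column_names)
        df.insert(0, "trial_id", self.trial_ids)
        df.insert(1, "label", self.labels)
        df.insert(2, "offset_s", self.offset)
        df.insert(3, "band", self.band)
        return df

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path


def build_feature_set(
    env: BandPowerEnvelope,
    events: TrialEvents,
    speech_spec: ClassWindowSpec | None = None,
    contrast_spec: ClassWindowSpec | None = None,
    offset: float = 0.0,
    band: str = "high_gamma",
    task_filter: str | None = None,
    seed: int = 0,
) -> FeatureSet:
    """Assemble the balanced, class-labeled decoding matrix at one offset.

    Speech-intent windows end at ``voice_onset + offset`` per trial; the
    contrast class (silence or instructed delay) keeps its fixed anchor
    regardless of offset.  Trials whose windows touch invalid samples are
    dropped; the majority class is then subsampled without replacement
    (seeded) so both classes have equal row counts.
    """
    speech_spec = speech_spec or speech_window_spec()
    contrast_spec = contrast_spec or silence_window_spec(speech_spec.n_windows)
    if speech_spec.n_windows != contrast_spec.n_windows:
        raise ValueError("speech and contrast specs must use the same n_windows")

    table = events.table
    if task_filter and task_filter != "all":
        table = table[table["task"] == task_filter]
        if table.empty:
            raise ValueError(f"no trials with task '{task_filter}'")
    if contrast_spec.class_name == "delay":
        if (table["task"] == "visual_nodelay").any():
            raise ValueError(
                "instructed-delay contrast is undefined for the no-delay task"
            )
        if not np.isfinite(table["stimulus_offset_s"]).all():
            raise ValueError(
                "instructed-delay contrast needs stimulus offsets for every trial"
            )

    good = env.good_mask
    channel_names = [n for n, g in zip(env.channel_names, good) if g]

    rows, labels, trial_ids = [], [], []
    for _, row in table.iterrows():
        for spec, t_end in (
            (speech_spec, row["voice_onset_s"] + offset),
            (contrast_spec, contrast_spec.end_time(row)),
        ):
            if not np.isfinite(t_end):
                continue
            try:
                feats = window_mean_power(env, t_end, spec.n_windows, channel_mask=good)
            except WindowInvalidError:
                continue
            rows.append(feats.ravel())  # channel-major: ch0 w0..w3, ch1 w0..w3, ...
            labels.append(spec.class_name)
            trial_ids.append(row["trial_id"])

    labels = np.asarray(labels)
    for cls in (speech_spec.class_name, contrast_spec.class_name):
        if (labels == cls).sum() == 0:
            raise ValueError(f"class '{cls}' is empty after window exclusions")

    matrix = np.asarray(rows)
    trial_ids = np.asarray(trial_ids)

    # balance classes by subsampling the majority without replacement
    rng = np.random.default_rng(seed)
    idx_a = np.flatnonzero(labels == speech_spec.class_name)
    idx_b = np.flatnonzero(labels == contrast_spec.class_name)
    n_keep = min(len(idx_a), len(idx_b))
    keep = np.concatenate(
        [
            np.sort(rng.choice(idx_a, n_keep, replace=False)),
            np.sort(rng.choice(idx_b, n_keep, replace=False)),
        ]
    )
    keep.sort()

    column_names = [
        f"{name}_w{w}"
        for name in channel_names
        for w in range(speech_spec.n_windows)
    ]
    return FeatureSet(
        matrix=matrix[keep],
        labels=labels[keep],
        trial_ids=trial_ids[keep],
        offset=float(offset),
        band=band,
        contrast=contrast_spec.class_name,
        column_names=column_names,
        channel_names=channel_names,
        task_filter=task_filter or "all",
        seed=seed,
    )
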