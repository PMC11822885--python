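"""Demixed PCA of speech-intent vs silence population activity.

Trial-averaged high-gamma envelopes from the two behavioral conditions
(speech intent: the 500 ms before voice onset; silence: 1.0-1.5 s after
voice offset) are decomposed into components attributable to the task
factors: a condition-independent (time) marginalization and a
condition-dependent one.  Per marginalization, a ridge-regularized
reduced-rank regression finds decoder/encoder pairs that reconstruct the
marginalized data from the full data; components are ordered by explained
variance and the condition components maximally separate intent from
silence while the time components capture shared dynamics.

Envelopes are smoothed with a centered 4th-order Savitzky-Golay filter of
201 ms length before marginalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .core import TrialEvents
from .preprocess import BandPowerEnvelope, epoch

__all__ = [
    "DPCAInput",
    "DPCAResult",
    "build_dpca_input",
    "dpca_fit",
    "project_trials",
]

#: condition windows (seconds): speech relative to voice onset,
#: silence relative to voice offset
SPEECH_WINDOW = (-0.5, 0.0)
SILENCE_WINDOW = (1.0, 1.5)

SAVGOL_ORDER = 4
SAVGOL_LENGTH_S = 0.201


@dataclass
class DPCAInput:
    """Smoothed condition-mean envelopes: (2 conditions) x channels x time."""

    condition_means: np.ndarray
    sampling_rate: float
    condition_names: tuple[str, str] = ("speech_intent", "silence")
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.condition_means = np.asarray(self.condition_means, dtype=float)
        if self.condition_means.ndim != 3 or self.condition_means.shape[0] != 2:
            raise ValueError("condition_means must be (2, n_channels, n_time)")


def _savgol_samples(sampling_rate: float, length_s: float = SAVGOL_LENGTH_S) -> int:
    n = int(round(length_s * sampling_rate))
    return n + 1 if n % 2 == 0 else n  # centered filter needs odd length


def build_dpca_input(
    env: BandPowerEnvelope,
    events: TrialEvents,
    speech_window: tuple[float, float] = SPEECH_WINDOW,
    silence_window: tuple[float, float] = SILENCE_WINDOW,
) -> DPCAInput:
    """Cut, trial-average and smooth the two condition windows.

    Both windows must span the same duration so the conditions share a
    time axis.
    """
    if not np.isclose(speech_window[1] - speech_window[0],
                      silence_window[1] - silence_window[0]):
        raise ValueError("speech and silence windows must have equal duration")
    ep_speech = epoch(env, events, align="voice_onset", window=speech_window)
    ep_silence = epoch(env, events, align="voice_offset", window=silence_window)
    n_t = min(ep_speech.data.shape[2], ep_silence.data.shape[2])
    means = np.stack(
        [ep_speech.data[..., :n_t].mean(axis=0), ep_silence.data[..., :n_t].mean(axis=0)]
    )
    win = _savgol_samples(env.sampling_rate)
    if n_t >= win:
        means = savgol_filter(means, win, SAVGOL_ORDER, axis=-1, mode="interp")
    else:
        raise ValueError(
            f"window of {n_t} samples shorter than the {win}-sample smoother"
        )
    good = env.good_mask
    return DPCAInput(
        condition_means=means[:, good, :],
        sampling_rate=env.sampling_rate,
        channel_names=[n for n, g in zip(env.channel_names, good) if g],
    )


@dataclass
class DPCAResult:
    """Decoders/encoders per marginalization with explained variance."""

    decoders: dict  # marginalization -> (n_components, n_channels)
    encoders: dict  # marginalization -> (n_channels, n_components)
    explained_variance: dict  # marginalization -> fraction per component
    trajectories: dict  # marginalization -> (n_conditions, n_time, n_components)
    condition_names: tuple[str, str]
    total_variance: float

    @property
    def total_explained(self) -> float:
        return float(sum(v.sum() for v in self.explained_variance.values()))

    def summary(self) -> str:
        lines = ["dPCA decomposition (condition x time)"]
        for marg, ev in self.explained_variance.items():
            pct = ", ".join(f"{100 * v:.1f}%" for v in ev)
            lines.append(f"  {marg}: explained variance per component: {pct}")
        lines.append(f"  total explained: {100 * self.total_explained:.1f}%")
        return "\n".join(lines)


def dpca_fit(
    data: DPCAInput,
    regularization: float | None = None,
    n_components: int = 3,
) -> DPCAResult:
    """Fit two-factor demixed PCA to the condition means.

    The data are mean-centered per channel, split into a
    condition-independent (time) marginalization — the across-condition
    mean — and a condition-dependent residual.  For each marginalization
    X_phi, the decoder D and encoder F minimize
    ``|| X_phi - F D X ||^2 + lambda ||D||^2`` (reduced-rank ridge
    regression on the full centered data X); components are ordered by
    explained variance.

    ``regularization`` is the absolute ridge lambda; by default 1e-6 of
    the total variance, enough to make the solve well-posed without
    visibly biasing the components.
    """
    X = data.condition_means.copy()
    n_cond, n_ch, n_t = X.shape
    if n_ch < 2:
        raise ValueError("dPCA needs at least 2 channels")
    # per-channel mean over conditions and time
    X -= X.mean(axis=(0, 2), keepdims=True)

    X_time = np.broadcast_to(X.mean(axis=0, keepdims=True), X.shape)
    marginals = {"time": X_time, "condition": X - X_time}

    flat = lambda a: np.ascontiguousarray(np.swapaxes(a, 0, 1).reshape(n_ch, -1))
    Xf = flat(X)
    total_var = float(np.sum(Xf**2))
    if total_var == 0:
        raise ValueError("data has zero variance")
    lam = 1e-6 * total_var if regularization is None else float(regularization)

    cov = Xf @ Xf.T + lam * np.eye(n_ch)
    if lam == 0:
        if np.linalg.matrix_rank(cov) < n_ch:
            raise np.linalg.LinAlgError(
                "covariance is singular; use a nonzero regularization"
            )
    decoders, encoders, explained, trajectories = {}, {}, {}, {}
    for name, Xm in marginals.items():
        Xmf = flat(np.ascontiguousarray(Xm))
        B = np.linalg.solve(cov.T, (Xmf @ Xf.T).T).T  # Xm X' (X X' + lam I)^-1
        M = B @ Xf
        q = min(n_components, n_ch, M.shape[1])
        U, _, _ = np.linalg.svd(M, full_matrices=False)
        F = U[:, :q]  # encoder
        D = F.T @ B  # decoder
        decoders[name], encoders[name] = D, F
        # per-component explained variance: R^2-style credit of the rank-1
        # reconstruction F_j d_j X against the full centered data
        comp_scores = D @ Xf  # (q, n_cond * n_t)
        ev = np.empty(q)
        for j in range(q):
            recon = F[:, [j]] @ comp_scores[[j]]
            ev[j] = 2.0 * float(np.sum(Xf * recon)) - float(np.sum(recon**2))
        explained[name] = ev / total_var
        trajectories[name] = np.swapaxes(
            comp_scores.reshape(q, n_cond, n_t), 0, 1
        ).transpose(0, 2, 1)

    return DPCAResult(
        decoders=decoders,
        encoders=encoders,
        explained_variance=explained,
        trajectories=trajectories,
        condition_names=data.condition_names,
        total_variance=total_var,
    )


def project_trials(result: DPCAResult, trials: np.ndarray, marginalization: str = "condition") -> np.ndarray:
    """Project single-trial data (trials x channels x time) onto the
    fitted decoder axes; returns trials x time x components."""
    D = result.decoders[marginalization]
    centered = trials - trials.mean(axis=(0, 2), keepdims=True)
    return np.einsum("qc,nct->ntq", D, centered)
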