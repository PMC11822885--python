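"""Spatiotemporal clustering of voice-onset-locked envelope dynamics.

Each electrode is summarized by its trial-averaged, Gaussian-smoothed,
z-scored high-gamma envelope in a window from 1 s before to 0.5 s after
voice onset.  K-means over these time courses (k swept from 2 to 10,
multiple restarts, elbow-selected k) groups electrodes by the shape of
their modulation; clusters are then labeled by when their centroid first
exceeds its pre-window baseline: before voice onset -> "production",
at/after it -> "perception", never -> "unmodulated".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from sklearn.cluster import KMeans

from .preprocess import EpochArray

__all__ = ["ClusterResult", "cluster_envelopes", "label_clusters"]

#: Gaussian smoothing width (SD) in seconds
GAUSSIAN_WIDTH_S = 0.025

#: baseline span (from window start) used for onset detection, seconds
BASELINE_SPAN_S = 0.25


@dataclass
class ClusterResult:
    """K-means partition of electrodes by envelope time course."""

    assignments: np.ndarray  # per-electrode cluster id (for chosen_k)
    centroids: np.ndarray  # (chosen_k, n_time)
    chosen_k: int
    distortion_curve: dict  # k -> mean within-cluster distance
    times: np.ndarray  # seconds relative to voice onset
    channel_names: list[str]
    cluster_labels: list[str] | None = None
    cluster_onsets: list[float] | None = None
    degenerate_centroids: bool = False

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"channel": self.channel_names, "cluster": self.assignments}
        )
        if self.cluster_labels is not None:
            df["cluster_label"] = [self.cluster_labels[c] for c in self.assignments]
        return df


def _mean_within_cluster_distance(X: np.ndarray, labels: np.ndarray, centers: np.ndarray) -> float:
    d = np.linalg.norm(X - centers[labels], axis=1)
    return float(d.mean())


def cluster_envelopes(
    epochs: EpochArray,
    gaussian_width: float = GAUSSIAN_WIDTH_S,
    k_range: tuple[int, int] = (2, 10),
    n_restarts: int = 20,
    seed: int = 0,
) -> ClusterResult:
    """Cluster electrodes by their trial-averaged envelope time course.

    The per-electrode time course is the trial mean, smoothed with a
    Gaussian kernel of SD ``gaussian_width`` seconds and z-scored over the
    window.  K-means is run for each k in ``k_range`` (inclusive) with
    ``n_restarts`` restarts, skipping k values exceeding the electrode
    count; the elbow (maximum positive second difference of the mean
    within-cluster distance curve) picks the reported k.  Deterministic
    given ``seed``.
    """
    if epochs.alignment_event != "voice_onset":
        raise ValueError("clustering expects voice-onset-aligned epochs")
    traces = epochs.data.mean(axis=0)  # channels x time
    sigma = gaussian_width * epochs.sampling_rate
    traces = gaussian_filter1d(traces, sigma, axis=-1)
    sd = traces.std(axis=1, keepdims=True)
    flat = sd[:, 0] == 0
    sd[flat] = 1.0
    traces = (traces - traces.mean(axis=1, keepdims=True)) / sd

    n_elec = traces.shape[0]
    ks = [k for k in range(k_range[0], k_range[1] + 1) if k <= n_elec]
    if not ks:
        raise ValueError(
            f"{n_elec} electrodes cannot support any k in {k_range}"
        )
    ss = np.random.SeedSequence(seed)
    k_seeds = {
        k: int(np.random.default_rng(s).integers(0, 2**31 - 1))
        for k, s in zip(ks, ss.spawn(len(ks)))
    }
    fits, distortion = {}, {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=k_seeds[k])
        labels = km.fit_predict(traces)
        fits[k] = (labels, km.cluster_centers_)
        distortion[k] = _mean_within_cluster_distance(traces, labels, km.cluster_centers_)

    if len(ks) >= 3:
        curve = np.array([distortion[k] for k in ks])
        d2 = curve[:-2] - 2 * curve[1:-1] + curve[2:]
        chosen_k = ks[1 + int(np.argmax(d2))]
    else:
        chosen_k = ks[0]

    labels, centers = fits[chosen_k]
    # duplicate centroids signal fewer effective clusters than requested
    degenerate = False
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            if np.allclose(centers[i], centers[j], atol=1e-8):
                degenerate = True

    return ClusterResult(
        assignments=labels,
        centroids=centers,
        chosen_k=chosen_k,
        distortion_curve=distortion,
        times=epochs.times,
        channel_names=[c.name for c in epochs.channels],
        degenerate_centroids=degenerate,
    )


def label_clusters(result: ClusterResult) -> ClusterResult:
    """Label clusters production / perception / unmodulated by centroid onset.

    The onset is the first time the centroid exceeds the mean + 2 SD of
    its own baseline (the first 0.25 s of the window).  Onset before voice
    onset (t < 0) -> production; at or after -> perception; never
    exceeded -> unmodulated.
    """
    times = result.times
    base = times < (times[0] + BASELINE_SPAN_S)
    labels, onsets = [], []
    for centroid in result.centroids:
        thresh = centroid[base].mean() + 2.0 * centroid[base].std()
        above = np.flatnonzero(centroid > thresh)
        above = above[~base[above]] if above.size else above
        if above.size == 0:
            labels.append("unmodulated")
            onsets.append(np.nan)
            continue
        onset = float(times[above[0]])
        onsets.append(onset)
        labels.append("production" if onset < 0 else "perception")
    result.cluster_labels = labels
    result.cluster_onsets = onsets
    return result
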