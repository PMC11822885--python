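"""Cross-validated RBF-SVM decoding with permutation-based significance.

The decoding protocol: a feature set is split 80/20 (stratified) into
training and test rows; within the training rows a 5-fold cross-validated
grid search picks the SVM penalty C and RBF kernel width gamma; the best
pair is refit on all training rows and scored on the held-out 20%.  This
outer resampling is iterated 20 times and the mean test accuracy is the
decoder's performance.

Significance is assessed against an empirical chance distribution: the
held-out test labels are shuffled and re-scored against the fitted
decoder's predictions, 500 shuffles pooled across the 20 iterations.  The
permutation p-value uses the add-one estimator
``p = (1 + #{null >= observed}) / (1 + n_shuffles)``; when the test sets
are small enough that all distinct label arrangements can be enumerated,
the null is computed exhaustively and the p-value is exact.  An offset (or
electrode) counts as significant only if the observed mean accuracy also
exceeds the null's 95th percentile and the Benjamini-Hochberg-adjusted
p-value clears alpha.

Sweeping the end of the speech-intent feature window from -1.5 to +0.7 s
around voice onset (the silence contrast; -0.2 to 0 s for the
instructed-delay contrast) localizes *when* decodable intent information
first appears; the first significant offset is the headline latency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from .core import TrialEvents
from .features import (
    ClassWindowSpec,
    FeatureSet,
    build_feature_set,
    delay_window_spec,
    silence_window_spec,
    speech_window_spec,
)
from .preprocess import BandPowerEnvelope

__all__ = [
    "DecoderConfig",
    "DecodeResult",
    "SweepResult",
    "fit_and_test",
    "empirical_null_and_p",
    "bh_fdr",
    "offset_sweep",
    "group_significance",
    "single_electrode_map",
    "compare_contrasts",
    "sweep_offsets",
]


@dataclass
class DecoderConfig:
    """Hyperparameters of the decoding protocol.

    ``kernel_width_grid`` entries may be numbers or the string ``"1/d"``,
    resolved to 1/n_features at fit time.  ``n_shuffles`` is the total
    number of label shuffles pooled across the outer iterations.
    """

    outer_split: float = 0.8
    inner_folds: int = 5
    n_iterations: int = 20
    penalty_grid: tuple = (0.1, 1.0, 10.0, 100.0)
    kernel_width_grid: tuple = (0.01, 0.1, "1/d", 1.0, 10.0)
    n_shuffles: int = 500
    alpha: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.outer_split < 1.0):
            raise ValueError("outer_split must be in (0, 1)")
        if not self.penalty_grid or not self.kernel_width_grid:
            raise ValueError("hyperparameter grids must be non-empty")
        if self.n_shuffles < 100:
            raise ValueError("n_shuffles must be at least 100")
        if self.n_iterations < 1 or self.inner_folds < 2:
            raise ValueError("need >= 1 iteration and >= 2 inner folds")

    def resolved_widths(self, n_features: int) -> list[float]:
        out = []
        for w in self.kernel_width_grid:
            out.append(1.0 / n_features if w == "1/d" else float(w))
        return out


@dataclass
class DecodeResult:
    """Decoding performance and its permutation null at one offset."""

    offset: float
    iteration_accuracies: np.ndarray
    mean_accuracy: float
    null_accuracies: np.ndarray | None = None
    null_95th: float = np.nan
    p_value: float = np.nan
    p_adjusted: float = np.nan
    significant: bool = False
    exhaustive_null: bool = False
    # per-iteration (true test labels, predicted labels), retained so the
    # null can be built by shuffling test labels against fixed predictions
    test_pairs: list = field(default_factory=list, repr=False)

    def above_null_gate(self) -> bool:
        return bool(self.mean_accuracy > self.null_95th)


def _zscore_train(train: np.ndarray, test: np.ndarray):
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return (train - mean) / sd, (test - mean) / sd


def fit_and_test(features: FeatureSet, cfg: DecoderConfig) -> DecodeResult:
    """Nested cross-validated RBF-SVM decoding of one feature set.

    Each of ``cfg.n_iterations`` outer iterations draws a fresh stratified
    80/20 split, grid-searches (C, gamma) by 5-fold cross-validation on
    the training rows (ties broken toward the smallest C, then the
    smallest gamma), refits the winner on all training rows, and scores
    the held-out 20%.  Features are standardized with training-set
    statistics only.
    """
    cfg.validate()
    X = np.asarray(features.matrix, dtype=float)
    y = np.asarray(features.labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"expected 2 classes, got {list(classes)}")
    if counts.min() < 10:
        raise ValueError(
            f"need >= 10 rows per class, got {dict(zip(classes, counts))}"
        )
    if X.std(axis=0).max() == 0:
        raise ValueError("degenerate features: zero variance everywhere")

    widths = cfg.resolved_widths(X.shape[1])
    grid = sorted(
        {(float(c), float(g)) for c in cfg.penalty_grid for g in widths}
    )  # ascending C then gamma: first strict improvement wins ties

    ss = np.random.SeedSequence(cfg.seed)
    iter_seeds = ss.spawn(cfg.n_iterations)

    accuracies = np.empty(cfg.n_iterations)
    pairs = []
    for it in range(cfg.n_iterations):
        rs = np.random.default_rng(iter_seeds[it])
        split_seed, fold_seed = rs.integers(0, 2**31 - 1, size=2)
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, train_size=cfg.outer_split, stratify=y, random_state=int(split_seed)
        )
        X_tr, X_te = _zscore_train(X_tr, X_te)

        if len(grid) == 1:
            best_c, best_g = grid[0]
        else:
            skf = StratifiedKFold(
                n_splits=cfg.inner_folds, shuffle=True, random_state=int(fold_seed)
            )
            folds = list(skf.split(X_tr, y_tr))
            best_score, best_c, best_g = -np.inf, *grid[0]
            for c, g in grid:
                score = 0.0
                for tr_idx, va_idx in folds:
                    clf = SVC(C=c, gamma=g, kernel="rbf")
                    clf.fit(X_tr[tr_idx], y_tr[tr_idx])
                    score += clf.score(X_tr[va_idx], y_tr[va_idx])
                score /= len(folds)
                if score > best_score:
                    best_score, best_c, best_g = score, c, g

        clf = SVC(C=best_c, gamma=best_g, kernel="rbf")
        clf.fit(X_tr, y_tr)
        y_pred = clf.predict(X_te)
        accuracies[it] = float(np.mean(y_pred == y_te))
        pairs.append((y_te, y_pred))

    return DecodeResult(
        offset=features.offset,
        iteration_accuracies=accuracies,
        mean_accuracy=float(accuracies.mean()),
        test_pairs=pairs,
    )


def _exhaustive_null(pairs: list) -> np.ndarray:
    """All distinct test-label arrangements, pooled across iterations."""
    null = []
    for y_te, y_pred in pairs:
        classes, counts = np.unique(y_te, return_counts=True)
        n = len(y_te)
        k = int(counts[0])
        for pos in combinations(range(n), k):
            perm = np.full(n, classes[1], dtype=y_te.dtype)
            perm[list(pos)] = classes[0]
            null.append(float(np.mean(perm == y_pred)))
    return np.asarray(null)


def empirical_null_and_p(result: DecodeResult, cfg: DecoderConfig) -> DecodeResult:
    """Fill a DecodeResult's chance distribution and permutation p-value.

    Shuffles the test labels of each outer iteration against that
    iteration's fixed predictions, pooling ``cfg.n_shuffles`` accuracies
    (round-robin over iterations).  When the total number of distinct
    label arrangements does not exceed ``cfg.n_shuffles`` the null is
    enumerated exhaustively and the p-value is the exact permutation
    p ``#{null >= observed} / n_arrangements``; otherwise the add-one
    Monte Carlo estimator is used.
    """
    if not result.test_pairs:
        raise ValueError("DecodeResult holds no retained test sets")
    n_distinct = 0
    for y_te, _ in result.test_pairs:
        _, counts = np.unique(y_te, return_counts=True)
        n_distinct += comb(len(y_te), int(counts[0]))

    if n_distinct <= cfg.n_shuffles:
        null = _exhaustive_null(result.test_pairs)
        p = float(np.mean(null >= result.mean_accuracy))
        exhaustive = True
    else:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5E1F]))
        n_iter = len(result.test_pairs)
        null = np.empty(cfg.n_shuffles)
        for s in range(cfg.n_shuffles):
            y_te, y_pred = result.test_pairs[s % n_iter]
            perm = rng.permutation(y_te)
            null[s] = float(np.mean(perm == y_pred))
        p = (1.0 + float(np.sum(null >= result.mean_accuracy))) / (1.0 + cfg.n_shuffles)
        exhaustive = False

    result.null_accuracies = null
    result.null_95th = float(np.percentile(null, 95))
    result.p_value = p
    result.exhaustive_null = exhaustive
    return result


def bh_fdr(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up correction.

    Returns (adjusted p-values, rejection mask at level ``q``).
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to correct")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


@dataclass
class SweepResult:
    """Per-offset decoding results across a feature-window offset sweep."""

    offsets: np.ndarray
    results: list  # DecodeResult or None where an offset had no usable trials
    contrast: str
    first_significant_offset: float | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for off, res in zip(self.offsets, self.results):
            if res is None:
                rows.append(
                    dict(offset_s=off, mean_accuracy=np.nan, p=np.nan,
                         p_adj=np.nan, significant=False, missing=True)
                )
            else:
                rows.append(
                    dict(
                        offset_s=off,
                        mean_accuracy=res.mean_accuracy,
                        p=res.p_value,
                        p_adj=res.p_adjusted,
                        significant=res.significant,
                        missing=False,
                    )
                )
        return pd.DataFrame(rows)

    def accuracy_at(self, offset: float) -> float:
        i = int(np.argmin(np.abs(self.offsets - offset)))
        res = self.results[i]
        return np.nan if res is None else res.mean_accuracy

    def summary(self) -> str:
        df = self.to_frame()
        lines = [
            f"Offset sweep vs {self.contrast}: {len(self.offsets)} offsets",
            f"first significant offset: {self.first_significant_offset}",
            df.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)


def sweep_offsets(contrast: str, start: float = -1.5, stop: float = 0.7,
                  step: float = 0.1) -> np.ndarray:
    """The canonical offset grids: 23 offsets for the silence contrast,
    three causal offsets (-0.2, -0.1, 0) for the instructed-delay control."""
    if contrast == "delay":
        return np.array([-0.2, -0.1, 0.0])
    n = int(round((stop - start) / step)) + 1
    return np.round(start + step * np.arange(n), 10)


def _apply_significance(results: list, alpha: float) -> None:
    """BH-correct across non-missing results and set the dual-gate flag."""
    live = [r for r in results if r is not None]
    if not live:
        raise ValueError("all offsets missing; nothing to correct")
    p_adj, _ = bh_fdr([r.p_value for r in live], q=alpha)
    for r, pa in zip(live, p_adj):
        r.p_adjusted = float(pa)
        r.significant = bool(pa < alpha and r.above_null_gate())


def offset_sweep(
    env: BandPowerEnvelope,
    events: TrialEvents,
    cfg: DecoderConfig,
    contrast: str = "silence",
    n_windows: int = 4,
    band: str = "high_gamma",
    task_filter: str | None = None,
    offsets: np.ndarray | None = None,
) -> SweepResult:
    """Decode at every feature-window offset and localize the first
    significant one.

    Offsets shift the end of the speech-intent windows relative to voice
    onset; contrast windows stay fixed.  P-values are BH-corrected across
    offsets; an offset is significant when the adjusted p clears alpha
    *and* the mean accuracy exceeds the null's 95th percentile.  Offsets
    whose classes empty out (e.g. windows falling off the record) are
    reported missing rather than fabricated.
    """
    if contrast not in ("silence", "delay"):
        raise ValueError("contrast must be 'silence' or 'delay'")
    if offsets is None:
        offsets = sweep_offsets(contrast)
    speech = speech_window_spec(n_windows)
    contrast_spec = (
        delay_window_spec() if contrast == "delay" else silence_window_spec(n_windows)
    )

    ss = np.random.SeedSequence(cfg.seed)
    offset_seeds = ss.spawn(len(offsets))

    results: list = []
    for off, seed in zip(offsets, offset_seeds):
        sub_seed = int(np.random.default_rng(seed).integers(0, 2**31 - 1))
        try:
            fs = build_feature_set(
                env, events, speech, contrast_spec,
                offset=float(off), band=band, task_filter=task_filter,
                seed=sub_seed,
            )
            sub_cfg = DecoderConfig(**{**cfg.__dict__, "seed": sub_seed})
            res = fit_and_test(fs, sub_cfg)
            res = empirical_null_and_p(res, sub_cfg)
        except ValueError as err:
            warnings.warn(
                f"offset {off:+.1f} s skipped: {err}", RuntimeWarning, stacklevel=2
            )
            results.append(None)
            continue
        results.append(res)

    _apply_significance(results, cfg.alpha)
    first = None
    for off, res in zip(offsets, results):
        if res is not None and res.significant:
            first = float(off)
            break
    return SweepResult(
        offsets=np.asarray(offsets),
        results=results,
        contrast=contrast,
        first_significant_offset=first,
    )


def group_significance(sweeps: list[SweepResult], alpha: float = 0.05) -> pd.DataFrame:
    """Across-dataset significance at each offset.

    The s-th group-null sample is the mean, across datasets, of each
    dataset's s-th shuffled accuracy; the observed group mean accuracy is
    compared to that distribution (add-one p), gated at the group null's
    95th percentile and BH-corrected across offsets.
    """
    if len(sweeps) < 2:
        raise ValueError("group significance needs >= 2 datasets")
    base = sweeps[0].offsets
    for sw in sweeps[1:]:
        if len(sw.offsets) != len(base) or not np.allclose(sw.offsets, base):
            raise ValueError("offset grids are misaligned across datasets")

    rows = []
    for i, off in enumerate(base):
        per_ds = [sw.results[i] for sw in sweeps]
        if any(r is None or r.null_accuracies is None for r in per_ds):
            rows.append(dict(offset_s=off, group_accuracy=np.nan, p=np.nan))
            continue
        n_null = min(len(r.null_accuracies) for r in per_ds)
        group_null = np.mean([r.null_accuracies[:n_null] for r in per_ds], axis=0)
        obs = float(np.mean([r.mean_accuracy for r in per_ds]))
        p = (1.0 + float(np.sum(group_null >= obs))) / (1.0 + n_null)
        rows.append(
            dict(
                offset_s=off,
                group_accuracy=obs,
                p=p,
                null_95th=float(np.percentile(group_null, 95)),
            )
        )
    df = pd.DataFrame(rows)
    ok = df["p"].notna()
    if not ok.any():
        raise ValueError("no offsets with complete nulls across datasets")
    p_adj, _ = bh_fdr(df.loc[ok, "p"], q=alpha)
    df.loc[ok, "p_adj"] = p_adj
    df["significant"] = (
        (df["p_adj"] < alpha) & (df["group_accuracy"] > df["null_95th"])
    ).fillna(False)
    return df


def single_electrode_map(
    env: BandPowerEnvelope,
    events: TrialEvents,
    cfg: DecoderConfig,
    n_windows: int = 4,
    band: str = "high_gamma",
) -> pd.DataFrame:
    """Decode speech intent vs silence from each electrode alone (offset 0).

    One feature set is built at offset 0 and sliced per electrode, so the
    class balancing is identical across electrodes; significance is
    BH-corrected across electrodes.
    """
    fs_all = build_feature_set(
        env,
        events,
        speech_window_spec(n_windows),
        silence_window_spec(n_windows),
        offset=0.0,
        band=band,
        seed=cfg.seed,
    )
    labels = {c.name: c.anatomical_label for c in env.channels}
    ss = np.random.SeedSequence(cfg.seed)
    elec_seeds = ss.spawn(len(fs_all.channel_names))

    rows, results = [], []
    for e, name in enumerate(fs_all.channel_names):
        mask = np.zeros(len(fs_all.column_names), dtype=bool)
        mask[e * n_windows: (e + 1) * n_windows] = True
        sub = fs_all.select_columns(mask)
        sub_seed = int(np.random.default_rng(elec_seeds[e]).integers(0, 2**31 - 1))
        sub_cfg = DecoderConfig(**{**cfg.__dict__, "seed": sub_seed})
        res = empirical_null_and_p(fit_and_test(sub, sub_cfg), sub_cfg)
        results.append(res)
        rows.append(
            dict(
                channel=name,
                anatomical_label=labels.get(name, "unknown"),
                mean_accuracy=res.mean_accuracy,
                p=res.p_value,
            )
        )
    _apply_significance(results, cfg.alpha)
    df = pd.DataFrame(rows)
    df["p_adj"] = [r.p_adjusted for r in results]
    df["significant"] = [r.significant for r in results]
    return df


def compare_contrasts(acc_silence, acc_delay) -> float:
    """Two-sided Wilcoxon rank-sum p comparing accuracy samples from the
    silence and instructed-delay contrasts (exact for small tie-free
    samples)."""
    x = np.asarray(list(acc_silence), dtype=float)
    y = np.asarray(list(acc_delay), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both accuracy samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn(
            "identical constant samples; rank-sum p set to 1", RuntimeWarning,
            stacklevel=2,
        )
        return 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (not has_ties and max(x.size, y.size) <= 25) else "asymptotic"
    stat = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(stat.pvalue)
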