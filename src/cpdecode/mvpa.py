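"""Time-resolved multivariate pattern analysis.

Decoding follows the noise-normalized pairwise scheme standard in
sensor-space MEG MVPA: trials are split into k stratified folds; a noise
covariance is estimated from the training folds with the "epoch" method
(per-condition, per-time-point residual covariances averaged over time and
conditions) and regularized by Ledoit-Wolf shrinkage toward a scaled
identity; training and test data are whitened with the training covariance's
inverse principal square root; same-condition trials are averaged within
each fold into summary trials; and a linear maximum-margin classifier is
trained and scored per time point.  Pairwise decoding of all 45 stimulus
pairs yields a 10 x 10 dissimilarity (RDM) time series per subject; percept
decoding classifies ba- vs. da-labeled trials with the same machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.covariance import ledoit_wolf_shrinkage

from ._svm import svm_decision, svm_train_batch
from .synth import EpochSet, N_STEPS

__all__ = [
    "PAIRS",
    "FoldAssignment",
    "NoiseCovariance",
    "RDMSeries",
    "DecodingTimecourse",
    "ActivationPattern",
    "assign_folds",
    "estimate_noise_covariance",
    "whiten",
    "whitening_matrix",
    "make_summary_trials",
    "decode_pair",
    "decode_all_pairs",
    "decode_percept",
    "average_rdm",
    "haufe_transform",
    "pair_index",
]

#: canonical pair ordering: (i, j) with i < j, lexicographic over steps 1..10
PAIRS: List[Tuple[int, int]] = [
    (i, j) for i in range(1, N_STEPS + 1) for j in range(i + 1, N_STEPS + 1)
]
_PAIR_INDEX = {p: k for k, p in enumerate(PAIRS)}


def pair_index(i: int, j: int) -> int:
    """Position of the (i, j) stimulus pair in the 45-vector convention."""
    if i == j:
        raise ValueError("the RDM diagonal (i == j) is undefined")
    key = (min(i, j), max(i, j))
    if key not in _PAIR_INDEX:
        raise ValueError(f"invalid stimulus pair {(i, j)}; steps must be in 1..{N_STEPS}")
    return _PAIR_INDEX[key]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldAssignment:
    """Per-trial fold indices (0..k-1), stratified within condition."""

    folds: np.ndarray
    k: int
    repetition: int = 0


@dataclass(frozen=True)
class NoiseCovariance:
    """Shrinkage-regularized noise covariance (channels x channels)."""

    matrix: np.ndarray
    shrinkage: float

    def __post_init__(self):
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("covariance must be square")
        if not (0.0 <= self.shrinkage <= 1.0):
            raise ValueError("shrinkage intensity must lie in [0, 1]")


@dataclass
class DecodingTimecourse:
    """Decoding accuracy (percent) per time point for one subject."""

    times: np.ndarray
    values: np.ndarray
    subject_id: str = ""
    task: str = ""
    sensor_subset: str = "all"
    label: str = ""

    def __post_init__(self):
        if len(self.times) != len(self.values):
            raise ValueError("times and values must align")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": self.subject_id,
                "task": self.task,
                "subset": self.sensor_subset,
                "label": self.label,
                "time_ms": self.times,
                "accuracy": self.values,
            }
        )


@dataclass
class RDMSeries:
    """Time-resolved 45-pair decoding-accuracy dissimilarities for one subject.

    ``values`` is time x 45 in percent, columns ordered by :data:`PAIRS`.
    """

    times: np.ndarray
    values: np.ndarray
    subject_id: str = ""
    task: str = ""
    sensor_subset: str = "all"

    def __post_init__(self):
        if self.values.shape != (len(self.times), len(PAIRS)):
            raise ValueError(f"values must be (n_times, {len(PAIRS)})")

    def matrix_at(self, time_index: int) -> np.ndarray:
        """Symmetric 10 x 10 RDM view at one time sample (zero diagonal)."""
        m = np.zeros((N_STEPS, N_STEPS))
        for k, (i, j) in enumerate(PAIRS):
            m[i - 1, j - 1] = m[j - 1, i - 1] = self.values[time_index, k]
        return m

    def pair(self, i: int, j: int) -> np.ndarray:
        return self.values[:, pair_index(i, j)]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for k, (i, j) in enumerate(PAIRS):
            rows.append(
                pd.DataFrame(
                    {
                        "subject": self.subject_id,
                        "task": self.task,
                        "subset": self.sensor_subset,
                        "pair": f"{i}-{j}",
                        "time_ms": self.times,
                        "accuracy": self.values[:, k],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


@dataclass
class ActivationPattern:
    """Forward-model activation pattern derived from classifier weights."""

    values: np.ndarray
    window_ms: Optional[Tuple[float, float]] = None


# ---------------------------------------------------------------------------
# Cross-validation machinery
# ---------------------------------------------------------------------------

def assign_folds(labels: Sequence, k: int = 5, seed: int = 0, repetition: int = 0) -> FoldAssignment:
    """Random stratified fold assignment: within each condition the fold
    sizes differ by at most one.  Reproducible from ``seed``."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    folds = np.empty(len(labels), dtype=int)
    for cond in np.unique(labels):
        idx = np.flatnonzero(labels == cond)
        if len(idx) < k:
            raise ValueError(
                f"condition {cond!r} has {len(idx)} trials but k={k} folds were requested"
            )
        perm = rng.permutation(idx)
        folds[perm] = np.arange(len(idx)) % k
    return FoldAssignment(folds=folds, k=k, repetition=repetition)


def estimate_noise_covariance(
    data: np.ndarray,
    labels: Sequence,
    shrinkage: float | str = "auto",
) -> NoiseCovariance:
    """Epoch-method noise covariance from training trials.

    Residuals are trial minus condition mean at each time point; the
    per-time-point covariances are averaged across time points and
    conditions, then shrunk toward nu*I (nu = mean eigenvalue).  With
    ``shrinkage="auto"`` the intensity is the analytic Ledoit-Wolf optimum
    computed from the pooled residuals.
    """
    data = np.asarray(data)
    labels = np.asarray(labels)
    n, c, t = data.shape
    per_cond = []
    resid_pool = []
    for cond in np.unique(labels):
        idx = np.flatnonzero(labels == cond)
        if len(idx) < 2:
            raise ValueError(
                f"condition {cond!r} has a single training trial; residuals are zero. "
                "Reduce the number of folds or merge conditions."
            )
        resid = data[idx].astype(np.float64) - data[idx].mean(axis=0, keepdims=True, dtype=np.float64)
        # average over time of per-time-point covariances
        flat = np.moveaxis(resid, 1, 2).reshape(-1, c)  # (n_c * t, channels)
        per_cond.append(flat.T @ flat / (t * (len(idx) - 1)))
        resid_pool.append(flat)
    cov = np.mean(per_cond, axis=0)

    if shrinkage == "auto":
        pooled = np.concatenate(resid_pool, axis=0)
        if pooled.shape[0] > 4000:  # intensity estimate stabilizes well before this
            step = pooled.shape[0] // 4000 + 1
            pooled = pooled[::step]
        lam = float(ledoit_wolf_shrinkage(pooled, assume_centered=True))
    else:
        lam = float(shrinkage)
        if not (0.0 <= lam <= 1.0):
            raise ValueError("shrinkage intensity must lie in [0, 1]")
    nu = np.trace(cov) / c
    shrunk = (1.0 - lam) * cov + lam * nu * np.eye(c)
    return NoiseCovariance(matrix=shrunk, shrinkage=lam)


def whitening_matrix(cov: NoiseCovariance | np.ndarray) -> np.ndarray:
    """Inverse principal (symmetric) square root of a positive-definite covariance."""
    m = cov.matrix if isinstance(cov, NoiseCovariance) else np.asarray(cov)
    vals, vecs = np.linalg.eigh(m)
    if vals.min() <= 0:
        raise ValueError("covariance is not positive-definite; increase shrinkage")
    return (vecs / np.sqrt(vals)) @ vecs.T


def _apply_channel_transform(w: np.ndarray, data: np.ndarray) -> np.ndarray:
    """w @ data along the channel axis of (trials, channels, time) data (BLAS path)."""
    return np.moveaxis(np.tensordot(w, data, axes=(1, 1)), 0, 1)


def _gram_per_timepoint(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """(time, n_a, n_b) Gram matrices from (n, channels, time) arrays."""
    at = np.ascontiguousarray(np.transpose(a, (2, 0, 1)))
    bt = np.ascontiguousarray(np.transpose(b, (2, 1, 0)))
    return at @ bt


def whiten(epochs, cov: NoiseCovariance | np.ndarray):
    """Multiply the channel axis by the inverse principal square root of ``cov``.

    Accepts an :class:`EpochSet` (returns a new one) or a raw
    (trials, channels, time) array.
    """
    w = whitening_matrix(cov)
    if isinstance(epochs, EpochSet):
        return epochs.copy_with(data=_apply_channel_transform(w, epochs.data))
    return _apply_channel_transform(w, np.asarray(epochs))


def make_summary_trials(
    data: np.ndarray,
    labels: Sequence,
    folds: FoldAssignment,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Average same-condition trials within each fold into summary trials.

    Returns (summary data, summary condition labels, summary fold index);
    one summary trial per condition per fold.
    """
    labels = np.asarray(labels)
    conds = np.unique(labels)
    out, out_lab, out_fold = [], [], []
    for cond in conds:
        for f in range(folds.k):
            idx = np.flatnonzero((labels == cond) & (folds.folds == f))
            if len(idx) == 0:
                raise ValueError(f"condition {cond!r} has no trials in fold {f}")
            out.append(data[idx].mean(axis=0))
            out_lab.append(cond)
            out_fold.append(f)
    return np.stack(out), np.array(out_lab), np.array(out_fold)


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------

def _score_fold(
    strain: np.ndarray,
    stest: np.ndarray,
    y_train: np.ndarray,
    y_test: np.ndarray,
    svm_c: float,
) -> np.ndarray:
    """Train per time point and score the held-out summary trials.

    Inputs are whitened summary trials (n, channels, time).  Returns the
    fraction correct per time point; a decision value of exactly 0 counts
    as 0.5 (unbiased at chance).
    """
    k_train = _gram_per_timepoint(strain, strain)
    k_test = _gram_per_timepoint(stest, strain)
    alpha, b = svm_train_batch(k_train, y_train, C=svm_c)
    dec = svm_decision(k_test, alpha, b, y_train)  # (T, n_test)
    score = np.where(dec * y_test[None, :] > 0, 1.0, np.where(dec == 0.0, 0.5, 0.0))
    return score.mean(axis=1)


def _decode_binary(
    data: np.ndarray,
    y: np.ndarray,
    k: int,
    n_reps: int,
    seed: int,
    svm_c: float = 1.0,
    shrinkage: float | str = "auto",
    full_rotation: bool = True,
    audit: Optional[list] = None,
) -> np.ndarray:
    """Cross-validated two-class decoding accuracy per time point (percent).

    ``y`` holds +-1 class labels.  Per repetition, folds are re-randomized;
    with ``full_rotation`` every fold serves as the test fold once
    (otherwise only fold 0, the literal single-split reading).
    """
    n, c, t = data.shape
    rng = np.random.default_rng(seed)
    acc = np.zeros(t)
    n_scored = 0
    for rep in range(n_reps):
        fa = assign_folds(y, k=k, seed=int(rng.integers(2**31 - 1)), repetition=rep)
        sdata, slab, sfold = make_summary_trials(data, y, fa)
        test_folds = range(k) if full_rotation else (0,)
        for tf in test_folds:
            train_mask = fa.folds != tf
            cov = estimate_noise_covariance(data[train_mask], y[train_mask], shrinkage)
            if audit is not None:
                audit.append(
                    {
                        "cov_trials": np.flatnonzero(train_mask),
                        "test_trials": np.flatnonzero(~train_mask),
                    }
                )
            w = whitening_matrix(cov)
            sw = _apply_channel_transform(w, sdata)
            tr = sfold != tf
            acc += _score_fold(sw[tr], sw[~tr], slab[tr].astype(float), slab[~tr].astype(float), svm_c)
            n_scored += 1
    return 100.0 * acc / n_scored


def _select(epochs: EpochSet, sensor_subset: str) -> Tuple[np.ndarray, np.ndarray]:
    ch = epochs.layout.subset_indices(sensor_subset)
    return epochs.data[:, ch, :], ch


def decode_pair(
    epochs: EpochSet,
    cond_a: int,
    cond_b: int,
    k: int = 5,
    n_reps: int = 100,
    sensor_subset: str = "all",
    seed: int = 0,
    svm_c: float = 1.0,
    shrinkage: float | str = "auto",
    full_rotation: bool = True,
    labels: Optional[np.ndarray] = None,
    audit: Optional[list] = None,
) -> DecodingTimecourse:
    """Pairwise decoding of two stimulus conditions at every time point.

    ``labels`` overrides the stimulus labels (e.g. for label-permutation
    chance checks) and must align with the trial axis.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    lab = epochs.stimulus if labels is None else np.asarray(labels)
    mask = (lab == cond_a) | (lab == cond_b)
    if (lab == cond_a).sum() == 0 or (lab == cond_b).sum() == 0:
        raise ValueError(f"conditions {cond_a} and {cond_b} must both be present")
    data, _ = _select(epochs, sensor_subset)
    y = np.where(lab[mask] == cond_a, 1.0, -1.0)
    values = _decode_binary(
        data[mask], y, k, n_reps, seed, svm_c, shrinkage, full_rotation, audit
    )
    return DecodingTimecourse(
        times=epochs.times,
        values=values,
        subject_id=epochs.subject_id,
        task=epochs.task,
        sensor_subset=sensor_subset,
        label=f"pair_{min(cond_a, cond_b)}_{max(cond_a, cond_b)}",
    )


def decode_all_pairs(
    epochs: EpochSet,
    k: int = 5,
    n_reps: int = 100,
    sensor_subset: str = "all",
    seed: int = 0,
    svm_c: float = 1.0,
    shrinkage: float | str = "auto",
    full_rotation: bool = True,
) -> RDMSeries:
    """Pairwise decoding of all 45 stimulus pairings into an RDM time series.

    Folds, the noise covariance and the summary trials are shared across
    pairs within each repetition/rotation: the covariance is estimated from
    the training trials of all 10 conditions (the epoch method averages
    across conditions), and each pair's classifier sees only its own two
    conditions' summary trials.
    """
    missing = set(range(1, N_STEPS + 1)) - set(np.unique(epochs.stimulus).tolist())
    if missing:
        raise ValueError(f"stimulus conditions missing from the epochs: {sorted(missing)}")
    data, _ = _select(epochs, sensor_subset)
    labels = epochs.stimulus
    n, c, t = data.shape
    rng = np.random.default_rng(seed)
    acc = np.zeros((t, len(PAIRS)))
    n_scored = 0

    y_pair = np.concatenate([np.ones(k - 1), -np.ones(k - 1)])
    y_test = np.array([1.0, -1.0])

    for rep in range(n_reps):
        fa = assign_folds(labels, k=k, seed=int(rng.integers(2**31 - 1)), repetition=rep)
        sdata, slab, sfold = make_summary_trials(data, labels, fa)
        test_folds = range(k) if full_rotation else (0,)
        for tf in test_folds:
            train_mask = fa.folds != tf
            cov = estimate_noise_covariance(data[train_mask], labels[train_mask], shrinkage)
            w = whitening_matrix(cov)
            sw = _apply_channel_transform(w, sdata)
            gram = _gram_per_timepoint(sw, sw)  # (t, 10k, 10k)
            for p, (ci, cj) in enumerate(PAIRS):
                tr_idx = np.flatnonzero(
                    ((slab == ci) | (slab == cj)) & (sfold != tf)
                )
                te_idx = np.flatnonzero(((slab == ci) | (slab == cj)) & (sfold == tf))
                # order: ci summaries first, then cj (labels +1 then -1)
                tr_idx = np.concatenate([tr_idx[slab[tr_idx] == ci], tr_idx[slab[tr_idx] == cj]])
                te_idx = np.concatenate([te_idx[slab[te_idx] == ci], te_idx[slab[te_idx] == cj]])
                k_train = gram[:, tr_idx[:, None], tr_idx[None, :]]
                k_test = gram[:, te_idx[:, None], tr_idx[None, :]]
                alpha, b = svm_train_batch(k_train, y_pair, C=svm_c)
                dec = svm_decision(k_test, alpha, b, y_pair)
                score = np.where(dec * y_test[None, :] > 0, 1.0, np.where(dec == 0.0, 0.5, 0.0))
                acc[:, p] += score.mean(axis=1)
            n_scored += 1
    return RDMSeries(
        times=epochs.times,
        values=100.0 * acc / n_scored,
        subject_id=epochs.subject_id,
        task=epochs.task,
        sensor_subset=sensor_subset,
    )


def decode_percept(
    epochs: EpochSet,
    k: int = 5,
    n_reps: int = 100,
    sensor_subset: str = "all",
    seed: int = 0,
    svm_c: float = 1.0,
    shrinkage: float | str = "auto",
    full_rotation: bool = True,
) -> DecodingTimecourse:
    """Binary decoding of the reported percept (all ba- vs. all da-labeled trials).

    Class counts may be unequal; no equalization is applied (accuracy is the
    mean over the two held-out summary trials, which weights classes equally).
    """
    percept = np.asarray(epochs.percept)
    n_ba = int((percept == "ba").sum())
    n_da = int((percept == "da").sum())
    if n_ba == 0 or n_da == 0:
        raise ValueError(
            f"percept decoding needs both classes; got {n_ba} ba and {n_da} da trials"
        )
    data, _ = _select(epochs, sensor_subset)
    y = np.where(percept == "ba", 1.0, -1.0)
    values = _decode_binary(data, y, k, n_reps, seed, svm_c, shrinkage, full_rotation)
    return DecodingTimecourse(
        times=epochs.times,
        values=values,
        subject_id=epochs.subject_id,
        task=epochs.task,
        sensor_subset=sensor_subset,
        label="percept",
    )


def average_rdm(rdm: RDMSeries) -> DecodingTimecourse:
    """Overall stimulus decoding: unweighted mean over the 45 pairs per time point."""
    return DecodingTimecourse(
        times=rdm.times,
        values=rdm.values.mean(axis=1),
        subject_id=rdm.subject_id,
        task=rdm.task,
        sensor_subset=rdm.sensor_subset,
        label="overall",
    )


def haufe_transform(
    weights: np.ndarray,
    data_cov: np.ndarray,
    latent_cov: float | np.ndarray = 1.0,
    window_ms: Optional[Tuple[float, float]] = None,
) -> ActivationPattern:
    """Transform backward-model classifier weights into activation patterns.

    ``A = data_cov @ W @ latent_cov^{-1}``: left-multiplication by the data
    covariance and right-multiplication by the inverse of the latent
    (decision-score) covariance turns extraction-filter weights into
    forward-model patterns interpretable as per-channel activations.
    """
    w = np.asarray(weights, dtype=float)
    squeeze = w.ndim == 1
    if squeeze:
        w = w[:, None]
    data_cov = np.asarray(data_cov, dtype=float)
    if np.isscalar(latent_cov) or np.ndim(latent_cov) == 0:
        if latent_cov == 0:
            raise ValueError("latent covariance is singular")
        a = data_cov @ w / float(latent_cov)
    else:
        latent = np.atleast_2d(latent_cov)
        if abs(np.linalg.det(latent)) < 1e-300:
            raise ValueError("latent covariance is singular")
        a = data_cov @ w @ np.linalg.inv(latent)
    return ActivationPattern(values=a[:, 0] if squeeze else a, window_ms=window_ms)
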