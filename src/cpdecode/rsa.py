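"""Representational similarity analysis against behavioral models.

Two 10 x 10 behavioral model RDMs are built from the identification data:

* **Perceptual** — cell (i, j) is the absolute difference between the
  percent of trials labeled *ba* for the two stimuli; large where the two
  steps fall on opposite sides of the category boundary.
* **Ambiguity** — the labeling proportion is first mapped to a consistency
  index (100 = same label on every trial, 0 = labeled *ba* on exactly half
  of trials); cell (i, j) is the absolute consistency difference, large
  where one stimulus is ambiguous and the other is not.

Neural RDM time series are compared with each model by partial Spearman
correlation (partialling out the other model), and window-level effects of
task, model, and their interaction are tested by bootstrap resampling of
subjects with model RDMs rebuilt per bootstrap sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import rankdata

from .mvpa import PAIRS, RDMSeries
from .synth import BehaviorTable, N_STEPS, consistency_index

__all__ = [
    "ModelRDM",
    "RSAWindowEffects",
    "build_perceptual_rdm",
    "build_ambiguity_rdm",
    "partial_spearman",
    "rsa_timecourse",
    "bootstrap_window_tests",
]

RSA_ALPHA = 0.017  # Bonferroni-corrected level for three windows


@dataclass(frozen=True)
class ModelRDM:
    """Behavioral dissimilarity model: 10 x 10 symmetric, zero diagonal, 0-100."""

    kind: str
    values: np.ndarray

    def __post_init__(self):
        v = self.values
        if v.shape != (N_STEPS, N_STEPS):
            raise ValueError(f"model RDM must be {N_STEPS} x {N_STEPS}")
        if not np.allclose(v, v.T):
            raise ValueError("model RDM must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("model RDM must have a zero diagonal")
        if v.min() < -1e-9 or v.max() > 100 + 1e-9:
            raise ValueError("model RDM entries must lie in [0, 100]")

    def vector(self) -> np.ndarray:
        """45-vector in the canonical pair ordering."""
        return np.array([self.values[i - 1, j - 1] for i, j in PAIRS])


@dataclass(frozen=True)
class RSAWindowEffects:
    """Bootstrap test of one effect in one time window."""

    window_ms: Tuple[float, float]
    effect: str  # task | model | interaction
    estimate: float
    p_value: float
    n_boot: int
    alpha: float = RSA_ALPHA

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def _rdm_from_profile(profile: np.ndarray, kind: str) -> ModelRDM:
    m = np.abs(profile[:, None] - profile[None, :])
    return ModelRDM(kind=kind, values=m)


def build_perceptual_rdm(behavior: BehaviorTable | np.ndarray) -> ModelRDM:
    """Perceptual model: |%ba(i) - %ba(j)| from subject-averaged labeling.

    The matrix has minimum 0 and reaches 100 exactly when one stimulus is
    always labeled *ba* and another never.
    """
    prop = behavior.prop_ba() if isinstance(behavior, BehaviorTable) else np.asarray(behavior, float)
    if len(prop) != N_STEPS:
        raise ValueError(f"need prop_ba for all {N_STEPS} stimuli")
    return _rdm_from_profile(100.0 * prop, "perceptual")


def build_ambiguity_rdm(
    behavior: BehaviorTable | np.ndarray,
    consistency_fn: Callable[[np.ndarray], np.ndarray] = consistency_index,
) -> Tuple[ModelRDM, np.ndarray]:
    """Ambiguity model: |consistency(i) - consistency(j)|.

    ``consistency_fn`` maps prop_ba to the 0-100 consistency scale (linear
    in |prop_ba - 0.5| by default; pluggable since only the two anchors are
    pinned).  Returns the model and the per-stimulus consistency index.
    """
    prop = behavior.prop_ba() if isinstance(behavior, BehaviorTable) else np.asarray(behavior, float)
    if len(prop) != N_STEPS:
        raise ValueError(f"need prop_ba for all {N_STEPS} stimuli")
    cons = np.asarray(consistency_fn(prop), dtype=float)
    return _rdm_from_profile(cons, "ambiguity"), cons


# ---------------------------------------------------------------------------
# Partial Spearman correlation
# ---------------------------------------------------------------------------

def _check_nonconstant(name: str, v: np.ndarray) -> None:
    if np.ptp(v) == 0:
        raise ValueError(f"{name} vector is constant; its rank correlation is undefined")


def partial_spearman(
    neural: np.ndarray,
    model: np.ndarray | ModelRDM,
    partial_out: np.ndarray | ModelRDM,
) -> float:
    """Partial Spearman correlation of ``neural`` with ``model`` given ``partial_out``.

    All three inputs are vectorized over the same 45 pairs, rank-transformed
    (mid-ranks for ties), and the partial product-moment correlation of the
    ranks is returned.
    """
    x = np.asarray(neural, dtype=float)
    y = model.vector() if isinstance(model, ModelRDM) else np.asarray(model, float)
    z = partial_out.vector() if isinstance(partial_out, ModelRDM) else np.asarray(partial_out, float)
    if not (x.shape == y.shape == z.shape):
        raise ValueError("all three vectors must share the same pair dimension")
    _check_nonconstant("neural", x)
    _check_nonconstant("model", y)
    _check_nonconstant("partial_out", z)
    rx, ry, rz = rankdata(x), rankdata(y), rankdata(z)
    r = np.corrcoef(np.stack([rx, ry, rz]))
    rxy, rxz, ryz = r[0, 1], r[0, 2], r[1, 2]
    denom = np.sqrt((1 - rxz**2) * (1 - ryz**2))
    if denom == 0:
        raise ValueError("partialled variable is perfectly rank-correlated with an input")
    return float((rxy - rxz * ryz) / denom)


def _partial_spearman_series(values: np.ndarray, model: np.ndarray, other: np.ndarray) -> np.ndarray:
    """partial_spearman per row of a (time, 45) array (models rank-cached).

    A constant row (all 45 pair accuracies equal, possible in heavily
    quantized scaled-down runs) yields NaN; an all-constant series raises.
    """
    ry = rankdata(model)
    rz = rankdata(other)
    ry_c = ry - ry.mean()
    rz_c = rz - rz.mean()
    ryz = float(np.dot(ry_c, rz_c) / np.sqrt(np.dot(ry_c, ry_c) * np.dot(rz_c, rz_c)))
    out = np.empty(values.shape[0])
    for t in range(values.shape[0]):
        rx = rankdata(values[t])
        rx_c = rx - rx.mean()
        sx = np.sqrt(np.dot(rx_c, rx_c))
        if sx == 0:
            out[t] = np.nan
            continue
        rxy = float(np.dot(rx_c, ry_c) / (sx * np.sqrt(np.dot(ry_c, ry_c))))
        rxz = float(np.dot(rx_c, rz_c) / (sx * np.sqrt(np.dot(rz_c, rz_c))))
        out[t] = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
    if np.isnan(out).all():
        raise ValueError("neural RDM series is constant; rank correlation undefined")
    return out


def _average_series(series: Sequence[RDMSeries]) -> np.ndarray:
    vals = np.stack([s.values for s in series])
    return vals.mean(axis=0)


def rsa_timecourse(
    rdms: Dict[str, Sequence[RDMSeries]],
    perceptual: ModelRDM,
    ambiguity: ModelRDM,
) -> Dict[Tuple[str, str], np.ndarray]:
    """Four neural-model correlation time series (task x model).

    ``rdms`` maps task name to that task's per-subject RDM series; the
    subject-averaged neural RDM at each time point is correlated with each
    model, partialling out the other.
    """
    if not rdms:
        raise ValueError("no tasks provided")
    pv = perceptual.vector()
    av = ambiguity.vector()
    out: Dict[Tuple[str, str], np.ndarray] = {}
    for task, series in rdms.items():
        if len(series) == 0:
            raise ValueError(f"task {task!r} has no subjects")
        avg = _average_series(series)
        out[(task, "perceptual")] = _partial_spearman_series(avg, pv, av)
        out[(task, "ambiguity")] = _partial_spearman_series(avg, av, pv)
    return out


# ---------------------------------------------------------------------------
# Bootstrap window tests
# ---------------------------------------------------------------------------

def _window_mean_partial(values: np.ndarray, model: np.ndarray, other: np.ndarray) -> float:
    """Window-mean partial correlation; NaN for a fully degenerate window."""
    try:
        return float(np.nanmean(_partial_spearman_series(values, model, other)))
    except ValueError:
        return float("nan")


def _window_mask(times: np.ndarray, window: Tuple[float, float]) -> np.ndarray:
    mask = (times >= window[0]) & (times <= window[1])
    if not mask.any():
        raise ValueError(f"window {window} contains no time samples")
    return mask


def bootstrap_window_tests(
    subject_rdms: Dict[str, Sequence[RDMSeries]],
    subject_behavior: BehaviorTable,
    windows: Sequence[Tuple[float, float]],
    n_boot: int = 5000,
    seed: int = 0,
    alpha: float = RSA_ALPHA,
    consistency_fn: Callable[[np.ndarray], np.ndarray] = consistency_index,
) -> List[RSAWindowEffects]:
    """Subject-bootstrap tests of task, model, and interaction effects per window.

    Per bootstrap sample, subjects are resampled with replacement; neural
    RDMs are re-averaged per task and both model RDMs are rebuilt from the
    resampled behavior.  Window-mean partial correlations per (task, model)
    yield three statistics:

    * task effect: mean over models of (active - passive),
    * model effect: mean over tasks of (perceptual - ambiguity),
    * interaction: difference of the model effect between tasks.

    Two-sided p-values are the fraction of bootstrap statistics crossing 0
    (doubled, capped at 1) and compared against the Bonferroni-corrected
    alpha of 0.017 for the three windows.
    """
    import warnings

    tasks = sorted(subject_rdms.keys())
    if set(tasks) != {"active", "passive"}:
        raise ValueError("subject_rdms must contain exactly the 'passive' and 'active' tasks")
    n_sub = len(subject_rdms["active"])
    if n_sub != len(subject_rdms["passive"]):
        raise ValueError("both tasks must have the same subjects")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; p-value resolution is poor", stacklevel=2)

    subjects = [s.subject_id for s in subject_rdms["active"]]
    behav_subjects = set(subject_behavior.subject_ids)
    missing = [s for s in subjects if s not in behav_subjects]
    if missing:
        raise ValueError(f"behavior missing for subjects {missing}")

    times = subject_rdms["active"][0].times
    masks = [_window_mask(times, w) for w in windows]
    vals = {
        task: np.stack([s.values for s in subject_rdms[task]]) for task in tasks
    }  # (subjects, time, 45)

    # cache per-subject prop_ba for fast model rebuilding
    prop_by_subject = np.stack([subject_behavior.prop_ba(s) for s in subjects])

    rng = np.random.default_rng(seed)
    draws = rng.integers(0, n_sub, size=(n_boot, n_sub))

    def window_stats(indices: np.ndarray) -> np.ndarray:
        """(n_windows, 2 tasks, 2 models) window-mean partial correlations."""
        prop = prop_by_subject[indices].mean(axis=0)
        pv = build_perceptual_rdm(prop).vector()
        av, _ = build_ambiguity_rdm(prop, consistency_fn)
        av = av.vector()
        out = np.empty((len(windows), 2, 2))
        for ti, task in enumerate(("active", "passive")):
            avg = vals[task][indices].mean(axis=0)
            for wi, mask in enumerate(masks):
                sub = avg[mask]
                out[wi, ti, 0] = _window_mean_partial(sub, pv, av)
                out[wi, ti, 1] = _window_mean_partial(sub, av, pv)
        return out

    observed = window_stats(np.arange(n_sub))
    boot = np.empty((n_boot, len(windows), 2, 2))
    for bi in range(n_boot):
        boot[bi] = window_stats(draws[bi])

    def effects(stats: np.ndarray) -> Dict[str, np.ndarray]:
        active, passive = stats[..., 0, :], stats[..., 1, :]
        task_eff = (active - passive).mean(axis=-1)
        model_eff = (stats[..., 0] - stats[..., 1]).mean(axis=-1)  # perceptual - ambiguity
        interaction = (active[..., 0] - active[..., 1]) - (passive[..., 0] - passive[..., 1])
        return {"task": task_eff, "model": model_eff, "interaction": interaction}

    obs_eff = effects(observed)
    boot_eff = effects(boot)

    results = []
    for wi, window in enumerate(windows):
        for name in ("task", "model", "interaction"):
            samples = boot_eff[name][:, wi]
            valid = samples[~np.isnan(samples)]
            if len(valid) < max(2, n_boot // 10):
                p = 1.0  # window too degenerate to test
            else:
                frac_le = float((valid <= 0).mean())
                frac_ge = float((valid >= 0).mean())
                p = min(1.0, 2.0 * min(frac_le, frac_ge))
                p = max(p, 1.0 / n_boot)  # resolution floor; p is never exactly 0
            results.append(
                RSAWindowEffects(
                    window_ms=(float(window[0]), float(window[1])),
                    effect=name,
                    estimate=float(obs_eff[name][wi]),
                    p_value=p,
                    n_boot=n_boot,
                    alpha=alpha,
                )
            )
    return results
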