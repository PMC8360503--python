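"""Nonparametric sign-flip permutation tests with cluster-size inference.

Group-level significance of decoding-accuracy time courses is assessed by
randomly flipping each subject's curve around the null value (chance level,
or 0 for paired contrasts) before averaging.  Contiguous time points whose
permutation p-values fall below the cluster-defining threshold form
clusters; each observed cluster's length is compared with the permutation
distribution of cluster lengths (maximum length per permutation map by
default, which guarantees familywise error control).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple
import json

import numpy as np

from .mvpa import DecodingTimecourse, RDMSeries, pair_index

__all__ = [
    "ClusterResult",
    "sign_permutation_cluster_test",
    "paired_contrast_test",
    "extract_pair_timecourse",
]


@dataclass(frozen=True)
class Cluster:
    """One temporal cluster of above-null statistics."""

    onset_ms: float
    offset_ms: float
    length_ms: float
    p_value: float
    start_index: int
    stop_index: int  # inclusive


@dataclass
class ClusterResult:
    """Clusters found by a one-sided sign-flip cluster-size permutation test."""

    clusters: List[Cluster]
    n_permutations: int
    cluster_defining_alpha: float
    cluster_alpha: float
    direction: str
    seed: Optional[int] = None
    times: Optional[np.ndarray] = None

    @property
    def significant(self) -> List[Cluster]:
        return [c for c in self.clusters if c.p_value <= self.cluster_alpha]

    def to_json(self) -> str:
        return json.dumps(
            {
                "clusters": [
                    {
                        "onset_ms": c.onset_ms,
                        "offset_ms": c.offset_ms,
                        "length_ms": c.length_ms,
                        "p_value": c.p_value,
                    }
                    for c in self.clusters
                ],
                "n_permutations": self.n_permutations,
                "cluster_defining_alpha": self.cluster_defining_alpha,
                "cluster_alpha": self.cluster_alpha,
                "direction": self.direction,
                "seed": self.seed,
            },
            indent=2,
        )


def _runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Contiguous True runs as (start, stop_inclusive) index pairs."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(int))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1) - 1
    return list(zip(starts, stops))


def _max_run_lengths(mask_rows: np.ndarray) -> np.ndarray:
    """Maximum run length of True per row of a boolean matrix."""
    n_rows, n_cols = mask_rows.shape
    out = np.zeros(n_rows, dtype=int)
    padded = np.zeros((n_rows, n_cols + 2), dtype=int)
    padded[:, 1:-1] = mask_rows
    d = np.diff(padded, axis=1)
    for r in range(n_rows):
        starts = np.flatnonzero(d[r] == 1)
        if len(starts):
            stops = np.flatnonzero(d[r] == -1)
            out[r] = (stops - starts).max()
    return out


def _all_run_lengths(mask_rows: np.ndarray) -> np.ndarray:
    """Pooled run lengths across all rows (for the pooled-cluster null)."""
    lens = []
    padded = np.zeros((mask_rows.shape[0], mask_rows.shape[1] + 2), dtype=int)
    padded[:, 1:-1] = mask_rows
    d = np.diff(padded, axis=1)
    for r in range(mask_rows.shape[0]):
        starts = np.flatnonzero(d[r] == 1)
        if len(starts):
            stops = np.flatnonzero(d[r] == -1)
            lens.extend((stops - starts).tolist())
    return np.asarray(lens, dtype=int)


def sign_permutation_cluster_test(
    subject_timecourses: np.ndarray,
    null_value: float = 50.0,
    n_perm: int = 5000,
    cluster_defining_alpha: float = 0.05,
    cluster_alpha: float = 0.05,
    direction: str = "greater",
    seed: int = 0,
    times: Optional[np.ndarray] = None,
    cluster_stat: str = "max",
    exhaustive: bool = False,
) -> ClusterResult:
    """One-sided sign-flip permutation test with cluster-size inference.

    Parameters
    ----------
    subject_timecourses : (subjects, time) array
        One accuracy (or difference) curve per subject; every time point in
        the epoch participates in the test.
    null_value : float
        Value around which subject curves are flipped (50 for decoding
        accuracy against chance, 0 for paired differences).
    direction : {"greater", "less"}
        Direction of the one-sided hypothesis; it is never inferred.
    cluster_stat : {"max", "pooled"}
        Null distribution of cluster lengths: maximum cluster length per
        permutation map (familywise-exact, default) or all cluster lengths
        pooled across maps.
    exhaustive : bool
        Enumerate all 2^S sign patterns instead of sampling (small S only);
        ``n_perm`` is then ignored.

    Per-time-point permutation p-values use (1 + #{perm >= obs}) / (1 + n_perm),
    so p can never be exactly zero.
    """
    x = np.asarray(subject_timecourses, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a (subjects >= 2, time) array of time courses")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    if cluster_stat not in ("max", "pooled"):
        raise ValueError("cluster_stat must be 'max' or 'pooled'")
    n_sub, n_time = x.shape

    centered = x - null_value
    if direction == "less":
        centered = -centered
    obs = centered.mean(axis=0)

    if exhaustive:
        if n_sub > 20:
            raise ValueError("exhaustive enumeration is limited to <= 20 subjects")
        signs = np.array(
            [[1 if (m >> s) & 1 == 0 else -1 for s in range(n_sub)] for m in range(2**n_sub)],
            dtype=float,
        )
        n_perm = signs.shape[0]
    else:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))
    perm_means = signs @ centered / n_sub  # (n_perm, time)

    # per-time-point p-values for the observed map
    exceed_obs = (perm_means >= obs[None, :]).sum(axis=0)
    p_obs = (1.0 + exceed_obs) / (1.0 + n_perm)
    obs_mask = p_obs <= cluster_defining_alpha

    # permutation maps thresholded the same way: a permutation value is
    # suprathreshold iff its tie-aware within-column count gives p <= alpha
    ge_counts = np.empty_like(perm_means, dtype=int)
    for t in range(n_time):
        col = perm_means[:, t]
        s = np.sort(col)
        ge_counts[:, t] = n_perm - np.searchsorted(s, col, side="left")
    p_perm = ge_counts / (1.0 + n_perm)
    perm_mask = p_perm <= cluster_defining_alpha

    if cluster_stat == "max":
        null_lengths = _max_run_lengths(perm_mask)
    else:
        null_lengths = _all_run_lengths(perm_mask)
        if len(null_lengths) == 0:
            null_lengths = np.zeros(1, dtype=int)

    if times is None:
        times = np.arange(n_time, dtype=float)
    times = np.asarray(times, dtype=float)
    dt = float(times[1] - times[0]) if n_time > 1 else 1.0

    clusters = []
    denom = len(null_lengths) if cluster_stat == "pooled" else n_perm
    for start, stop in _runs(obs_mask):
        length = stop - start + 1
        p = (1.0 + (null_lengths >= length).sum()) / (1.0 + denom)
        clusters.append(
            Cluster(
                onset_ms=float(times[start]),
                offset_ms=float(times[stop]),
                length_ms=length * dt,
                p_value=float(p),
                start_index=int(start),
                stop_index=int(stop),
            )
        )
    return ClusterResult(
        clusters=clusters,
        n_permutations=int(n_perm),
        cluster_defining_alpha=cluster_defining_alpha,
        cluster_alpha=cluster_alpha,
        direction=direction,
        seed=None if exhaustive else seed,
        times=times,
    )


def paired_contrast_test(
    timecourses_a: np.ndarray,
    timecourses_b: np.ndarray,
    direction: str = "greater",
    **kwargs,
) -> ClusterResult:
    """Paired contrast (a - b) tested against 0 with the sign-flip cluster test.

    Used for Active > Passive overall decoding, sensor-subset contrasts,
    and within- vs. between-category pair contrasts.  Rows of the two
    inputs must be the same subjects in the same order.
    """
    a = np.asarray(timecourses_a, dtype=float)
    b = np.asarray(timecourses_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"subject mismatch: shapes {a.shape} vs {b.shape}")
    return sign_permutation_cluster_test(a - b, null_value=0.0, direction=direction, **kwargs)


def extract_pair_timecourse(rdm: RDMSeries, pair: Tuple[int, int]) -> DecodingTimecourse:
    """Decoding-accuracy time series of one stimulus pair from an RDM series.

    The pair is order-invariant: (7, 4) returns the same series as (4, 7).
    """
    i, j = pair
    values = rdm.values[:, pair_index(i, j)]
    return DecodingTimecourse(
        times=rdm.times,
        values=values,
        subject_id=rdm.subject_id,
        task=rdm.task,
        sensor_subset=rdm.sensor_subset,
        label=f"pair_{min(i, j)}_{max(i, j)}",
    )
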