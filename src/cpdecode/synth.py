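"""Synthetic MEG-like data with planted representational geometry.

The generator emulates a categorical-perception experiment: listeners hear a
10-step acoustic continuum morphing /ba/ into /da/ while 306-channel MEG is
recorded, either passively (visual cover task) or actively (labeling each
token *ba* or *da*).  Epochs are built as evoked templates plus spatially
correlated sensor noise.  The templates carry three orthogonal spatial
components whose time courses are controlled by :class:`GeometrySpec`:

* a *stimulus-identity* component (one unique pattern per continuum step),
* a *phonemic-category* component signed by how /ba/-like a step is
  perceived (early, category-like structure),
* an *ambiguity* component scaled by labeling consistency (late structure
  separating ambiguous boundary steps from consistent endpoint steps).

The two geometry presets differ only in how long the planted signals are
maintained after onset, emulating longer information maintenance when the
continuum is task-relevant.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "N_STEPS",
    "SensorLayout",
    "TrialSchedule",
    "GeometrySpec",
    "BehaviorTable",
    "EpochSet",
    "make_sensor_layout",
    "build_trial_schedule",
    "simulate_identification",
    "simulate_epochs",
    "default_times",
]

#: number of continuum steps between the /ba/ and /da/ endpoints
N_STEPS = 10

#: analysis trials per stimulus step in both tasks
TRIALS_PER_STEP = 40

#: tokens per step presented in the passive task (3 per step are visual targets)
PASSIVE_TOKENS_PER_STEP = 43
PASSIVE_N_TARGETS = 30

# fixed seed for the shared (pre-jitter) spatial pattern basis; subjects
# share the base geometry and differ by a small random rotation of it
_BASIS_SEED = 746381


# ---------------------------------------------------------------------------
# Sensor layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SensorLayout:
    """306-channel MEG sensor map: 102 locations x (1 magnetometer + 2 gradiometers).

    Attributes
    ----------
    channel_id : array of str
        Unique channel names, e.g. ``"MEG0421"``.
    channel_type : array of str
        ``"magnetometer"`` or ``"planar_gradiometer"`` per channel.
    location_index : array of int
        Helmet location (1..102); each location hosts exactly three channels.
    hemisphere : array of str
        ``"left"``, ``"right"`` or ``"midline"`` per channel.
    """

    channel_id: np.ndarray
    channel_type: np.ndarray
    location_index: np.ndarray
    hemisphere: np.ndarray

    @property
    def n_channels(self) -> int:
        return len(self.channel_id)

    def subset_indices(self, subset: str) -> np.ndarray:
        """Channel indices of a sensor subset.

        ``"all"`` returns every channel; ``"left"``/``"right"`` return the
        144-channel hemisphere groups (midline channels are never part of a
        hemisphere subset).
        """
        if subset == "all":
            return np.arange(self.n_channels)
        if subset in ("left", "right"):
            return np.flatnonzero(self.hemisphere == subset)
        raise ValueError(f"unknown sensor subset {subset!r}; use 'all', 'left' or 'right'")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "channel_id": self.channel_id,
                "channel_type": self.channel_type,
                "location_index": self.location_index,
                "hemisphere": self.hemisphere,
            }
        )


def make_sensor_layout() -> SensorLayout:
    """Build the canonical 306-channel layout.

    102 helmet locations each host one magnetometer and two planar
    gradiometers.  48 locations lie over each hemisphere and 6 on the
    midline, giving channel counts of 144 (left), 144 (right) and 18
    (midline).  Deterministic.
    """
    hemis_by_loc = ["left"] * 48 + ["right"] * 48 + ["midline"] * 6
    ids, types, locs, hemis = [], [], [], []
    for loc in range(1, 103):
        for sub, ctype in ((1, "magnetometer"), (2, "planar_gradiometer"), (3, "planar_gradiometer")):
            ids.append(f"MEG{loc:03d}{sub}")
            types.append(ctype)
            locs.append(loc)
            hemis.append(hemis_by_loc[loc - 1])
    return SensorLayout(
        channel_id=np.array(ids),
        channel_type=np.array(types),
        location_index=np.array(locs, dtype=int),
        hemisphere=np.array(hemis),
    )


# ---------------------------------------------------------------------------
# Trial schedules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialSchedule:
    """Pseudorandom stimulus order for one task run.

    ``stimulus_step`` and ``is_target`` are aligned per presented trial.
    Passive runs contain 43 tokens per step of which 3 per step coincide
    with a visual target (discarded from neural analysis); active runs
    contain 40 tokens per step and no targets.
    """

    task: str
    stimulus_step: np.ndarray
    is_target: np.ndarray

    @property
    def n_trials(self) -> int:
        return len(self.stimulus_step)

    @property
    def analysis_mask(self) -> np.ndarray:
        return ~self.is_target


def build_trial_schedule(task: str, seed: int) -> TrialSchedule:
    """Pseudorandom trial order for ``task`` (``"passive"`` or ``"active"``).

    Reproducible from ``seed``.  Passive: 430 tokens (43 per step), 30
    flagged as visual-target trials (3 per step) so that exactly 40
    analysis trials per step remain.  Active: 400 tokens, 40 per step, no
    targets.
    """
    if task not in ("passive", "active"):
        raise ValueError(f"unknown task {task!r}; use 'passive' or 'active'")
    rng = np.random.default_rng(seed)
    if task == "passive":
        steps = np.repeat(np.arange(1, N_STEPS + 1), PASSIVE_TOKENS_PER_STEP)
        # 3 target tokens per step -> 30 targets, 400 analysis trials
        targets = np.zeros_like(steps, dtype=bool)
        targets[np.arange(len(steps)) % PASSIVE_TOKENS_PER_STEP < 3] = True
    else:
        steps = np.repeat(np.arange(1, N_STEPS + 1), TRIALS_PER_STEP)
        targets = np.zeros_like(steps, dtype=bool)
    order = rng.permutation(len(steps))
    return TrialSchedule(task=task, stimulus_step=steps[order], is_target=targets[order])


# ---------------------------------------------------------------------------
# Behavioral identification
# ---------------------------------------------------------------------------

@dataclass
class BehaviorTable:
    """Per-subject identification data for the 10-step continuum.

    ``table`` has columns ``subject_id, stimulus_step, n_trials, prop_ba``.
    ``trial_draws`` holds the underlying per-trial boolean ba/da draws,
    keyed by ``(subject_id, stimulus_step)``; they are reused to attach
    percept labels to simulated active-task epochs so that the labels and
    the identification function agree trial for trial.
    """

    table: pd.DataFrame
    trial_draws: Optional[Dict[Tuple[str, int], np.ndarray]] = None

    def prop_ba(self, subject_id: Optional[str] = None) -> np.ndarray:
        """prop_ba per continuum step, for one subject or averaged across all."""
        df = self.table
        if subject_id is not None:
            df = df[df["subject_id"] == subject_id]
            if df.empty:
                raise KeyError(f"no behavior rows for subject {subject_id!r}")
        by_step = df.groupby("stimulus_step")["prop_ba"].mean()
        missing = set(range(1, N_STEPS + 1)) - set(by_step.index)
        if missing:
            raise ValueError(f"behavior table is missing stimulus steps {sorted(missing)}")
        return by_step.reindex(range(1, N_STEPS + 1)).to_numpy()

    @property
    def subject_ids(self) -> list:
        return sorted(self.table["subject_id"].unique())

    def for_subjects(self, subject_ids) -> "BehaviorTable":
        """Restrict (with repetition allowed) to the given subjects.

        Repetition supports bootstrap resampling: the returned table stacks
        one copy of each requested subject's rows per occurrence.
        """
        parts = [self.table[self.table["subject_id"] == s] for s in subject_ids]
        return BehaviorTable(table=pd.concat(parts, ignore_index=True), trial_draws=self.trial_draws)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BehaviorTable":
        df = pd.read_csv(path)
        required = {"subject_id", "stimulus_step", "n_trials", "prop_ba"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"behavior CSV is missing columns {sorted(missing)}")
        return cls(table=df)


def logistic_identification(steps: np.ndarray, boundary: float, slope: float) -> np.ndarray:
    """P(label = ba | continuum step) under a logistic identification function.

    ``boundary`` is the step at which labeling is 50/50 and ``slope`` the
    logistic scale in continuum units; ``slope -> 0`` gives a step function.
    """
    steps = np.asarray(steps, dtype=float)
    if slope < 0:
        raise ValueError("slope must be >= 0")
    if slope == 0:
        p = np.where(steps < boundary, 1.0, 0.0)
        p[steps == boundary] = 0.5
        return p
    return 1.0 / (1.0 + np.exp((steps - boundary) / slope))


def simulate_identification(
    boundary: float = 5.5,
    slope: float = 0.5,
    n_trials: int = TRIALS_PER_STEP,
    n_subjects: int = 1,
    seed: int = 0,
) -> BehaviorTable:
    """Simulate ba/da labeling of the continuum for ``n_subjects`` listeners.

    Each trial's label is a Bernoulli draw from the logistic identification
    function; the returned table holds the empirical proportion of *ba*
    labels per subject and step, and the per-trial draws are kept for
    attaching percept labels to simulated epochs.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    steps = np.arange(1, N_STEPS + 1)
    p_ba = logistic_identification(steps, boundary, slope)
    rows = []
    draws: Dict[Tuple[str, int], np.ndarray] = {}
    for si in range(n_subjects):
        subject = f"S{si + 1:02d}"
        for step, p in zip(steps, p_ba):
            labels = rng.random(n_trials) < p
            draws[(subject, int(step))] = labels
            rows.append(
                {
                    "subject_id": subject,
                    "stimulus_step": int(step),
                    "n_trials": n_trials,
                    "prop_ba": labels.mean(),
                }
            )
    return BehaviorTable(table=pd.DataFrame(rows), trial_draws=draws)


def consistency_index(prop_ba: np.ndarray) -> np.ndarray:
    """Labeling consistency on a 0-100 scale.

    100 when a stimulus receives the same label on every trial
    (prop_ba 0 or 1), 0 when labeled *ba* on exactly half of trials;
    linear in |prop_ba - 0.5| between the anchors.
    """
    prop_ba = np.asarray(prop_ba, dtype=float)
    return 200.0 * np.abs(prop_ba - 0.5)


# ---------------------------------------------------------------------------
# Geometry specification
# ---------------------------------------------------------------------------

@dataclass
class GeometrySpec:
    """Planted representational geometry of the simulated evoked responses.

    Gains are unitless multipliers on unit-norm spatial patterns; all
    amplitude time courses are zero before stimulus onset.  ``snr`` is the
    ratio of the peak evoked-pattern norm to the per-channel noise standard
    deviation (``np.inf`` for noiseless data).

    Time courses may be supplied explicitly (arrays aligned with the epoch
    time axis) via ``category_amplitude`` / ``ambiguity_amplitude`` /
    ``identity_amplitude``; otherwise they are built from the gain and
    latency parameters: a gamma-shaped onset response peaking near
    ``peak_ms`` that is sustained until ``maintenance_offset_ms`` for the
    identity and category components, and a late ramp starting at
    ``ambiguity_onset_ms`` for the ambiguity component.
    """

    identity_gain: float = 1.0
    category_gain: float = 1.0
    ambiguity_gain: float = 2.0
    maintenance_offset_ms: float = 450.0
    snr: float = 0.15
    onset_ms: float = 60.0
    peak_ms: float = 130.0
    ambiguity_onset_ms: float = 350.0
    category_offset_ms: float = 500.0
    decay_ms: float = 120.0
    noise_condition_number: float = 100.0
    subject_jitter: float = 0.1
    identity_amplitude: Optional[np.ndarray] = field(default=None, repr=False)
    category_amplitude: Optional[np.ndarray] = field(default=None, repr=False)
    ambiguity_amplitude: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self):
        for name in ("identity_gain", "category_gain", "ambiguity_gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.snr <= 0:
            raise ValueError("snr must be positive (np.inf for noiseless)")

    def _onset_envelope(self, times: np.ndarray, offset_ms: float) -> np.ndarray:
        # gamma-shaped rise peaking at peak_ms, then sustained to offset_ms
        t = np.asarray(times, dtype=float)
        x = (t - self.onset_ms) / max(self.peak_ms - self.onset_ms, 1e-9)
        rise = np.where(x > 0, np.where(x < 1, x * np.exp(1.0 - x), 1.0), 0.0)
        return rise * self._decay_window(t, offset_ms)

    def _decay_window(self, t: np.ndarray, offset_ms: float) -> np.ndarray:
        # smooth cosine decay ending at offset_ms
        d = self.decay_ms
        m = np.ones_like(t)
        ramp = (t - (offset_ms - d)) / d
        m = np.where(ramp > 0, 0.5 * (1 + np.cos(np.pi * np.clip(ramp, 0, 1))), m)
        m[t < 0] = 0.0
        return m

    def amplitudes(self, times: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(identity, category, ambiguity) amplitude time courses on ``times`` (ms)."""
        times = np.asarray(times, dtype=float)
        if self.identity_amplitude is not None:
            ident = np.asarray(self.identity_amplitude, float)
        else:
            ident = self.identity_gain * self._onset_envelope(times, self.maintenance_offset_ms)
        if self.category_amplitude is not None:
            cat = np.asarray(self.category_amplitude, float)
        else:
            # the phonemic-category signal is transient: it decays by
            # category_offset_ms even when identity information is maintained
            cat_off = min(self.category_offset_ms, self.maintenance_offset_ms)
            cat = self.category_gain * self._onset_envelope(times, cat_off)
        if self.ambiguity_amplitude is not None:
            amb = np.asarray(self.ambiguity_amplitude, float)
        else:
            ramp = np.clip((times - self.ambiguity_onset_ms) / 100.0, 0.0, 1.0)
            amb = self.ambiguity_gain * ramp * self._decay_window(times, self.maintenance_offset_ms)
        for name, a in (("identity", ident), ("category", cat), ("ambiguity", amb)):
            if a.shape != times.shape:
                raise ValueError(f"{name} amplitude time course does not match the time axis")
            if np.any(a < 0):
                raise ValueError(f"{name} amplitude must be >= 0 everywhere")
            if np.any(a[times < 0] != 0):
                raise ValueError(f"{name} amplitude must be zero before stimulus onset")
        return ident, cat, amb

    @classmethod
    def passive_like(cls, **overrides) -> "GeometrySpec":
        """Preset emulating passive listening: signals decay by ~450 ms."""
        kw = dict(maintenance_offset_ms=450.0)
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def active_like(cls, **overrides) -> "GeometrySpec":
        """Preset emulating active labeling: signals maintained to ~900 ms."""
        kw = dict(maintenance_offset_ms=900.0)
        kw.update(overrides)
        return cls(**kw)


# ---------------------------------------------------------------------------
# Epoch container
# ---------------------------------------------------------------------------

@dataclass
class EpochSet:
    """Epoched multi-sensor trial data with stimulus/percept/task labels.

    ``data`` is trials x channels x time in normalized sensor units;
    ``times`` in milliseconds covering -200..1000 with 0 = stimulus onset.
    ``percept`` is ``"none"`` for every passive trial and ``"ba"``/``"da"``
    for every active trial.
    """

    data: np.ndarray
    times: np.ndarray
    stimulus: np.ndarray
    percept: np.ndarray
    task: str
    subject_id: str
    layout: SensorLayout

    def __post_init__(self):
        n, c, t = self.data.shape
        if c != self.layout.n_channels:
            raise ValueError(
                f"data has {c} channels but layout has {self.layout.n_channels}"
            )
        if len(self.times) != t:
            raise ValueError("times length does not match the data time axis")
        if len(self.stimulus) != n or len(self.percept) != n:
            raise ValueError("per-trial label arrays do not match the trial axis")
        if not np.any(self.times == 0):
            raise ValueError("epoch time axis must include 0 (stimulus onset)")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def sfreq(self) -> float:
        """Sampling frequency in Hz inferred from the time axis (ms)."""
        dt = np.diff(self.times)
        if not np.allclose(dt, dt[0]):
            raise ValueError("time axis is not uniformly sampled")
        return 1000.0 / dt[0]

    def copy_with(self, **updates) -> "EpochSet":
        return dataclasses.replace(self, **updates)

    def time_mask(self, tmin: float, tmax: float) -> np.ndarray:
        return (self.times >= tmin) & (self.times <= tmax)

    def save_h5(self, path) -> None:
        """Persist to an HDF5 container (float32 data + label datasets)."""
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data.astype(np.float32))
            f.create_dataset("times", data=self.times)
            f.create_dataset("stimulus", data=self.stimulus)
            f.create_dataset("percept", data=np.array(self.percept, dtype="S4"))
            f.attrs["task"] = self.task
            f.attrs["subject"] = self.subject_id
            g = f.create_group("layout")
            g.create_dataset("channel_id", data=np.array(self.layout.channel_id, dtype="S16"))
            g.create_dataset("channel_type", data=np.array(self.layout.channel_type, dtype="S20"))
            g.create_dataset("location_index", data=self.layout.location_index)
            g.create_dataset("hemisphere", data=np.array(self.layout.hemisphere, dtype="S8"))

    @classmethod
    def load_h5(cls, path) -> "EpochSet":
        with h5py.File(path, "r") as f:
            layout = SensorLayout(
                channel_id=f["layout/channel_id"][()].astype(str),
                channel_type=f["layout/channel_type"][()].astype(str),
                location_index=f["layout/location_index"][()],
                hemisphere=f["layout/hemisphere"][()].astype(str),
            )
            return cls(
                data=f["data"][()].astype(np.float64),
                times=f["times"][()],
                stimulus=f["stimulus"][()],
                percept=f["percept"][()].astype(str),
                task=f.attrs["task"],
                subject_id=f.attrs["subject"],
                layout=layout,
            )


def default_times(sfreq: float = 1000.0, tmin_ms: float = -200.0, tmax_ms: float = 1000.0) -> np.ndarray:
    """Epoch time axis in ms (inclusive of both ends; 1201 samples at 1 kHz)."""
    step = 1000.0 / sfreq
    n = int(round((tmax_ms - tmin_ms) / step)) + 1
    return tmin_ms + step * np.arange(n)


# ---------------------------------------------------------------------------
# Epoch simulation
# ---------------------------------------------------------------------------

def _pattern_basis(n_channels: int, subject_id: str, jitter: float) -> np.ndarray:
    """12 orthonormal spatial patterns: 10 identity + phoneme axis + ambiguity axis.

    The base patterns are shared across subjects; a small random rotation
    within the 12-dimensional pattern subspace individualizes each subject.
    The rotation is a pure function of the subject id, so one subject's
    spatial geometry is identical across tasks and runs.
    """
    base_rng = np.random.default_rng(_BASIS_SEED)
    basis, _ = np.linalg.qr(base_rng.standard_normal((n_channels, 12)))
    if jitter > 0:
        rng_jitter = np.random.default_rng([_BASIS_SEED, *subject_id.encode()])
        skew = rng_jitter.standard_normal((12, 12)) * jitter
        skew = skew - skew.T
        # Cayley map: orthogonal rotation close to identity for small jitter
        eye = np.eye(12)
        rot = np.linalg.solve(eye + 0.5 * skew, eye - 0.5 * skew)
        basis = basis @ rot
    return basis


def _noise_covariance_factor(
    n_channels: int, rng: np.random.Generator, condition_number: float
) -> np.ndarray:
    """Cholesky-like factor L of a random SPD spatial covariance, unit mean variance."""
    q, _ = np.linalg.qr(rng.standard_normal((n_channels, n_channels)))
    lam = np.geomspace(1.0 / np.sqrt(condition_number), np.sqrt(condition_number), n_channels)
    cov = (q * lam) @ q.T
    cov *= n_channels / np.trace(cov)
    return np.linalg.cholesky(cov)


def condition_templates(
    geometry: GeometrySpec,
    prop_ba: np.ndarray,
    times: np.ndarray,
    basis: np.ndarray,
) -> np.ndarray:
    """Noise-free evoked templates, one per continuum step: (10, channels, time)."""
    ident_a, cat_a, amb_a = geometry.amplitudes(times)
    cons = consistency_index(prop_ba) / 100.0
    u = basis[:, :N_STEPS]          # stimulus-unique patterns
    phoneme_axis = basis[:, N_STEPS]
    ambiguity_axis = basis[:, N_STEPS + 1]
    templates = (
        ident_a[None, None, :] * u.T[:, :, None]
        + cat_a[None, None, :] * phoneme_axis[None, :, None] * (prop_ba - 0.5)[:, None, None]
        + amb_a[None, None, :] * ambiguity_axis[None, :, None] * cons[:, None, None]
    )
    return templates


def simulate_epochs(
    schedule: TrialSchedule,
    behavior: BehaviorTable,
    geometry: GeometrySpec,
    layout: SensorLayout,
    seed: int,
    subject_id: Optional[str] = None,
    sfreq: float = 1000.0,
    dtype=np.float32,
) -> EpochSet:
    """Simulate one subject's epochs for one task run.

    Each analysis trial is its stimulus's evoked template plus zero-mean
    noise with a full (non-diagonal) spatial covariance; the noise standard
    deviation is set from ``geometry.snr`` relative to the peak evoked
    pattern norm.  Passive target trials are dropped (they are excluded
    from all neural analyses), so the returned set holds 40 trials per
    step.  Active percept labels are taken from the behavioral per-trial
    draws so that labels and the identification function agree.  Fully
    reproducible from ``seed``.
    """
    if subject_id is None:
        subject_id = behavior.subject_ids[0]
    rng = np.random.default_rng(seed)
    times = default_times(sfreq=sfreq)
    prop = behavior.prop_ba(subject_id)

    basis = _pattern_basis(layout.n_channels, subject_id, geometry.subject_jitter)
    templates = condition_templates(geometry, prop, times, basis)

    mask = schedule.analysis_mask
    steps = schedule.stimulus_step[mask]
    n_trials = len(steps)

    # noise scale is referenced to the evoked-response peak so that presets
    # differing only in late maintenance share the same early SNR
    peak_idx = int(np.argmin(np.abs(times - geometry.peak_ms)))
    peak_norm = float(np.linalg.norm(templates[:, :, peak_idx], axis=1).mean())
    if peak_norm == 0:
        peak_norm = float(np.linalg.norm(templates, axis=1).max())
    if not np.isfinite(geometry.snr):
        sigma = 0.0
    else:
        sigma = peak_norm / geometry.snr if peak_norm > 0 else 1.0 / geometry.snr

    data = templates[steps - 1].astype(dtype, copy=True)
    if sigma > 0:
        chol = _noise_covariance_factor(layout.n_channels, rng, geometry.noise_condition_number)
        z = rng.standard_normal((n_trials, layout.n_channels, len(times)), dtype=np.float32)
        colored = np.tensordot(chol.astype(dtype), z.astype(dtype, copy=False), axes=(1, 1))
        data += dtype(sigma) * np.moveaxis(colored, 0, 1)

    if schedule.task == "active":
        if behavior.trial_draws is None:
            raise ValueError(
                "behavior has no per-trial draws; simulate_identification must "
                "be used to label active-task epochs"
            )
        percept = np.empty(n_trials, dtype=object)
        counters = {s: 0 for s in range(1, N_STEPS + 1)}
        for i, s in enumerate(steps):
            draws = behavior.trial_draws[(subject_id, int(s))]
            if counters[s] >= len(draws):
                raise ValueError(
                    f"behavior for subject {subject_id} step {s} has fewer trials "
                    "than the schedule presents"
                )
            percept[i] = "ba" if draws[counters[s]] else "da"
            counters[s] += 1
        percept = percept.astype(str)
    else:
        percept = np.full(n_trials, "none")

    return EpochSet(
        data=data,
        times=times,
        stimulus=steps.astype(int),
        percept=percept,
        task=schedule.task,
        subject_id=subject_id,
        layout=layout,
    )
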