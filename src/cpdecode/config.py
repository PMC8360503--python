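"""Pipeline configuration: YAML-backed, validated, round-trippable.

Defaults hold the analysis constants of the full-scale study design
(5 folds, 100 decoding repetitions, 5,000 permutations, 5,000 bootstrap
samples, 80/20-ms MDS windows, alpha 0.05 / 0.017); scaled-down runs
override them explicitly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import yaml

__all__ = ["PipelineConfig", "validate_config"]


@dataclass
class PipelineConfig:
    # cohort / generator
    seed: int = 0
    n_subjects: int = 24
    tasks: List[str] = field(default_factory=lambda: ["passive", "active"])
    sfreq: float = 1000.0
    snr: float = 0.15  # generator study-condition default (see GeometrySpec)
    boundary: float = 5.5
    slope: float = 0.5
    geometry_preset: Dict[str, str] = field(
        default_factory=lambda: {"passive": "passive-like", "active": "active-like"}
    )
    # preprocessing
    baseline_window: Tuple[float, float] = (-200.0, 0.0)
    lowpass_hz: float = 15.0
    per_trial_znorm: bool = False
    # decoding
    k_folds: int = 5
    n_reps: int = 100
    svm_c: float = 1.0
    shrinkage: str | float = "auto"
    sensor_subsets: List[str] = field(default_factory=lambda: ["all"])
    decode_decim: int = 1
    # statistics
    n_perm: int = 5000
    cluster_alpha: float = 0.05
    cluster_defining_alpha: float = 0.05
    cluster_stat: str = "max"
    # rsa
    n_boot: int = 5000
    rsa_alpha: float = 0.017
    rsa_windows: Optional[List[Tuple[float, float]]] = None  # None -> from percept clusters
    # geometry
    mds_window_ms: float = 80.0
    mds_step_ms: float = 20.0
    mds_dims: int = 2
    mds_inits: int = 10
    kmeans_k: List[int] = field(default_factory=lambda: [2, 3, 4, 5])
    # io
    outdir: str = "results"

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        errors = []
        if self.seed is None:
            errors.append("seed must be set explicitly")
        if self.n_subjects < 1:
            errors.append("n_subjects must be >= 1")
        for t in self.tasks:
            if t not in ("passive", "active"):
                errors.append(f"unknown task {t!r}")
        if self.k_folds < 2:
            errors.append("k_folds must be >= 2")
        if self.k_folds > 40:
            errors.append("k_folds exceeds the 40 trials available per condition")
        if self.n_reps < 1:
            errors.append("n_reps must be >= 1")
        if self.n_perm < 1:
            errors.append("n_perm must be >= 1")
        if self.n_boot < 1:
            errors.append("n_boot must be >= 1")
        if not (0 < self.cluster_alpha < 1) or not (0 < self.cluster_defining_alpha < 1):
            errors.append("alpha levels must lie in (0, 1)")
        if not (0 < self.rsa_alpha < 1):
            errors.append("rsa_alpha must lie in (0, 1)")
        if self.lowpass_hz >= self.sfreq / 2:
            errors.append(f"lowpass_hz {self.lowpass_hz} must be below Nyquist ({self.sfreq / 2})")
        if self.mds_dims < 1:
            errors.append("mds_dims must be >= 1")
        if self.mds_inits < 1:
            errors.append("mds_inits must be >= 1")
        for k in self.kmeans_k:
            if not (2 <= k <= 9):
                errors.append(f"kmeans k={k} out of range [2, 9] for 10 stimuli")
        for s in self.sensor_subsets:
            if s not in ("all", "left", "right"):
                errors.append(f"unknown sensor subset {s!r}")
        if self.cluster_stat not in ("max", "pooled"):
            errors.append("cluster_stat must be 'max' or 'pooled'")
        if self.decode_decim < 1:
            errors.append("decode_decim must be >= 1")
        if isinstance(self.shrinkage, (int, float)) and not (0 <= self.shrinkage <= 1):
            errors.append("shrinkage must be 'auto' or in [0, 1]")
        if errors:
            raise ValueError("invalid configuration:\n  - " + "\n  - ".join(errors))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["baseline_window"] = list(d["baseline_window"])
        if d["rsa_windows"] is not None:
            d["rsa_windows"] = [list(w) for w in d["rsa_windows"]]
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        kwargs = dict(raw)
        if "baseline_window" in kwargs:
            kwargs["baseline_window"] = tuple(kwargs["baseline_window"])
        if kwargs.get("rsa_windows") is not None:
            kwargs["rsa_windows"] = [tuple(w) for w in kwargs["rsa_windows"]]
        return cls(**kwargs)


def validate_config(path) -> PipelineConfig:
    """Load and validate a YAML config; an empty file yields full defaults."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text) if text.strip() else {}
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("configuration file must contain a YAML mapping")
    return PipelineConfig.from_dict(raw)
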