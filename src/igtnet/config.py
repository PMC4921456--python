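"""Pipeline configuration: one YAML-serializable block per stage."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class SyntheticConfig:
    n_subjects: int = 9
    n_timepoints: int = 120
    tr_seconds: float = 2.0
    rest_rho_within: float = 0.60
    rest_rho_between: float = 0.10
    rest_network_rho: dict = field(default_factory=lambda: {"DMN": 0.68, "FPN": 0.55})
    task_rho_within: float = 0.45
    task_rho_between: float = 0.30
    task_network_rho: dict = field(default_factory=lambda: {"DMN": 0.50, "FPN": 0.62})
    ar1_coef: float = 0.3
    global_signal_sd: float = 0.5
    noise_sd: float = 0.2


@dataclass
class PreprocessConfig:
    n_discard: int = 10
    fd_threshold_mm: float = 0.5
    band_low_hz: float = 0.009
    band_high_hz: float = 0.08
    include_global: bool = True
    filter_before_regression: bool = True


@dataclass
class ThresholdConfig:
    S: float = 2.5
    sweep_S: list = field(default_factory=list)  # optional extra exponents


@dataclass
class HubConfig:
    fraction: float = 0.20
    n_perm: int = 512
    scheme: str = "within-subject"


@dataclass
class IGTConfig:
    n_trials: int = 60
    policy: str = "epsilon-greedy"
    epsilon: float = 0.1


@dataclass
class PipelineConfig:
    """Full run configuration; round-trips through YAML."""

    out_dir: str = "results/run"
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    threshold: ThresholdConfig = field(default_factory=ThresholdConfig)
    hubs: HubConfig = field(default_factory=HubConfig)
    igt: IGTConfig = field(default_factory=IGTConfig)
    roi_table: str | None = None  # optional path overriding the packaged table

    def validate(self) -> None:
        s = self.synthetic
        if s.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0 <= s.rest_rho_between <= min(
            s.rest_rho_within, *s.rest_network_rho.values()
        ):
            raise ValueError("rest rho_between must not exceed any rho_within")
        if not 0 <= s.task_rho_between <= min(
            s.task_rho_within, *s.task_network_rho.values()
        ):
            raise ValueError("task rho_between must not exceed any rho_within")
        if self.preprocess.band_high_hz >= 1 / (2 * s.tr_seconds):
            raise ValueError("band_high_hz must lie below Nyquist")
        if self.threshold.S <= 0:
            raise ValueError("S must be positive")
        if not 0 < self.hubs.fraction <= 1:
            raise ValueError("hub fraction must lie in (0, 1]")
        if self.hubs.scheme not in ("within-subject", "free-label"):
            raise ValueError(f"unknown permutation scheme {self.hubs.scheme!r}")
        if self.igt.policy not in ("uniform-random", "epsilon-greedy"):
            raise ValueError(f"unknown IGT policy {self.igt.policy!r}")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sections = {
            "synthetic": SyntheticConfig,
            "preprocess": PreprocessConfig,
            "threshold": ThresholdConfig,
            "hubs": HubConfig,
            "igt": IGTConfig,
        }
        kwargs = {}
        for key, val in d.items():
            if key in sections:
                known = sections[key].__dataclass_fields__
                unknown = set(val) - set(known)
                if unknown:
                    raise ValueError(f"unknown {key} options: {sorted(unknown)}")
                kwargs[key] = sections[key](**val)
            elif key in cls.__dataclass_fields__:
                kwargs[key] = val
            else:
                raise ValueError(f"unknown config key {key!r}")
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]
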