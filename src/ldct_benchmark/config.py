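"""Run configuration: schema, validation, YAML round trip, fingerprinting."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from ldct_benchmark.sim.case import DEFAULT_DOSE_FRACTIONS, SimConfig
from ldct_benchmark.sim.phantom import EXAM_TYPES, PhantomConfig


class ConfigError(ValueError):
    """Configuration failed schema validation."""


@dataclass
class RunConfig:
    """Everything a benchmark run needs, reproducible from one seed.

    Defaults mirror the benchmark protocol: reduced dose 25% for
    abdomen/head and 10% for chest, 50 SMBO iterations, 10 retrain seeds,
    alpha = 0.05, and the q-grid for the hard subsets.
    """

    seed: int = 0
    exam_types: tuple[str, ...] = ("abdomen", "head", "chest")
    scans_per_type: int = 5
    dose_fractions: dict = field(default_factory=lambda: dict(DEFAULT_DOSE_FRACTIONS))

    # simulation
    image_size: int = 256
    fov: float = 350.0
    n_angles: int = 512
    photons_per_ray: float = 1e5
    filter_name: str = "hann"
    n_slices_range: tuple[int, int] = (8, 32)

    # methods and metrics
    methods: tuple[str, ...] = ("gaussian", "bilateral", "cnn3")
    metrics: tuple[str, ...] = ("SSIM", "PSNR", "VIF")
    data_range: float = 2000.0

    # hyperparameter optimization
    hpo_n_iter: int = 50
    hpo_n_init: int = 5

    # evaluation
    retrain_seeds: int = 10
    alpha: float = 0.05
    hard_q: tuple[float, ...] = (100.0, 60.0, 40.0, 20.0)
    # explicit per-exam-type split counts (train, validation, test); None -> 70/20/10 by patient
    split_counts: tuple[int, int, int] | None = None

    output_dir: str = "runs/default"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        unknown = set(self.exam_types) - set(EXAM_TYPES)
        if unknown:
            raise ConfigError(f"unknown exam types {sorted(unknown)}")
        if self.scans_per_type < 1:
            raise ConfigError("scans_per_type must be >= 1")
        for e in self.exam_types:
            d = self.dose_fractions.get(e)
            if d is None or not (0 < d <= 1):
                raise ConfigError(f"dose fraction for {e} must lie in (0, 1]")
        if self.retrain_seeds < 1:
            raise ConfigError("retrain_seeds must be >= 1")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must lie in (0, 1)")
        if self.hpo_n_init < 2 or self.hpo_n_iter < self.hpo_n_init:
            raise ConfigError("need hpo_n_iter >= hpo_n_init >= 2")
        for q in self.hard_q:
            if not (0 < q <= 100):
                raise ConfigError("hard-subset q must lie in (0, 100]")
        if self.split_counts is not None:
            if len(self.split_counts) != 3 or any(c < 0 for c in self.split_counts):
                raise ConfigError("split_counts must be three non-negative integers")
            if sum(self.split_counts) != self.scans_per_type:
                raise ConfigError("split_counts must sum to scans_per_type")

    def sim_config(self) -> SimConfig:
        return SimConfig(
            phantom=PhantomConfig(image_size=self.image_size, fov=self.fov,
                                  n_slices_range=tuple(self.n_slices_range)),
            n_angles=self.n_angles,
            photons_per_ray=self.photons_per_ray,
            filter_name=self.filter_name,
            dose_fractions=dict(self.dose_fractions),
        )

    def fingerprint(self) -> str:
        payload = asdict(self)
        payload.pop("output_dir")  # where results land does not change what they are
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]

    @classmethod
    def desk(cls, **overrides) -> "RunConfig":
        """Small configuration that completes in minutes on one CPU."""
        defaults = dict(
            image_size=128, n_angles=192, n_slices_range=(3, 5),
            scans_per_type=4, retrain_seeds=3, hpo_n_iter=10, hpo_n_init=4,
            split_counts=(2, 1, 1),
        )
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"{path} does not contain a mapping")
        raw.pop("config_fingerprint", None)  # provenance written by to_yaml, not a field
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        for key in ("exam_types", "methods", "metrics", "hard_q", "n_slices_range", "split_counts"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        payload = asdict(self)
        payload["config_fingerprint"] = self.fingerprint()
        path.write_text(yaml.safe_dump(payload, sort_keys=True))
        return path
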