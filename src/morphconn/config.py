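"""Run configuration, seed derivation, and provenance.

A :class:`RunConfig` carries every stage parameter of an end-to-end
run. All stage seeds are derived deterministically from the single
global seed, so a run is reproducible from the YAML config alone; the
config's SHA-256 hash is stamped into every output table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import yaml

from .cohort import CohortConfig

__all__ = ["RunConfig", "derive_seed"]


def derive_seed(global_seed: int, label: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    ss = np.random.SeedSequence([int(global_seed), zlib.crc32(label.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    s_min: float = 0.10
    s_max: float = 0.34
    s_step: float = 0.01
    n_nulls: int = 100
    n_perm_group: int = 10_000
    n_perm_svm: int = 1000
    n_folds: int = 10
    svm_C: float = 1.0
    small_world: bool = True
    predict: bool = True
    out_dir: str = "morphconn_run"
    seed: int = 7

    def __post_init__(self) -> None:
        if not 0 < self.s_min < self.s_max < 1:
            raise ValueError("require 0 < s_min < s_max < 1")
        if self.s_step <= 0:
            raise ValueError("s_step must be positive")
        for name in ("n_nulls", "n_perm_group", "n_perm_svm", "n_folds"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    # -- sparsity scheme ----------------------------------------------------
    def scheme(self):
        from .topology import ThresholdScheme

        n = int(round((self.s_max - self.s_min) / self.s_step)) + 1
        s = np.round(self.s_min + self.s_step * np.arange(n), 10)
        return ThresholdScheme(s_values=tuple(float(x) for x in s))

    # -- seeds ----------------------------------------------------------------
    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.seed, stage)

    # -- (de)serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["timepoints"] = list(d["cohort"]["timepoints"])
        d["cohort"]["response_signal_regions"] = list(d["cohort"]["response_signal_regions"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        coh = dict(d.pop("cohort", {}))
        if "timepoints" in coh:
            coh["timepoints"] = tuple(coh["timepoints"])
        if "response_signal_regions" in coh:
            coh["response_signal_regions"] = tuple(coh["response_signal_regions"])
        return cls(cohort=CohortConfig(**coh), **d)

    def to_yaml(self, path: str) -> str:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return path

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @property
    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # hash the scientific configuration only
        canon = json.dumps(d, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def provenance(self) -> dict:
        import morphconn

        return {
            "config_hash": self.config_hash,
            "morphconn_version": morphconn.__version__,
            "numpy_version": np.__version__,
            "global_seed": self.seed,
        }
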