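"""Run configuration: one structured object tying the pipeline together."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .microsim_engine import InterventionPolicy

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Settings for a simulation, PSA or scenario run.

    ``horizon`` is ``None`` for the lifetime horizon or a year count (10 or
    20 in the shipped scenarios).  ``cohort_overrides`` are keyword
    overrides for :class:`~t2dsim.synthetic_population.CohortSpec`;
    ``policy_overrides`` for :class:`~t2dsim.microsim_engine.InterventionPolicy`.
    """

    seed: int = 1
    n_per_arm: int = 10_000
    n_draws: int = 1_000
    discount_rate: float = 0.03
    horizon: int | None = None
    include_productivity: bool = True
    prs_test_price: float = 50.0
    wtp_max: float = 100_000.0
    wtp_step: float = 2_500.0
    parameter_file: str | None = None
    output_dir: str = "outputs"
    cohort_overrides: dict = field(default_factory=dict)
    policy_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_per_arm <= 0 or self.n_draws <= 0:
            raise ValueError("n_per_arm and n_draws must be positive")
        if self.discount_rate < 0:
            raise ValueError("discount_rate must be non-negative")
        if self.horizon is not None and self.horizon <= 0:
            raise ValueError("horizon must be positive or None (lifetime)")
        if self.prs_test_price < 0:
            raise ValueError("prs_test_price must be non-negative")
        if self.wtp_step <= 0 or self.wtp_max < 0:
            raise ValueError("invalid WTP grid")

    def wtp_grid(self) -> np.ndarray:
        return np.arange(0.0, self.wtp_max + self.wtp_step / 2, self.wtp_step)

    def base_policy(self) -> InterventionPolicy:
        return InterventionPolicy(**self.policy_overrides)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Hash of the scientifically meaningful settings (where outputs are
        written does not affect what is computed)."""
        payload = self.to_dict()
        payload.pop("output_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
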