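"""Model parameters and experiment configuration.

All scalar constants of the cell and network equations live in
:class:`ModelParams`, a flat, serialisable registry.  The shipped defaults
were obtained by calibrating the intact model's per-segment tracing speeds on
the narrow-wide line-pair stimulus (see ``docs/methods.md``); lesion
experiments reuse them unchanged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["ModelParams", "ExperimentConfig", "default_params"]


@dataclass
class ModelParams:
    """Every scalar constant of the dynamical equations.

    Units: spatial scales (``sigma_*``, ``rho_*``) are in pixels of the map
    the kernel lives on (kernels are built at the *source* map's resolution);
    potentials and conductances are dimensionless; time constants are in
    units of one synchronous sweep and are used only by explicit-integration
    cross-checks (the simulator iterates the algebraic fixed points).
    """

    n_theta: int = 12

    # pyramidal basal compartment
    beta_b: float = 1.3  # excitatory reversal potential
    g_leak_b: float = 1.0
    # divisive-inhibition scale per area
    kappa_b: dict = field(default_factory=lambda: {"V1": 0.3, "V2": 1.0, "V4": 0.3})
    tau_b: float = 1.0

    # pyramidal apical compartment
    beta_a: float = 1.3
    g_leak_a: float = 1.3
    tau_a: float = 1.0

    # higher-order thalamic (interfacing) cells
    beta_ho: float = 1.0
    g_leak_ho: float = 1.0
    tau_ho: float = 1.0

    # feedforward gains and gating gains per cortical area
    k_ff: dict = field(default_factory=lambda: {"V1": 0.33, "V2": 1.3, "V4": 3.0})
    lam: dict = field(default_factory=lambda: {"V1": 160.0, "V2": 100.0, "V4": 0.0})

    # thalamic evidence-accumulation gains per source
    k_ho: dict = field(
        default_factory=lambda: {"V1": 9.2, "V2": 8.0, "V4": 1.0, "S": 6.0}
    )

    # suppressive-feedback scale per channel (applied to the negative Gabor
    # pathway); the uniform feature kernel averages over all orientation
    # channels, so effective magnitudes are large
    xi: dict = field(default_factory=lambda: {"V2->V1": -8.0, "V4->V2": -40.0})

    # kernel scales, at the source map's resolution
    sigma_ff: dict = field(
        default_factory=lambda: {"Inp->V1": 1.0, "V1->V2": 1.0, "V2->V4": 1.0}
    )
    sigma_inh: dict = field(default_factory=lambda: {"V1": 1.5, "V2": 1.5, "V4": 1.5})
    sigma_fb: dict = field(default_factory=lambda: {"V2->V1": 1.2, "V4->V2": 1.3})
    rho_b1: dict = field(default_factory=lambda: {"V1": 5, "V2": 11, "V4": 5})
    rho_b2: dict = field(default_factory=lambda: {"V1": 7, "V2": 7, "V4": 3})

    # task-module seed injected into the interfacing module
    seed_amplitude: float = 1.0
    seed_footprint: int = 2  # square side length, HO pixels

    def validate(self) -> None:
        for name in ("beta_b", "beta_a", "beta_ho"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("g_leak_b", "g_leak_a", "g_leak_ho"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(v > 0 for v in self.xi.values()):
            raise ValueError("xi scales the suppressive feedback pathway and must be <= 0")
        for d in (self.k_ff, self.lam, self.k_ho):
            for v in d.values():
                if v < 0:
                    raise ValueError("gains must be non-negative")
        if self.n_theta < 2:
            raise ValueError("n_theta must be >= 2")

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        merged = cls()
        for key, value in d.items():
            if not hasattr(merged, key):
                raise KeyError(f"unknown parameter {key!r}")
            current = getattr(merged, key)
            if isinstance(current, dict):
                current = dict(current)
                current.update(value)
                setattr(merged, key, current)
            else:
                setattr(merged, key, value)
        merged.validate()
        return merged

    def override(self, overrides: dict) -> "ModelParams":
        """Return a copy with (possibly nested) overrides applied."""
        d = self.to_dict()
        for key, value in overrides.items():
            if isinstance(value, dict) and isinstance(d.get(key), dict):
                d[key].update(value)
            else:
                d[key] = value
        return ModelParams.from_dict(d)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def default_params() -> ModelParams:
    """The shipped (calibrated) parameter registry."""
    return ModelParams()


@dataclass
class ExperimentConfig:
    """A fully serialisable description of one simulation run."""

    stimulus: dict = field(default_factory=dict)  # generator name + kwargs
    seed_id: str | None = None  # which annotated seed to use
    params: dict = field(default_factory=dict)  # ModelParams overrides
    lesions: list = field(default_factory=list)  # ["FB:V4:V2", ...]
    n_steps: int = 600
    record_every: int = 50
    probe_spacing: int = 10
    baseline_step: int | None = None
    rng_seed: int = 0
    output_dir: str = "runs"

    def resolved_params(self) -> ModelParams:
        return default_params().override(self.params)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]
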