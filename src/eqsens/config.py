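"""Run configuration: tolerances, Newton settings, method pair, seeds, output.

A RunConfig wraps the numerical EquilibrationConfig together with the
workflow-level choices (method pair, sample count, seed, output directory).
YAML keys mirror the dataclass fields; the WRMS tolerances are exposed as
``rtol_ss``/``atol_ss`` and the integrator tolerances as ``rtol``/``atol``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError
from .objective import PAIR_NAMES
from .steady_state import EquilibrationConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    equilibration: EquilibrationConfig = field(default_factory=EquilibrationConfig)
    method_pair: str = "int_lin_fsa"
    seed: int = 1
    n_samples: int = 100
    output_dir: str = "results"
    log_level: str = "INFO"

    def __post_init__(self):
        if self.method_pair not in PAIR_NAMES:
            raise ValidationError(
                f"unknown method pair {self.method_pair!r}; "
                f"choose from {sorted(PAIR_NAMES)}"
            )
        if self.equilibration.fd_step <= 0:
            raise ValidationError("fd_step must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        eq_kwargs = {}
        mapping = {
            "rtol": "int_rtol",
            "atol": "int_atol",
            "rtol_ss": "rtol",
            "atol_ss": "atol",
        }
        for key, attr in mapping.items():
            if key in doc:
                eq_kwargs[attr] = float(doc.pop(key))
        for key in (
            "max_time",
            "max_steps",
            "newton_max_iters",
            "gamma_init",
            "gamma_min",
            "gamma_up",
            "gamma_down",
            "neg_tol",
            "fd_step",
            "cond_limit",
        ):
            if key in doc:
                eq_kwargs[key] = doc.pop(key)
        top = {
            k: doc[k]
            for k in ("method_pair", "seed", "n_samples", "output_dir", "log_level")
            if k in doc
        }
        return cls(equilibration=EquilibrationConfig(**eq_kwargs), **top)
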