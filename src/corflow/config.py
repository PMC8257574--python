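"""Run configuration: a single JSON document driving the whole pipeline."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

from .geometry import ValidationError

__all__ = ["RunConfig", "load_config", "config_hash"]


@dataclasses.dataclass
class RunConfig:
    """Paths, method selection and solver knobs for one pipeline run.

    Exactly one of two input modes applies: a ``phantom_seed`` (the case is
    generated), or explicit ``mask_path``/``trees_path``/``patient_path``
    (``lesions_path`` optional). Keys mirror the CLI flags.
    """

    out_dir: str = "corflow-out"
    phantom_seed: int | None = None
    mask_path: str | None = None
    trees_path: str | None = None
    lesions_path: str | None = None
    patient_path: str | None = None
    method: str = "territory"
    scaling_a: float = 0.64
    scaling_b: float = 0.75
    viscosity_pa_s: float = 0.003
    density_kg_m3: float = 1060.0
    step_mm: float = 0.25
    territory_step_mm: float = 0.5
    expansion_k: float = 1.0
    hyperemia_multiplier: float = 1.0
    cutoff: float = 0.80

    def validate_paths(self) -> None:
        if self.phantom_seed is not None:
            return
        required = {"mask_path": self.mask_path, "trees_path": self.trees_path,
                    "patient_path": self.patient_path}
        missing = [k for k, v in required.items() if not v]
        if missing:
            raise ValidationError(f"config missing required paths: {missing}")
        for k, v in {**required, "lesions_path": self.lesions_path}.items():
            if v and not Path(v).exists():
                raise ValidationError(f"config path {k} does not exist: {v}")

    def solver_settings(self):
        from . import flow, hemo
        from .pipeline import SolverSettings

        return SolverSettings(
            scaling=flow.ScalingParams(a=self.scaling_a, b=self.scaling_b),
            fluid=hemo.FluidProperties(
                viscosity_pa_s=self.viscosity_pa_s, density_kg_m3=self.density_kg_m3
            ),
            step_mm=self.step_mm,
            territory_step_mm=self.territory_step_mm,
            expansion_k=self.expansion_k,
            hyperemia_multiplier=self.hyperemia_multiplier,
            cutoff=self.cutoff,
        )


def load_config(path) -> RunConfig:
    doc = json.loads(Path(path).read_text())
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(doc) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**doc)


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the canonicalized configuration, for provenance."""
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
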