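"""Pipeline configuration: flat YAML with one include level.

Unknown keys are rejected with a warning listing them; no environment
variable interpolation, so a (config, seed) pair regenerates every
artifact bit-identically.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .design import MeasurementModel, PKParameters, StudyDesign, default_pk_map

__all__ = ["PipelineConfig", "load_config"]

_KNOWN_KEYS = {
    "include", "seed", "output_dir", "design", "measurement", "pk_presets", "qsar",
}
_DESIGN_KEYS = {
    "dose_levels", "dosing_interval", "n_doses", "group_sizes",
    "plasma_times_day7", "collection_days", "hair_harvest_day", "gavage_volume",
    "body_mass_kg", "urine_volume_ml", "faeces_mass_g",
}


@dataclass
class PipelineConfig:
    design: StudyDesign = field(default_factory=StudyDesign)
    measurement: MeasurementModel = field(default_factory=MeasurementModel)
    pk_presets: dict[str, PKParameters] = field(default_factory=default_pk_map)
    qsar: dict = field(default_factory=dict)
    seed: int = 0
    output_dir: Path = Path("out")

    def config_hash(self) -> str:
        payload = repr(
            (self.design, self.measurement, sorted(self.pk_presets.items()),
             sorted(self.qsar.items()), self.seed)
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _warn_unknown(mapping: dict, known: set, context: str) -> None:
    unknown = sorted(set(mapping) - known)
    if unknown:
        warnings.warn(
            f"ignoring unknown {context} key(s): {', '.join(unknown)}",
            stacklevel=3,
        )


def load_config(path: str | Path | None = None, seed: int | None = None) -> PipelineConfig:
    """Load a YAML config (optional), following at most one include level."""
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "include" in data:
            base = yaml.safe_load(
                (Path(path).parent / data["include"]).read_text()
            ) or {}
            if "include" in base:
                raise ValueError("only one include level is supported")
            base.update({k: v for k, v in data.items() if k != "include"})
            data = base
    _warn_unknown(data, _KNOWN_KEYS, "config")

    design_kwargs = dict(data.get("design") or {})
    _warn_unknown(design_kwargs, _DESIGN_KEYS, "design")
    design_kwargs = {k: v for k, v in design_kwargs.items() if k in _DESIGN_KEYS}
    for key in ("dose_levels", "plasma_times_day7"):
        if key in design_kwargs:
            design_kwargs[key] = tuple(design_kwargs[key])
    if "collection_days" in design_kwargs:
        design_kwargs["collection_days"] = {
            m: tuple(v) for m, v in design_kwargs["collection_days"].items()
        }
    design = StudyDesign(**design_kwargs)

    meas = MeasurementModel(**(data.get("measurement") or {}))
    pk_map = default_pk_map()
    for name, kwargs in (data.get("pk_presets") or {}).items():
        pk_map[name] = PKParameters(**kwargs)

    cfg = PipelineConfig(
        design=design,
        measurement=meas,
        pk_presets=pk_map,
        qsar=dict(data.get("qsar") or {}),
        seed=int(data.get("seed", 0)),
        output_dir=Path(data.get("output_dir", "out")),
    )
    if seed is not None:
        cfg = replace(cfg, seed=int(seed))
    return cfg
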