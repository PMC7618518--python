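"""YAML pipeline configuration with strict key validation.

A config file has up to five sections -- ``seed``, ``field`` (cluster
field generator, or ``preset: HL60|OCIAML3`` plus overrides), ``smlm``
(localization chain), ``counts`` (spectral-count generator), ``cluster``
(Ripley-seeded DBSCAN parameters) -- every key checked against the
corresponding parameter set so typos fail loudly.  The resolved config is
written next to the outputs of every run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import yaml

from .cluster import RipleySeededDBSCAN
from .localization import SMLMConfig
from .simulate import PRESETS, ClusterFieldSpec, CountTableSpec


def _build_dataclass(cls, data: dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown key(s) in {where}: {sorted(unknown)}")
    coerced = {}
    for k, v in data.items():
        coerced[k] = tuple(tuple(x) if isinstance(x, list) else x
                           for x in v) if isinstance(v, list) else v
    return cls(**coerced)


def _build_field_spec(data: dict) -> ClusterFieldSpec:
    data = dict(data)
    preset = data.pop("preset", None)
    if preset is not None:
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}; choose from "
                             f"{sorted(PRESETS)}")
        base = dataclasses.asdict(PRESETS[preset])
        base.update(data)
        data = base
    return _build_dataclass(ClusterFieldSpec, data, "field")


def _check_cluster_params(data: dict) -> dict:
    valid = set(RipleySeededDBSCAN().get_params())
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown key(s) in cluster: {sorted(unknown)}")
    return {k: (tuple(v) if isinstance(v, list) else v)
            for k, v in data.items()}


@dataclass
class PipelineConfig:
    seed: int = 0
    field: ClusterFieldSpec = dc_field(default_factory=ClusterFieldSpec)
    smlm: SMLMConfig = dc_field(default_factory=SMLMConfig)
    counts: CountTableSpec = dc_field(default_factory=CountTableSpec)
    cluster: dict = dc_field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {"seed", "field", "smlm", "counts", "cluster"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown top-level key(s): {sorted(unknown)}")
        return cls(
            seed=int(data.get("seed", 0)),
            field=_build_field_spec(data.get("field", {}) or {}),
            smlm=_build_dataclass(SMLMConfig, data.get("smlm", {}) or {},
                                  "smlm"),
            counts=_build_dataclass(CountTableSpec,
                                    data.get("counts", {}) or {}, "counts"),
            cluster=_check_cluster_params(data.get("cluster", {}) or {}),
        )

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config {path} is not a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "field": dataclasses.asdict(self.field),
            "smlm": dataclasses.asdict(self.smlm),
            "counts": dataclasses.asdict(self.counts),
            "cluster": dict(self.cluster),
        }

    def dump(self, path) -> None:
        """Write the fully resolved configuration for provenance."""
        Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                             sort_keys=True))


__all__ = ["PipelineConfig"]
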