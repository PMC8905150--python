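"""Configuration loading, seed bookkeeping and run manifests.

Configurations are plain YAML/JSON mappings whose keys mirror
:class:`~antsync.model.ModelParams` (distribution fields are nested mappings
with a ``kind`` key), or reference a species preset by name.  Unknown keys
are rejected so typos fail loudly.  A :class:`RunManifest` snapshots
everything needed to regenerate a campaign's outputs bit-identically:
configuration, seeds, package version and the output file registry.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List

import yaml

from .distributions import DistributionSpec
from .experiments import get_preset
from .fixtures import FixtureSpec
from .model import ModelParams

__all__ = ["load_config", "RunManifest", "replicate_seeds"]

logger = logging.getLogger("antsync")

_DIST_KEYS = {"kind", "mean", "lo", "hi", "value", "halfwidth"}
_MODEL_KEYS = {f.name for f in dataclasses.fields(ModelParams)}
_FIXTURE_KEYS = {f.name for f in dataclasses.fields(FixtureSpec)}


def replicate_seeds(base_seed: int, n: int, condition_index: int = 0) -> List[int]:
    """Deterministic per-replicate substreams: ``base_seed + cond*n + i``."""
    return [int(base_seed) + condition_index * n + i for i in range(n)]


def _parse_distribution(obj, where: str) -> DistributionSpec:
    if isinstance(obj, DistributionSpec):
        return obj
    if not isinstance(obj, dict) or "kind" not in obj:
        raise ValueError(f"{where}: expected a mapping with a 'kind' key")
    unknown = set(obj) - _DIST_KEYS
    if unknown:
        raise ValueError(f"{where}: unknown distribution keys {sorted(unknown)}")
    return DistributionSpec(**obj)


def _load_mapping(path_or_mapping) -> dict:
    if isinstance(path_or_mapping, dict):
        return dict(path_or_mapping)
    text = Path(path_or_mapping).read_text()
    data = yaml.safe_load(text)  # YAML is a superset of JSON
    if not isinstance(data, dict):
        raise ValueError(f"configuration in {path_or_mapping} is not a mapping")
    return data


def load_config(path_or_mapping):
    """Parse a model, fixture or preset configuration.

    A mapping with a ``preset`` key yields the named species preset (with
    optional ``seed``/``n_steps``/... overrides); a ``kind`` key yields a
    :class:`FixtureSpec`; otherwise the keys must mirror
    :class:`ModelParams`.  A missing seed defaults to 0 with a warning.
    """
    data = _load_mapping(path_or_mapping)

    if "preset" in data:
        name = data.pop("preset")
        params = get_preset(name)
        unknown = set(data) - _MODEL_KEYS
        if unknown:
            raise ValueError(f"unknown configuration keys {sorted(unknown)}")
        if "seed" not in data:
            warnings.warn("no seed given; defaulting to seed=0")
            data["seed"] = 0
        for k in ("refractory_spec", "spontaneous_spec"):
            if k in data:
                data[k] = _parse_distribution(data[k], k)
        return dataclasses.replace(params, **data)

    if "kind" in data:
        unknown = set(data) - _FIXTURE_KEYS
        if unknown:
            raise ValueError(f"unknown fixture keys {sorted(unknown)}")
        if "seed" not in data:
            warnings.warn("no seed given; defaulting to seed=0")
        spec = FixtureSpec(**data)
        if spec.components:
            spec.components = [tuple(c) for c in spec.components]
        return spec

    unknown = set(data) - _MODEL_KEYS
    if unknown:
        raise ValueError(f"unknown configuration keys {sorted(unknown)}")
    for k in ("refractory_spec", "spontaneous_spec"):
        if k not in data:
            raise ValueError(f"model configuration missing required key {k!r}")
        data[k] = _parse_distribution(data[k], k)
    if "active_duration" not in data:
        raise ValueError("model configuration missing required key 'active_duration'")
    if "seed" not in data:
        warnings.warn("no seed given; defaulting to seed=0")
        data["seed"] = 0
    return ModelParams(**data)


@dataclass
class RunManifest:
    """Snapshot sufficient to regenerate every output of a run."""

    config: dict
    seeds: List[int]
    version: str = ""
    created: str = field(default_factory=lambda: datetime.datetime.now().isoformat(timespec="seconds"))
    outputs: Dict[str, str] = field(default_factory=dict)

    def register(self, name: str, path) -> None:
        self.outputs[name] = str(path)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
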