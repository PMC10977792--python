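"""Parameter-set configuration files and the shipped table fixtures.

Network parameter sets are YAML (JSON is a YAML subset and is accepted)
with gene names as keys; three fixtures ship with the package: versions I
(initial guess), II (automatized grid screen) and III (semi-manual tuning).
Loading returns a beta-calibrated :class:`~gcgrn.network.NetworkModel`.
"""

from __future__ import annotations

from importlib import resources
from os import PathLike
from typing import Any, Mapping

import yaml

from .network import (
    DEFAULT_FLOOR_FRACTION,
    DEFAULT_KOFF_MIN,
    GENES,
    GeneParameters,
    InteractionParams,
    NetworkModel,
)

VERSIONS = ("I", "II", "III")

#: optional per-gene keys accepted in configs on top of the required ones
_OPTIONAL_GENE_KEYS = ("kon_min", "kon_max", "koff_min", "koff_max")
_REQUIRED_GENE_KEYS = ("s0", "d0", "s1", "d1", "kon_init", "koff_init")


class ConfigError(ValueError):
    """Raised on malformed or incomplete parameter configuration."""


def _model_from_mapping(cfg: Mapping[str, Any], source: str) -> NetworkModel:
    try:
        gene_cfg = cfg["genes"]
        theta_cfg = cfg["theta"]
        h_cfg = cfg["H"]
    except KeyError as exc:
        raise ConfigError(f"{source}: missing top-level section {exc}") from exc
    genes = []
    for gid in GENES:
        if gid not in gene_cfg:
            raise ConfigError(f"{source}: missing gene {gid!r}")
        entry = dict(gene_cfg[gid])
        missing = [k for k in _REQUIRED_GENE_KEYS if k not in entry]
        if missing:
            raise ConfigError(f"{source}: gene {gid!r} missing key(s) {missing}")
        unknown = set(entry) - set(_REQUIRED_GENE_KEYS) - set(_OPTIONAL_GENE_KEYS)
        if unknown:
            raise ConfigError(f"{source}: gene {gid!r} has unknown key(s) {sorted(unknown)}")
        # default basal-floor policy unless the config pins the bounds itself
        entry.setdefault("kon_min", DEFAULT_FLOOR_FRACTION * float(entry["kon_init"]))
        entry.setdefault("koff_min", DEFAULT_KOFF_MIN)
        genes.append(GeneParameters(gene_id=gid, **{k: float(v) for k, v in entry.items()}))

    def parse_pairs(section: Mapping[str, Any], label: str) -> dict:
        out = {}
        for key, value in section.items():
            parts = str(key).split(".")
            if len(parts) != 2:
                raise ConfigError(f"{source}: {label} key {key!r} must be '<regulator>.<target>'")
            out[(parts[0], parts[1])] = float(value)
        return out

    interactions = InteractionParams(
        theta=parse_pairs(theta_cfg, "theta"),
        H=parse_pairs(h_cfg, "H"),
        gamma=float(cfg.get("gamma", 2.0)),
    )
    return NetworkModel(genes=tuple(genes), interactions=interactions)


def load_network_config(path: str | PathLike) -> NetworkModel:
    """Load a beta-calibrated network model from a YAML/JSON config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise ConfigError(f"{path}: config must be a mapping")
    return _model_from_mapping(cfg, str(path)).calibrate()


def load_parameter_version(tag: str, calibrate: bool = True) -> NetworkModel:
    """Load one of the shipped parameter-table fixtures ('I', 'II', 'III').

    Returns the fully populated model, beta-calibrated unless
    ``calibrate=False``.  Unknown tags are rejected.
    """
    if tag not in VERSIONS:
        raise ValueError(f"unknown parameter version {tag!r}; expected one of {VERSIONS}")
    ref = resources.files("gcgrn.parameters") / f"version_{tag}.yaml"
    cfg = yaml.safe_load(ref.read_text())
    model = _model_from_mapping(cfg, f"version_{tag}.yaml")
    if cfg.get("version") != tag:
        raise ConfigError(f"fixture integrity failure: version_{tag}.yaml declares {cfg.get('version')!r}")
    return model.calibrate() if calibrate else model
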