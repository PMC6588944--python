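"""Run configuration: YAML schema, validation and defaults.

A run is driven either by a *manifest* of existing clonotype TSVs (one entry
per sample: path, individual, time point, compartment) or by a ``simulate``
block of synthetic-generator parameters — never both.  Module parameter
blocks carry the analysis defaults: top-abundance fraction 0.01, similarity
cutoff 1 edit, correlation threshold 0.95, and permutation counts of 10,000
(connectivity, publicness) and 1000 (cohorts).
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field, fields
from typing import Any, Optional

import yaml

from .synthetic import SimConfig
from .types import Compartment


class ConfigError(ValueError):
    """Schema violation in a run configuration."""


@dataclass
class ManifestEntry:
    path: str
    individual: str
    time_point: int
    compartment: Compartment


@dataclass
class StatsParams:
    top_fraction: float = 0.01
    rarefaction_reps: int = 10


@dataclass
class NetworkParams:
    d_max: int = 1
    same_vj: bool = False
    n_perm: int = 10_000


@dataclass
class CohortParams:
    fraction: float = 0.01
    min_times: int = 2
    threshold: float = 0.95
    inclusive: bool = False
    n_perm: int = 1000
    methods: tuple[str, ...] = ("spearman", "pearson")


@dataclass
class PublicParams:
    high_threshold: float = 0.70
    most_public_threshold: float = 0.90
    n_perm: int = 10_000


@dataclass
class RunConfig:
    seed: int
    outdir: str
    simulate: Optional[SimConfig] = None
    manifest: list[ManifestEntry] = field(default_factory=list)
    sharing_table: Optional[str] = None
    stats: StatsParams = field(default_factory=StatsParams)
    network: NetworkParams = field(default_factory=NetworkParams)
    cohort: CohortParams = field(default_factory=CohortParams)
    public: PublicParams = field(default_factory=PublicParams)
    high_abundance_parallel: bool = False


_SCALAR_CASTS = {int: int, float: float, bool: bool, str: str}


def _build_block(cls, raw: dict, block: str):
    """Instantiate a params dataclass, rejecting unknown keys, casting types."""
    if not isinstance(raw, dict):
        raise ConfigError(f"block {block!r} must be a mapping")
    known = {f.name: f for f in fields(cls)}
    kwargs: dict[str, Any] = {}
    for key, value in raw.items():
        if key not in known:
            raise ConfigError(f"unknown key {block}.{key!r}")
        ftype = known[key].type
        try:
            if ftype in ("int", int):
                if isinstance(value, bool) or int(value) != value:
                    raise ValueError
                value = int(value)
            elif ftype in ("float", float):
                value = float(value)
            elif ftype in ("bool", bool):
                if not isinstance(value, bool):
                    raise ValueError
            elif "tuple" in str(ftype):
                value = tuple(value)
        except (TypeError, ValueError):
            raise ConfigError(
                f"key {block}.{key!r}: expected {ftype}, got {value!r}"
            ) from None
        kwargs[key] = value
    return cls(**kwargs)


TOP_LEVEL_KEYS = {
    "seed", "outdir", "simulate", "manifest", "sharing_table",
    "stats", "network", "cohort", "public", "high_abundance_parallel",
}


def validate_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys are rejected with the offending key named; every manifest
    path must exist at validation time; ``simulate`` and ``manifest`` are
    mutually exclusive and one is required.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a YAML mapping")
    for key in raw:
        if key not in TOP_LEVEL_KEYS:
            raise ConfigError(f"unknown key {key!r}")
    if "seed" not in raw:
        raise ConfigError("missing required key 'seed' (expected int)")
    if not isinstance(raw["seed"], int) or isinstance(raw["seed"], bool):
        raise ConfigError(f"key 'seed': expected int, got {raw['seed']!r}")
    if "outdir" not in raw or not isinstance(raw["outdir"], str):
        raise ConfigError("missing or invalid key 'outdir' (expected str)")

    has_sim = "simulate" in raw and raw["simulate"] is not None
    has_manifest = bool(raw.get("manifest"))
    if has_sim == has_manifest:
        raise ConfigError("exactly one of 'simulate' and 'manifest' is required")

    sim = None
    manifest: list[ManifestEntry] = []
    if has_sim:
        sim_raw = dict(raw["simulate"])
        sim_raw.setdefault("seed", raw["seed"])
        known = {f.name for f in fields(SimConfig)}
        for key in sim_raw:
            if key not in known:
                raise ConfigError(f"unknown key simulate.{key!r}")
        if "time_points" in sim_raw:
            sim_raw["time_points"] = tuple(sim_raw["time_points"])
        if "sorted_time_points" in sim_raw:
            sim_raw["sorted_time_points"] = tuple(sim_raw["sorted_time_points"])
        sim = SimConfig(**sim_raw)
    else:
        base = os.path.dirname(os.path.abspath(path))
        for i, entry in enumerate(raw["manifest"]):
            if not isinstance(entry, dict):
                raise ConfigError(f"manifest[{i}] must be a mapping")
            extra = set(entry) - {"path", "individual", "time_point", "compartment"}
            if extra:
                raise ConfigError(f"unknown key manifest[{i}].{extra.pop()!r}")
            try:
                p = str(entry["path"])
                if not os.path.isabs(p):
                    p = os.path.join(base, p)
                me = ManifestEntry(
                    path=p,
                    individual=str(entry["individual"]),
                    time_point=int(entry["time_point"]),
                    compartment=Compartment(entry["compartment"]),
                )
            except KeyError as e:
                raise ConfigError(f"manifest[{i}] missing key {e.args[0]!r}") from None
            except ValueError as e:
                raise ConfigError(f"manifest[{i}]: {e}") from None
            if not os.path.exists(me.path):
                raise ConfigError(f"manifest[{i}]: file not found: {me.path}")
            manifest.append(me)

    sharing = raw.get("sharing_table")
    if sharing is not None:
        if not os.path.isabs(sharing):
            sharing = os.path.join(os.path.dirname(os.path.abspath(path)), sharing)
        if not os.path.exists(sharing):
            raise ConfigError(f"sharing_table file not found: {sharing}")

    hap = raw.get("high_abundance_parallel", False)
    if not isinstance(hap, bool):
        raise ConfigError("key 'high_abundance_parallel': expected bool")

    return RunConfig(
        seed=raw["seed"],
        outdir=raw["outdir"],
        simulate=sim,
        manifest=manifest,
        sharing_table=sharing,
        stats=_build_block(StatsParams, raw.get("stats", {}), "stats"),
        network=_build_block(NetworkParams, raw.get("network", {}), "network"),
        cohort=_build_block(CohortParams, raw.get("cohort", {}), "cohort"),
        public=_build_block(PublicParams, raw.get("public", {}), "public"),
        high_abundance_parallel=hap,
    )
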