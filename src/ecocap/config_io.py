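"""Structured-text serialization: food-web configs, forcings, run outputs.

Configs are YAML documents with an explicit schema tag; reading is
strict (unknown keys are rejected with their location) and
``write_config`` then ``read_config`` is an exact round trip. Forcing
series are two-column day-of-year/temperature tables with header
metadata. Run results and equilibrium summaries export as tidy
tab-separated tables, accompanied by a run manifest whose config digest
is stable under semantically identical configurations.
"""

from __future__ import annotations

import dataclasses
import hashlib
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, ForcingDataError
from .foodweb import DietMatrix, FoodWebConfig, GroupSpec
from .forcing import DAYS_PER_YEAR, ForcingSeries
from .simulator import EquilibriumSummary, RunResult

__all__ = [
    "CONFIG_SCHEMA",
    "read_config",
    "write_config",
    "config_digest",
    "read_forcing",
    "write_forcing",
    "save_run",
    "save_summary",
    "load_summary",
    "run_manifest",
]

CONFIG_SCHEMA = "ecocap-foodweb/1"

_GROUP_FIELDS = {f.name: f for f in dataclasses.fields(GroupSpec)}


def _group_to_dict(g: GroupSpec) -> dict:
    d = {}
    for name in _GROUP_FIELDS:
        val = getattr(g, name)
        if isinstance(val, tuple):
            val = [float(x) for x in val]
        d[name] = val
    return d


def _group_from_dict(d: dict, where: str) -> GroupSpec:
    if not isinstance(d, dict):
        raise ConfigurationError(f"{where}: expected a mapping")
    unknown = set(d) - set(_GROUP_FIELDS)
    if unknown:
        raise ConfigurationError(f"{where}: unknown keys {sorted(unknown)}")
    if "id" not in d:
        raise ConfigurationError(f"{where}: missing required key 'id'")
    kwargs = dict(d)
    for key in ("W_ref", "spawn_window", "niche"):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = tuple(float(x) for x in kwargs[key])
    return GroupSpec(**kwargs)


def write_config(config: FoodWebConfig, path) -> None:
    doc = {
        "schema": CONFIG_SCHEMA,
        "groups": [_group_to_dict(g) for g in config.groups],
        "diet": {
            "half_saturation": {k: float(v)
                                for k, v in sorted(config.diet.half_saturation.items())},
            "availability": [
                {"pred": pred, "prey": prey,
                 "value": (float(val) if np.ndim(val) == 0
                           else [float(x) for x in val])}
                for (pred, prey), val in sorted(config.diet.availability.items())
            ],
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False, width=100))


def read_config(path) -> FoodWebConfig:
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ConfigurationError(f"{path}: not a mapping document")
    unknown = set(doc) - {"schema", "groups", "diet"}
    if unknown:
        raise ConfigurationError(f"{path}: unknown top-level keys {sorted(unknown)}")
    if doc.get("schema") != CONFIG_SCHEMA:
        raise ConfigurationError(
            f"{path}: schema is {doc.get('schema')!r}, expected {CONFIG_SCHEMA!r}")
    groups = [_group_from_dict(g, f"{path}: groups[{i}]")
              for i, g in enumerate(doc.get("groups", []))]
    diet_doc = doc.get("diet", {}) or {}
    unknown = set(diet_doc) - {"half_saturation", "availability"}
    if unknown:
        raise ConfigurationError(f"{path}: unknown diet keys {sorted(unknown)}")
    availability = {}
    for i, row in enumerate(diet_doc.get("availability", []) or []):
        extra = set(row) - {"pred", "prey", "value"}
        if extra:
            raise ConfigurationError(
                f"{path}: diet.availability[{i}]: unknown keys {sorted(extra)}")
        val = row["value"]
        availability[(row["pred"], row["prey"])] = (
            float(val) if np.ndim(val) == 0 else tuple(float(x) for x in val))
    diet = DietMatrix(availability=availability,
                      half_saturation={k: float(v) for k, v in
                                       (diet_doc.get("half_saturation") or {}).items()})
    return FoodWebConfig(groups=groups, diet=diet)


def config_digest(config: FoodWebConfig) -> str:
    """SHA-256 of a canonical (sorted-keys) dump; stable under
    semantically identical configs."""
    doc = {
        "groups": [_group_to_dict(g) for g in config.groups],
        "half_saturation": {k: float(v)
                            for k, v in sorted(config.diet.half_saturation.items())},
        "availability": {f"{p}->{q}": [float(x) for x in np.atleast_1d(v)]
                         for (p, q), v in sorted(config.diet.availability.items())},
    }
    canonical = yaml.safe_dump(doc, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


# --------------------------------------------------------------------------
# forcing files
# --------------------------------------------------------------------------

def write_forcing(series: ForcingSeries, path) -> None:
    lines = [f"# label: {series.label}"]
    for gid, s in sorted(series.productivity_scalars.items()):
        lines.append(f"# scalar: {gid}\t{s!r}")
    lines.append("day\ttemperature")
    for d, T in enumerate(series.daily_T, start=1):
        lines.append(f"{d}\t{float(T)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_forcing(path) -> ForcingSeries:
    label, scalars, temps = "unnamed", {}, []
    for line in Path(path).read_text().splitlines():
        if line.startswith("# label:"):
            label = line.split(":", 1)[1].strip()
        elif line.startswith("# scalar:"):
            gid, val = line.split(":", 1)[1].strip().split("\t")
            scalars[gid] = float(val)
        elif line.startswith("#") or line.startswith("day") or not line.strip():
            continue
        else:
            temps.append(float(line.split("\t")[1]))
    if len(temps) != DAYS_PER_YEAR:
        raise ForcingDataError(f"{path}: expected {DAYS_PER_YEAR} days, got {len(temps)}")
    return ForcingSeries(daily_T=np.array(temps), productivity_scalars=scalars,
                         label=label)


# --------------------------------------------------------------------------
# run outputs and manifests
# --------------------------------------------------------------------------

def save_run(result: RunResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.to_frame().to_csv(out / "series.tsv", sep="\t", index=False)
    naa = []
    T, G, A = result.naa.shape
    for gi, gid in enumerate(result.group_ids):
        for a in range(A):
            col = result.naa[:, gi, a]
            if not np.any(col > 0):
                continue
            naa.append(pd.DataFrame({"year": result.years, "group": gid,
                                     "age": a + 1, "numbers": col}))
    if naa:
        pd.concat(naa, ignore_index=True).to_csv(out / "numbers_at_age.tsv",
                                                 sep="\t", index=False)


def save_summary(summary: EquilibriumSummary, path) -> None:
    # 17 significant digits: doubles survive the text round trip exactly
    summary.table.to_csv(path, sep="\t", float_format="%.17g")


def load_summary(path) -> EquilibriumSummary:
    table = pd.read_csv(path, sep="\t", index_col="group",
                        float_precision="round_trip")
    agg = float(table.loc[table["is_focal"], "catch_mean"].sum())
    return EquilibriumSummary(table=table, aggregate_focal_catch=agg)


def run_manifest(config: FoodWebConfig, runs: list[dict], extra: dict | None = None
                 ) -> dict:
    from . import __version__
    manifest = {
        "software": "ecocap",
        "version": __version__,
        "created": datetime.now(timezone.utc).isoformat(timespec="seconds"),
        "config_digest": config_digest(config),
        "n_runs": len(runs),
        "runs": runs,
    }
    if extra:
        manifest.update(extra)
    return manifest
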