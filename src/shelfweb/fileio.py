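"""Delimited-text and JSON interchange, run configuration, comparison.

Tabular formats are plain CSV: a groups table (one row per functional
group, empty cell = unknown), a diet matrix (first column prey names, one
column per predator, optional trailing ``__import__`` row), catch series
(year, catch) and interview records. Solved models travel as versioned
JSON. Numbers are rounded only at presentation; files round-trip at full
precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .balance import FlowNetwork
from .comsir import CatchSeries
from .core import BalancedModel, Diagnostic, DietMatrix, EcopathInputs, GroupInput
from .elicitation import InterviewRecord
from .network import AttributeReport

GROUP_COLUMNS = ["name", "category", "biomass", "pb", "qb", "ee", "landings",
                 "gs", "ba", "migration", "detritus_import"]

SCHEMA_VERSION = 1

#: verbatim system-attribute row names, in canonical table order
ATTRIBUTE_ROWS: list[tuple[str, str]] = [
    ("Sum of all production", "sum_of_production"),
    ("Total system throughput", "total_system_throughput"),
    ("Total net primary production", "total_net_pp"),
    ("Total primary production/Total respiration", "pp_over_respiration"),
    ("Total primary production/Total biomass", "pp_over_biomass"),
    ("Total biomass/Total throughput", "biomass_over_throughput"),
    ("Total biomass (excluding detritus)", "total_biomass_excl_detritus"),
    ("Total catch", "total_catch"),
    ("Mean trophic level of the catch", "mean_tl_catch"),
    ("Connectance index", "connectance"),
    ("System omnivory index", "system_omnivory"),
    ("Ascendancy (% of capacity)", "ascendency_pct"),
    ("Overhead (% of capacity)", "overhead_pct"),
    ("Throughput cycled (excluding detritus)", "throughput_cycled"),
    ("Finn's cycling index", "finn_cycling_pct"),
    ("Finn's mean path length", "finn_mean_path_length"),
]


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# groups table
# ---------------------------------------------------------------------------

def _opt(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) \
            or value == "":
        return None
    return float(value)


def read_groups(path: str | Path) -> list[GroupInput]:
    df = pd.read_csv(path)
    missing = {"name", "category"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    dupes = df["name"][df["name"].duplicated()].tolist()
    if dupes:
        raise ParseError(f"{path}: duplicate group names {dupes}")
    groups = []
    for i, row in df.iterrows():
        try:
            groups.append(GroupInput(
                name=str(row["name"]), category=str(row["category"]),
                biomass=_opt(row.get("biomass")), pb=_opt(row.get("pb")),
                qb=_opt(row.get("qb")), ee=_opt(row.get("ee")),
                landings=_opt(row.get("landings")) or 0.0,
                gs=_opt(row.get("gs")),
                ba=_opt(row.get("ba")) or 0.0,
                migration=_opt(row.get("migration")) or 0.0,
                detritus_import=_opt(row.get("detritus_import")) or 0.0,
            ))
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: line {i + 2}: {exc}") from exc
    return groups


def write_groups(groups: list[GroupInput], path: str | Path) -> None:
    rows = [{c: getattr(g, c) for c in GROUP_COLUMNS} for g in groups]
    pd.DataFrame(rows, columns=GROUP_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# diet matrix
# ---------------------------------------------------------------------------

def read_diet(path: str | Path, names: list[str] | None = None) -> DietMatrix:
    df = pd.read_csv(path, index_col=0)
    import_row = None
    if "__import__" in df.index:
        import_row = df.loc["__import__"].to_numpy(dtype=float)
        df = df.drop(index="__import__")
    prey = [str(i) for i in df.index]
    predators = [str(c) for c in df.columns]
    if prey != predators:
        raise ParseError(
            f"{path}: prey rows and predator columns differ "
            f"(rows={prey[:3]}..., cols={predators[:3]}...)")
    if names is not None:
        missing = set(names) - set(prey)
        extra = set(prey) - set(names)
        if missing or extra:
            raise ParseError(
                f"{path}: diet groups do not match the groups table "
                f"(missing={sorted(missing)}, unexpected={sorted(extra)})")
    values = df.to_numpy(dtype=float)
    values = np.nan_to_num(values)
    dm = DietMatrix(prey, values,
                    np.nan_to_num(import_row) if import_row is not None
                    else None)
    return dm.reorder(names) if names is not None else dm


def write_diet(diet: DietMatrix, path: str | Path) -> None:
    df = pd.DataFrame(diet.values, index=diet.names, columns=diet.names)
    if diet.import_row.any():
        df.loc["__import__"] = diet.import_row
    df.to_csv(path, index_label="prey")


def read_inputs(groups_path: str | Path,
                diet_path: str | Path) -> EcopathInputs:
    groups = read_groups(groups_path)
    diet = read_diet(diet_path, names=[g.name for g in groups])
    return EcopathInputs(groups, diet)


# ---------------------------------------------------------------------------
# catch series and interview records
# ---------------------------------------------------------------------------

def read_catch(path: str | Path) -> CatchSeries:
    df = pd.read_csv(path)
    if not {"year", "catch"} <= set(df.columns):
        raise ParseError(f"{path}: expected columns year,catch")
    df = df.sort_values("year")
    return CatchSeries(df["year"].astype(int).tolist(),
                       df["catch"].to_numpy(dtype=float))


def read_records(path: str | Path) -> list[InterviewRecord]:
    df = pd.read_csv(path)
    required = {"fisher_id", "round", "species", "parameter", "value"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(required)}")
    records = []
    for _, row in df.iterrows():
        raw = row["value"]
        try:
            value: float | str = float(raw)
        except (TypeError, ValueError):
            value = str(raw)
        records.append(InterviewRecord(
            str(row["fisher_id"]), int(row["round"]), str(row["species"]),
            str(row["parameter"]), value, str(row.get("units", "") or "")))
    return records


# ---------------------------------------------------------------------------
# model JSON
# ---------------------------------------------------------------------------

def model_to_dict(model: BalancedModel) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "groups": [{c: getattr(g, c) for c in GROUP_COLUMNS}
                   for g in model.groups],
        "diet": {"names": model.diet.names,
                 "values": model.diet.values.tolist(),
                 "import_row": model.diet.import_row.tolist()},
        "residuals": model.residuals.tolist(),
        "warnings": [{"severity": w.severity, "where": w.where,
                      "message": w.message} for w in model.warnings],
        "detritus_ee": model.detritus_ee,
    }


def model_from_dict(data: dict) -> BalancedModel:
    groups = [GroupInput(**g) for g in data["groups"]]
    diet = DietMatrix(data["diet"]["names"],
                      np.asarray(data["diet"]["values"]),
                      np.asarray(data["diet"]["import_row"]))
    return BalancedModel(
        groups, diet, np.asarray(data["residuals"]),
        [Diagnostic(**w) for w in data["warnings"]],
        dict(data.get("detritus_ee", {})))


def write_model(model: BalancedModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1))


def read_model(path: str | Path) -> BalancedModel:
    return model_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    gs_default: float = 0.2
    temperature: float = 27.0
    area_km2: float = 16_400.0
    import_tl: str = "producer"
    include_cannibalism_links: bool = False
    consensus_threshold: float = 0.5
    consensus_numeric_band: float = 0.2
    seed: int | None = None
    extra: dict = field(default_factory=dict)


def load_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {k: data.pop(k) for k in list(data)
             if k in RunConfig.__dataclass_fields__ and k != "extra"}
    return RunConfig(**known, extra=data)


# ---------------------------------------------------------------------------
# comparison reports
# ---------------------------------------------------------------------------

def attribute_frame(report: AttributeReport) -> pd.Series:
    vals = report.as_dict()
    return pd.Series({row: vals[key] for row, key in ATTRIBUTE_ROWS},
                     name="value")


def compare_models(report_a: AttributeReport, report_b: AttributeReport,
                   label_a: str = "a", label_b: str = "b") -> pd.DataFrame:
    """Side-by-side system attributes plus the b/a ratio (2 decimals)."""
    a = attribute_frame(report_a)
    b = attribute_frame(report_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (b / a).round(2)
    return pd.DataFrame({label_a: a, label_b: b,
                         f"{label_b}/{label_a}": ratio})


def compare_trophic(report_a, report_b, species: list[str],
                    label_a: str = "a", label_b: str = "b") -> pd.DataFrame:
    """Per-species TL/OI/keystone-rank comparison on a caller-chosen list."""
    for rep in (report_a, report_b):
        missing = sorted(set(species) - set(rep.names))
        if missing:
            raise ValueError(f"groups absent from one report: {missing}")
    rows = {}
    for rep, label in ((report_a, label_a), (report_b, label_b)):
        ix = [rep.names.index(s) for s in species]
        rows[f"TL_{label}"] = rep.tl[ix]
        rows[f"OI_{label}"] = rep.oi[ix]
        rows[f"rank_{label}"] = rep.keystone_rank[ix]
    return pd.DataFrame(rows, index=pd.Index(species, name="group"))
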