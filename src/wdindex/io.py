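"""Readers and writers for the package's delimited-text interfaces.

Dialect is fixed: comma-separated, UTF-8, "." decimal, header row.  Intake
matrices have one row per subject (first column ``subject_id``) and one
column per item; empty cells are missing (never silently zero).  Schemas and
rule sets travel as YAML, coefficient tables and reference statistics as CSV,
score sets as CSV plus a JSON sidecar carrying the per-variant divisors.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .mets import MetSRuleSet, default_rulesets
from .schema import (
    CoefficientTable,
    Component,
    ComponentSchema,
    ReferenceStats,
    ScoreSet,
    validate_intake_matrix,
)

__all__ = [
    "read_intake",
    "write_intake",
    "read_phenotypes",
    "write_phenotypes",
    "read_schema",
    "write_schema",
    "read_coefficients",
    "write_coefficients",
    "read_reference_stats",
    "write_reference_stats",
    "read_rulesets",
    "write_rulesets",
    "read_scores",
    "write_scores",
    "write_report",
]


def read_intake(path: str | Path, schema: ComponentSchema | None = None) -> pd.DataFrame:
    """Read a subject x item intake matrix; validates against the schema's
    item ids when a schema is given (unknown columns are an error)."""
    df = pd.read_csv(path, index_col="subject_id")
    if df.index.has_duplicates:
        dupes = list(df.index[df.index.duplicated()].unique())
        raise ValueError(f"duplicate subject_id values: {dupes}")
    if schema is not None:
        known = set(schema.item_ids) | set(schema.component_ids)
        unknown = [c for c in df.columns if c not in known]
        if unknown:
            raise ValueError(f"unknown intake columns (not in schema): {unknown}")
    return validate_intake_matrix(df)


def write_intake(intakes: pd.DataFrame, path: str | Path) -> None:
    intakes.to_csv(path, index_label="subject_id")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="subject_id")
    if df.index.has_duplicates:
        dupes = list(df.index[df.index.duplicated()].unique())
        raise ValueError(f"duplicate subject_id values: {dupes}")
    if "smoking" in df.columns:
        df["smoking"] = df["smoking"].astype("boolean").astype(object)
    return df


def write_phenotypes(phenotypes: pd.DataFrame, path: str | Path) -> None:
    phenotypes.to_csv(path, index_label="subject_id")


def read_schema(path: str | Path) -> ComponentSchema:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    comps = [
        Component(
            component_id=c["component_id"],
            display_name=c.get("display_name", c["component_id"]),
            unit=c.get("unit", ""),
            aggregation=c.get("aggregation", "single"),
            members=tuple(c.get("members", []) or []),
            food_group_18=c.get("food_group_18"),
        )
        for c in doc["components"]
    ]
    return ComponentSchema(comps)


def write_schema(schema: ComponentSchema, path: str | Path, header: str | None = None) -> None:
    doc = {
        "components": [
            {
                "component_id": c.component_id,
                "display_name": c.display_name,
                "unit": c.unit,
                "aggregation": c.aggregation,
                "members": list(c.members),
                "food_group_18": c.food_group_18,
            }
            for c in schema
        ]
    }
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_coefficients(path: str | Path) -> CoefficientTable:
    """Read a coefficient CSV (columns: id, coefficient[, centralized])."""
    df = pd.read_csv(path, comment="#").set_index("id")
    cen = df["centralized"] if "centralized" in df.columns else None
    return CoefficientTable(coefficient=df["coefficient"], centralized=cen)


def write_coefficients(table: CoefficientTable, path: str | Path, header: str | None = None) -> None:
    df = pd.DataFrame({"coefficient": table.coefficient})
    if table.centralized is not None:
        df["centralized"] = table.centralized
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index_label="id")


def read_reference_stats(path: str | Path, source: str = "global") -> ReferenceStats:
    df = pd.read_csv(path, comment="#").set_index("id")
    return ReferenceStats(mean=df["mean"], sd=df["sd"], source=source)


def write_reference_stats(ref: ReferenceStats, path: str | Path, header: str | None = None) -> None:
    df = pd.DataFrame({"mean": ref.mean, "sd": ref.sd})
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write(f"# source: {ref.source}\n")
        df.to_csv(fh, index_label="id")


def read_rulesets(path: str | Path) -> dict[str, MetSRuleSet]:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return {d["definition"]: MetSRuleSet.from_dict(d) for d in doc["rulesets"]}


def write_rulesets(rulesets: Mapping[str, MetSRuleSet] | None, path: str | Path) -> None:
    if rulesets is None:
        rulesets = default_rulesets()
    doc = {"rulesets": [rs.to_dict() for rs in rulesets.values()]}
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def write_scores(scores: ScoreSet, path: str | Path, precision: int = 4) -> None:
    """Write per-subject scores as CSV plus a ``<path>.meta.json`` sidecar
    with the per-variant divisors and skipped components."""
    path = Path(path)
    scores.scores.round(precision).to_csv(path, index_label="subject_id")
    sidecar = {"divisors": scores.divisors, "skipped": scores.skipped}
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(sidecar, indent=2), encoding="utf-8"
    )


def read_scores(path: str | Path) -> ScoreSet:
    path = Path(path)
    frame = pd.read_csv(path, index_col="subject_id")
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text(encoding="utf-8"))
    else:
        meta = {"divisors": {}, "skipped": {}}
    return ScoreSet(scores=frame, divisors=meta["divisors"], skipped=meta["skipped"])


def write_report(report: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=str), encoding="utf-8")


def example_data_path(name: str) -> Path:
    """Path to one of the shipped example/config files (synthetic,
    NON-AUTHORITATIVE; see each file's header)."""
    from importlib.resources import files

    p = Path(str(files("wdindex") / "data" / name))
    if not p.exists():
        available = sorted(q.name for q in p.parent.glob("*"))
        raise FileNotFoundError(f"no example file {name!r}; available: {available}")
    return p
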