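"""Domain types shared across the package.

The index is computed over *components*: a component is either a single food
item, a group of same-unit items (scored as the z-score of the member sum), or
a group of mixed-unit items (scored as the mean of member z-scores).  An
optional 18-way food-group partition over components supports the food-group
variant of the index.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

SINGLE = "single"
GROUP_SAME_UNIT = "group_same_unit"
GROUP_MIXED_UNIT = "group_mixed_unit"
AGGREGATIONS = (SINGLE, GROUP_SAME_UNIT, GROUP_MIXED_UNIT)


class SchemaError(ValueError):
    """Raised when a component schema violates its invariants."""


@dataclass(frozen=True)
class Component:
    """One scored food component.

    Parameters
    ----------
    component_id : str
        Unique token identifying the component.
    display_name : str
        Human-readable name.
    unit : str
        Intake unit of the component (for a mixed-unit group, the unit of the
        group z-score, i.e. dimensionless).
    aggregation : str
        One of ``single``, ``group_same_unit``, ``group_mixed_unit``.
    members : tuple of str
        Constituent item ids; empty iff ``aggregation == "single"``.
    food_group_18 : str or None
        Membership in the 18-way food-group partition, or None if the
        component does not enter the food-group variant.
    """

    component_id: str
    display_name: str
    unit: str
    aggregation: str = SINGLE
    members: tuple[str, ...] = ()
    food_group_18: str | None = None

    def __post_init__(self) -> None:
        if self.aggregation not in AGGREGATIONS:
            raise SchemaError(
                f"unknown aggregation {self.aggregation!r} for {self.component_id!r}"
            )
        if self.aggregation == SINGLE and self.members:
            raise SchemaError(f"single component {self.component_id!r} has members")
        if self.aggregation != SINGLE and not self.members:
            raise SchemaError(f"group component {self.component_id!r} has no members")

    @property
    def is_group(self) -> bool:
        return self.aggregation != SINGLE

    @property
    def item_ids(self) -> tuple[str, ...]:
        """Leaf item ids: the members for a group, the component itself otherwise."""
        return self.members if self.is_group else (self.component_id,)


class ComponentSchema:
    """Ordered collection of components with the 18-group partition.

    Invariants enforced on construction: component ids unique, member ids
    unique across the schema and disjoint from component ids, and every
    food-group-assigned component belongs to exactly one group.
    """

    def __init__(self, components: Iterable[Component]):
        self.components: tuple[Component, ...] = tuple(components)
        ids = [c.component_id for c in self.components]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SchemaError(f"duplicate component ids: {dupes}")
        members: list[str] = []
        for c in self.components:
            members.extend(c.members)
        if len(set(members)) != len(members):
            dupes = sorted({m for m in members if members.count(m) > 1})
            raise SchemaError(f"item assigned to more than one component: {dupes}")
        overlap = set(members) & set(ids)
        if overlap:
            raise SchemaError(f"ids used both as component and member: {sorted(overlap)}")
        self._by_id = {c.component_id: c for c in self.components}

    def __iter__(self):
        return iter(self.components)

    def __len__(self) -> int:
        return len(self.components)

    def __getitem__(self, component_id: str) -> Component:
        try:
            return self._by_id[component_id]
        except KeyError:
            raise SchemaError(f"unknown component {component_id!r}") from None

    def __contains__(self, component_id: str) -> bool:
        return component_id in self._by_id

    @property
    def component_ids(self) -> list[str]:
        return [c.component_id for c in self.components]

    @property
    def item_ids(self) -> list[str]:
        """All leaf item ids, in schema order."""
        out: list[str] = []
        for c in self.components:
            out.extend(c.item_ids)
        return out

    def food_groups(self) -> dict[str, list[str]]:
        """Mapping food-group name -> component ids, for assigned components only."""
        groups: dict[str, list[str]] = {}
        for c in self.components:
            if c.food_group_18 is not None:
                groups.setdefault(c.food_group_18, []).append(c.component_id)
        return groups

    def reference_ids(self, component_ids: Iterable[str] | None = None) -> list[str]:
        """Ids that need reference statistics for z-referenced scoring.

        Singles and same-unit groups are referenced under the component id
        (the latter as the member sum); mixed-unit groups under each member id.
        """
        out: list[str] = []
        for cid in component_ids if component_ids is not None else self.component_ids:
            c = self[cid]
            if c.aggregation == GROUP_MIXED_UNIT:
                out.extend(c.members)
            else:
                out.append(c.component_id)
        return out


@dataclass(frozen=True)
class CoefficientTable:
    """Index weights per component/item/group id, with the derived centralized column.

    ``centralized`` maps each raw coefficient through its fractional rank
    (rank / n, mean rank for ties) to 2*rank/n - 1, a monotone transform of
    the raw column bounded in (-1, 1].
    """

    coefficient: pd.Series
    centralized: pd.Series | None = None

    def __post_init__(self) -> None:
        coef = self.coefficient.astype(float)
        if coef.index.has_duplicates:
            raise SchemaError("duplicate ids in coefficient table")
        if coef.isna().any():
            missing = list(coef.index[coef.isna()])
            raise SchemaError(f"missing coefficient values for: {missing}")
        object.__setattr__(self, "coefficient", coef)
        if self.centralized is not None:
            cen = self.centralized.astype(float).reindex(coef.index)
            if cen.isna().any():
                raise SchemaError("centralized column does not cover all ids")
            object.__setattr__(self, "centralized", cen)

    def __len__(self) -> int:
        return len(self.coefficient)

    def centralize(self) -> "CoefficientTable":
        """Return a copy with the centralized column derived from the raw one."""
        coef = self.coefficient
        if len(coef) == 0:
            raise SchemaError("cannot centralize an empty coefficient table")
        frac = rankdata(coef.to_numpy(), method="average") / len(coef)
        cen = pd.Series(2.0 * frac - 1.0, index=coef.index)
        return replace(self, centralized=cen)

    def get(self, ids: Iterable[str], kind: str = "raw") -> pd.Series:
        """Coefficients for ``ids`` (``kind`` = 'raw' or 'centralized')."""
        if kind == "raw":
            src = self.coefficient
        elif kind == "centralized":
            if self.centralized is None:
                src = self.centralize().centralized
            else:
                src = self.centralized
        else:
            raise ValueError(f"unknown coefficient kind {kind!r}")
        ids = list(ids)
        missing = [i for i in ids if i not in src.index]
        if missing:
            raise SchemaError(f"no coefficient for: {missing}")
        return src.loc[ids]


@dataclass(frozen=True)
class ReferenceStats:
    """Per-id reference mean and SD used for z-scoring intakes.

    ``source`` records whether the statistics describe an external (global)
    population or the analysis cohort itself; the scoring variant family is
    selected by this tag.
    """

    mean: pd.Series
    sd: pd.Series
    source: str  # "global" | "population"

    def __post_init__(self) -> None:
        if self.source not in ("global", "population"):
            raise ValueError(f"source must be 'global' or 'population', got {self.source!r}")
        mean = self.mean.astype(float)
        sd = self.sd.astype(float).reindex(mean.index)
        if sd.isna().any():
            raise ValueError("sd column does not cover all ids with a mean")
        if (sd < 0).any():
            bad = list(sd.index[sd < 0])
            raise ValueError(f"negative SD for: {bad}")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "sd", sd)

    def require(self, ids: Iterable[str]) -> None:
        missing = [i for i in ids if i not in self.mean.index]
        if missing:
            raise KeyError(f"no reference statistics for: {missing}")

    def zero_variance_ids(self, ids: Iterable[str]) -> list[str]:
        self.require(ids)
        return [i for i in ids if self.sd.loc[i] <= 0]


VARIANTS = ("wdi_g", "wdi_gc", "wdi_gs", "wdi_p", "wdi_pc", "wdi_ps", "wdi_i", "wdi_fg")


@dataclass
class VariantScores:
    """Per-subject scores for one index variant plus scoring metadata."""

    variant: str
    values: pd.Series
    divisor: int
    skipped: list[str] = field(default_factory=list)


@dataclass
class ScoreSet:
    """Per-subject values of the computed index variants.

    ``scores`` has one row per subject and one column per variant (NaN where a
    subject could not be scored); ``divisors`` and ``skipped`` record, per
    variant, how many components entered the mean and which were dropped.
    """

    scores: pd.DataFrame
    divisors: dict[str, int]
    skipped: dict[str, list[str]] = field(default_factory=dict)

    @classmethod
    def from_variants(cls, variants: Iterable[VariantScores]) -> "ScoreSet":
        variants = list(variants)
        frame = pd.DataFrame({v.variant: v.values for v in variants})
        return cls(
            scores=frame,
            divisors={v.variant: v.divisor for v in variants},
            skipped={v.variant: list(v.skipped) for v in variants},
        )

    @property
    def subject_ids(self) -> pd.Index:
        return self.scores.index

    def __getitem__(self, variant: str) -> pd.Series:
        return self.scores[variant]


@dataclass(frozen=True)
class RangeSummary:
    """Observed range and moments of one variant's score distribution."""

    variant: str
    min: float
    max: float
    span: float
    mean: float
    sd: float


def validate_intake_matrix(intakes: pd.DataFrame) -> pd.DataFrame:
    """Check intake-matrix invariants: unique subjects, non-negative values."""
    if intakes.index.has_duplicates:
        dupes = list(intakes.index[intakes.index.duplicated()].unique())
        raise ValueError(f"duplicate subject ids: {dupes}")
    numeric = intakes.astype(float)
    if (numeric < 0).any().any():
        bad = [c for c in numeric.columns if (numeric[c] < 0).any()]
        raise ValueError(f"negative intakes in columns: {bad}")
    return numeric
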