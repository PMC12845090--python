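"""The eight Westernized Diet Index (WDI) scoring algorithms.

All variants share one convention: a higher score means *lower* adherence to a
Westernized dietary pattern.  The z-referenced family (WDI-G/GC/GS with
external "global" reference statistics; WDI-P/PC/PS with within-cohort
statistics) z-scores each food component first and then averages
coefficient-weighted z-scores over the scored components.  The item-level
variant (WDI-I) weights each raw item intake by its coefficient *first* and
then averages the within-cohort z-scores of the weighted columns; the
food-group variant (WDI-FG) does the same over the 18 aggregated food groups.

Missing data policy: a subject missing any scored component gets a missing
score for that variant (optionally mean-imputed via ``impute="mean"``); a
zero-variance component is skipped with a warning and the divisor reduced,
because a constant column carries no between-subject information and its
z-score is undefined.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .schema import (
    GROUP_MIXED_UNIT,
    GROUP_SAME_UNIT,
    SINGLE,
    CoefficientTable,
    Component,
    ComponentSchema,
    RangeSummary,
    ReferenceStats,
    SchemaError,
    ScoreSet,
    VariantScores,
    validate_intake_matrix,
)

__all__ = [
    "ZeroVarianceError",
    "zscore",
    "compute_population_stats",
    "component_zscore",
    "centralize_coefficients",
    "score_zref_variant",
    "standardize_scores",
    "score_wdi_i",
    "score_wdi_fg",
    "score_all",
    "summarize_range",
    "effect_per_range_fraction",
]


class ZeroVarianceError(ValueError):
    """A z-score was requested against a zero (or negative) reference SD."""


def zscore(intake: float, mean: float, sd: float) -> float:
    """Standardize one intake value: ``(intake - mean) / sd``.

    Raises
    ------
    ZeroVarianceError
        If ``sd <= 0``.
    """
    if sd <= 0:
        raise ZeroVarianceError(f"z-score undefined for sd={sd}")
    return (intake - mean) / sd


def _reference_frame(
    intakes: pd.DataFrame,
    schema: ComponentSchema,
    component_ids: Sequence[str],
) -> pd.DataFrame:
    """One column per reference id: raw columns for singles and mixed-unit
    members, member sums for same-unit groups."""
    cols: dict[str, pd.Series] = {}
    for cid in component_ids:
        comp = schema[cid]
        if comp.aggregation == GROUP_SAME_UNIT:
            members = list(comp.members)
            _require_columns(intakes, members, cid)
            cols[cid] = intakes[members].sum(axis=1, min_count=len(members))
        elif comp.aggregation == GROUP_MIXED_UNIT:
            _require_columns(intakes, list(comp.members), cid)
            for m in comp.members:
                cols[m] = intakes[m]
        else:
            _require_columns(intakes, [cid], cid)
            cols[cid] = intakes[cid]
    return pd.DataFrame(cols)


def _require_columns(intakes: pd.DataFrame, ids: list[str], owner: str) -> None:
    missing = [i for i in ids if i not in intakes.columns]
    if missing:
        raise SchemaError(f"intake matrix lacks columns {missing} needed by {owner!r}")


def compute_population_stats(
    intakes: pd.DataFrame,
    schema: ComponentSchema,
    component_ids: Sequence[str] | None = None,
) -> ReferenceStats:
    """Within-cohort reference mean/SD per reference id (sample SD, n-1).

    Same-unit groups are summarized as the member sum; mixed-unit groups
    contribute one entry per member.  A component observed fewer than twice is
    an error; a constant column yields sd=0, which downstream scoring treats
    under the zero-variance rule.
    """
    intakes = validate_intake_matrix(intakes)
    if component_ids is None:
        component_ids = [c.component_id for c in schema if _columns_present(intakes, c)]
    ref = _reference_frame(intakes, schema, component_ids)
    counts = ref.notna().sum()
    if (counts < 2).any():
        bad = list(counts.index[counts < 2])
        raise ValueError(f"fewer than 2 observations for: {bad}")
    return ReferenceStats(mean=ref.mean(), sd=ref.std(ddof=1), source="population")


def _columns_present(intakes: pd.DataFrame, comp: Component) -> bool:
    return all(i in intakes.columns for i in comp.item_ids)


def component_zscore(
    intakes: pd.DataFrame,
    component_id: str,
    ref: ReferenceStats,
    schema: ComponentSchema,
) -> pd.Series:
    """Per-subject z-score of one component against the given reference.

    single -> z of the raw column; group_mixed_unit -> mean of the member
    z-scores; group_same_unit -> z of the member sum using the sum's
    reference mean/SD.
    """
    comp = schema[component_id]
    if comp.aggregation == GROUP_MIXED_UNIT:
        ref.require(comp.members)
        zs = {}
        for m in comp.members:
            sd = float(ref.sd.loc[m])
            if sd <= 0:
                raise ZeroVarianceError(f"member {m!r} of {component_id!r} has sd={sd}")
            zs[m] = (intakes[m] - ref.mean.loc[m]) / sd
        return pd.DataFrame(zs).mean(axis=1, skipna=False)
    ref.require([component_id])
    sd = float(ref.sd.loc[component_id])
    if sd <= 0:
        raise ZeroVarianceError(f"component {component_id!r} has sd={sd}")
    if comp.aggregation == GROUP_SAME_UNIT:
        col = intakes[list(comp.members)].sum(axis=1, min_count=len(comp.members))
    else:
        col = intakes[component_id]
    return (col - ref.mean.loc[component_id]) / sd


def centralize_coefficients(table: CoefficientTable) -> CoefficientTable:
    """Fractional-rank centralization of the raw coefficients.

    Each coefficient is mapped to its fractional rank r = rank/n (ascending,
    ties get the mean rank) and then to 2r - 1, giving a monotone, symmetric
    transform bounded in (-1, 1].
    """
    return table.centralize()


def score_zref_variant(
    intakes: pd.DataFrame,
    schema: ComponentSchema,
    table: CoefficientTable,
    ref: ReferenceStats,
    coeff_kind: str = "raw",
    component_ids: Sequence[str] | None = None,
    impute: str | None = None,
) -> VariantScores:
    """Z-reference family scorer (WDI-G / WDI-GC / WDI-P / WDI-PC).

    Per subject: mean over scored components of component z-score times the
    component coefficient.  ``ref.source`` selects the family (global ->
    WDI-G/GC, population -> WDI-P/PC); ``coeff_kind`` selects raw vs
    centralized coefficients.  Zero-variance components are skipped with a
    warning and the divisor reduced.
    """
    intakes = validate_intake_matrix(intakes)
    if component_ids is None:
        component_ids = [c.component_id for c in schema if _columns_present(intakes, c)]
    component_ids = list(component_ids)
    if not component_ids:
        raise ValueError("no components to score")
    if impute == "mean":
        intakes = _mean_impute(intakes, schema, component_ids)

    scored: dict[str, pd.Series] = {}
    skipped: list[str] = []
    for cid in component_ids:
        try:
            scored[cid] = component_zscore(intakes, cid, ref, schema)
        except ZeroVarianceError:
            warnings.warn(
                f"component {cid!r} has zero reference variance; skipped and divisor reduced",
                stacklevel=2,
            )
            skipped.append(cid)
    if not scored:
        raise ValueError("all components skipped (zero variance)")
    coef = table.get(scored.keys(), kind=coeff_kind)
    zmat = pd.DataFrame(scored)
    weighted = zmat.mul(coef, axis=1)
    values = weighted.sum(axis=1, skipna=False) / len(scored)
    prefix = "wdi_g" if ref.source == "global" else "wdi_p"
    variant = prefix + ("c" if coeff_kind == "centralized" else "")
    return VariantScores(variant=variant, values=values, divisor=len(scored), skipped=skipped)


def _mean_impute(
    intakes: pd.DataFrame, schema: ComponentSchema, component_ids: Sequence[str]
) -> pd.DataFrame:
    cols: list[str] = []
    for cid in component_ids:
        cols.extend(schema[cid].item_ids)
    cols = [c for c in cols if c in intakes.columns]
    n_missing = int(intakes[cols].isna().sum().sum())
    if n_missing:
        warnings.warn(f"mean-imputing {n_missing} missing intake cells", stacklevel=3)
        intakes = intakes.copy()
        intakes[cols] = intakes[cols].fillna(intakes[cols].mean())
    return intakes


def standardize_scores(scores: pd.Series) -> pd.Series:
    """Cohort-standardize a score column to sample mean 0, SD 1 (n-1).

    Produces WDI-GS from WDI-G and WDI-PS from WDI-P.  Missing scores stay
    missing; the mean/SD are computed over the non-missing subjects.
    """
    valid = scores.dropna()
    if len(valid) < 2:
        raise ValueError("need at least 2 non-missing scores to standardize")
    sd = valid.std(ddof=1)
    if sd <= 0:
        raise ZeroVarianceError("score column has zero variance")
    return (scores - valid.mean()) / sd


def _weighted_population_scores(
    weighted: pd.DataFrame, variant: str
) -> VariantScores:
    """Average within-cohort z-scores of pre-weighted columns (WDI-I / WDI-FG core).

    Constant weighted columns are skipped (warning, divisor reduced); if every
    column is constant the score is defined as 0 for all subjects.
    """
    sds = weighted.std(ddof=1)
    keep = [c for c in weighted.columns if sds[c] > 0]
    skipped = [c for c in weighted.columns if c not in keep]
    if skipped:
        warnings.warn(
            f"{len(skipped)} zero-variance weighted column(s) skipped: {skipped}",
            stacklevel=3,
        )
    if not keep:
        values = pd.Series(0.0, index=weighted.index)
        return VariantScores(variant=variant, values=values, divisor=0, skipped=skipped)
    z = (weighted[keep] - weighted[keep].mean()) / sds[keep]
    values = z.sum(axis=1, skipna=False) / len(keep)
    return VariantScores(variant=variant, values=values, divisor=len(keep), skipped=skipped)


def score_wdi_i(
    intakes: pd.DataFrame,
    schema: ComponentSchema,
    table: CoefficientTable,
    item_ids: Sequence[str] | None = None,
    impute: str | None = None,
) -> VariantScores:
    """Item-level weight-then-standardize variant (WDI-I).

    Each item intake is multiplied by its coefficient first; the within-cohort
    z-scores of the weighted columns are then averaged over the items (57 in
    the full configuration).
    """
    intakes = validate_intake_matrix(intakes)
    if item_ids is None:
        item_ids = [i for i in schema.item_ids if i in intakes.columns]
    item_ids = list(item_ids)
    if not item_ids:
        raise ValueError("no items to score")
    _require_columns(intakes, item_ids, "wdi_i")
    if impute == "mean":
        sub = intakes[item_ids]
        n_missing = int(sub.isna().sum().sum())
        if n_missing:
            warnings.warn(f"mean-imputing {n_missing} missing intake cells", stacklevel=2)
            intakes = intakes.copy()
            intakes[item_ids] = sub.fillna(sub.mean())
    coef = table.get(item_ids, kind="raw")
    weighted = intakes[item_ids].mul(coef, axis=1)
    return _weighted_population_scores(weighted, "wdi_i")


def score_wdi_fg(
    intakes: pd.DataFrame,
    schema: ComponentSchema,
    table: CoefficientTable,
    group_names: Sequence[str] | None = None,
    impute: str | None = None,
) -> VariantScores:
    """Food-group variant (WDI-FG) over the 18-group partition.

    Group intake = sum of member-component intakes (components summed over
    their own items); each group intake is weighted by the group coefficient
    and the within-cohort z-scores of the weighted group columns averaged.
    """
    intakes = validate_intake_matrix(intakes)
    groups = schema.food_groups()
    if not groups:
        raise SchemaError("schema defines no food-group partition")
    if group_names is None:
        group_names = list(groups)
    missing = [g for g in group_names if g not in groups]
    if missing:
        raise SchemaError(f"unknown food groups: {missing}")
    cols: dict[str, pd.Series] = {}
    for g in group_names:
        member_items: list[str] = []
        for cid in groups[g]:
            member_items.extend(schema[cid].item_ids)
        _require_columns(intakes, member_items, f"food group {g!r}")
        sub = intakes[member_items]
        if impute == "mean":
            sub = sub.fillna(sub.mean())
        cols[g] = sub.sum(axis=1, min_count=len(member_items))
    frame = pd.DataFrame(cols)
    coef = table.get(group_names, kind="raw")
    weighted = frame.mul(coef, axis=1)
    return _weighted_population_scores(weighted, "wdi_fg")


def score_all(
    intakes: pd.DataFrame,
    schema: ComponentSchema,
    table: CoefficientTable,
    global_ref: ReferenceStats | None = None,
    component_ids: Sequence[str] | None = None,
    item_ids: Sequence[str] | None = None,
    impute: str | None = None,
) -> ScoreSet:
    """Compute every variant the inputs support and assemble a ScoreSet.

    The population family (WDI-P/PC/PS/I/FG) is always computed; the global
    family (WDI-G/GC/GS) only when external reference statistics are given.
    """
    intakes = validate_intake_matrix(intakes)
    if component_ids is None:
        component_ids = [c.component_id for c in schema if _columns_present(intakes, c)]
    table = table if table.centralized is not None else table.centralize()
    pop_ref = compute_population_stats(
        intakes if impute != "mean" else _mean_impute(intakes, schema, component_ids),
        schema,
        component_ids,
    )
    variants: list[VariantScores] = []
    if global_ref is not None:
        if global_ref.source != "global":
            raise ValueError("global_ref must have source='global'")
        g = score_zref_variant(intakes, schema, table, global_ref, "raw", component_ids, impute)
        gc = score_zref_variant(
            intakes, schema, table, global_ref, "centralized", component_ids, impute
        )
        gs = VariantScores("wdi_gs", standardize_scores(g.values), g.divisor, list(g.skipped))
        variants += [g, gc, gs]
    p = score_zref_variant(intakes, schema, table, pop_ref, "raw", component_ids, impute)
    pc = score_zref_variant(intakes, schema, table, pop_ref, "centralized", component_ids, impute)
    ps = VariantScores("wdi_ps", standardize_scores(p.values), p.divisor, list(p.skipped))
    variants += [p, pc, ps]
    variants.append(score_wdi_i(intakes, schema, table, item_ids, impute))
    if schema.food_groups():
        variants.append(score_wdi_fg(intakes, schema, table, impute=impute))
    return ScoreSet.from_variants(variants)


def summarize_range(scores: pd.Series, variant: str) -> RangeSummary:
    """Observed min, max, span (max - min), mean, and sample SD of a variant."""
    valid = scores.dropna()
    if valid.empty:
        raise ValueError(f"no non-missing scores for {variant!r}")
    lo, hi = float(valid.min()), float(valid.max())
    return RangeSummary(
        variant=variant,
        min=lo,
        max=hi,
        span=hi - lo,
        mean=float(valid.mean()),
        sd=float(valid.std(ddof=1)) if len(valid) > 1 else 0.0,
    )


def effect_per_range_fraction(beta: float, span: float, fraction: float = 0.1) -> float:
    """Convert a per-unit regression slope into the effect of moving a given
    fraction of the score's observed range.

    Returns ``|beta| * fraction * span`` rounded to 2 decimals; the unrounded
    span is used (e.g. 0.1 * 3.14 = 0.314 units, not a pre-rounded 0.31).
    """
    if span <= 0:
        raise ValueError(f"span must be positive, got {span}")
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    return round(abs(beta) * fraction * span, 2)
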