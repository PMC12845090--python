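"""Synthetic FFQ-like cohort generator with planted diet-biomarker effects.

A single latent *healthy-diet adherence* factor W (centered normal) drives
both intakes and biomarkers:

* item intakes are log-normal — ``intake = exp(loc + loading * W + scale * eps)``
  — guaranteeing non-negative, right-skewed columns whose correlation with W
  has the sign of the loading.  Loadings are sign-aligned with the item's
  index coefficient, so a higher index score (lower Westernization) tracks
  higher W;
* biomarkers are ``baseline + effect * W + noise`` with effects expressed per
  latent-factor SD.  Adverse markers (glucose, triglycerides, blood pressure,
  waist) carry negative default effects, HDL-c a positive one, planting the
  protective direction: higher index scores associate with healthier
  biomarker profiles;
* covariates (age, sex, physical activity, smoking, energy) are drawn
  independently of W by default; an optional ``confounding`` knob couples age
  and sex to W to exercise covariate adjustment.

The generator's stored truth (per-subject W, the planted effects) is consumed
only by tests and parameter-recovery checks, never by scoring or validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import (
    GROUP_MIXED_UNIT,
    GROUP_SAME_UNIT,
    CoefficientTable,
    Component,
    ComponentSchema,
)

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "SyntheticCohort",
    "default_schema",
    "example_coefficients",
    "default_generator_config",
    "generate",
    "make_fixture",
    "FIXTURES",
]

# ---------------------------------------------------------------------------
# Default schema: 30 components (29 scored; supplements carry no data in the
# reference configuration), 57 scored leaf items, 18 food groups.
# ---------------------------------------------------------------------------

_COMPONENT_DEFS: list[tuple[str, str, str, tuple[str, ...], str | None, float]] = [
    # (id, unit, aggregation, members, food_group_18, example coefficient)
    ("whole_grains", "g/day", GROUP_SAME_UNIT,
     ("wholegrain_bread", "barley", "bulgur"), "whole grains", 0.80),
    ("refined_grains", "g/day", GROUP_SAME_UNIT,
     ("white_bread", "white_rice", "pasta"), "refined grains", -0.70),
    ("legumes", "g/day", GROUP_SAME_UNIT, ("lentils", "beans"), "legumes", 0.60),
    ("nuts_seeds", "g/day", GROUP_SAME_UNIT, ("nuts", "seeds"), "nuts and seeds", 0.50),
    ("vegetable_oils", "g/day", "single", (), "oils", 0.20),
    ("olive_oil", "g/day", "single", (), "oils", 0.70),
    ("butter", "g/day", "single", (), "refined fats", -0.50),
    ("hydrogenated_fats", "g/day", "single", (), "refined fats", -0.90),
    ("soft_drinks", "g/day", "single", (), "soft drinks", -0.80),
    ("coffee", "g/day", "single", (), "coffee/tea/waters", 0.10),
    ("tea", "g/day", "single", (), "coffee/tea/waters", 0.15),
    ("processed_foods", "g/day", GROUP_SAME_UNIT,
     ("fast_food", "salty_snacks"), "processed foods", -0.85),
    ("sweets", "g/day", GROUP_SAME_UNIT, ("sugar", "confectionery"), "processed foods", -0.75),
    ("salt", "g/day", "single", (), "processed foods", -0.45),
    ("fruits", "g/day", GROUP_SAME_UNIT,
     ("apples", "citrus", "berries", "dried_fruit", "other_fruit"), "fruits", 0.90),
    ("vegetables", "g/day", GROUP_SAME_UNIT,
     ("leafy_veg", "root_veg", "tomatoes", "cucurbits", "alliums", "other_veg"),
     "vegetables", 0.95),
    ("red_meat", "g/day", "single", (), "red meat", -0.60),
    ("processed_meat", "g/day", "single", (), "processed meat", -0.95),
    ("white_meat", "g/day", "single", (), "white meat", 0.30),
    ("fish", "g/day", "single", (), "fish", 0.65),
    ("dairy_high_fat", "g/day", "single", (), "dairy", -0.30),
    ("dairy_low_fat", "g/day", "single", (), "dairy", 0.35),
    ("eggs", "g/day", "single", (), "dairy", 0.05),
    ("diet_drinks", "g/day", "single", (), "diet drinks", -0.40),
    ("alcoholic_drinks", "g/day", "single", (), "alcoholic drinks", -0.55),
    ("vitamins_minerals", "z-units", GROUP_MIXED_UNIT,
     ("vitamin_c", "vitamin_e", "vitamin_a", "folate", "zinc",
      "selenium", "magnesium", "calcium", "iron"), None, 0.55),
    ("phytochemicals", "z-units", GROUP_MIXED_UNIT,
     ("polyphenols", "carotenoids", "phytosterols", "flavonoids"), None, 0.75),
    ("fiber", "g/day", "single", (), None, 0.85),
    ("omega3", "g/day", "single", (), None, 0.62),
    ("dietary_supplements", "units/day", "single", (), None, 0.25),
]

# typical daily amounts used as log-normal medians (example values, not survey data)
_ITEM_MEDIANS: dict[str, float] = {
    "wholegrain_bread": 60, "barley": 15, "bulgur": 20,
    "white_bread": 120, "white_rice": 150, "pasta": 40,
    "lentils": 25, "beans": 30, "nuts": 15, "seeds": 5,
    "vegetable_oils": 20, "olive_oil": 8, "butter": 10, "hydrogenated_fats": 12,
    "soft_drinks": 100, "coffee": 80, "tea": 400,
    "fast_food": 50, "salty_snacks": 20, "sugar": 30, "confectionery": 25, "salt": 8,
    "apples": 80, "citrus": 70, "berries": 20, "dried_fruit": 15, "other_fruit": 90,
    "leafy_veg": 60, "root_veg": 50, "tomatoes": 80, "cucurbits": 60,
    "alliums": 25, "other_veg": 70,
    "red_meat": 45, "processed_meat": 12, "white_meat": 55, "fish": 25,
    "dairy_high_fat": 100, "dairy_low_fat": 150, "eggs": 30,
    "diet_drinks": 30, "alcoholic_drinks": 5,
    "vitamin_c": 90, "vitamin_e": 12, "vitamin_a": 0.8, "folate": 0.35,
    "zinc": 10, "selenium": 0.06, "magnesium": 320, "calcium": 900, "iron": 14,
    "polyphenols": 900, "carotenoids": 12, "phytosterols": 250, "flavonoids": 300,
    "fiber": 22, "omega3": 1.5, "dietary_supplements": 0.5,
}

# default biomarker model: (baseline, effect per latent SD, residual SD)
_BIOMARKER_DEFAULTS: dict[str, tuple[float, float, float]] = {
    "wc": (93.2, -3.5, 10.5),
    "hc": (99.6, -2.0, 8.5),
    "bmi": (25.7, -1.2, 4.5),
    "dbp": (74.5, -3.0, 11.0),
    "pulse_pressure": (37.0, -2.0, 11.0),  # sbp = dbp + pulse pressure, kept > 0
    "pr": (74.2, -1.0, 10.5),
    "fbg": (92.9, -8.0, 26.0),
    "tg": (132.2, -30.0, 65.0),
    "chol": (185.8, -6.0, 38.0),
    "ldl": (107.9, -5.0, 32.0),
    "hdl": (51.4, 4.0, 15.0),
}


def default_schema(include_supplements: bool = True) -> ComponentSchema:
    """The shipped example component schema (30 components, 18 food groups)."""
    comps = []
    for cid, unit, agg, members, fg, _coef in _COMPONENT_DEFS:
        if cid == "dietary_supplements" and not include_supplements:
            continue
        comps.append(
            Component(
                component_id=cid,
                display_name=cid.replace("_", " "),
                unit=unit,
                aggregation=agg,
                members=members,
                food_group_18=fg,
            )
        )
    return ComponentSchema(comps)


def example_coefficients(schema: ComponentSchema | None = None) -> CoefficientTable:
    """NON-AUTHORITATIVE example coefficient table.

    Illustrative weights only (healthier components positive, Westernized
    components negative), used in tests and demonstrations; real analyses
    must supply the published coefficient table as config.  Items inherit
    their parent component's coefficient; each of the 18 food groups gets the
    mean coefficient of its member components.
    """
    if schema is None:
        schema = default_schema()
    comp_coef = {cid: coef for cid, _u, _a, _m, _f, coef in _COMPONENT_DEFS}
    entries: dict[str, float] = {}
    for comp in schema:
        coef = comp_coef[comp.component_id]
        entries[comp.component_id] = coef
        for m in comp.members:
            entries[m] = coef
    for fg, cids in schema.food_groups().items():
        entries[fg] = float(np.mean([comp_coef[c] for c in cids]))
    return CoefficientTable(pd.Series(entries)).centralize()


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic cohort generator.

    ``loadings`` give, per leaf item, the slope of log-intake on the latent
    factor; ``locations``/``scales`` the log-normal location and residual
    log-scale; ``biomarkers`` maps each biomarker to (baseline, effect per
    latent SD, residual SD).  ``seed`` is mandatory.
    """

    n_subjects: int
    seed: int
    schema: ComponentSchema = field(default_factory=default_schema)
    loadings: dict[str, float] = field(default_factory=dict)
    locations: dict[str, float] = field(default_factory=dict)
    scales: dict[str, float] = field(default_factory=dict)
    latent_sd: float = 1.0
    biomarkers: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_BIOMARKER_DEFAULTS)
    )
    female_fraction: float = 0.558
    age_mean: float = 48.9
    age_sd: float = 9.4
    mets_mean: float = 41.4
    mets_sd: float = 11.2
    smoking_rate: float = 0.082
    energy_mean: float = 2922.0
    energy_sd: float = 1134.0
    confounding: float = 0.0  # couples age (years per latent SD) to W
    intake_distribution: str = "lognormal"  # or "gamma"
    # components declared in the schema but never observed in the intake data
    # (the reference configuration has no supplement intake records)
    unobserved_components: tuple[str, ...] = ("dietary_supplements",)

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.latent_sd <= 0:
            raise ValueError("latent_sd must be positive")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.intake_distribution not in ("lognormal", "gamma"):
            raise ValueError(f"unknown intake distribution {self.intake_distribution!r}")
        bad = [k for k, v in self.scales.items() if v <= 0]
        if bad:
            raise ValueError(f"nonpositive scales for: {bad}")


@dataclass
class SyntheticTruth:
    """Ground truth stored alongside generated data, for tests only."""

    w: pd.Series  # latent factor per subject
    effects: dict[str, float]  # planted biomarker effect per latent SD
    loadings: dict[str, float]  # log-intake loading per item


@dataclass
class SyntheticCohort:
    intakes: pd.DataFrame
    phenotypes: pd.DataFrame
    truth: SyntheticTruth


def default_generator_config(n_subjects: int = 2000, seed: int = 0, **overrides) -> GeneratorConfig:
    """Default study conditions: 57 scored items + supplements, loadings
    proportional to the example coefficients (scale 0.35), log-scale 0.5."""
    schema = overrides.pop("schema", default_schema())
    table = example_coefficients(schema)
    loadings = {}
    locations = {}
    scales = {}
    for comp in schema:
        for item in comp.item_ids:
            loadings[item] = 0.35 * float(table.coefficient[comp.component_id])
            locations[item] = float(np.log(_ITEM_MEDIANS.get(item, 50.0)))
            scales[item] = 0.5
    cfg = GeneratorConfig(
        n_subjects=n_subjects,
        seed=seed,
        schema=schema,
        loadings=loadings,
        locations=locations,
        scales=scales,
        **overrides,
    )
    return cfg


def generate(config: GeneratorConfig) -> SyntheticCohort:
    """Draw one cohort; byte-identical for identical configs and seeds."""
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    subjects = pd.Index([f"S{i:05d}" for i in range(1, n + 1)], name="subject_id")
    w = rng.normal(0.0, config.latent_sd, n)
    w_std = w / config.latent_sd  # effects are per latent SD

    items = [
        i
        for c in config.schema
        if c.component_id not in config.unobserved_components
        for i in c.item_ids
    ]
    intake_cols: dict[str, np.ndarray] = {}
    for item in items:
        loading = config.loadings.get(item, 0.0)
        loc = config.locations.get(item, np.log(50.0))
        scale = config.scales.get(item, 0.5)
        log_mean = loc + loading * w_std
        if config.intake_distribution == "lognormal":
            intake_cols[item] = np.exp(log_mean + scale * rng.normal(size=n))
        else:  # gamma with matched median/log-dispersion
            shape = 1.0 / (np.expm1(scale**2)) if scale < 2 else 0.25
            mean = np.exp(log_mean + scale**2 / 2.0)
            intake_cols[item] = rng.gamma(shape, mean / shape, size=n)
    intakes = pd.DataFrame(intake_cols, index=subjects)

    sex = np.where(rng.random(n) < config.female_fraction, "female", "male")
    age = rng.normal(config.age_mean, config.age_sd, n) + config.confounding * w_std
    pheno = pd.DataFrame(index=subjects)
    pheno["age"] = np.clip(age, 35.0, 95.0)
    pheno["sex"] = sex
    pheno["mets_score"] = np.clip(rng.normal(config.mets_mean, config.mets_sd, n), 5.0, None)
    pheno["smoking"] = rng.random(n) < config.smoking_rate
    pheno["energy"] = np.clip(rng.normal(config.energy_mean, config.energy_sd, n), 800.0, None)

    bio: dict[str, np.ndarray] = {}
    for name, (baseline, effect, noise) in config.biomarkers.items():
        bio[name] = baseline + effect * w_std + noise * rng.normal(size=n)
    height = np.where(sex == "female", rng.normal(1.59, 0.06, n), rng.normal(1.72, 0.07, n))
    pheno["height"] = np.round(height, 3)
    bmi = np.clip(bio.pop("bmi"), 14.0, None)
    pheno["weight"] = np.round(bmi * height**2, 1)
    pp = np.clip(bio.pop("pulse_pressure"), 5.0, None)
    for name, vals in bio.items():
        pheno[name] = np.maximum(vals, 1.0)
    pheno["sbp"] = pheno["dbp"] + pp  # guarantees sbp > dbp

    truth = SyntheticTruth(
        w=pd.Series(w, index=subjects, name="latent_w"),
        effects={k: v[1] for k, v in config.biomarkers.items()},
        loadings=dict(config.loadings),
    )
    return SyntheticCohort(intakes=intakes, phenotypes=pheno, truth=truth)


# ---------------------------------------------------------------------------
# Deterministic micro-fixtures used throughout the test suite
# ---------------------------------------------------------------------------

def _fixture_two_subject_minimal() -> dict:
    schema = ComponentSchema(
        [
            Component("c1", "c1", "g/day"),
            Component("c2", "c2", "g/day"),
        ]
    )
    intakes = pd.DataFrame(
        {"c1": [4.0, 6.0], "c2": [10.0, 14.0]},
        index=pd.Index(["s1", "s2"], name="subject_id"),
    )
    table = CoefficientTable(pd.Series({"c1": 1.0, "c2": -0.5})).centralize()
    # hand arithmetic: pop stats c1: mean 5, sd sqrt(2); c2: mean 12, sd 2*sqrt(2)
    # z(s1) = (-1/sqrt2, -1/sqrt2), z(s2) = (+1/sqrt2, +1/sqrt2)
    # wdi_p(s1) = (-1/sqrt2*1.0 + -1/sqrt2*-0.5)/2 = -0.5/(2*sqrt2)
    v = 0.5 / (2.0 * np.sqrt(2.0))
    expected_wdi_p = pd.Series([-v, v], index=intakes.index)
    return {
        "schema": schema,
        "intakes": intakes,
        "coefficients": table,
        "expected_wdi_p": expected_wdi_p,
    }


# ATPIII criterion bits: (wc, tg, hdl, bp, fbg); subjects constructed so the
# same bits drive hand-derivable WHO and IDF labels (see values below).
_METS_BITS = [
    (0, 0, 0, 0, 0),
    (1, 0, 0, 0, 0), (0, 1, 0, 0, 0), (0, 0, 1, 0, 0), (0, 0, 0, 1, 0), (0, 0, 0, 0, 1),
    (1, 1, 0, 0, 0), (1, 0, 1, 0, 0), (1, 0, 0, 1, 0), (1, 0, 0, 0, 1), (0, 1, 1, 0, 0),
    (0, 1, 0, 1, 0), (0, 1, 0, 0, 1), (0, 0, 1, 1, 0), (0, 0, 1, 0, 1), (0, 0, 0, 1, 1),
    (1, 1, 1, 0, 0), (1, 1, 0, 1, 1), (0, 1, 1, 1, 1),
    (1, 1, 1, 1, 1),
]


def _fixture_mets_truth_table() -> dict:
    rows = []
    expected = []
    for i, (b_wc, b_tg, b_hdl, b_bp, b_fbg) in enumerate(_METS_BITS, start=1):
        rows.append(
            {
                "subject_id": f"m{i:02d}",
                "sex": "female",
                "age": 50.0,
                "wc": 95.0 if b_wc else 70.0,
                "hc": 100.0,
                "weight": 60.0,
                "height": 1.60,
                "tg": 200.0 if b_tg else 100.0,
                "hdl": 40.0 if b_hdl else 60.0,
                "sbp": 140.0 if b_bp else 110.0,
                "dbp": 90.0 if b_bp else 70.0,
                "fbg": 120.0 if b_fbg else 85.0,
            }
        )
        # hand-scored: ATPIII >= 3 of 5; IDF = central obesity (wc 95 >= 80)
        # AND >= 2 of the other four; WHO = glucose arm (fbg 120 >= 110) AND
        # >= 2 of {obesity via whr 0.95 > 0.85, dyslipidemia via tg,
        # bp 140/90}; hdl 40 is not < 39 so never triggers WHO dyslipidemia,
        # and bmi 60/1.6^2 = 23.4 never triggers WHO obesity.
        expected.append(
            {
                "subject_id": f"m{i:02d}",
                "atpiii": (b_wc + b_tg + b_hdl + b_bp + b_fbg) >= 3,
                "idf": bool(b_wc) and (b_tg + b_hdl + b_bp + b_fbg) >= 2,
                "who": bool(b_fbg) and (b_wc + b_tg + b_bp) >= 2,
            }
        )
    pheno = pd.DataFrame(rows).set_index("subject_id")
    exp = pd.DataFrame(expected).set_index("subject_id")
    return {"phenotypes": pheno, "expected": exp}


def _fixture_tied_scores() -> dict:
    scores = pd.Series(
        [0.1, 0.1, 0.3, 0.3, 0.3, 0.5, 0.5, 0.8],
        index=pd.Index([f"t{i}" for i in range(8)], name="subject_id"),
    )
    labels = pd.Series([0, 0, 0, 1, 0, 1, 1, 1], index=scores.index)
    return {"scores": scores, "labels": labels}


FIXTURES = {
    "two_subject_minimal": _fixture_two_subject_minimal,
    "mets_truth_table": _fixture_mets_truth_table,
    "tied_scores": _fixture_tied_scores,
}


def make_fixture(name: str) -> dict:
    """Return one of the registered deterministic micro-fixtures."""
    try:
        builder = FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None
    return builder()
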