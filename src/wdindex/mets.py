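"""Rule-based metabolic-syndrome (MetS) classification.

Implements derived anthropometric/hemodynamic measures (BMI, waist-to-hip
ratio, mean arterial pressure) and configurable rule sets for the three
standard MetS definitions:

* **WHO (1999)** — mandatory glucose-dysregulation arm plus at least two of
  obesity, dyslipidemia, and raised blood pressure.  The insulin-resistance
  arm is approximated by a fasting-glucose threshold (>= 110 mg/dL) because
  insulin/HOMA measurements are not part of the phenotype table; this is a
  deliberate approximation and is configurable.
* **NCEP ATP III** — any 3 of 5: raised waist circumference, triglycerides,
  low HDL-c, raised blood pressure, raised fasting glucose (>= 100 mg/dL per
  the updated criterion).
* **IDF (2006)** — mandatory central obesity (sex-specific waist cutoffs)
  plus at least two of the remaining four criteria.

Every threshold is configurable; the defaults below follow the published
definitions.  Thresholds compare with ">=" for "raised" criteria and "<" for
"low HDL" unless a rule overrides the operator.  A subject missing any input
needed by an evaluated criterion gets a missing label with the reason
recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Clause",
    "Criterion",
    "MetSRuleSet",
    "default_rulesets",
    "derive_measures",
    "classify",
    "classify_cohort",
    "prevalence",
]

_OPS = {
    "ge": lambda x, t: x >= t,
    "gt": lambda x, t: x > t,
    "le": lambda x, t: x <= t,
    "lt": lambda x, t: x < t,
}


@dataclass(frozen=True)
class Clause:
    """One comparison: ``variable op threshold``, threshold optionally sex-specific."""

    variable: str
    op: str
    threshold: float | Mapping[str, float]

    def resolve_threshold(self, sex: str) -> float:
        if isinstance(self.threshold, Mapping):
            try:
                return float(self.threshold[sex])
            except KeyError:
                raise ValueError(f"no threshold for sex {sex!r} on {self.variable}") from None
        return float(self.threshold)

    def evaluate(self, row: Mapping[str, float], sex: str) -> bool | None:
        value = row.get(self.variable)
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return None
        return bool(_OPS[self.op](float(value), self.resolve_threshold(sex)))


@dataclass(frozen=True)
class Criterion:
    """A diagnostic criterion: satisfied if ANY of its clauses holds.

    Blood-pressure criteria are the canonical multi-clause case
    (SBP >= 130 OR DBP >= 85).
    """

    name: str
    clauses: tuple[Clause, ...]

    def evaluate(self, row: Mapping[str, float], sex: str) -> bool | None:
        results = [c.evaluate(row, sex) for c in self.clauses]
        if any(r is True for r in results):
            return True
        if any(r is None for r in results):
            return None  # cannot rule the criterion in or out
        return False


@dataclass(frozen=True)
class MetSRuleSet:
    """One MetS definition: criteria, an optional mandatory criterion, and the
    minimum number of *non-mandatory* criteria that must also be met."""

    definition: str
    criteria: tuple[Criterion, ...]
    mandatory: str | None
    min_criteria: int

    def __post_init__(self) -> None:
        if self.min_criteria < 1:
            raise ValueError("min_criteria must be >= 1")
        names = [c.name for c in self.criteria]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate criterion names in {self.definition}")
        if self.mandatory is not None and self.mandatory not in names:
            raise ValueError(f"mandatory criterion {self.mandatory!r} not defined")

    def to_dict(self) -> dict:
        return {
            "definition": self.definition,
            "mandatory": self.mandatory,
            "min_criteria": self.min_criteria,
            "criteria": [
                {
                    "name": c.name,
                    "clauses": [
                        {
                            "variable": cl.variable,
                            "op": cl.op,
                            "threshold": dict(cl.threshold)
                            if isinstance(cl.threshold, Mapping)
                            else cl.threshold,
                        }
                        for cl in c.clauses
                    ],
                }
                for c in self.criteria
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MetSRuleSet":
        criteria = tuple(
            Criterion(
                name=c["name"],
                clauses=tuple(
                    Clause(cl["variable"], cl["op"], cl["threshold"]) for cl in c["clauses"]
                ),
            )
            for c in d["criteria"]
        )
        return cls(
            definition=d["definition"],
            criteria=criteria,
            mandatory=d.get("mandatory"),
            min_criteria=int(d["min_criteria"]),
        )


def _sexed(female: float, male: float) -> dict[str, float]:
    return {"female": female, "male": male}


def default_rulesets() -> dict[str, MetSRuleSet]:
    """The three shipped rule sets (WHO 1999, NCEP ATP III updated, IDF 2006)."""
    bp_130_85 = Criterion(
        "raised_bp", (Clause("sbp", "ge", 130.0), Clause("dbp", "ge", 85.0))
    )
    tg_150 = Criterion("raised_tg", (Clause("tg", "ge", 150.0),))
    low_hdl = Criterion(
        "low_hdl", (Clause("hdl", "lt", _sexed(female=50.0, male=40.0)),)
    )
    fbg_100 = Criterion("raised_fbg", (Clause("fbg", "ge", 100.0),))

    who = MetSRuleSet(
        definition="WHO",
        criteria=(
            # glucose-dysregulation arm: FBG proxy for insulin resistance
            Criterion("glucose_dysregulation", (Clause("fbg", "ge", 110.0),)),
            Criterion(
                "obesity",
                (
                    Clause("bmi", "gt", 30.0),
                    Clause("whr", "gt", _sexed(female=0.85, male=0.90)),
                ),
            ),
            Criterion(
                "dyslipidemia",
                (
                    Clause("tg", "ge", 150.0),
                    Clause("hdl", "lt", _sexed(female=39.0, male=35.0)),
                ),
            ),
            Criterion(
                "raised_bp_140_90",
                (Clause("sbp", "ge", 140.0), Clause("dbp", "ge", 90.0)),
            ),
        ),
        mandatory="glucose_dysregulation",
        min_criteria=2,
    )

    atpiii = MetSRuleSet(
        definition="ATPIII",
        criteria=(
            Criterion(
                "raised_wc", (Clause("wc", "gt", _sexed(female=88.0, male=102.0)),)
            ),
            tg_150,
            low_hdl,
            bp_130_85,
            fbg_100,
        ),
        mandatory=None,
        min_criteria=3,
    )

    idf = MetSRuleSet(
        definition="IDF",
        criteria=(
            Criterion(
                "central_obesity", (Clause("wc", "ge", _sexed(female=80.0, male=94.0)),)
            ),
            tg_150,
            low_hdl,
            bp_130_85,
            fbg_100,
        ),
        mandatory="central_obesity",
        min_criteria=2,
    )
    return {"WHO": who, "ATPIII": atpiii, "IDF": idf}


def derive_measures(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Add derived columns: bmi = weight/height^2 (kg/m^2), whr = wc/hc, and
    mean arterial pressure map = dbp + (sbp - dbp)/3 (mmHg).

    Columns already present are left untouched; derivation is skipped (NaN)
    where inputs are missing.  Nonpositive height or hip circumference is an
    error.
    """
    out = phenotypes.copy()
    if "bmi" not in out.columns and {"weight", "height"} <= set(out.columns):
        if (out["height"] <= 0).any():
            raise ValueError("nonpositive height")
        out["bmi"] = out["weight"] / out["height"] ** 2
    if "whr" not in out.columns and {"wc", "hc"} <= set(out.columns):
        if (out["hc"] <= 0).any():
            raise ValueError("nonpositive hip circumference")
        out["whr"] = out["wc"] / out["hc"]
    if "map" not in out.columns and {"sbp", "dbp"} <= set(out.columns):
        out["map"] = out["dbp"] + (out["sbp"] - out["dbp"]) / 3.0
    return out


def classify(row: Mapping[str, float], sex: str, rules: MetSRuleSet) -> dict:
    """Classify one subject; returns label (True/False/None) plus the
    per-criterion breakdown and, when the label is missing, the reason."""
    breakdown: dict[str, bool | None] = {}
    for crit in rules.criteria:
        breakdown[crit.name] = crit.evaluate(row, sex)

    others = [c.name for c in rules.criteria if c.name != rules.mandatory]
    label: bool | None
    reason = None
    if rules.mandatory is not None and breakdown[rules.mandatory] is False:
        label = False  # mandatory criterion decidedly unmet
    else:
        met = sum(1 for n in others if breakdown[n] is True)
        unknown = [n for n in others if breakdown[n] is None]
        mandatory_unknown = (
            rules.mandatory is not None and breakdown[rules.mandatory] is None
        )
        if met >= rules.min_criteria and not mandatory_unknown:
            label = True
        elif unknown or mandatory_unknown:
            label = None
            missing = unknown + ([rules.mandatory] if mandatory_unknown else [])
            reason = f"undecidable criteria: {missing}"
        else:
            label = False
    return {"label": label, "breakdown": breakdown, "reason": reason}


def classify_cohort(
    phenotypes: pd.DataFrame,
    rulesets: Mapping[str, MetSRuleSet] | None = None,
) -> pd.DataFrame:
    """Classify every subject under every rule set.

    Returns a DataFrame indexed like ``phenotypes`` with one nullable-boolean
    label column per definition (lowercased name) plus per-criterion boolean
    columns ``<definition>__<criterion>``.  Derived measures are computed on
    the fly if absent.
    """
    if rulesets is None:
        rulesets = default_rulesets()
    pheno = derive_measures(phenotypes)
    if "sex" not in pheno.columns:
        raise ValueError("phenotype table needs a 'sex' column")
    out = pd.DataFrame(index=pheno.index)
    records = pheno.to_dict("index")
    for name, rules in rulesets.items():
        labels = []
        crit_cols: dict[str, list] = {c.name: [] for c in rules.criteria}
        for sid in pheno.index:
            row = records[sid]
            res = classify(row, str(row["sex"]), rules)
            labels.append(res["label"])
            for cname, val in res["breakdown"].items():
                crit_cols[cname].append(val)
        key = name.lower()
        out[key] = pd.array(labels, dtype="boolean")
        for cname, vals in crit_cols.items():
            out[f"{key}__{cname}"] = pd.array(vals, dtype="boolean")
    return out


def prevalence(labels: pd.Series) -> dict:
    """Counts and percentage of positives among non-missing labels.

    The percentage is rounded to one decimal, matching conventional
    prevalence reporting.
    """
    valid = labels.dropna()
    if valid.empty:
        raise ValueError("no non-missing labels")
    n_yes = int(valid.astype(bool).sum())
    n_no = int(len(valid) - n_yes)
    return {
        "n_yes": n_yes,
        "n_no": n_no,
        "n": int(len(valid)),
        "pct": round(100.0 * n_yes / len(valid), 1),
    }
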