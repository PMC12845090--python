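"""Validation battery for the diet-index scores.

Group comparisons (Welch t-test), crude/adjusted logistic and linear
association models (delegated to statsmodels), ROC analysis with the
nonparametric trapezoidal / Wilcoxon-Mann-Whitney AUC and Youden's-index
cutoff (implemented here via the rank statistic), and two-cluster k-means
construct validation (scikit-learn), plus a report builder that assembles
the whole battery for a cohort.

Orientation convention: higher index scores mean lower adherence to the
Westernized pattern and are therefore *protective* for metabolic outcomes;
ROC analysis negates the score when needed so that the reported AUC is
>= 0.5, and records which orientation was used.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.cluster import KMeans

from .schema import ScoreSet
from . import scoring

__all__ = [
    "ModelSpec",
    "AssociationResult",
    "RocResult",
    "ClusterResult",
    "ADJUSTMENT_SETS",
    "DEFAULT_BIOMARKER_PANEL",
    "compare_groups",
    "fit_association",
    "roc_auc",
    "youden_cutoff",
    "kmeans_two",
    "build_report",
]

# covariate sets for crude / age-sex / fully adjusted models
ADJUSTMENT_SETS: dict[str, tuple[str, ...]] = {
    "crude": (),
    "age_sex": ("age", "sex"),
    "full": ("age", "sex", "mets_score", "smoking", "energy"),
}

DEFAULT_BIOMARKER_PANEL = ("wc", "dbp", "sbp", "fbg", "tg", "chol", "ldl", "hdl")


@dataclass(frozen=True)
class ModelSpec:
    """One association model: outcome ~ exposure (+ covariates)."""

    outcome: str
    exposure: str
    covariates: str = "crude"  # key into ADJUSTMENT_SETS
    family: str = "logistic"  # "logistic" | "linear"

    def covariate_names(self) -> tuple[str, ...]:
        try:
            return ADJUSTMENT_SETS[self.covariates]
        except KeyError:
            raise ValueError(f"unknown adjustment set {self.covariates!r}") from None


@dataclass(frozen=True)
class AssociationResult:
    """Estimate with Wald 95% CI; OR scale for logistic, slope for linear."""

    estimate: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    family: str

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "n": self.n,
            "family": self.family,
        }


@dataclass(frozen=True)
class RocResult:
    auc: float
    cutoff: float | None
    j: float | None
    sens: float | None
    spec: float | None
    orientation: str  # "as_is" | "negated"

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "cutoff": self.cutoff,
            "j": self.j,
            "sens": self.sens,
            "spec": self.spec,
            "orientation": self.orientation,
        }


@dataclass
class ClusterResult:
    labels: pd.Series  # "healthy" / "unhealthy" per subject
    centers: pd.DataFrame  # original-scale biomarker means per cluster
    naming_rule: str
    inertia: float


def compare_groups(values: pd.Series, group_labels: pd.Series) -> dict:
    """Per-group mean +/- SD and a two-sided Welch (unequal-variance) t-test."""
    df = pd.DataFrame({"value": values, "group": group_labels}).dropna()
    groups = df["group"].unique()
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(groups)}")
    a = df.loc[df["group"] == groups[0], "value"]
    b = df.loc[df["group"] == groups[1], "value"]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return {
        "groups": {
            str(groups[0]): {"n": int(len(a)), "mean": float(a.mean()), "sd": float(a.std(ddof=1))},
            str(groups[1]): {"n": int(len(b)), "mean": float(b.mean()), "sd": float(b.std(ddof=1))},
        },
        "t": float(t),
        "p": float(p),
    }


def _design(data: pd.DataFrame, spec: ModelSpec) -> tuple[pd.Series, pd.DataFrame]:
    cols = [spec.outcome, spec.exposure, *spec.covariate_names()]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    sub = data[cols].copy()
    # encode common categorical covariates numerically
    for c in sub.columns:
        if sub[c].dtype == object or isinstance(sub[c].dtype, pd.CategoricalDtype):
            codes, _ = pd.factorize(sub[c], sort=True)
            sub[c] = np.where(codes < 0, np.nan, codes).astype(float)
        elif sub[c].dtype == bool or str(sub[c].dtype) == "boolean":
            sub[c] = sub[c].astype("float64")
    sub = sub.dropna()  # complete-case analysis
    y = sub[spec.outcome]
    X = sm.add_constant(sub[[spec.exposure, *spec.covariate_names()]], has_constant="add")
    return y, X


def fit_association(data: pd.DataFrame, spec: ModelSpec) -> AssociationResult:
    """Fit one crude/adjusted association model and extract the exposure term.

    Logistic models report the odds ratio with the Wald 95% CI exponentiated
    from the link scale; linear models report the slope.  Fitting is delegated
    to statsmodels; complete cases only, with n reported.
    """
    y, X = _design(data, spec)
    n = len(y)
    if n == 0:
        raise ValueError("no complete cases")
    if spec.family == "logistic":
        uniq = set(pd.unique(y))
        if not uniq <= {0, 1, 0.0, 1.0, True, False}:
            raise ValueError(f"logistic outcome must be binary, got values {sorted(uniq)[:5]}")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y.astype(float), X).fit(disp=0)
        except Exception as exc:  # singular design / perfect separation
            raise ValueError(f"logistic fit failed ({exc})") from exc
        if not np.all(np.isfinite(fit.bse)):
            raise ValueError("logistic fit unstable (separation or singular design)")
        beta = fit.params[spec.exposure]
        lo, hi = fit.conf_int().loc[spec.exposure]
        return AssociationResult(
            estimate=float(np.exp(beta)),
            ci_low=float(np.exp(lo)),
            ci_high=float(np.exp(hi)),
            p=float(fit.pvalues[spec.exposure]),
            n=n,
            family="logistic",
        )
    elif spec.family == "linear":
        fit = sm.OLS(y.astype(float), X).fit()
        if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
            raise ValueError("singular design matrix")
        lo, hi = fit.conf_int().loc[spec.exposure]
        return AssociationResult(
            estimate=float(fit.params[spec.exposure]),
            ci_low=float(lo),
            ci_high=float(hi),
            p=float(fit.pvalues[spec.exposure]),
            n=n,
            family="linear",
        )
    raise ValueError(f"unknown family {spec.family!r}")


def _check_binary(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"need both classes present, got {classes}")
    return labels == classes.max(), labels == classes.min()


def _auc_rank(scores: np.ndarray, case: np.ndarray) -> float:
    """Wilcoxon-Mann-Whitney AUC: P(case > control) + 0.5 P(tie), via ranks.

    Equals the trapezoidal area under the empirical ROC curve.
    """
    ranks = stats.rankdata(scores)
    n1 = int(case.sum())
    n0 = len(scores) - n1
    u = ranks[case].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_auc(scores: pd.Series | np.ndarray, labels: pd.Series | np.ndarray) -> RocResult:
    """Nonparametric AUC with orientation handling (reported AUC >= 0.5)."""
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels)
    mask = ~np.isnan(s)
    s, lab = s[mask], lab[mask]
    case, _ = _check_binary(lab)
    auc = _auc_rank(s, case)
    orientation = "as_is"
    if auc < 0.5:
        auc, orientation = 1.0 - auc, "negated"
    return RocResult(auc=auc, cutoff=None, j=None, sens=None, spec=None, orientation=orientation)


def youden_cutoff(scores: pd.Series | np.ndarray, labels: pd.Series | np.ndarray) -> RocResult:
    """Optimal cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Thresholds are taken midway between consecutive distinct scores (on the
    oriented scale); subjects at or above the cutoff are called positive; ties
    in J resolve to the smallest cutoff.  The returned cutoff is on the
    oriented scale (negated scores when orientation == "negated").
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels)
    mask = ~np.isnan(s)
    s, lab = s[mask], lab[mask]
    case, _ = _check_binary(lab)
    base = roc_auc(s, lab)
    oriented = -s if base.orientation == "negated" else s

    distinct = np.unique(oriented)
    if len(distinct) == 1:
        # degenerate: everyone on one side of any threshold
        cut = float(distinct[0])
        sens, spec = 1.0, 0.0
        return RocResult(base.auc, cut, sens + spec - 1.0, sens, spec, base.orientation)
    cuts = (distinct[:-1] + distinct[1:]) / 2.0
    n1 = case.sum()
    n0 = (~case).sum()
    best = None
    for cut in cuts:  # exhaustive scan over all distinct thresholds
        pred = oriented >= cut
        sens = float((pred & case).sum() / n1)
        spec = float((~pred & ~case).sum() / n0)
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, float(cut), sens, spec)
    j, cut, sens, spec = best
    return RocResult(base.auc, cut, j, sens, spec, base.orientation)


def kmeans_two(
    biomarkers: pd.DataFrame,
    seed: int,
    n_restarts: int = 10,
    naming_column: str = "tg",
) -> ClusterResult:
    """Two-cluster k-means on z-standardized biomarker columns.

    The cluster with the higher triglyceride center (configurable via
    ``naming_column``) is labeled "unhealthy"; centers are reported on the
    original measurement scale.
    """
    if biomarkers.isna().any().any():
        raise ValueError("biomarker matrix must have no missing values")
    if len(biomarkers) < 2:
        raise ValueError("need at least 2 subjects for 2 clusters")
    if naming_column not in biomarkers.columns:
        raise ValueError(f"naming column {naming_column!r} not in biomarker panel")
    mu = biomarkers.mean()
    sd = biomarkers.std(ddof=1)
    if (sd <= 0).all():
        raise ValueError("degenerate biomarker matrix: all columns constant")
    keep = sd.index[sd > 0]
    dropped = [c for c in biomarkers.columns if c not in keep]
    if dropped:
        warnings.warn(f"constant biomarker columns dropped before clustering: {dropped}")
    X = ((biomarkers[keep] - mu[keep]) / sd[keep]).to_numpy()
    km = KMeans(n_clusters=2, n_init=n_restarts, random_state=seed, algorithm="lloyd")
    raw = km.fit_predict(X)
    centers_z = pd.DataFrame(km.cluster_centers_, columns=keep)
    centers = centers_z * sd[keep] + mu[keep]
    if naming_column in centers.columns:
        unhealthy = int(centers[naming_column].idxmax())
    else:  # naming column was constant; fall back to first retained column
        unhealthy = int(centers[keep[0]].idxmax())
    names = {unhealthy: "unhealthy", 1 - unhealthy: "healthy"}
    labels = pd.Series([names[k] for k in raw], index=biomarkers.index, name="cluster")
    centers.index = [names[i] for i in centers.index]
    return ClusterResult(
        labels=labels,
        centers=centers.sort_index(),
        naming_rule=f"highest_{naming_column}_center",
        inertia=float(km.inertia_),
    )


def _config_hash(config: Mapping) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def build_report(
    scores: ScoreSet,
    mets_labels: pd.DataFrame,
    phenotypes: pd.DataFrame,
    config: Mapping | None = None,
    biomarkers: Sequence[str] = ("fbg", "tg", "sbp", "dbp", "map", "wc", "chol", "ldl", "hdl"),
    adjustments: Sequence[str] = ("crude", "age_sex", "full"),
    cluster_seed: int = 0,
) -> dict:
    """Assemble the full validation battery into a JSON-serializable report.

    Sections: per-variant range summaries; group comparisons by MetS status;
    OR grids (variant x definition x adjustment); linear-beta grids
    (variant x biomarker x adjustment) with per-10%-of-range effect
    conversions; ROC/Youden per variant-definition pair; and the two-cluster
    comparison.  Subject ids of all three tables must align.
    """
    config = dict(config or {})
    orphans = scores.subject_ids.symmetric_difference(phenotypes.index)
    orphans = orphans.union(scores.subject_ids.symmetric_difference(mets_labels.index))
    if len(orphans):
        raise ValueError(f"subject id mismatch across inputs: {list(orphans)[:10]}")
    pheno = phenotypes.copy()
    from .mets import derive_measures  # local import to avoid cycle at module load

    pheno = derive_measures(pheno)
    definitions = [c for c in mets_labels.columns if "__" not in c]
    variants = list(scores.scores.columns)

    report: dict = {
        "config_hash": _config_hash(config),
        "config": config,
        "divisors": scores.divisors,
        "n_subjects": int(len(scores.subject_ids)),
        "ranges": {},
        "group_comparisons": {},
        "logistic": {},
        "linear": {},
        "effects_per_10pct": {},
        "roc": {},
        "clusters": {},
        "prevalence": {},
    }

    spans: dict[str, float] = {}
    for v in variants:
        rs = scoring.summarize_range(scores[v], v)
        spans[v] = rs.span
        report["ranges"][v] = {
            "min": round(rs.min, 4),
            "max": round(rs.max, 4),
            "span": round(rs.span, 4),
            "mean": round(rs.mean, 4),
            "sd": round(rs.sd, 4),
        }

    from .mets import prevalence as _prevalence

    merged = pd.concat([scores.scores, pheno, mets_labels[definitions]], axis=1)

    for d in definitions:
        lab = mets_labels[d]
        report["prevalence"][d] = _prevalence(lab)
        report["group_comparisons"][d] = {}
        grp = lab.map({True: "yes", False: "no"})
        for v in variants:
            try:
                report["group_comparisons"][d][v] = compare_groups(scores[v], grp)
            except ValueError as exc:
                report["group_comparisons"][d][v] = {"error": str(exc)}

    for v in variants:
        report["logistic"][v] = {}
        for d in definitions:
            report["logistic"][v][d] = {}
            for adj in adjustments:
                data = merged.assign(_y=mets_labels[d].astype("float64"))
                spec = ModelSpec("_y", v, adj, "logistic")
                try:
                    report["logistic"][v][d][adj] = fit_association(data, spec).to_dict()
                except ValueError as exc:
                    report["logistic"][v][d][adj] = {"error": str(exc)}

    usable_biomarkers = [b for b in biomarkers if b in pheno.columns]
    for v in variants:
        report["linear"][v] = {}
        report["effects_per_10pct"][v] = {}
        for b in usable_biomarkers:
            report["linear"][v][b] = {}
            for adj in adjustments:
                spec = ModelSpec(b, v, adj, "linear")
                try:
                    res = fit_association(merged, spec)
                    report["linear"][v][b][adj] = res.to_dict()
                    if adj == "full" and spans[v] > 0:
                        report["effects_per_10pct"][v][b] = scoring.effect_per_range_fraction(
                            res.estimate, spans[v], 0.1
                        )
                except ValueError as exc:
                    report["linear"][v][b][adj] = {"error": str(exc)}

    for v in variants:
        report["roc"][v] = {}
        for d in definitions:
            lab = mets_labels[d].dropna()
            sc = scores[v].reindex(lab.index)
            try:
                report["roc"][v][d] = youden_cutoff(sc, lab.astype(bool)).to_dict()
            except ValueError as exc:
                report["roc"][v][d] = {"error": str(exc)}

    panel = [b for b in DEFAULT_BIOMARKER_PANEL if b in pheno.columns]
    cluster_data = pheno[panel].dropna()
    if len(cluster_data) >= 2 and panel:
        cl = kmeans_two(cluster_data, seed=cluster_seed)
        report["clusters"] = {
            "n": int(len(cl.labels)),
            "sizes": cl.labels.value_counts().to_dict(),
            "naming_rule": cl.naming_rule,
            "centers": {k: {c: round(float(x), 4) for c, x in row.items()}
                        for k, row in cl.centers.iterrows()},
            "wdi_by_cluster": {},
        }
        for v in variants:
            try:
                report["clusters"]["wdi_by_cluster"][v] = compare_groups(
                    scores[v].reindex(cl.labels.index), cl.labels
                )
            except ValueError as exc:
                report["clusters"]["wdi_by_cluster"][v] = {"error": str(exc)}
    return report
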