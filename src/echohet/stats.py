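"""Cohort-level diagnostic statistics.

Implements the analysis block run on patient-level heterogeneity scores:

* one-way ANOVA across pathological groups with Tukey's HSD post-hoc test
  (Tukey-Kramer for unequal group sizes) and partial eta squared as effect
  size, banded at the conventional 0.01 / 0.06 / 0.14 cut points;
* Pearson (degree-1 polynomial) correlation between scores and an ordinal
  grade coding of the combined Bethesda/pathology categories;
* empirical ROC analysis: AUROC, Youden-optimal cutoff with the rule
  "positive if score >= cutoff" (ties broken toward the smallest such
  threshold), a DeLong 95% CI and z-test p-value, and the confusion-table
  metrics sensitivity / specificity / PPV / NPV / diagnostic accuracy, each
  kept as raw counts so rounding never propagates.

The cohort container is a plain pandas DataFrame with columns
``patient_id``, ``group``, ``grade_code`` and ``score_pct``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from .errors import CohortError

logger = logging.getLogger(__name__)

#: The five-level combined Bethesda/surgical-pathology grouping, ordered by
#: increasing degree of malignancy, and its default ordinal coding.
GROUP_ORDER = ["normal", "II-B", "III-B", "III-M", "V/VI-M"]
DEFAULT_GRADE_CODING: dict[str, int] = {g: i for i, g in enumerate(GROUP_ORDER)}

#: The six benign-vs-malignant pooled comparisons reported by the tool.
DEFAULT_COMPARISONS: list[tuple[str, tuple[str, ...], tuple[str, ...]]] = [
    ("III-B vs. III-M", ("III-B",), ("III-M",)),
    ("III-B vs. III-M/V&VI-M", ("III-B",), ("III-M", "V/VI-M")),
    ("II-B/III-B vs. III-M", ("II-B", "III-B"), ("III-M",)),
    ("II-B/III-B vs. III-M/V&VI-M", ("II-B", "III-B"), ("III-M", "V/VI-M")),
    ("Normal/II-B/III-B vs. III-M", ("normal", "II-B", "III-B"), ("III-M",)),
    (
        "Normal/II-B/III-B vs. III-M/V&VI-M",
        ("normal", "II-B", "III-B"),
        ("III-M", "V/VI-M"),
    ),
]

COHORT_COLUMNS = ["patient_id", "group", "grade_code", "score_pct"]


def make_cohort(
    df: pd.DataFrame, grade_coding: Mapping[str, int] | None = None
) -> pd.DataFrame:
    """Validate (and complete) a cohort table.

    Requires ``patient_id``, ``group`` and ``score_pct`` columns; fills
    ``grade_code`` from the coding map if absent and checks the invariants
    (unique patients, non-negative scores, codes consistent with groups).
    """
    coding = dict(grade_coding or DEFAULT_GRADE_CODING)
    df = df.copy()
    missing = {"patient_id", "group", "score_pct"} - set(df.columns)
    if missing:
        raise CohortError(f"cohort table missing columns {sorted(missing)}")
    unknown = set(df["group"]) - set(coding)
    if unknown:
        raise CohortError(
            f"unknown group labels {sorted(unknown)}; valid labels: {sorted(coding)}"
        )
    if "grade_code" not in df.columns:
        df["grade_code"] = df["group"].map(coding)
    elif not (df["grade_code"] == df["group"].map(coding)).all():
        raise CohortError("grade_code column inconsistent with the grade coding")
    if df["patient_id"].duplicated().any():
        raise CohortError("patient_id values must be unique")
    if (df["score_pct"] < 0).any():
        raise CohortError("score_pct must be non-negative")
    return df[COHORT_COLUMNS]


def load_cohort(
    path, grade_coding: Mapping[str, int] | None = None
) -> pd.DataFrame:
    return make_cohort(pd.read_csv(path), grade_coding)


# ---------------------------------------------------------------------------
# ANOVA + Tukey + effect size
# ---------------------------------------------------------------------------


EFFECT_BANDS = ((0.01, "negligible"), (0.06, "small"), (0.14, "medium"))


def effect_band(eta_sq: float) -> str:
    for cut, name in EFFECT_BANDS:
        if eta_sq < cut:
            return name
    return "large"


@dataclass(frozen=True)
class TukeyPair:
    group_a: str
    group_b: str
    mean_diff: float  # mean(b) - mean(a)
    p_adj: float


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p: float
    eta_sq: float
    effect_band: str
    tukey: tuple[TukeyPair, ...]
    df_between: int
    df_within: int


def one_way_anova(
    groups: Sequence[Sequence[float]], names: Sequence[str] | None = None
) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA with Tukey HSD post-hoc.

    Partial eta squared is ``SS_between / (SS_between + SS_within)`` (for a
    one-way design this equals plain eta squared).  Tukey adjusted p-values
    come from the studentized range distribution with the Tukey-Kramer
    standard error for unequal group sizes.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise CohortError("ANOVA needs at least 2 groups")
    if any(len(a) < 2 for a in arrays):
        raise CohortError("every group needs at least 2 observations")
    if names is None:
        names = [f"group{i}" for i in range(len(arrays))]

    k = len(arrays)
    ns = np.array([len(a) for a in arrays])
    means = np.array([a.mean() for a in arrays])
    n_total = int(ns.sum())
    grand = float(np.concatenate(arrays).mean())

    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((a - m) ** 2).sum() for a, m in zip(arrays, means)))
    df_b, df_w = k - 1, n_total - k
    ms_w = ss_within / df_w

    if ms_w > 0:
        F = (ss_between / df_b) / ms_w
        p = float(sps.f.sf(F, df_b, df_w))
    else:
        F = 0.0 if ss_between == 0 else float("inf")
        p = 1.0 if ss_between == 0 else 0.0
    total = ss_between + ss_within
    eta_sq = ss_between / total if total > 0 else 0.0

    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(ms_w / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            diff = means[j] - means[i]
            if se == 0.0:
                p_adj = 1.0 if diff == 0 else 0.0
            else:
                q = abs(diff) / se
                p_adj = float(
                    np.clip(sps.studentized_range.sf(q, k, df_w), 0.0, 1.0)
                )
            pairs.append(TukeyPair(names[i], names[j], float(diff), p_adj))

    return AnovaResult(
        F=float(F),
        p=p,
        eta_sq=eta_sq,
        effect_band=effect_band(eta_sq),
        tukey=tuple(pairs),
        df_between=df_b,
        df_within=df_w,
    )


# ---------------------------------------------------------------------------
# Grade correlation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


def grade_correlation(cohort: pd.DataFrame) -> CorrelationResult:
    """Pearson correlation between scores and the ordinal grade code.

    The grade enters as a degree-1 polynomial of its integer code; p is the
    two-sided value from the t transform with n - 2 degrees of freedom.
    """
    x = cohort["grade_code"].to_numpy(dtype=float)
    y = cohort["score_pct"].to_numpy(dtype=float)
    n = len(x)
    if n < 3:
        raise CohortError("correlation needs at least 3 patients")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise CohortError("correlation undefined: constant grades or scores")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return CorrelationResult(r=float(np.sign(r)), p=0.0, n=n)
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return CorrelationResult(r=r, p=p, n=n)


# ---------------------------------------------------------------------------
# ROC analysis
# ---------------------------------------------------------------------------


def _check_binary(scores: np.ndarray, labels: np.ndarray) -> None:
    if scores.shape != labels.shape:
        raise CohortError("scores and labels must have equal length")
    if labels.all() or not labels.any():
        raise CohortError("both classes must be present for ROC analysis")


def auroc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Empirical AUROC: P(score_pos > score_neg) + 0.5 P(tie)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    _check_binary(s, y)
    return float(roc_auc_score(y, s))


def _midranks(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    ranks = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        ranks[i:j] = 0.5 * (i + j - 1) + 1.0
        i = j
    out = np.empty(n)
    out[order] = ranks
    return out


def delong_auc_variance(
    pos: np.ndarray, neg: np.ndarray
) -> tuple[float, float]:
    """AUROC and its DeLong variance from the positive/negative score lists.

    Uses the midrank formulation (Sun & Xu) of DeLong's structural
    components: var = S10/m + S01/n with sample variances of the per-case
    placement values.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    m, n = len(pos), len(neg)
    tz = _midranks(np.concatenate([pos, neg]))
    tx = _midranks(pos)
    ty = _midranks(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    s10 = float(v10.var(ddof=1)) if m > 1 else 0.0
    s01 = float(v01.var(ddof=1)) if n > 1 else 0.0
    return float(auc), s10 / m + s01 / n


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fn < 1 or self.tn + self.fp < 1:
            raise ValueError("both classes must contribute at least one case")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class Metric:
    """One diagnostic metric as a raw fraction; ``pct`` is None when the
    denominator is zero (metric undefined)."""

    numerator: int
    denominator: int

    @property
    def pct(self) -> float | None:
        if self.denominator == 0:
            return None
        return 100.0 * self.numerator / self.denominator

    def __str__(self) -> str:
        if self.pct is None:
            return f"undefined (0/{self.denominator})"
        return f"{self.pct:.1f} ({self.numerator}/{self.denominator})"


@dataclass(frozen=True)
class ConfusionMetrics:
    sensitivity: Metric
    specificity: Metric
    ppv: Metric
    npv: Metric
    da: Metric  # diagnostic accuracy = (TP+TN)/(TP+FP+TN+FN)


def confusion_metrics(table: ConfusionTable) -> ConfusionMetrics:
    """Diagnostic metrics from raw counts; percentages are exact fractions
    and are only rounded at display time."""
    return ConfusionMetrics(
        sensitivity=Metric(table.tp, table.tp + table.fn),
        specificity=Metric(table.tn, table.tn + table.fp),
        ppv=Metric(table.tp, table.tp + table.fp),
        npv=Metric(table.tn, table.tn + table.fn),
        da=Metric(table.tp + table.tn, table.total),
    )


@dataclass(frozen=True)
class ROCResult:
    auroc: float
    ci95: tuple[float, float]
    cutoff: float
    youden_j: float
    confusion: ConfusionTable
    metrics: ConfusionMetrics
    p_value: float
    n_pos: int
    n_neg: int


def select_cutoff(
    scores: Sequence[float], labels: Sequence[bool]
) -> ROCResult:
    """Full ROC analysis with a Youden-optimal operating point.

    The cutoff maximizes J = sensitivity + specificity - 1 over the observed
    scores with the rule "positive if score >= cutoff"; ties are broken
    toward the smallest such threshold.  The 95% CI and the p-value of the
    AUROC (against the chance value 0.5, two-sided z-test) use DeLong's
    variance estimate.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    _check_binary(s, y)
    pos, neg = s[y], s[~y]
    n_pos, n_neg = len(pos), len(neg)

    thresholds = np.unique(s)
    tp = (pos[:, None] >= thresholds[None, :]).sum(axis=0)
    tn = (neg[:, None] < thresholds[None, :]).sum(axis=0)
    j = tp / n_pos + tn / n_neg - 1.0
    best = int(np.argmax(j))  # argmax takes the first (smallest) maximizer
    cutoff = float(thresholds[best])

    table = ConfusionTable(
        tp=int(tp[best]),
        fp=n_neg - int(tn[best]),
        tn=int(tn[best]),
        fn=n_pos - int(tp[best]),
    )

    auc, var = delong_auc_variance(pos, neg)
    se = float(np.sqrt(var))
    ci = (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se))
    if se > 0:
        p = float(2.0 * sps.norm.sf(abs(auc - 0.5) / se))
    else:
        p = 1.0 if auc == 0.5 else 0.0

    return ROCResult(
        auroc=auc,
        ci95=ci,
        cutoff=cutoff,
        youden_j=float(j[best]),
        confusion=table,
        metrics=confusion_metrics(table),
        p_value=p,
        n_pos=n_pos,
        n_neg=n_neg,
    )


# ---------------------------------------------------------------------------
# Cohort report
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComparisonRow:
    name: str
    neg_groups: tuple[str, ...]
    pos_groups: tuple[str, ...]
    roc: ROCResult


@dataclass(frozen=True)
class GroupReport:
    group_summary: pd.DataFrame  # group, n, mean, sd
    anova: AnovaResult
    correlation: CorrelationResult
    comparisons: tuple[ComparisonRow, ...]
    skipped: tuple[str, ...] = ()

    def comparisons_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.comparisons:
            m = c.roc.metrics
            rows.append(
                {
                    "comparison": c.name,
                    "cutoff_pct": c.roc.cutoff,
                    "sensitivity_pct": m.sensitivity.pct,
                    "specificity_pct": m.specificity.pct,
                    "ppv_pct": m.ppv.pct,
                    "npv_pct": m.npv.pct,
                    "da_pct": m.da.pct,
                    "auroc": c.roc.auroc,
                    "ci95_low": c.roc.ci95[0],
                    "ci95_high": c.roc.ci95[1],
                    "p_value": c.roc.p_value,
                    "tp": c.roc.confusion.tp,
                    "fp": c.roc.confusion.fp,
                    "tn": c.roc.confusion.tn,
                    "fn": c.roc.confusion.fn,
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "group_summary": self.group_summary.to_dict(orient="records"),
            "anova": {
                "F": self.anova.F,
                "p": self.anova.p,
                "eta_sq": self.anova.eta_sq,
                "effect_band": self.anova.effect_band,
                "df_between": self.anova.df_between,
                "df_within": self.anova.df_within,
                "tukey": [
                    {
                        "pair": [t.group_a, t.group_b],
                        "mean_diff": t.mean_diff,
                        "p_adj": t.p_adj,
                    }
                    for t in self.anova.tukey
                ],
            },
            "correlation": {
                "r": self.correlation.r,
                "p": self.correlation.p,
                "n": self.correlation.n,
            },
            "comparisons": self.comparisons_frame().to_dict(orient="records"),
            "skipped": list(self.skipped),
        }


def run_group_report(
    cohort: pd.DataFrame,
    comparisons: Sequence[tuple[str, Sequence[str], Sequence[str]]] | None = None,
    anova_groups: Sequence[str] | None = None,
    strict: bool = False,
) -> GroupReport:
    """Run the full cohort analysis.

    Emits per-group mean +/- SD summaries, the ANOVA/Tukey/effect-size block
    (by default over the four nodule groups, excluding the normal-parenchyma
    reference), the grade correlation over the whole cohort, and one ROC row
    per benign-vs-malignant comparison.  Comparisons whose groups are absent
    from the cohort are skipped with a warning, or raise when ``strict``.
    """
    cohort = make_cohort(cohort)
    present = set(cohort["group"])
    if comparisons is None:
        comparisons = DEFAULT_COMPARISONS

    order = [g for g in GROUP_ORDER if g in present]
    summary = (
        cohort.groupby("group")["score_pct"]
        .agg(n="size", mean="mean", sd=lambda s: s.std(ddof=1))
        .reindex(order)
        .reset_index()
    )

    if anova_groups is None:
        anova_groups = [g for g in GROUP_ORDER if g != "normal" and g in present]
    arrays = [
        cohort.loc[cohort["group"] == g, "score_pct"].to_numpy()
        for g in anova_groups
    ]
    anova = one_way_anova(arrays, names=list(anova_groups))
    corr = grade_correlation(cohort)

    rows: list[ComparisonRow] = []
    skipped: list[str] = []
    for name, neg_set, pos_set in comparisons:
        missing = (set(neg_set) | set(pos_set)) - present
        if missing:
            msg = f"comparison {name!r}: groups {sorted(missing)} absent from cohort"
            if strict:
                raise CohortError(msg)
            logger.warning("%s; skipping", msg)
            skipped.append(name)
            continue
        neg = cohort.loc[cohort["group"].isin(neg_set), "score_pct"].to_numpy()
        pos = cohort.loc[cohort["group"].isin(pos_set), "score_pct"].to_numpy()
        scores = np.concatenate([neg, pos])
        labels = np.concatenate(
            [np.zeros(len(neg), dtype=bool), np.ones(len(pos), dtype=bool)]
        )
        rows.append(
            ComparisonRow(
                name=name,
                neg_groups=tuple(neg_set),
                pos_groups=tuple(pos_set),
                roc=select_cutoff(scores, labels),
            )
        )

    return GroupReport(
        group_summary=summary,
        anova=anova,
        correlation=corr,
        comparisons=tuple(rows),
        skipped=tuple(skipped),
    )
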