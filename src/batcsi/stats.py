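"""Per-patient summaries, group comparisons and ROC analysis.

The clinical questions answered here: does the periprostatic water-to-oil
ratio differ between risk strata, and how well do the per-patient mean
ratio, serum iPSA, and their logistic combination discriminate high-risk
patients.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import (
    ExtractionSpec,
    RatioPolicy,
    apply_roi,
    extract_brown_fat,
    water_oil_ratio,
)
from .phantom import PatientRecord

logger = logging.getLogger(__name__)

CLINICALLY_SIGNIFICANT = ("high", "intermediate")


@dataclass(frozen=True)
class PatientSummary:
    patient_id: str
    mean_rwo_full: float
    mean_rwo_retained: float
    n_elements_full: int
    n_elements_retained: int

    def __post_init__(self) -> None:
        if self.mean_rwo_full < 0 or self.mean_rwo_retained < 0:
            raise ValueError("means must be nonnegative")
        if self.n_elements_retained > self.n_elements_full:
            raise ValueError("retained count cannot exceed full count")


@dataclass(frozen=True)
class GroupComparison:
    """Two-group location comparison (Welch t and Mann-Whitney)."""

    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    difference: float
    difference_ci_low: float
    difference_ci_high: float
    t_statistic: float
    t_p_value: float
    mannwhitney_p_value: float


@dataclass(frozen=True)
class RocResult:
    auc: float
    curve: tuple[tuple[float, float], ...]
    feature_label: str = ""
    auc_sd: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None


# ---------------------------------------------------------------------------
# Per-patient summarisation
# ---------------------------------------------------------------------------


def summarize_patient(
    record: PatientRecord,
    extraction: ExtractionSpec = ExtractionSpec(),
    policy: RatioPolicy = RatioPolicy(),
) -> PatientSummary:
    """Run the per-slice pipeline and pool elements across slices.

    For every slice: water/fat ratio -> ROI masking -> top-fraction
    extraction.  In-ROI elements (and retained elements) are pooled across
    slices before averaging, so slices contribute proportionally to their
    ROI size.
    """
    full_vals: list[np.ndarray] = []
    retained_vals: list[np.ndarray] = []
    for i, (water, fat, mask) in enumerate(record.slices):
        if mask.n_in_roi == 0:
            raise ValueError(
                f"patient {record.patient_id!r}: slice {i} has an empty ROI"
            )
        ratio = water_oil_ratio(water, fat, policy)
        prwo = apply_roi(ratio, mask)
        bprwo, retained = extract_brown_fat(prwo, mask, extraction)
        full_vals.append(prwo.values[mask.in_roi])
        retained_vals.append(np.array([bprwo.values[r, c] for r, c in retained]))
    full = np.concatenate(full_vals)
    kept = np.concatenate(retained_vals)
    return PatientSummary(
        patient_id=record.patient_id,
        mean_rwo_full=float(full.mean()),
        mean_rwo_retained=float(kept.mean()),
        n_elements_full=int(full.size),
        n_elements_retained=int(kept.size),
    )


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    alpha: float = 0.05,
    equal_var: bool = False,
) -> GroupComparison:
    """Welch (default) t-test plus Mann-Whitney for two samples.

    The confidence interval for the mean difference a - b comes from the
    same t procedure (Welch-Satterthwaite degrees of freedom unless
    ``equal_var``).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")

    t_res = sps.ttest_ind(a, b, equal_var=equal_var)
    diff = float(a.mean() - b.mean())
    ci = t_res.confidence_interval(confidence_level=1 - alpha)

    mw = sps.mannwhitneyu(a, b, alternative="two-sided")

    return GroupComparison(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        difference=diff,
        difference_ci_low=float(ci.low),
        difference_ci_high=float(ci.high),
        t_statistic=float(t_res.statistic),
        t_p_value=float(t_res.pvalue),
        mannwhitney_p_value=float(mw.pvalue),
    )


# ---------------------------------------------------------------------------
# ROC analysis
# ---------------------------------------------------------------------------


def roc_curve(
    scores: Sequence[float],
    labels: Sequence[bool],
    feature_label: str = "",
) -> RocResult:
    """ROC curve by sweeping all distinct score thresholds.

    AUC is the trapezoidal area, which with grouped ties equals the
    Mann-Whitney relation U/(n_pos * n_neg) with half-credit for ties.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and equal length")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]

    # group tied scores so each distinct threshold yields one curve point
    distinct = np.flatnonzero(np.diff(s_sorted)) if s.size > 1 else np.array([], int)
    cut_ends = np.append(distinct, s.size - 1)
    tp = np.cumsum(y_sorted)[cut_ends]
    fp = (cut_ends + 1) - tp
    tpr = tp / n_pos
    fpr = fp / n_neg

    curve = [(0.0, 0.0)] + list(zip(fpr.tolist(), tpr.tolist()))
    xs = np.array([p[0] for p in curve])
    ys = np.array([p[1] for p in curve])
    auc = float(np.trapezoid(ys, xs))
    return RocResult(auc=auc, curve=tuple(curve), feature_label=feature_label)


def combine_features(
    ipsa: Sequence[float],
    mean_rwo: Sequence[float],
    labels: Sequence[bool],
) -> np.ndarray:
    """Maximum-likelihood logistic score combining log iPSA and mean ratio.

    Fits a two-feature logistic model on (log iPSA, mean R) and returns
    the in-sample linear predictor.  Under perfect separation the
    coefficients are not identifiable; a warning is emitted and a
    large-margin fit is used instead (the score ranking remains valid).
    """
    import statsmodels.api as sm

    x1 = np.log(np.asarray(ipsa, dtype=float))
    x2 = np.asarray(mean_rwo, dtype=float)
    y = np.asarray(labels, dtype=int)
    if not (x1.size == x2.size == y.size):
        raise ValueError("ipsa, mean_rwo and labels must have equal length")
    if y.min() == y.max():
        raise ValueError("both classes must be present")

    X = sm.add_constant(np.column_stack([x1, x2]), has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        return np.asarray(X @ fit.params, dtype=float)
    except Exception:
        warnings.warn(
            "logistic fit did not converge (possible perfect separation); "
            "falling back to a weakly regularised fit — coefficient values "
            "are not identifiable but the score ranking is valid",
            stacklevel=2,
        )
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(C=1e6, max_iter=5000)
        Z = np.column_stack([x1, x2])
        clf.fit(Z, y)
        return np.asarray(clf.decision_function(Z), dtype=float)


def bootstrap_auc(
    scores: Sequence[float],
    labels: Sequence[bool],
    n_reps: int = 2000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Stratified nonparametric bootstrap of the AUC.

    Positives and negatives are resampled separately (so every replicate
    keeps both classes).  Returns (SD of bootstrap AUCs, percentile 2.5%,
    percentile 97.5%).
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    pos = np.flatnonzero(y)
    neg = np.flatnonzero(~y)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")

    rng = np.random.default_rng(seed)
    aucs = np.empty(n_reps)
    for i in range(n_reps):
        pi = rng.choice(pos, size=pos.size, replace=True)
        ni = rng.choice(neg, size=neg.size, replace=True)
        idx = np.concatenate([pi, ni])
        aucs[i] = roc_curve(s[idx], y[idx]).auc
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(aucs.std(ddof=1)), float(lo), float(hi)


# ---------------------------------------------------------------------------
# Cohort report
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReportConfig:
    extraction: ExtractionSpec = ExtractionSpec()
    policy: RatioPolicy = RatioPolicy()
    bootstrap_reps: int = 2000
    seed: int = 0
    roc_feature: str = "mean_rwo_full"  # or "mean_rwo_retained"
    run_bootstrap: bool = True


@dataclass
class CohortReport:
    summaries: pd.DataFrame
    group_stats: pd.DataFrame
    comparison: GroupComparison
    rocs: dict[str, RocResult]

    def to_text(self) -> str:
        lines = ["Cohort report", "=" * 13, ""]
        lines.append(self.group_stats.to_string())
        c = self.comparison
        lines += [
            "",
            "Clinically-significant (high+intermediate) vs low mean ratio:",
            f"  {c.mean_a:.2f} vs {c.mean_b:.2f} "
            f"(95% CI of difference: {c.difference_ci_low:.2f} to "
            f"{c.difference_ci_high:.2f}; Welch t p={c.t_p_value:.4g}; "
            f"Mann-Whitney p={c.mannwhitney_p_value:.4g})",
            "",
            "ROC (positive class: high risk):",
        ]
        for name, r in self.rocs.items():
            sd = f" (SD {r.auc_sd:.3f})" if r.auc_sd is not None else ""
            lines.append(f"  {name}: AUC {r.auc:.3f}{sd}")
        return "\n".join(lines) + "\n"


def cohort_report(
    cohort: Sequence[PatientRecord],
    config: ReportConfig = ReportConfig(),
) -> CohortReport:
    """Full cohort analysis.

    Produces per-patient summaries, per-group mean/SD of the full-ROI
    mean ratio, the clinically-significant (high+intermediate) vs low
    comparison, and three ROC analyses with high risk as the positive
    class: mean ratio alone, iPSA alone, and the logistic combination.
    """
    groups_present = {r.risk_group for r in cohort}
    if len(groups_present) < 2:
        raise ValueError("cohort report needs at least 2 risk groups")

    rows = []
    for record in cohort:
        summ = summarize_patient(record, config.extraction, config.policy)
        rows.append(
            {
                "patient_id": record.patient_id,
                "risk_group": record.risk_group,
                "ipsa_ng_ml": record.ipsa,
                "mean_rwo_full": summ.mean_rwo_full,
                "mean_rwo_retained": summ.mean_rwo_retained,
                "n_elements_full": summ.n_elements_full,
                "n_elements_retained": summ.n_elements_retained,
            }
        )
    df = pd.DataFrame(rows)

    group_stats = (
        df.groupby("risk_group")["mean_rwo_full"]
        .agg(n="count", mean="mean", sd="std")
        .reindex([g for g in ("low", "intermediate", "high") if g in groups_present])
    )

    sig = df[df["risk_group"].isin(CLINICALLY_SIGNIFICANT)]
    low = df[df["risk_group"] == "low"]
    if sig.empty or low.empty:
        raise ValueError(
            "comparison requires both a low-risk group and a "
            "high/intermediate stratum"
        )
    comparison = compare_groups(
        sig["mean_rwo_full"].to_numpy(), low["mean_rwo_full"].to_numpy()
    )

    labels = (df["risk_group"] == "high").to_numpy()
    feature = df[config.roc_feature].to_numpy()
    ipsa = df["ipsa_ng_ml"].to_numpy()
    combined_scores = combine_features(ipsa, feature, labels)

    rocs: dict[str, RocResult] = {}
    for name, scores in (
        ("mean_rwo", feature),
        ("ipsa", ipsa),
        ("combined", combined_scores),
    ):
        r = roc_curve(scores, labels, feature_label=name)
        if config.run_bootstrap:
            sd, lo, hi = bootstrap_auc(
                scores, labels, n_reps=config.bootstrap_reps, seed=config.seed
            )
            r = RocResult(
                auc=r.auc,
                curve=r.curve,
                feature_label=name,
                auc_sd=sd,
                ci_low=lo,
                ci_high=hi,
            )
        rocs[name] = r

    return CohortReport(
        summaries=df, group_stats=group_stats, comparison=comparison, rocs=rocs
    )
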