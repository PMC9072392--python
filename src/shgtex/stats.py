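"""Group-level comparison of per-ROI features.

Pairwise comparisons use the classic equal-variance two-sample two-tailed
t-test, with significance stars following the figure-caption convention
p < 0.1 (*), p < 0.01 (**), p < 0.001 (***). Distributions are summarized
by box statistics: quartiles, median, and whiskers at 1.5x the
interquartile range clipped to the data range. An optional one-way ANOVA
F-test across all groups is provided separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .texture import FOSFeatures, SOSFeatures

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.1, "*"))


@dataclass
class FeatureRecord:
    """Per-ROI feature bundle: the row type of the pipeline output table."""

    roi_id: str
    group_label: str
    oi: float
    fos: FOSFeatures
    sos: SOSFeatures

    def to_row(self) -> dict:
        return {
            "roi_id": self.roi_id,
            "group": self.group_label,
            "oi": self.oi,
            "mean": self.fos.mean,
            "std": self.fos.std,
            "skewness": self.fos.skewness,
            "kurtosis": self.fos.kurtosis,
            "energy": self.sos.energy,
            "inertia": self.sos.inertia,
            "correlation": self.sos.correlation,
            "idm": self.sos.idm,
            "entropy": self.sos.entropy,
        }


FEATURE_COLUMNS = (
    "oi", "mean", "std", "skewness", "kurtosis",
    "energy", "inertia", "correlation", "idm", "entropy",
)


@dataclass
class GroupComparison:
    feature_name: str
    group_a: str
    group_b: str
    t_statistic: float
    p_value: float
    stars: str
    n_a: int
    n_b: int
    n_dropped: int = 0


@dataclass
class BoxSummary:
    median: float
    q25: float
    q75: float
    whisker_low: float
    whisker_high: float
    n: int


def stars_for_p(p_value: float) -> str:
    """Significance label: p < 0.1 '*', p < 0.01 '**', p < 0.001 '***'."""
    for threshold, label in STAR_THRESHOLDS:
        if p_value < threshold:
            return label
    return ""


def _extract(records, feature_name: str, group: str) -> np.ndarray:
    vals = []
    for rec in records:
        if rec.group_label != group:
            continue
        row = rec.to_row()
        if feature_name not in row:
            raise KeyError(f"unknown feature {feature_name!r}")
        vals.append(row[feature_name])
    return np.asarray(vals, dtype=float)


def compare_groups(
    records,
    feature_name: str,
    group_a: str,
    group_b: str,
) -> GroupComparison:
    """Equal-variance two-sample two-tailed t-test between two groups.

    Missing values (nan) are dropped with their count recorded; fewer than
    two remaining observations in either group is an error.
    """
    a = _extract(records, feature_name, group_a)
    b = _extract(records, feature_name, group_b)
    n_dropped = int(np.isnan(a).sum() + np.isnan(b).sum())
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    for vals, name in ((a, group_a), (b, group_b)):
        if len(vals) < 2:
            raise ValueError(
                f"group {name!r} has {len(vals)} usable observations "
                f"for {feature_name!r}; need >= 2"
            )
    t, p = sps.ttest_ind(a, b, equal_var=True)
    # identical samples give 0/0; report t = 0, p = 1
    if np.isnan(t):
        t, p = 0.0, 1.0
    return GroupComparison(
        feature_name=feature_name,
        group_a=group_a,
        group_b=group_b,
        t_statistic=float(t),
        p_value=float(p),
        stars=stars_for_p(float(p)),
        n_a=len(a),
        n_b=len(b),
        n_dropped=n_dropped,
    )


def anova_f(records, feature_name: str, groups) -> tuple:
    """Optional global one-way ANOVA F-test across all groups."""
    samples = []
    for g in groups:
        v = _extract(records, feature_name, g)
        v = v[~np.isnan(v)]
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 usable observations")
        samples.append(v)
    f, p = sps.f_oneway(*samples)
    return float(f), float(p)


def box_summary(values) -> BoxSummary:
    """Quartiles (linear interpolation) and 1.5x IQR whiskers clipped to data."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("box_summary requires at least one finite value")
    q25, med, q75 = np.percentile(v, [25.0, 50.0, 75.0])
    iqr = q75 - q25
    return BoxSummary(
        median=float(med),
        q25=float(q25),
        q75=float(q75),
        whisker_low=float(max(v.min(), q25 - 1.5 * iqr)),
        whisker_high=float(min(v.max(), q75 + 1.5 * iqr)),
        n=int(v.size),
    )
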