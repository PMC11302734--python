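"""Phenotype stratification of the mucosal (or fecal) microbiome.

Subjects are grouped by age (LOW 44-53 vs HIGH 54-68 years), gender, BMI
(DOWN 19.7-23 vs UP 23.5-27 kg/m2, the printed gap excluded) or polyp risk
(Group 1 hyperplastic/low, Group 2 tubular/moderate, Group 3 tubulovillous/
high), and features are screened between groups with the two-sided
Mann-Whitney rank-sum test — the groups contain disjoint subjects, so paired
tests do not apply. The polyp contrast compares only the low- and high-risk
extremes and warns when either group is small.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .containers import AbundanceTable, site_sample_ids, validate_metadata
from .differential import DifferentialResult, rank_sum_test
from .exceptions import ValidationError
from .simulate import AGE_GROUPS, BMI_GROUPS, POLYP_LABELS

logger = logging.getLogger(__name__)

SMALL_GROUP_WARNING = 5


@dataclass(frozen=True)
class GroupingScheme:
    """How a phenotype variable maps samples to two (or three) labeled groups.

    ``group_labels`` is ordered: the first label is group A, whose enrichment
    is reported as positive downstream. ``intervals`` (numeric variables) maps
    label -> closed [lo, hi]; values falling outside every interval are
    excluded. ``categories`` (categorical variables) maps raw value -> label.
    """

    variable: str  # metadata column
    group_labels: tuple[str, ...]
    intervals: Optional[Mapping[str, tuple[float, float]]] = None
    categories: Optional[Mapping[object, str]] = None

    def __post_init__(self) -> None:
        if len(self.group_labels) < 2:
            raise ValidationError("a grouping scheme needs at least two labels")
        if (self.intervals is None) == (self.categories is None):
            raise ValidationError("provide exactly one of intervals or categories")
        if self.intervals is not None:
            labels = set(self.intervals)
            for (lo, hi) in self.intervals.values():
                if not lo <= hi:
                    raise ValidationError("interval bounds must satisfy lo <= hi")
        else:
            labels = set(self.categories.values())
        if labels != set(self.group_labels):
            raise ValidationError("rule labels must match group_labels")


def age_scheme() -> GroupingScheme:
    return GroupingScheme("age", ("HIGH", "LOW"), intervals=AGE_GROUPS)


def bmi_scheme() -> GroupingScheme:
    return GroupingScheme("bmi", ("UP", "DOWN"), intervals=BMI_GROUPS)


def gender_scheme() -> GroupingScheme:
    return GroupingScheme(
        "gender", ("female", "male"),
        categories={"female": "female", "male": "male"},
    )


def polyp_scheme() -> GroupingScheme:
    return GroupingScheme(
        "polyp_group", ("Group 3", "Group 2", "Group 1"),
        categories={k: v for k, v in POLYP_LABELS.items()},
    )


SCHEMES = {
    "age": age_scheme,
    "gender": gender_scheme,
    "bmi": bmi_scheme,
    "polyp_risk": polyp_scheme,
}


def assign_groups(metadata: pd.DataFrame, scheme: GroupingScheme) -> pd.Series:
    """Sample -> group label; samples outside the scheme's rule are NaN (excluded)."""
    validate_metadata(metadata)
    if scheme.variable not in metadata.columns:
        raise ValidationError(f"metadata lacks column {scheme.variable!r}")
    col = metadata[scheme.variable]
    if col.isna().any():
        missing = metadata.index[col.isna()].tolist()
        raise ValidationError(f"missing {scheme.variable} for samples: {missing[:5]}")

    if scheme.intervals is not None:
        def label_of(v):
            for lab, (lo, hi) in scheme.intervals.items():
                if lo <= v <= hi:
                    return lab
            return np.nan
        labels = col.map(label_of)
    else:
        labels = col.map(lambda v: scheme.categories.get(v, np.nan))
    excluded = metadata.index[labels.isna()].tolist()
    if excluded:
        logger.warning(
            "%d samples fall outside the %s grouping and are excluded: %s",
            len(excluded), scheme.variable, excluded[:6],
        )
    labels.name = "group"
    return labels


def subgroup_screen(
    table: AbundanceTable,
    metadata: pd.DataFrame,
    scheme: GroupingScheme,
    site_filter: str = "mucosa",
    alpha: float = 0.05,
    group_pair: Optional[tuple[str, str]] = None,
) -> list[DifferentialResult]:
    """Between-group rank-sum screen within one site's samples.

    Group A is ``group_pair[0]`` (default: the scheme's first label), so
    positive downstream reporter scores mean enrichment in that group.
    """
    if not 0.0 < alpha < 1.0:
        raise ValidationError("alpha must lie in (0, 1)")
    label_a, label_b = group_pair or scheme.group_labels[:2]
    site_samples = [s for s in site_sample_ids(metadata, site_filter)
                    if s in table.data.columns]
    if not site_samples:
        raise ValidationError(f"no {site_filter} samples present in the table")
    labels = assign_groups(metadata.loc[site_samples], scheme)
    cols_a = labels.index[labels == label_a].tolist()
    cols_b = labels.index[labels == label_b].tolist()
    for lab, cols in ((label_a, cols_a), (label_b, cols_b)):
        if len(cols) < 2:
            raise ValidationError(f"group {lab!r} has fewer than two samples after filtering")
    if min(len(cols_a), len(cols_b)) <= SMALL_GROUP_WARNING:
        logger.warning(
            "small-group contrast: %s n=%d vs %s n=%d — interpret with caution",
            label_a, len(cols_a), label_b, len(cols_b),
        )

    mat_a = table.data[cols_a].to_numpy()
    mat_b = table.data[cols_b].to_numpy()
    results: list[DifferentialResult] = []
    skipped = 0
    for i, feature in enumerate(table.data.index):
        if not mat_a[i].any() and not mat_b[i].any():
            skipped += 1
            continue
        res = rank_sum_test(mat_a[i], mat_b[i], feature_id=feature, level=table.level)
        res.significant = bool(res.testable and res.p_value < alpha)
        results.append(res)
    if skipped:
        logger.info("skipped %d features absent from both groups", skipped)
    return results


def polyp_risk_contrast(
    table: AbundanceTable,
    metadata: pd.DataFrame,
    alpha: float = 0.05,
    site_filter: str = "mucosa",
) -> list[DifferentialResult]:
    """Low-risk vs high-risk polyp groups only (Group 2 excluded).

    Group A = Group 3 (high risk), so ``higher_in_a`` means abundance rises
    with risk.
    """
    return subgroup_screen(
        table, metadata, polyp_scheme(), site_filter=site_filter, alpha=alpha,
        group_pair=("Group 3", "Group 1"),
    )
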