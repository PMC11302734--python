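"""Paired and unpaired per-feature location tests, cross-site correlation,
leave-one-feature-out leverage, and outlier sensitivity.

The workhorse paired test is the Wilcoxon signed-rank test on within-subject
differences. Zero differences are dropped (the classical convention) and their
count reported. For n <= 25 retained pairs the two-sided p-value comes from
the exact sign-flip null distribution, computed by dynamic programming over
the (tie-averaged) rank sums — identical to enumerating all 2^n sign
assignments, including under ties. Larger n uses the normal approximation
whose variance term sum(r_i^2)/4 is automatically tie-corrected.

The paired t-test and the (unpaired) Mann-Whitney rank-sum test delegate to
scipy.stats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AbundanceTable, paired_sample_ids
from .exceptions import ValidationError
from .profiling import site_mean_abundance

logger = logging.getLogger(__name__)

EXACT_MAX_N = 25
P_FLOOR = 1e-300

METHODS = ("wilcoxon", "paired_t", "rank_sum")


@dataclass
class DifferentialResult:
    feature_id: str
    level: str
    mean_a: float  # group A = mucosa (site screens) or the scheme's first label
    mean_b: float
    statistic: float
    p_value: float
    direction: str  # higher_in_a | higher_in_b | none
    method: str
    n_used: int = 0
    n_dropped: int = 0
    testable: bool = True
    significant: bool = False
    q_value: Optional[float] = None


def _direction(mean_a: float, mean_b: float) -> str:
    if mean_a > mean_b:
        return "higher_in_a"
    if mean_a < mean_b:
        return "higher_in_b"
    return "none"


def _clamp_p(p: float) -> float:
    return float(min(max(p, P_FLOOR), 1.0))


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def _exact_signed_rank_p(ranks: np.ndarray, w_pos: float) -> float:
    """Two-sided exact p for the signed-rank statistic via DP over rank sums.

    Works on doubled ranks so tie-averaged (half-integer) ranks stay integral.
    Equivalent to enumerating all 2^n sign assignments.
    """
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    t2 = int(r2.sum())
    counts = np.zeros(t2 + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        nxt = counts.copy()
        nxt[r:] += counts[: t2 + 1 - r]
        counts = nxt
    total = 2.0 ** len(r2)
    w2 = int(np.rint(2.0 * w_pos))
    w_min = min(w2, t2 - w2)
    if w_min == t2 - w_min:
        return 1.0
    tail = counts[: w_min + 1].sum() + counts[t2 - w_min:].sum()
    return float(min(tail / total, 1.0))


def wilcoxon_signed_rank(
    values_a: Sequence[float], values_b: Sequence[float], exact_max_n: int = EXACT_MAX_N
) -> tuple[float, float, int, int]:
    """Signed-rank test of paired samples. Returns (W, p, n_used, n_dropped)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("paired vectors must be 1-d and equally long")
    if a.size < 2:
        raise ValidationError("paired test needs at least two pairs")
    d = a - b
    nz = d != 0
    n_dropped = int(d.size - nz.sum())
    d = d[nz]
    n = d.size
    if n == 0:
        logger.warning("all paired differences are zero; p set to 1")
        return 0.0, 1.0, 0, n_dropped
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n < 2:
        return w_pos, 1.0, n, n_dropped
    if n <= exact_max_n:
        p = _exact_signed_rank_p(ranks, w_pos)
    else:
        mu = ranks.sum() / 2.0
        sigma = np.sqrt(np.sum(ranks ** 2) / 4.0)
        z = (w_pos - mu) / sigma
        p = 2.0 * stats.norm.sf(abs(z))
    return w_pos, _clamp_p(p), n, n_dropped


# ---------------------------------------------------------------------------
# single-feature tests
# ---------------------------------------------------------------------------

def paired_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    method: str = "wilcoxon",
    feature_id: str = "",
    level: str = "gene",
) -> DifferentialResult:
    """Two-sided paired location test between aligned per-subject vectors."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("paired vectors must be 1-d and equally long")
    if a.size < 2:
        raise ValidationError("paired test needs at least two pairs")
    mean_a, mean_b = float(a.mean()), float(b.mean())

    if method == "wilcoxon":
        stat, p, n_used, n_dropped = wilcoxon_signed_rank(a, b)
        testable = n_used >= 2
        if not testable and n_used > 0:
            logger.warning("fewer than two nonzero differences; result flagged untestable")
        direction = _direction(mean_a, mean_b) if n_used else "none"
        return DifferentialResult(
            feature_id, level, mean_a, mean_b, stat, p, direction, method,
            n_used=n_used, n_dropped=n_dropped, testable=testable,
        )
    if method == "paired_t":
        d = a - b
        if np.all(d == 0):
            logger.warning("all paired differences are zero; p set to 1")
            return DifferentialResult(
                feature_id, level, mean_a, mean_b, 0.0, 1.0, "none", method,
                n_used=0, n_dropped=a.size, testable=True,
            )
        res = stats.ttest_rel(a, b)
        return DifferentialResult(
            feature_id, level, mean_a, mean_b, float(res.statistic),
            _clamp_p(float(res.pvalue)), _direction(mean_a, mean_b), method,
            n_used=a.size, n_dropped=0,
        )
    raise ValidationError(f"unknown paired method {method!r}; use one of {METHODS[:2]}")


def rank_sum_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    feature_id: str = "",
    level: str = "gene",
) -> DifferentialResult:
    """Two-sided Mann-Whitney rank-sum test between independent groups."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("rank-sum test needs at least two observations per group")
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        return DifferentialResult(
            feature_id, level, float(a.mean()), float(b.mean()), 0.0, 1.0,
            "none", "rank_sum", n_used=a.size + b.size,
        )
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return DifferentialResult(
        feature_id, level, float(a.mean()), float(b.mean()), float(res.statistic),
        _clamp_p(float(res.pvalue)), _direction(float(a.mean()), float(b.mean())),
        "rank_sum", n_used=a.size + b.size,
    )


# ---------------------------------------------------------------------------
# per-feature screens
# ---------------------------------------------------------------------------

def differential_screen(
    table: AbundanceTable,
    metadata: pd.DataFrame,
    method: str = "wilcoxon",
    alpha: float = 0.05,
    fdr: bool = False,
) -> list[DifferentialResult]:
    """Paired mucosa-vs-feces test per feature; group A = mucosa.

    Features absent from both sites are skipped (logged, not tested). No
    multiple-testing correction is applied unless ``fdr`` (Benjamini-Hochberg,
    reported as ``q_value``) is requested.
    """
    if not 0.0 < alpha < 1.0:
        raise ValidationError("alpha must lie in (0, 1)")
    _, mucosa_ids, feces_ids = paired_sample_ids(metadata)
    missing = [s for s in mucosa_ids + feces_ids if s not in table.data.columns]
    if missing:
        raise ValidationError(f"samples missing from the table: {missing[:5]}")
    mat_a = table.data[mucosa_ids].to_numpy()
    mat_b = table.data[feces_ids].to_numpy()

    results: list[DifferentialResult] = []
    skipped: list[str] = []
    for i, feature in enumerate(table.data.index):
        if not mat_a[i].any() and not mat_b[i].any():
            skipped.append(feature)
            continue
        res = paired_test(mat_a[i], mat_b[i], method=method,
                          feature_id=feature, level=table.level)
        res.significant = bool(res.testable and res.p_value < alpha)
        results.append(res)
    if skipped:
        logger.info("skipped %d features absent from both sites", len(skipped))
    if fdr and results:
        from statsmodels.stats.multitest import multipletests

        reject, q, _, _ = multipletests([r.p_value for r in results], alpha=alpha,
                                        method="fdr_bh")
        for r, qv, rej in zip(results, q, reject):
            r.q_value = float(qv)
            r.significant = bool(rej and r.testable)
    return results


def results_frame(results: Sequence[DifferentialResult]) -> pd.DataFrame:
    """Flat table of screen results, one row per feature."""
    return pd.DataFrame(
        {
            "feature": [r.feature_id for r in results],
            "level": [r.level for r in results],
            "mean_a": [r.mean_a for r in results],
            "mean_b": [r.mean_b for r in results],
            "statistic": [r.statistic for r in results],
            "p_value": [r.p_value for r in results],
            "direction": [r.direction for r in results],
            "method": [r.method for r in results],
            "n_used": [r.n_used for r in results],
            "n_dropped": [r.n_dropped for r in results],
            "testable": [r.testable for r in results],
            "significant": [r.significant for r in results],
            "q_value": [r.q_value for r in results],
        }
    ).set_index("feature")


# ---------------------------------------------------------------------------
# cross-site mean correlation and leverage
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    r_squared: float
    r: float
    n_features: int
    excluded_feature: Optional[str] = None


def group_mean_correlation(
    table: AbundanceTable,
    metadata: pd.DataFrame,
    features: Optional[Sequence[str]] = None,
    excluded: Optional[str] = None,
) -> CorrelationResult:
    """Squared Pearson correlation of per-feature site means (mucosa vs feces)."""
    means = site_mean_abundance(table, metadata, features)
    if excluded is not None:
        if excluded not in means.index:
            raise ValidationError(f"excluded feature {excluded!r} not among features")
        means = means.drop(index=excluded)
    if len(means) < 3:
        raise ValidationError("need at least three features for a correlation")
    x, y = means["mucosa"].to_numpy(), means["feces"].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("degenerate (constant) mean vector")
    r = float(np.corrcoef(x, y)[0, 1])
    return CorrelationResult(r_squared=r * r, r=r, n_features=len(means),
                             excluded_feature=excluded)


def leave_one_out_screen(
    table: AbundanceTable,
    metadata: pd.DataFrame,
    features: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-feature leverage on the cross-site mean correlation.

    delta_r2 = r2(without the feature) - r2(all features); sorted descending,
    so the top row is the most site-discriminating feature.
    """
    means = site_mean_abundance(table, metadata, features)
    if len(means) < 4:
        raise ValidationError("need at least four features for a leave-one-out screen")
    feats = means.index.tolist()
    full = group_mean_correlation(table, metadata, feats).r_squared
    rows = []
    for f in feats:
        without = group_mean_correlation(table, metadata, feats, excluded=f).r_squared
        rows.append((f, without - full, without))
    frame = pd.DataFrame(rows, columns=["feature", "delta_r2", "r2_without"])
    frame["r2_full"] = full
    return frame.sort_values(["delta_r2", "feature"], ascending=[False, True]).set_index("feature")


@dataclass
class OutlierSensitivity:
    p_full: float
    p_reduced: float
    dropped_index: int
    flag_changed: bool


def outlier_sensitivity(
    values_a: Sequence[float],
    values_b: Sequence[float],
    method: str = "wilcoxon",
    alpha: float = 0.05,
) -> OutlierSensitivity:
    """Re-test after dropping the subject with the largest |paired difference|."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3:
        raise ValidationError("outlier sensitivity needs at least three pairs")
    full = paired_test(a, b, method=method)
    drop = int(np.argmax(np.abs(a - b)))
    keep = np.ones(a.size, dtype=bool)
    keep[drop] = False
    reduced = paired_test(a[keep], b[keep], method=method)
    changed = (full.p_value < alpha) != (reduced.p_value < alpha)
    return OutlierSensitivity(
        p_full=full.p_value, p_reduced=reduced.p_value,
        dropped_index=drop, flag_changed=bool(changed),
    )
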