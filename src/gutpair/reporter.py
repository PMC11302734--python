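"""Reporter-score KO-pathway enrichment.

Each KO-level differential result is converted to a signed standard-normal
score z = sign(direction) * Phi^-1(1 - p/2) (positive = higher in group A). A
pathway of k scored member KOs gets the raw aggregate Z = sum(z)/sqrt(k),
which is then background-corrected against the empirical null of random
k-subsets of all scored KOs: corrected = (raw - mu_k)/sigma_k with mu_k and
sigma_k estimated from seeded draws without replacement. Corrected scores are
classified with the conventional thresholds: ++ above 2.3, + above 1.96, --
below -2.3, - below -1.96, 0 otherwise (strict inequalities).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .differential import DifferentialResult
from .exceptions import ValidationError

logger = logging.getLogger(__name__)

P_CLAMP = 1e-10
LABEL_THRESHOLDS = ((2.3, "++"), (1.96, "+"))


@dataclass(frozen=True)
class KoZScore:
    ko_id: str
    p_value: float
    direction: str
    z: float


@dataclass
class ReporterResult:
    pathway_id: str
    k: int
    raw_score: float
    corrected_score: float
    label: str
    low_confidence: bool = False  # single-KO pathways


def ko_zscore(result: DifferentialResult) -> KoZScore:
    """Signed z-score of one KO's two-sided differential p-value."""
    p = result.p_value
    if not 0.0 < p <= 1.0:
        raise ValidationError(f"p-value out of (0, 1]: {p}")
    p = min(max(p, P_CLAMP), 1.0 - P_CLAMP)
    magnitude = float(stats.norm.isf(p / 2.0))
    if result.direction == "higher_in_a":
        z = magnitude
    elif result.direction == "higher_in_b":
        z = -magnitude
    else:
        if result.p_value < 1.0:
            logger.warning(
                "KO %s has p=%.3g but no direction; z set to 0", result.feature_id, result.p_value
            )
        z = 0.0
    return KoZScore(ko_id=result.feature_id, p_value=result.p_value,
                    direction=result.direction, z=z)


def pathway_raw_score(z_values: Sequence[float]) -> float:
    """Aggregate member z-scores: Z = sum(z) / sqrt(k)."""
    z = np.asarray(z_values, dtype=float)
    if z.size == 0:
        raise ValidationError("a pathway needs at least one scored KO")
    return float(z.sum() / np.sqrt(z.size))


def _background_stats(
    k: int, all_z: np.ndarray, n_draws: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Mean and SD of raw scores of random k-subsets (without replacement per draw)."""
    n = all_z.size
    if k > n:
        raise ValidationError(f"subset size {k} exceeds population size {n}")
    # index-based sampling keeps the draws identical under sign flips of all_z
    idx = np.argsort(rng.random((n_draws, n)), axis=1)[:, :k]
    raw = all_z[idx].sum(axis=1) / np.sqrt(k)
    return float(raw.mean()), float(raw.std(ddof=0))


def _degenerate(mu: float, sigma: float) -> bool:
    # identical subset scores can leave a ~1 ulp residual std
    return sigma <= 1e-12 * max(1.0, abs(mu))


def background_correct(
    raw: float, k: int, all_z: Sequence[float], n_draws: int = 1000, seed: int = 0
) -> float:
    """Standardize a raw pathway score against the random-k-subset background."""
    all_z = np.asarray(all_z, dtype=float)
    if n_draws < 100:
        raise ValidationError("n_draws must be >= 100")
    if k < 1 or all_z.size < k:
        raise ValidationError("need |all_z| >= k >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), k]))
    mu, sigma = _background_stats(k, all_z, n_draws, rng)
    if _degenerate(mu, sigma):
        raise ValidationError(
            "degenerate KO z-score population (all background subset scores identical)"
        )
    return float((raw - mu) / sigma)


def classify_score(corrected: float) -> str:
    """Map a corrected reporter score to the --/-/0/+/++ label (strict thresholds)."""
    if not np.isfinite(corrected):
        raise ValidationError("corrected score must be finite")
    for threshold, label in LABEL_THRESHOLDS:
        if corrected > threshold:
            return label
        if corrected < -threshold:
            return "-" * len(label)
    return "0"


def enrich(
    ko_results: Sequence[DifferentialResult],
    pathway_map: Mapping[str, Sequence[str]],
    n_draws: int = 1000,
    seed: int = 0,
) -> list[ReporterResult]:
    """Full reporter chain per pathway, sorted by corrected score (descending).

    Pathways whose KO set does not intersect the scored KOs are omitted with a
    notice; positive scores mean enrichment in group A of the upstream screen.
    """
    if not pathway_map:
        raise ValidationError("empty pathway map")
    scores = {s.ko_id: s.z for s in map(ko_zscore, ko_results)}
    if not scores:
        raise ValidationError("no scored KOs supplied")
    all_z = np.asarray(list(scores.values()), dtype=float)

    bg_cache: dict[int, tuple[float, float]] = {}
    out: list[ReporterResult] = []
    any_overlap = False
    for pid in sorted(pathway_map):
        member_z = [scores[k] for k in pathway_map[pid] if k in scores]
        if not member_z:
            logger.info("pathway %s has no scored KOs; omitted", pid)
            continue
        any_overlap = True
        k = len(member_z)
        raw = pathway_raw_score(member_z)
        if k == all_z.size:
            # the pathway covers every scored KO: every background subset is the
            # population itself, so the pathway sits exactly at its background mean
            logger.warning("pathway %s covers all scored KOs; corrected score is 0", pid)
            out.append(ReporterResult(pid, k, raw, 0.0, "0", k == 1))
            continue
        if k not in bg_cache:
            rng = np.random.default_rng(np.random.SeedSequence([int(seed), k]))
            bg_cache[k] = _background_stats(k, all_z, n_draws, rng)
        mu, sigma = bg_cache[k]
        if _degenerate(mu, sigma):
            raise ValidationError(
                f"degenerate background for pathway {pid!r} (k={k}): zero variance"
            )
        corrected = float((raw - mu) / sigma)
        low_conf = k == 1
        if low_conf:
            logger.warning("pathway %s scored from a single KO; flagged low confidence", pid)
        out.append(ReporterResult(pid, k, raw, corrected, classify_score(corrected), low_conf))
    if not any_overlap:
        raise ValidationError("no pathway shares a KO with the differential results")
    out.sort(key=lambda r: (-r.corrected_score, r.pathway_id))
    return out
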