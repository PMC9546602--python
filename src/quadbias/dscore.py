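"""IAT D-scores, threshold classification, and subsample descriptives.

The D-score is a standardized latency difference between the two critical
pairings, computed with the improved scoring algorithm adapted to
latency-to-correct-response recording (no added error penalty: the built-in
error cost is already in the latency).  The sign convention is fixed:
positive D = evaluative preference for the relatively higher-status group.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .iat_data import Pairing, SessionRecord, StatusRole

__all__ = [
    "ScoringConfig",
    "DScoreResult",
    "ExclusionReason",
    "BiasClassification",
    "ClassificationConfig",
    "DescriptiveStats",
    "compute_d",
    "classify_by_d",
    "describe_subsamples",
]


class ExclusionReason(str, enum.Enum):
    TOO_FAST_TRIALS = "too_fast_trials"
    INSUFFICIENT_TRIALS = "insufficient_trials"


class BiasClassification(str, enum.Enum):
    OUTGROUP_BIASED = "outgroup_biased"
    INGROUP_BIASED = "ingroup_biased"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class ScoringConfig:
    """Trial-exclusion thresholds of the improved D algorithm."""

    slow_cutoff_ms: float = 10_000.0  # drop trials slower than this
    fast_cutoff_ms: float = 300.0  # "too fast" trials
    fast_fraction_limit: float = 0.10  # exclude participant above this fraction


@dataclass(frozen=True)
class DScoreResult:
    d: float
    excluded: bool
    exclusion_reason: ExclusionReason | None = None

    def __post_init__(self) -> None:
        if not self.excluded and not math.isfinite(self.d):
            raise ValueError("d must be finite when not excluded")


@dataclass(frozen=True)
class ClassificationConfig:
    """|D| threshold for bias-direction classification (strict inequality)."""

    threshold: float = 0.15

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ValueError("threshold must be positive")


_BLOCK_PAIRS = ((3, 6), (4, 7))


def compute_d(
    session: SessionRecord, config: ScoringConfig = ScoringConfig()
) -> DScoreResult:
    """Improved-algorithm D-score for one session.

    Per block pair (3, 6) and (4, 7):
    ``(mean latency, lower-status-favoring pairing - mean latency,
    higher-status-favoring pairing) / SD of the pair's pooled latencies``,
    then averaged over the available pairs.  A pairing "favors" a group
    when that group shares a key with "pleasant"; being slower in the
    lower-status-favoring pairing therefore yields positive D =
    higher-status preference.
    """
    # which semantic pairing favors the higher-status group for this person
    if session.status_role is StatusRole.LOWER:
        higher_pairing = Pairing.OUTGROUP_PLEASANT
    else:
        higher_pairing = Pairing.INGROUP_PLEASANT
    lower_pairing = (
        Pairing.INGROUP_PLEASANT
        if higher_pairing is Pairing.OUTGROUP_PLEASANT
        else Pairing.OUTGROUP_PLEASANT
    )

    critical = [t for t in session.critical_trials() if t.latency_ms <= config.slow_cutoff_ms]
    if not critical:
        return DScoreResult(math.nan, True, ExclusionReason.INSUFFICIENT_TRIALS)
    n_fast = sum(1 for t in critical if t.latency_ms < config.fast_cutoff_ms)
    if n_fast / len(critical) > config.fast_fraction_limit:
        return DScoreResult(math.nan, True, ExclusionReason.TOO_FAST_TRIALS)

    pair_ds = []
    for blocks in _BLOCK_PAIRS:
        lower_lat = [
            t.latency_ms
            for t in critical
            if t.block_index in blocks and t.pairing is lower_pairing
        ]
        higher_lat = [
            t.latency_ms
            for t in critical
            if t.block_index in blocks and t.pairing is higher_pairing
        ]
        if not lower_lat and not higher_lat:
            continue  # pair entirely absent (e.g. partial session)
        if not lower_lat or not higher_lat:
            return DScoreResult(math.nan, True, ExclusionReason.INSUFFICIENT_TRIALS)
        pooled = np.array(lower_lat + higher_lat, dtype=float)
        sd = float(np.std(pooled, ddof=1)) if pooled.size > 1 else 0.0
        if sd == 0.0:
            diff = float(np.mean(lower_lat) - np.mean(higher_lat))
            pair_ds.append(0.0 if diff == 0.0 else math.nan)
            continue
        pair_ds.append(float((np.mean(lower_lat) - np.mean(higher_lat)) / sd))

    if not pair_ds or any(math.isnan(x) for x in pair_ds):
        return DScoreResult(math.nan, True, ExclusionReason.INSUFFICIENT_TRIALS)
    return DScoreResult(float(np.mean(pair_ds)), False, None)


def classify_by_d(
    d: float,
    status_role: StatusRole,
    config: ClassificationConfig = ClassificationConfig(),
) -> BiasClassification:
    """Threshold classification of bias direction from a D-score.

    Lower-status participants: D > threshold -> outgroup bias (preference
    for the higher-status outgroup); D < -threshold -> ingroup bias.
    Higher-status participants are mirrored.  Values at exactly the
    threshold stay unclassified (strict inequalities).
    """
    if not math.isfinite(d):
        raise ValueError("d must be finite")
    thr = config.threshold
    if status_role is StatusRole.LOWER:
        if d > thr:
            return BiasClassification.OUTGROUP_BIASED
        if d < -thr:
            return BiasClassification.INGROUP_BIASED
    else:
        if d < -thr:
            return BiasClassification.OUTGROUP_BIASED
        if d > thr:
            return BiasClassification.INGROUP_BIASED
    return BiasClassification.UNCLASSIFIED


@dataclass(frozen=True)
class DescriptiveStats:
    n: int
    fraction_of_total: float
    mean_d: float
    sd_d: float
    t_vs_zero: float  # nan when unavailable
    d_vs_zero: float  # Cohen's d vs 0; nan when unavailable
    comparison_d: float  # standardized effect vs the opposite subsample; nan if absent
    available: bool  # False when n < 2 or sd == 0


def _one_group_stats(values: np.ndarray, total: int, comparison_d: float) -> DescriptiveStats:
    n = values.size
    if n == 0:
        return DescriptiveStats(0, 0.0, math.nan, math.nan, math.nan, math.nan,
                                comparison_d, False)
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if n > 1 else math.nan
    if n < 2 or not sd or math.isnan(sd):
        return DescriptiveStats(n, n / total, mean, sd if n > 1 else math.nan,
                                math.nan, math.nan, comparison_d, False)
    t = float(stats.ttest_1samp(values, 0.0).statistic)
    return DescriptiveStats(n, n / total, mean, sd, t, mean / sd, comparison_d, True)


def describe_subsamples(
    dscores_by_class: Mapping[BiasClassification, Sequence[float]],
) -> dict[BiasClassification, DescriptiveStats]:
    """Per-subsample descriptives: n, fraction, mean (SD), one-sample t and
    Cohen's d against zero, and a between-subsample standardized mean
    difference (pooled-SD, independent groups) between the outgroup- and
    ingroup-biased subsamples.
    """
    total = sum(len(v) for v in dscores_by_class.values())
    if total == 0:
        raise ValueError("no d-scores supplied")
    out = np.asarray(
        dscores_by_class.get(BiasClassification.OUTGROUP_BIASED, ()), dtype=float
    )
    ing = np.asarray(
        dscores_by_class.get(BiasClassification.INGROUP_BIASED, ()), dtype=float
    )
    comparison = math.nan
    if out.size >= 2 and ing.size >= 2:
        pooled_var = (
            (out.size - 1) * np.var(out, ddof=1) + (ing.size - 1) * np.var(ing, ddof=1)
        ) / (out.size + ing.size - 2)
        if pooled_var > 0:
            comparison = float(abs(np.mean(out) - np.mean(ing)) / math.sqrt(pooled_var))
        elif np.mean(out) == np.mean(ing):
            comparison = 0.0

    results = {}
    for cls, values in dscores_by_class.items():
        arr = np.asarray(values, dtype=float)
        cmp_d = comparison if cls in (
            BiasClassification.OUTGROUP_BIASED, BiasClassification.INGROUP_BIASED
        ) else math.nan
        results[cls] = _one_group_stats(arr, total, cmp_d)
    return results
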