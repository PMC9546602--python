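"""Feeling-thermometer classification and summary statistics.

Explicit warmth toward the ingroup and the outgroup is rated on an
11-point 0-10 scale with midpoint 5 as evaluative neutrality.  Bias
direction is the sign of the between-thermometer difference; equal
ratings are excluded.  Summaries report each thermometer's mean (SD),
one-sample t and Cohen's d against the midpoint, and a paired
standardized mean difference between the two thermometers (same people
rate both groups, so the comparison is genuinely paired: mean
within-person difference over the SD of within-person differences).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ThermometerRecord",
    "ThermoClassification",
    "ThermometerStats",
    "MIDPOINT",
    "classify_thermo",
    "thermo_stats",
    "cohens_d_vs_midpoint",
]

MIDPOINT = 5.0


class ThermoClassification(str, enum.Enum):
    OUTGROUP_BIASED = "outgroup_biased"
    INGROUP_BIASED = "ingroup_biased"
    EXCLUDED = "excluded"


@dataclass(frozen=True)
class ThermometerRecord:
    ingroup_warmth: int
    outgroup_warmth: int

    def __post_init__(self) -> None:
        for name in ("ingroup_warmth", "outgroup_warmth"):
            v = getattr(self, name)
            if not 0 <= v <= 10:
                raise ValueError(f"{name} must be in 0-10, got {v}")


def classify_thermo(rec: ThermometerRecord) -> ThermoClassification:
    """Bias direction from the two warmth ratings; ties are excluded."""
    if rec.outgroup_warmth > rec.ingroup_warmth:
        return ThermoClassification.OUTGROUP_BIASED
    if rec.ingroup_warmth > rec.outgroup_warmth:
        return ThermoClassification.INGROUP_BIASED
    return ThermoClassification.EXCLUDED


def cohens_d_vs_midpoint(mean: float, sd: float, midpoint: float = MIDPOINT) -> float:
    """(mean - midpoint) / SD; nan when the SD is zero."""
    if sd == 0 or math.isnan(sd):
        return math.nan
    return (mean - midpoint) / sd


@dataclass(frozen=True)
class ThermometerStats:
    n: int
    fraction_of_total: float
    mean_ingroup: float
    sd_ingroup: float
    d_ingroup_vs_midpoint: float  # nan when unavailable (SD = 0 or n < 2)
    t_ingroup_vs_midpoint: float
    mean_outgroup: float
    sd_outgroup: float
    d_outgroup_vs_midpoint: float
    t_outgroup_vs_midpoint: float
    comparison_d: float  # paired standardized mean difference, |d|


def thermo_stats(
    records_by_class: Mapping[ThermoClassification, Sequence[ThermometerRecord]],
) -> dict[ThermoClassification, ThermometerStats]:
    """Per-classification thermometer summaries.

    Means are compared to the scale midpoint in one-sample t tests; the
    two thermometers are compared to one another within person (paired).
    """
    total = sum(len(v) for v in records_by_class.values())
    if total == 0:
        raise ValueError("no thermometer records supplied")
    out = {}
    for cls, records in records_by_class.items():
        if not records:
            continue
        ing = np.array([r.ingroup_warmth for r in records], dtype=float)
        outg = np.array([r.outgroup_warmth for r in records], dtype=float)
        n = ing.size

        def summarize(values: np.ndarray) -> tuple[float, float, float, float]:
            mean = float(np.mean(values))
            sd = float(np.std(values, ddof=1)) if n > 1 else math.nan
            d = cohens_d_vs_midpoint(mean, sd)
            t = (
                float(stats.ttest_1samp(values, MIDPOINT).statistic)
                if n > 1 and sd > 0
                else math.nan
            )
            return mean, sd, d, t

        mi, si, di, ti = summarize(ing)
        mo, so, do, to = summarize(outg)
        diffs = ing - outg
        sd_diff = float(np.std(diffs, ddof=1)) if n > 1 else math.nan
        if n > 1 and sd_diff > 0:
            comparison = float(abs(np.mean(diffs)) / sd_diff)
        elif n > 1 and np.allclose(diffs, diffs[0]) and diffs[0] == 0:
            comparison = 0.0
        else:
            comparison = math.nan
        out[cls] = ThermometerStats(
            n, n / total, mi, si, di, ti, mo, so, do, to, comparison
        )
    return out
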