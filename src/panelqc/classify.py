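"""Decision thresholds and sample classification.

Two boundaries partition the R² axis into three identity calls:

* ``same_type_lower`` — mean + k·SD (default k = 1, sample SD) of the R²
  values that other-tissue MSC populations achieve against the target
  population's reference profile.  At or above it a sample is called the
  target MSC type.
* ``non_msc_upper`` — the maximum R² observed for non-MSC cell types.  At or
  below it a sample is flagged non-MSC-like.

Between the two bounds lies the "other MSC" zone: mesenchymal, but not the
target tissue type.  Reported threshold statistics are rounded to three
decimals, and the lower bound is the sum of the *rounded* mean and SD — the
convention that keeps the bound consistent with how the statistics are
printed in a QC report.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field

import numpy as np

from .correlate import CorrelationRecord

LABEL_TARGET = "target_msc"
LABEL_OTHER = "other_msc_zone"
LABEL_NON_MSC = "non_msc_like"

#: classification labels from least to most similar to the target type
LABEL_ORDER = (LABEL_NON_MSC, LABEL_OTHER, LABEL_TARGET)


@dataclass
class ThresholdSet:
    """Derived decision boundaries plus the statistics that produced them."""

    same_type_lower: float
    non_msc_upper: float
    other_msc_mean: float
    other_msc_sd: float
    sd_multiplier: float = 1.0
    provenance: list[CorrelationRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0 < self.non_msc_upper < self.same_type_lower < 1):
            raise ValueError(
                "invalid thresholds: need 0 < non_msc_upper "
                f"({self.non_msc_upper}) < same_type_lower "
                f"({self.same_type_lower}) < 1"
            )


def derive_thresholds(
    other_msc_r2,
    non_msc_r2,
    sd_multiplier: float = 1.0,
    provenance: list[CorrelationRecord] | None = None,
) -> ThresholdSet:
    """Derive the two boundaries from observed R² values.

    ``other_msc_r2`` are R² values of other-tissue MSC populations against
    the target reference (≥ 2 values, since the SD uses the n−1
    denominator); ``non_msc_r2`` are R² values of non-MSC cell types (≥ 1).
    All reported statistics are rounded to 3 decimals; the lower bound is
    rounded-mean + ``sd_multiplier`` × rounded-SD.
    """
    other = [float(v) for v in other_msc_r2]
    non = [float(v) for v in non_msc_r2]
    if len(other) < 2:
        raise ValueError("need at least 2 other-MSC R² values to estimate an SD")
    if not non:
        raise ValueError("need at least 1 non-MSC R² value")
    mean = round(statistics.fmean(other), 3)
    sd = round(statistics.stdev(other), 3)  # sample SD, n-1 denominator
    lower = round(mean + sd_multiplier * sd, 3)
    # ceil to 3 decimals: the bound must not round below the observed
    # maximum, or the defining sample would leave its own class
    upper = math.ceil(max(non) * 1000 - 1e-9) / 1000
    return ThresholdSet(
        same_type_lower=lower,
        non_msc_upper=upper,
        other_msc_mean=mean,
        other_msc_sd=sd,
        sd_multiplier=sd_multiplier,
        provenance=list(provenance or []),
    )


@dataclass(frozen=True)
class QCDecision:
    """Identity call for one sample: R² against the target reference."""

    sample_id: str
    r_squared: float
    label: str
    thresholds: ThresholdSet
    gene_set_name: str = ""


def classify_sample(
    r2: float,
    thresholds: ThresholdSet,
    sample_id: str = "",
    gene_set_name: str = "",
) -> QCDecision:
    """Label a sample by its R² against the target reference.

    Boundaries are inclusive on both sides: R² ≥ lower bound → target type;
    R² ≤ upper non-MSC bound → non-MSC-like; otherwise the other-MSC zone.
    """
    if not 0 <= r2 <= 1:
        raise ValueError(f"R² must lie in [0, 1], got {r2}")
    if r2 >= thresholds.same_type_lower:
        label = LABEL_TARGET
    elif r2 <= thresholds.non_msc_upper:
        label = LABEL_NON_MSC
    else:
        label = LABEL_OTHER
    return QCDecision(sample_id, r2, label, thresholds, gene_set_name)


@dataclass(frozen=True)
class PassagePoint:
    passage: str
    r_squared: float
    decision: QCDecision


@dataclass
class PassageTrend:
    """Per-passage decisions for one lot monitored across culture."""

    points: list[PassagePoint]
    first_degraded: str | None
    deltas: list[float]
    slope: float | None

    @property
    def labels(self) -> list[str]:
        return [p.decision.label for p in self.points]


def monitor_passages(series, thresholds: ThresholdSet) -> PassageTrend:
    """Track a lot's R² across successive passages.

    ``series`` is an ordered list of ``(passage_label, record_or_r2)``
    pairs (records may be :class:`CorrelationRecord`).  Reports the
    per-passage decision, the first passage at which the label drops below
    ``target_msc`` (None if never), the signed R² change between successive
    passages, and the least-squares slope of R² per passage step (None for a
    single-passage series).
    """
    series = list(series)
    if not series:
        raise ValueError("empty passage series")
    points: list[PassagePoint] = []
    for passage, rec in series:
        r2 = rec.r_squared if isinstance(rec, CorrelationRecord) else float(rec)
        sid = rec.sample_id if isinstance(rec, CorrelationRecord) else str(passage)
        dec = classify_sample(r2, thresholds, sample_id=sid)
        points.append(PassagePoint(str(passage), r2, dec))
    first_degraded = next(
        (p.passage for p in points if p.decision.label != LABEL_TARGET), None
    )
    r2s = [p.r_squared for p in points]
    deltas = list(np.diff(r2s))
    slope = (
        float(np.polyfit(np.arange(len(r2s)), r2s, 1)[0]) if len(r2s) >= 2 else None
    )
    return PassageTrend(points, first_degraded, deltas, slope)
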