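"""Panel-restricted correlation scoring and gene-set benchmarking.

The identity statistic is R²: the squared Pearson correlation between two
samples' log-TPM vectors over a gene set.  Discrimination of a cell type
from the reference population is summarised as

    %CV = |(R²_self − R²_other) / R²_self| × 100

where R²_self is the reference lot's agreement with its own population's
median profile.  Detection power of a curated panel against a comparator
gene set (random subset, or all genes) is the ratio of the two %CV values,
computed from unrounded R².
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, UnitError
from .matrix import ExpressionMatrix
from .panel import GenePanel, subset_matrix

MIN_GENES = 3


def _round_half_up(x: float, ndigits: int = 0) -> float:
    scale = 10.0 ** ndigits
    return math.floor(x * scale + 0.5) / scale


def r_squared(x, y, mode: str = "pearson_sq") -> float:
    """Coefficient of determination between two expression vectors.

    ``mode='pearson_sq'`` (default) squares the Pearson correlation and is
    symmetric in its arguments; ``mode='identity_line'`` instead measures
    1 − SSE/SST about the line y = x, which penalises systematic offsets.
    A negative Pearson slope still yields a high pearson_sq value, so it is
    flagged with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < MIN_GENES:
        raise ValueError(f"need at least {MIN_GENES} genes, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant vector: correlation undefined")
    if mode == "pearson_sq":
        xc = x - x.mean()
        yc = y - y.mean()
        denom = math.sqrt((xc @ xc) * (yc @ yc))
        if denom == 0:  # variance underflow on near-constant input
            raise DegenerateInputError("vector variance underflows to zero")
        r = float(xc @ yc / denom)
        if r < 0:
            warnings.warn(
                "negative correlation slope; R² hides the sign", stacklevel=2
            )
        return min(r * r, 1.0)
    if mode == "identity_line":
        sse = float(np.sum((y - x) ** 2))
        sst = float(np.sum((y - y.mean()) ** 2))
        return 1.0 - sse / sst
    raise ValueError(f"unknown r2 mode {mode!r}")


@dataclass(frozen=True)
class ReferenceProfile:
    """Per-gene median log-TPM across the lots of one cell population."""

    name: str
    values: pd.Series
    n_lots: int

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)


def reference_profile(
    matrix: ExpressionMatrix, name: str, sample_ids=None
) -> ReferenceProfile:
    """Median log-TPM profile across the given samples (default: all)."""
    if matrix.unit != "logTPM":
        raise UnitError(f"reference profiles need logTPM, got {matrix.unit!r}")
    cols = list(sample_ids) if sample_ids is not None else matrix.sample_ids
    if not cols:
        raise ValueError("need at least one sample to build a reference profile")
    sub = matrix.values[cols]
    return ReferenceProfile(name=name, values=sub.median(axis=1), n_lots=len(cols))


@dataclass(frozen=True)
class CorrelationRecord:
    """One pairwise comparison: sample vs. sample-or-reference."""

    sample_id: str
    reference_id: str
    gene_set_name: str
    n_genes: int
    r_squared: float


def correlation_table(
    matrix: ExpressionMatrix,
    panel: GenePanel | None,
    references: list[ReferenceProfile] = (),
    include_sample_pairs: bool = False,
    mode: str = "pearson_sq",
) -> list[CorrelationRecord]:
    """R² of every sample against each reference (and, optionally, each
    other sample), restricted to the panel's genes.

    ``panel=None`` uses every gene in the matrix (the "all genes" view).
    """
    if matrix.unit != "logTPM":
        raise UnitError(f"correlation needs logTPM, got {matrix.unit!r}")
    sub = subset_matrix(matrix, panel) if panel is not None else matrix
    set_name = panel.name if panel is not None else "all-genes"
    records: list[CorrelationRecord] = []
    for ref in references:
        shared = sub.values.index.intersection(ref.values.index)
        if len(shared) < MIN_GENES:
            raise ValueError(
                f"fewer than {MIN_GENES} genes shared with reference {ref.name!r}"
            )
        ref_vec = ref.values.loc[shared].to_numpy()
        for sample in sub.sample_ids:
            r2 = r_squared(sub.values.loc[shared, sample].to_numpy(), ref_vec, mode=mode)
            records.append(
                CorrelationRecord(sample, ref.name, set_name, len(shared), r2)
            )
    if include_sample_pairs:
        for a, b in itertools.combinations(sub.sample_ids, 2):
            r2 = r_squared(
                sub.values[a].to_numpy(), sub.values[b].to_numpy(), mode=mode
            )
            records.append(CorrelationRecord(a, b, set_name, sub.n_genes, r2))
    return records


def records_to_frame(records) -> pd.DataFrame:
    """Tidy DataFrame view of a list of CorrelationRecords."""
    return pd.DataFrame([r.__dict__ for r in records])


def cv_percent(r2_self: float, r2_other: float) -> float:
    """Relative deviation of a comparison R² from the self-reference R², in %.

    Returned unrounded; reports conventionally round to the nearest integer
    percent (see :func:`round_cv`).
    """
    if r2_self == 0:
        raise DegenerateInputError("self-reference R² is zero; %CV undefined")
    return abs((r2_self - r2_other) / r2_self) * 100.0


def round_cv(cv: float) -> int:
    """Report rounding for %CV: nearest integer percent, half away from zero."""
    return int(_round_half_up(cv))


def detection_power(
    r2_self_a: float, r2_other_a: float, r2_self_b: float, r2_other_b: float
) -> float:
    """CV ratio of gene set *a* (the curated panel) over comparator *b*.

    Computed from unrounded R²; reports round to 2 decimals
    (:func:`round_power`).  A comparator CV of zero has no defined ratio.
    """
    cv_a = cv_percent(r2_self_a, r2_other_a)
    cv_b = cv_percent(r2_self_b, r2_other_b)
    if cv_b == 0:
        raise DegenerateInputError("comparator gene set has zero %CV; power undefined")
    return cv_a / cv_b


def round_power(power: float) -> float:
    return _round_half_up(power, 2)


@dataclass
class ReferenceSpec:
    """How to anchor a gene-set benchmark.

    ``query_sample`` is the lot whose R² values populate the table (one lot
    of the target population); ``self_samples`` are the lots whose median is
    that population's reference profile; ``groups`` maps a display name of
    each compared population to the sample ids whose median profile it is
    scored against.
    """

    query_sample: str
    self_samples: list[str]
    groups: dict[str, list[str]] = field(default_factory=dict)


def benchmark_gene_sets(
    matrix: ExpressionMatrix,
    panel: GenePanel,
    reference_spec: ReferenceSpec,
    comparators: dict[str, GenePanel | None],
    mode: str = "pearson_sq",
) -> pd.DataFrame:
    """Score every group under the panel and each comparator gene set.

    Returns a DataFrame indexed by group with, per gene set *S*, columns
    ``r2_S`` and ``cv_S``, plus ``power_vs_S`` (panel CV / comparator CV)
    for each comparator.  A comparator of ``None`` means "all genes in the
    matrix".
    """
    gene_sets: dict[str, GenePanel | None] = {panel.name: panel, **comparators}
    spec = reference_spec
    out: dict[str, dict[str, float]] = {g: {} for g in spec.groups}
    self_r2: dict[str, float] = {}
    for set_name, gs in gene_sets.items():
        sub = subset_matrix(matrix, gs) if gs is not None else matrix
        self_ref = reference_profile(sub, "self", spec.self_samples)
        q = sub.values[spec.query_sample].to_numpy()
        self_r2[set_name] = r_squared(q, self_ref.values.to_numpy(), mode=mode)
        for group, samples in spec.groups.items():
            ref = reference_profile(sub, group, samples)
            r2 = r_squared(q, ref.values.to_numpy(), mode=mode)
            out[group][f"r2_{set_name}"] = r2
            out[group][f"cv_{set_name}"] = cv_percent(self_r2[set_name], r2)
    for group in spec.groups:
        for comp_name in comparators:
            cv_a = out[group][f"cv_{panel.name}"]
            cv_b = out[group][f"cv_{comp_name}"]
            out[group][f"power_vs_{comp_name}"] = (
                cv_a / cv_b if cv_b > 0 else float("nan")
            )
    frame = pd.DataFrame.from_dict(out, orient="index")
    frame.attrs["self_r2"] = self_r2
    return frame
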