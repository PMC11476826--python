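"""End-to-end QC workflow: counts → log-TPM → panel R² → thresholds → calls.

This is the orchestration a QC analyst runs on a labelled dataset: normalise
the counts, anchor a reference profile on the target population's lots,
derive thresholds from the other-MSC and non-MSC comparisons, and classify.
Target lots are scored leave-one-out (each against the median of the
*remaining* target lots) so a lot never certifies itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .classify import QCDecision, ThresholdSet, classify_sample, derive_thresholds
from .correlate import (
    CorrelationRecord,
    r_squared,
    reference_profile,
)
from .matrix import ExpressionMatrix
from .panel import GenePanel, subset_matrix
from .quantify import counts_to_tpm, log_transform
from .simulate import ROLE_NON_MSC, ROLE_OTHER_MSC, ROLE_TARGET


def preprocess_counts(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Counts → RPKM → TPM → log2 with below-minimum imputation."""
    return log_transform(counts_to_tpm(counts))


@dataclass
class QCReport:
    """Thresholds plus per-sample identity decisions for one dataset."""

    thresholds: ThresholdSet
    decisions: list[QCDecision]
    records: list[CorrelationRecord] = field(default_factory=list)

    @property
    def labels(self) -> pd.Series:
        return pd.Series({d.sample_id: d.label for d in self.decisions})

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sample_id": d.sample_id, "r_squared": d.r_squared, "label": d.label}
            for d in self.decisions
        ]
        return pd.DataFrame(rows).set_index("sample_id")


def qc_report(
    log_matrix: ExpressionMatrix,
    panel: GenePanel,
    cell_type_col: str = "cell_type",
    role_col: str = "role",
) -> QCReport:
    """Run the full identity QC on a labelled log-TPM matrix.

    ``sample_meta`` must assign each sample a cell type and a role
    (``target`` / ``other_msc`` / ``non_msc``).  Thresholds come from the
    per-type median R² of other-MSC populations and the per-sample R² of
    non-MSC samples, both against the target population's median profile.
    """
    meta = log_matrix.sample_meta
    if meta is None or role_col not in meta.columns:
        raise ValueError("sample_meta with a role column is required")
    sub = subset_matrix(log_matrix, panel)
    target_ids = list(meta.index[meta[role_col] == ROLE_TARGET])
    if len(target_ids) < 2:
        raise ValueError("need at least 2 target-role lots")
    target_ref = reference_profile(sub, "target-median", target_ids)

    records: list[CorrelationRecord] = []
    other_r2: list[float] = []
    for cell_type, group in meta[meta[role_col] == ROLE_OTHER_MSC].groupby(
        cell_type_col, sort=False
    ):
        type_ref = reference_profile(sub, str(cell_type), list(group.index))
        r2 = r_squared(type_ref.values.to_numpy(), target_ref.values.to_numpy())
        other_r2.append(r2)
        records.append(
            CorrelationRecord(f"{cell_type}(med)", target_ref.name, panel.name,
                              sub.n_genes, r2)
        )
    non_ids = list(meta.index[meta[role_col] == ROLE_NON_MSC])
    non_r2: dict[str, float] = {}
    for sid in non_ids:
        r2 = r_squared(sub.values[sid].to_numpy(), target_ref.values.to_numpy())
        non_r2[sid] = r2
        records.append(
            CorrelationRecord(sid, target_ref.name, panel.name, sub.n_genes, r2)
        )

    thresholds = derive_thresholds(other_r2, list(non_r2.values()),
                                   provenance=records)

    decisions: list[QCDecision] = []
    # target lots: leave-one-out against the median of the remaining lots
    for sid in target_ids:
        rest = [t for t in target_ids if t != sid]
        ref = reference_profile(sub, "target-median-loo", rest)
        r2 = r_squared(sub.values[sid].to_numpy(), ref.values.to_numpy())
        records.append(CorrelationRecord(sid, ref.name, panel.name, sub.n_genes, r2))
        decisions.append(classify_sample(r2, thresholds, sid, panel.name))
    for sid in meta.index[meta[role_col] != ROLE_TARGET]:
        if sid in non_r2:
            r2 = non_r2[sid]
        else:
            r2 = r_squared(sub.values[sid].to_numpy(), target_ref.values.to_numpy())
        decisions.append(classify_sample(r2, thresholds, sid, panel.name))
    return QCReport(thresholds=thresholds, decisions=decisions, records=records)
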