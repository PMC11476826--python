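"""Read trimming and expression normalization.

Quality trimming follows the cumulative-sum (modified-Mott) rule: each base's
Phred score is converted to an error probability p = 10^(−q/10), the
difference d = limit − p (limit defaults to 0.05) is accumulated with the
running sum clamped at zero, the trimmed read starts at the first position
where the clamped sum becomes positive and ends at the position where the
sum attains its maximum (first occurrence).  A read whose sum never goes
positive is discarded.

Normalization is the classic two-step: RPKM (reads per kilobase per million
mapped reads), then TPM by rescaling each sample's RPKM column to sum to one
million.  The log transform is log2 with below-minimum imputation: zeros are
replaced by half the smallest positive TPM in the matrix, so absence of
expression still carries weight in downstream correlations.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, FormatError
from .matrix import ExpressionMatrix, TPM_SCALE

DEFAULT_TRIM_LIMIT = 0.05


def phred_to_error_prob(q):
    """Error probability 10^(−q/10) for a Phred score (scalar or array)."""
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("Phred scores must be non-negative")
    p = 10.0 ** (-q / 10.0)
    return float(p) if p.ndim == 0 else p


@dataclass(frozen=True)
class TrimResult:
    """Retained interval [start, end) of a quality-trimmed read."""

    start: int
    end: int

    @property
    def kept_length(self) -> int:
        return self.end - self.start

    @property
    def discarded(self) -> bool:
        return self.kept_length == 0


def trim_read(qualities, limit: float = DEFAULT_TRIM_LIMIT) -> TrimResult:
    """Trim one read by the clamped cumulative-sum rule.

    Parameters
    ----------
    qualities
        Per-base Phred scores (integers, already decoded from Phred+33).
    limit
        Error-probability limit; bases with error probability above it pull
        the cumulative sum down.

    Returns
    -------
    TrimResult
        0-based half-open retained interval; ``start == end == 0`` encodes a
        fully discarded read.
    """
    q = np.asarray(qualities, dtype=float)
    if q.size == 0:
        raise ValueError("cannot trim an empty quality sequence")
    d = limit - phred_to_error_prob(q)
    s = np.empty_like(d)
    acc = 0.0
    for i, di in enumerate(d):
        acc = max(0.0, acc + di)
        s[i] = acc
    positive = s > 0
    if not positive.any():
        return TrimResult(0, 0)
    start = int(np.argmax(positive))
    end = int(np.argmax(s)) + 1  # first occurrence of the maximum
    return TrimResult(start, end)


@dataclass
class TrimSummary:
    """Bookkeeping from trimming a FASTQ file."""

    reads_in: int = 0
    reads_kept: int = 0
    reads_discarded: int = 0
    bases_in: int = 0
    bases_removed: int = 0


def _open_maybe_gzip(path, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def trim_fastq(in_path, out_path, limit: float = DEFAULT_TRIM_LIMIT) -> TrimSummary:
    """Quality-trim a Phred+33 FASTQ file; discarded reads are omitted.

    Read ids and input order are preserved.  Gzipped input/output is
    recognised by the ``.gz`` suffix.
    """
    from Bio import SeqIO
    from Bio.SeqRecord import SeqRecord

    summary = TrimSummary()
    with _open_maybe_gzip(in_path, "r") as fin, _open_maybe_gzip(out_path, "w") as fout:
        try:
            for idx, rec in enumerate(SeqIO.parse(fin, "fastq")):
                summary.reads_in += 1
                quals = rec.letter_annotations["phred_quality"]
                summary.bases_in += len(quals)
                res = trim_read(quals, limit=limit)
                if res.discarded:
                    summary.reads_discarded += 1
                    summary.bases_removed += len(quals)
                    continue
                summary.reads_kept += 1
                summary.bases_removed += len(quals) - res.kept_length
                trimmed: SeqRecord = rec[res.start : res.end]
                SeqIO.write(trimmed, fout, "fastq")
        except ValueError as exc:
            raise FormatError(
                f"malformed FASTQ near record {summary.reads_in}: {exc}"
            ) from exc
    return summary


def compute_rpkm(counts: ExpressionMatrix, gene_lengths=None) -> ExpressionMatrix:
    """Counts → RPKM: counts / (length/1e3) / (library/1e6) per sample."""
    if counts.unit != "counts":
        raise ValueError(f"expected a counts matrix, got unit {counts.unit!r}")
    lengths = gene_lengths if gene_lengths is not None else counts.gene_lengths
    if lengths is None:
        raise ValueError("gene lengths are required to compute RPKM")
    lengths = lengths.reindex(counts.values.index)
    bad = lengths.index[lengths.isna() | (lengths <= 0)]
    if len(bad):
        raise ValueError(f"missing or non-positive length for gene(s): {list(bad[:5])}")
    libsize = counts.values.sum(axis=0)
    zero = libsize.index[libsize == 0]
    if len(zero):
        raise DegenerateInputError(f"zero library size for sample(s): {list(zero[:5])}")
    per_kb = counts.values.div(lengths / 1e3, axis=0)
    rpkm = per_kb.div(libsize / 1e6, axis=1)
    return counts.replace(values=rpkm, unit="RPKM")


def rpkm_to_tpm(rpkm: ExpressionMatrix) -> ExpressionMatrix:
    """RPKM → TPM: rescale each sample so its column sums to one million."""
    if rpkm.unit != "RPKM":
        raise ValueError(f"expected an RPKM matrix, got unit {rpkm.unit!r}")
    colsum = rpkm.values.sum(axis=0)
    zero = colsum.index[colsum == 0]
    if len(zero):
        raise DegenerateInputError(f"all-zero RPKM column for sample(s): {list(zero[:5])}")
    tpm = rpkm.values.div(colsum, axis=1) * TPM_SCALE
    return rpkm.replace(values=tpm, unit="TPM")


def counts_to_tpm(counts: ExpressionMatrix, gene_lengths=None) -> ExpressionMatrix:
    """Convenience: counts → RPKM → TPM."""
    return rpkm_to_tpm(compute_rpkm(counts, gene_lengths))


def log_transform(tpm: ExpressionMatrix) -> ExpressionMatrix:
    """TPM → log2(TPM) with below-minimum imputation of zeros.

    Zeros (dropouts / undetected genes) are replaced by half the smallest
    positive TPM anywhere in the matrix before taking log2, so every imputed
    value sits strictly below every observed one.  The imputation value is
    recorded in ``attrs['log_impute_value']``.
    """
    if tpm.unit != "TPM":
        raise ValueError(f"expected a TPM matrix, got unit {tpm.unit!r}")
    arr = tpm.values.to_numpy(dtype=float)
    positive = arr[arr > 0]
    if positive.size == 0:
        raise DegenerateInputError("matrix is entirely zero; cannot log-transform")
    impute = positive.min() / 2.0
    filled = np.where(arr > 0, arr, impute)
    logged = tpm.values.copy()
    logged.loc[:, :] = np.log2(filled)
    out = tpm.replace(values=logged, unit="logTPM")
    out.attrs["log_impute_value"] = float(impute)
    return out
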