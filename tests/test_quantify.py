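"""Quality trimming, RPKM/TPM normalization and log imputation."""

import gzip
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panelqc import (
    DegenerateInputError,
    ExpressionMatrix,
    FormatError,
    compute_rpkm,
    log_transform,
    phred_to_error_prob,
    rpkm_to_tpm,
    trim_fastq,
    trim_read,
)


def oracle_trim(qualities, limit=0.05):
    """Independent brute-force reference for the clamped cumulative-sum rule."""
    sums = []
    acc = 0.0
    for q in qualities:
        acc = acc + (limit - 10 ** (-q / 10))
        if acc <= 0:
            acc = 0.0
        sums.append(acc)
    best = max(sums)
    if best <= 0:
        return (0, 0)
    end = sums.index(best) + 1
    start = next(i for i, s in enumerate(sums) if s > 0)
    return (start, end)


class TestPhred:
    @pytest.mark.parametrize(
        "q,p", [(0, 1.0), (10, 0.1), (20, 0.01), (2, 0.6310)]
    )
    def test_closed_form(self, q, p):
        assert phred_to_error_prob(q) == pytest.approx(p, abs=5e-5)

    def test_negative_score_rejected(self):
        with pytest.raises(ValueError):
            phred_to_error_prob(-1)

    def test_vectorized(self):
        np.testing.assert_allclose(
            phred_to_error_prob([0, 10, 20]), [1.0, 0.1, 0.01]
        )


class TestTrimRead:
    def test_high_quality_read_kept_whole(self):
        res = trim_read([40] * 10)
        assert (res.start, res.end) == (0, 10)

    def test_low_quality_read_discarded(self):
        res = trim_read([2] * 10)
        assert (res.start, res.end) == (0, 0)
        assert res.discarded

    def test_hand_computed_interval(self):
        # clamped sums: 0,0,.0499,.0998,.1497,0,.0499,0,0 -> [2, 5)
        res = trim_read([2, 2, 40, 40, 40, 2, 40, 2, 2])
        assert (res.start, res.end) == (2, 5)
        assert res.kept_length == 3

    def test_tie_breaks_at_first_maximum(self):
        # q=20 gives d=0.04 exactly; 20,20,0,20,20 sums: .04,.08,0,.04,.08
        res = trim_read([20, 20, 0, 20, 20])
        assert (res.start, res.end) == (0, 2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            trim_read([])

    @given(st.lists(st.integers(min_value=2, max_value=41), min_size=1,
                    max_size=30))
    @settings(deadline=None, max_examples=300)
    def test_matches_bruteforce_oracle(self, quals):
        res = trim_read(quals)
        assert (res.start, res.end) == oracle_trim(quals)

    def test_degrading_a_base_never_raises_quality_mass(self, rng):
        """Lowering one base's quality never increases the maximal clamped
        cumulative sum (the kept segment's quality mass).

        The interval *length* itself is not monotone: erasing an early peak
        can hand the argmax to a later, longer-reaching peak that survives a
        clamp reset unchanged.
        """

        def max_mass(quals):
            acc = best = 0.0
            for q in quals:
                acc = max(0.0, acc + (0.05 - 10 ** (-q / 10)))
                best = max(best, acc)
            return best

        for _ in range(200):
            quals = rng.integers(2, 42, size=rng.integers(1, 25)).tolist()
            i = int(rng.integers(0, len(quals)))
            worse = quals.copy()
            worse[i] = 2
            assert max_mass(worse) <= max_mass(quals) + 1e-12
            # and a discarded read stays discarded
            if trim_read(quals).discarded:
                assert trim_read(worse).discarded


def _write_fastq(path, records):
    text = "".join(
        f"@{rid}\n{seq}\n+\n{qual}\n" for rid, seq, qual in records
    )
    if str(path).endswith(".gz"):
        with gzip.open(path, "wt") as fh:
            fh.write(text)
    else:
        path.write_text(text)


class TestTrimFastq:
    def test_keeps_good_drops_bad(self, tmp_path):
        inp, out = tmp_path / "in.fastq", tmp_path / "out.fastq"
        good_q = chr(40 + 33) * 8
        bad_q = chr(2 + 33) * 8
        _write_fastq(inp, [("good", "ACGTACGT", good_q), ("bad", "ACGTACGT", bad_q)])
        summary = trim_fastq(inp, out)
        assert (summary.reads_in, summary.reads_kept, summary.reads_discarded) == (2, 1, 1)
        assert summary.bases_removed == 8
        lines = out.read_text().splitlines()
        assert lines[0] == "@good"
        assert len(lines) == 4

    def test_empty_file(self, tmp_path):
        inp, out = tmp_path / "in.fastq", tmp_path / "out.fastq"
        inp.write_text("")
        summary = trim_fastq(inp, out)
        assert summary.reads_in == 0
        assert out.read_text() == ""

    def test_trimming_is_idempotent_for_clean_reads(self, tmp_path):
        inp = tmp_path / "in.fastq"
        mid = tmp_path / "mid.fastq"
        out = tmp_path / "out.fastq"
        _write_fastq(inp, [("r1", "ACGTACGTAC", chr(40 + 33) * 10)])
        trim_fastq(inp, mid)
        summary = trim_fastq(mid, out)
        assert summary.bases_removed == 0
        assert mid.read_text() == out.read_text()

    def test_gzip_roundtrip(self, tmp_path):
        inp, out = tmp_path / "in.fastq.gz", tmp_path / "out.fastq.gz"
        _write_fastq(inp, [("r1", "ACGT", chr(40 + 33) * 4)])
        summary = trim_fastq(inp, out)
        assert summary.reads_kept == 1
        with gzip.open(out, "rt") as fh:
            assert fh.readline().strip() == "@r1"

    def test_malformed_record(self, tmp_path):
        inp, out = tmp_path / "in.fastq", tmp_path / "out.fastq"
        inp.write_text("@r1\nACGT\n+\nII\n")  # qual length mismatch
        with pytest.raises(FormatError):
            trim_fastq(inp, out)


class TestRpkmTpm:
    def test_single_gene_unit_case(self):
        em = ExpressionMatrix(
            values=pd.DataFrame({"s": [100.0]}, index=["g"]),
            unit="counts",
            gene_lengths=pd.Series([1000.0], index=["g"]),
        )
        rpkm = compute_rpkm(em)
        assert rpkm.values.loc["g", "s"] == pytest.approx(1e6)
        assert rpkm_to_tpm(rpkm).values.loc["g", "s"] == pytest.approx(1e6)

    def test_hand_arithmetic(self):
        em = ExpressionMatrix(
            values=pd.DataFrame({"s": [100.0, 100.0]}, index=["g1", "g2"]),
            unit="counts",
            gene_lengths=pd.Series([1000.0, 2000.0], index=["g1", "g2"]),
        )
        rpkm = compute_rpkm(em)
        np.testing.assert_allclose(rpkm.values["s"], [5e5, 2.5e5])
        tpm = rpkm_to_tpm(rpkm)
        np.testing.assert_allclose(tpm.values["s"], [1e6 * 2 / 3, 1e6 / 3])

    def test_rpkm_column_example(self):
        rpkm = ExpressionMatrix(
            values=pd.DataFrame({"s": [10.0, 30.0, 60.0]}, index=list("abc")),
            unit="RPKM",
        )
        tpm = rpkm_to_tpm(rpkm)
        np.testing.assert_allclose(tpm.values["s"], [1e5, 3e5, 6e5])

    def test_zero_count_stays_zero(self, small_counts):
        tpm = rpkm_to_tpm(compute_rpkm(small_counts))
        assert tpm.values.loc["g3", "s1"] == 0.0

    def test_column_sums_and_scale_invariance(self, rng):
        values = pd.DataFrame(
            rng.gamma(2.0, 50.0, size=(40, 5)),
            index=[f"g{i}" for i in range(40)],
            columns=[f"s{i}" for i in range(5)],
        )
        rpkm = ExpressionMatrix(values=values, unit="RPKM")
        tpm = rpkm_to_tpm(rpkm)
        np.testing.assert_allclose(tpm.values.sum(axis=0), 1e6, rtol=1e-9)
        scaled = ExpressionMatrix(values=values.assign(s0=values["s0"] * 7.3),
                                  unit="RPKM")
        tpm2 = rpkm_to_tpm(scaled)
        np.testing.assert_allclose(tpm2.values["s0"], tpm.values["s0"])

    def test_zero_library_names_sample(self):
        em = ExpressionMatrix(
            values=pd.DataFrame({"ok": [1.0], "empty": [0.0]}, index=["g"]),
            unit="counts",
            gene_lengths=pd.Series([1000.0], index=["g"]),
        )
        with pytest.raises(DegenerateInputError, match="empty"):
            compute_rpkm(em)

    def test_missing_length_names_gene(self):
        em = ExpressionMatrix(
            values=pd.DataFrame({"s": [1.0, 1.0]}, index=["g1", "g2"]),
            unit="counts",
            gene_lengths=pd.Series([1000.0, np.nan], index=["g1", "g2"]),
        )
        with pytest.raises(ValueError, match="g2"):
            compute_rpkm(em)

    def test_unit_guard(self, small_counts):
        with pytest.raises(ValueError, match="unit"):
            rpkm_to_tpm(small_counts)


class TestLogTransform:
    def _tpm(self, col):
        col = np.asarray(col, dtype=float)
        col = col / col.sum() * 1e6
        return ExpressionMatrix(
            values=pd.DataFrame({"s": col}, index=[f"g{i}" for i in range(len(col))]),
            unit="TPM",
        )

    def test_imputes_half_min_positive(self):
        # scale-free check: zeros become log2(min_positive / 2)
        em = self._tpm([8.0, 16.0, 24.0, 0.0])
        logged = log_transform(em)
        min_pos = em.values.values[em.values.values > 0].min()
        assert logged.attrs["log_impute_value"] == pytest.approx(min_pos / 2)
        assert logged.values.loc["g3", "s"] == pytest.approx(math.log2(min_pos / 2))
        assert logged.values.loc["g0", "s"] == pytest.approx(math.log2(min_pos))

    def test_no_zeros_plain_log2(self):
        em = self._tpm([1.0, 2.0, 5.0])
        logged = log_transform(em)
        np.testing.assert_allclose(logged.values["s"], np.log2(em.values["s"]))
        assert "log_impute_value" in logged.attrs

    def test_imputed_below_all_observed(self, rng):
        col = rng.gamma(0.5, 100.0, size=60)
        col[rng.random(60) < 0.3] = 0.0
        em = self._tpm(col)
        logged = log_transform(em)
        observed = logged.values.values[em.values.values > 0]
        imputed = logged.values.values[em.values.values == 0]
        assert imputed.size and (imputed < observed.min()).all()

    def test_order_preserving(self, rng):
        col = np.sort(rng.gamma(2.0, 10.0, size=30)) + 0.01
        logged = log_transform(self._tpm(col))
        assert np.all(np.diff(logged.values["s"]) > 0)

    def test_all_zero_matrix_rejected(self):
        em = ExpressionMatrix(
            values=pd.DataFrame({"s": [0.0, 0.0]}, index=["g1", "g2"]),
            unit="RPKM",
        )
        em.unit = "TPM"  # bypass the column-sum construction check
        with pytest.raises(DegenerateInputError):
            log_transform(em)
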