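import numpy as np
import pandas as pd
import pytest

from ribofate.core import (
    CountMatrix,
    ReadPosition,
    RibofateError,
    TranscriptRecord,
    most_abundant_isoform,
    read_counts,
    read_read_positions,
    read_transcriptome,
    write_counts,
    write_read_positions,
    write_transcriptome,
)


def _write_tx(tmp_path, entries):
    """entries: list of (tid, gene, utr5, cds, utr3) raw strings."""
    fasta = tmp_path / "tx.fa"
    regions = tmp_path / "regions.tsv"
    with open(fasta, "w") as fh:
        for tid, _, u5, cds, u3 in entries:
            fh.write(f">{tid}\n{u5}{cds}{u3}\n")
    pd.DataFrame(
        [
            {
                "transcript_id": tid,
                "gene_id": gid,
                "utr5_len": len(u5),
                "cds_len": len(cds),
                "utr3_len": len(u3),
            }
            for tid, gid, u5, cds, u3 in entries
        ]
    ).to_csv(regions, sep="\t", index=False)
    return fasta, regions


class TestTranscriptRecord:
    def test_regions_concatenate(self):
        r = TranscriptRecord("t1", "g1", "AAA", "ATGTAA", "CCC")
        assert r.sequence == "AAAATGTAACCC"
        assert r.cds_start == 3 and r.cds_end == 9 and r.length == 12

    def test_bad_alphabet_rejected(self):
        with pytest.raises(RibofateError):
            TranscriptRecord("t1", "g1", "AAX", "ATGTAA", "")

    def test_cds_not_multiple_of_three_rejected(self):
        with pytest.raises(RibofateError):
            TranscriptRecord("t1", "g1", "", "ATGA", "")


class TestReadTranscriptome:
    def test_consistent_lengths_single_record(self, tmp_path):
        fasta, regions = _write_tx(tmp_path, [("t1", "g1", "NNN", "ATGTAA", "NN")])
        recs = read_transcriptome(fasta, regions)
        assert len(recs) == 1
        assert recs[0].utr5 == "NNN" and recs[0].cds == "ATGTAA"

    def test_u_mapped_to_t(self, tmp_path):
        fasta, regions = _write_tx(tmp_path, [("t1", "g1", "AUG", "ATGTAA", "")])
        recs = read_transcriptome(fasta, regions)
        assert recs[0].utr5 == "ATG"

    def test_duplicate_sequences_collapsed(self, tmp_path):
        e = ("g1", "AAA", "ATGTAA", "CC")
        fasta, regions = _write_tx(
            tmp_path, [("t1", *e), ("t2", *e), ("t3", "g2", "TTT", "ATGTAA", "CC")]
        )
        recs = read_transcriptome(fasta, regions)
        assert [r.transcript_id for r in recs] == ["t1", "t3"]

    def test_dedup_idempotent(self, tmp_path):
        e = ("g1", "AAA", "ATGTAA", "CC")
        fasta, regions = _write_tx(tmp_path, [("t1", *e), ("t2", *e)])
        recs = read_transcriptome(fasta, regions)
        out_fa, out_reg = tmp_path / "o.fa", tmp_path / "o.tsv"
        write_transcriptome(recs, out_fa, out_reg)
        again = read_transcriptome(out_fa, out_reg)
        assert [r.transcript_id for r in again] == [r.transcript_id for r in recs]

    def test_cds_not_divisible_excluded_with_warning(self, tmp_path, caplog):
        fasta, regions = _write_tx(
            tmp_path,
            [("t1", "g1", "A", "ATGA", "C"), ("t2", "g2", "A", "ATGTAA", "C")],
        )
        with caplog.at_level("WARNING"):
            recs = read_transcriptome(fasta, regions)
        assert [r.transcript_id for r in recs] == ["t2"]
        assert "t1" in caplog.text

    def test_length_mismatch_fatal_names_transcript(self, tmp_path):
        fasta, regions = _write_tx(tmp_path, [("t1", "g1", "AAA", "ATGTAA", "CC")])
        df = pd.read_csv(regions, sep="\t")
        df.loc[0, "utr3_len"] = 5
        df.to_csv(regions, sep="\t", index=False)
        with pytest.raises(RibofateError, match="t1"):
            read_transcriptome(fasta, regions)


class TestReadCounts:
    def _write(self, tmp_path, counts, meta):
        cpath, mpath = tmp_path / "c.tsv", tmp_path / "m.tsv"
        counts.to_csv(cpath, sep="\t")
        meta.to_csv(mpath, sep="\t")
        return cpath, mpath

    def _basic_meta(self, cols, **extra):
        return pd.DataFrame(
            {"assay": "total", "condition": "control",
             "replicate": range(1, len(cols) + 1), **extra},
            index=pd.Index(cols, name="sample_id"),
        )

    def test_library_sizes_are_column_sums(self, tmp_path):
        counts = pd.DataFrame(
            [[1, 2], [3, 4]], index=pd.Index(["g1", "g2"], name="gene_id"),
            columns=["s1", "s2"],
        )
        cm = read_counts(*self._write(tmp_path, counts, self._basic_meta(["s1", "s2"])))
        assert list(cm.library_sizes) == [4, 6]

    def test_empty_gene_set_fatal(self, tmp_path):
        counts = pd.DataFrame(columns=["s1"], index=pd.Index([], name="gene_id"))
        with pytest.raises(RibofateError, match="no genes"):
            read_counts(*self._write(tmp_path, counts, self._basic_meta(["s1"])))

    def test_library_size_override_used(self, tmp_path, caplog):
        counts = pd.DataFrame(
            [[1], [5]], index=pd.Index(["g1", "g2"], name="gene_id"), columns=["s1"]
        )
        meta = self._basic_meta(["s1"], library_size=[10])
        with caplog.at_level("INFO"):
            cm = read_counts(*self._write(tmp_path, counts, meta))
        assert cm.library_sizes["s1"] == 10
        assert "override" in caplog.text

    def test_negative_counts_fatal(self, tmp_path):
        counts = pd.DataFrame(
            [[-1]], index=pd.Index(["g1"], name="gene_id"), columns=["s1"]
        )
        with pytest.raises(RibofateError):
            read_counts(*self._write(tmp_path, counts, self._basic_meta(["s1"])))

    def test_non_integer_counts_fatal(self, tmp_path):
        counts = pd.DataFrame(
            [[1.5]], index=pd.Index(["g1"], name="gene_id"), columns=["s1"]
        )
        with pytest.raises(RibofateError):
            read_counts(*self._write(tmp_path, counts, self._basic_meta(["s1"])))

    def test_unknown_assay_fatal(self, tmp_path):
        counts = pd.DataFrame(
            [[1]], index=pd.Index(["g1"], name="gene_id"), columns=["s1"]
        )
        meta = self._basic_meta(["s1"])
        meta["assay"] = "mystery"
        with pytest.raises(RibofateError, match="assay"):
            read_counts(*self._write(tmp_path, counts, meta))

    def test_round_trip_bit_exact(self, tmp_path, rng):
        counts = pd.DataFrame(
            rng.integers(0, 1000, size=(20, 4)),
            index=pd.Index([f"g{i}" for i in range(20)], name="gene_id"),
            columns=[f"s{i}" for i in range(4)],
        )
        cm = CountMatrix(counts=counts, sample_meta=self._basic_meta(counts.columns))
        write_counts(cm, tmp_path / "c.tsv", tmp_path / "m.tsv")
        back = read_counts(tmp_path / "c.tsv", tmp_path / "m.tsv")
        assert (back.counts.values == cm.counts.values).all()
        assert (back.library_sizes == cm.library_sizes).all()


class TestReadPositions:
    def test_round_trip(self, tmp_path):
        reads = [ReadPosition("t1", 0, 28), ReadPosition("t2", 100, 30)]
        write_read_positions(reads, tmp_path / "r.tsv")
        assert read_read_positions(tmp_path / "r.tsv") == reads

    def test_negative_position_rejected(self):
        with pytest.raises(RibofateError):
            ReadPosition("t1", -1, 28)


class TestMostAbundantIsoform:
    def test_highest_mean_wins(self):
        df = pd.DataFrame({"s1": [10, 30]}, index=["t1", "t2"])
        assert most_abundant_isoform(df, {"t1": "g", "t2": "g"}) == {"g": "t2"}

    def test_tie_broken_lexicographically(self):
        df = pd.DataFrame({"s1": [5, 5]}, index=["t2", "t1"])
        assert most_abundant_isoform(df, {"t1": "g", "t2": "g"}) == {"g": "t1"}

    def test_single_transcript_identity(self):
        df = pd.DataFrame({"s1": [3]}, index=["t9"])
        assert most_abundant_isoform(df, {"t9": "g"}) == {"g": "t9"}

    def test_all_zero_takes_first_and_warns(self, caplog):
        df = pd.DataFrame({"s1": [0, 0]}, index=["t2", "t1"])
        with caplog.at_level("WARNING"):
            out = most_abundant_isoform(df, {"t1": "g", "t2": "g"})
        assert out == {"g": "t1"}
        assert "zero" in caplog.text
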