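"""Domain types and file readers/writers shared by all pipeline stages.

Coordinates are 0-based, half-open, transcript-relative, sense strand only.
Sequences are held in the DNA alphabet (U is mapped to T on ingest).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_ASSAYS = frozenset(
    {"rip_ip", "rip_input", "total", "subpolysomal", "polysomal"}
)


class RibofateError(ValueError):
    """Fatal input or contract violation."""


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript split into its three sense-strand regions."""

    transcript_id: str
    gene_id: str
    utr5: str
    cds: str
    utr3: str

    def __post_init__(self) -> None:
        full = self.utr5 + self.cds + self.utr3
        if set(full) - set("ACGTN"):
            raise RibofateError(
                f"{self.transcript_id}: sequence contains characters outside ACGTN"
            )
        if self.cds and (len(self.cds) % 3 != 0 or len(self.cds) < 3):
            raise RibofateError(
                f"{self.transcript_id}: CDS length {len(self.cds)} not a positive multiple of 3"
            )

    @property
    def sequence(self) -> str:
        return self.utr5 + self.cds + self.utr3

    @property
    def length(self) -> int:
        return len(self.utr5) + len(self.cds) + len(self.utr3)

    @property
    def cds_start(self) -> int:
        """Transcript coordinate of the annotated AUG (first CDS base)."""
        return len(self.utr5)

    @property
    def cds_end(self) -> int:
        return len(self.utr5) + len(self.cds)


@dataclass
class CountMatrix:
    """Genes x samples non-negative integer counts with per-sample metadata.

    ``sample_meta`` is a DataFrame indexed like ``counts.columns`` with at
    least columns ``assay``, ``condition``, ``replicate``.  ``library_sizes``
    default to column sums; metadata may override via a ``library_size``
    column.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    library_sizes: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.counts.shape[0] == 0:
            raise RibofateError("no genes in count matrix")
        if (self.counts.values < 0).any():
            raise RibofateError("negative counts")
        if list(self.counts.columns) != list(self.sample_meta.index):
            raise RibofateError("sample metadata rows do not match count columns")
        bad = set(self.sample_meta["assay"]) - VALID_ASSAYS
        if bad:
            raise RibofateError(f"unknown assay labels: {sorted(bad)}")
        if self.library_sizes is None:
            if "library_size" in self.sample_meta.columns:
                sizes = self.sample_meta["library_size"].astype(float)
                sums = self.counts.sum(axis=0)
                for col in self.counts.columns:
                    if sizes[col] != sums[col]:
                        logger.info(
                            "library size override for %s: declared %s, column sum %s",
                            col, sizes[col], sums[col],
                        )
                self.library_sizes = sizes
            else:
                self.library_sizes = self.counts.sum(axis=0).astype(float)
        if (self.library_sizes <= 0).any():
            raise RibofateError("library sizes must be positive")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    def select(self, **criteria) -> "CountMatrix":
        """Subset samples by metadata equality, e.g. select(assay='rip_ip')."""
        mask = pd.Series(True, index=self.sample_meta.index)
        for key, val in criteria.items():
            mask &= self.sample_meta[key] == val
        cols = self.sample_meta.index[mask]
        if len(cols) == 0:
            raise RibofateError(f"no samples match {criteria}")
        return CountMatrix(
            counts=self.counts[cols],
            sample_meta=self.sample_meta.loc[cols].drop(
                columns=["library_size"], errors="ignore"
            ),
            library_sizes=self.library_sizes[cols],
        )


@dataclass(frozen=True)
class ReadPosition:
    """One aligned RPF read in transcript coordinates."""

    transcript_id: str
    five_prime_pos: int
    length: int

    def __post_init__(self) -> None:
        if self.five_prime_pos < 0:
            raise RibofateError("five_prime_pos must be >= 0")
        if self.length <= 0:
            raise RibofateError("read length must be positive")


@dataclass(frozen=True)
class InitiationPeakSet:
    transcript_id: str
    annotated_start: int
    peak_positions: frozenset[int]

    def __post_init__(self) -> None:
        if self.annotated_start < 0:
            raise RibofateError("annotated_start must be >= 0")


@dataclass(frozen=True)
class MirnaFamilyTargets:
    family_id: str
    target_gene_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.family_id:
            raise RibofateError("empty family_id")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_transcriptome(fasta_path, regions_path) -> list[TranscriptRecord]:
    """Read full-length transcript FASTA plus a region-length table.

    The region table must have columns transcript_id, gene_id, utr5_len,
    cds_len, utr3_len.  U is mapped to T.  Transcripts whose CDS length is
    not a positive multiple of 3 are excluded with a warning.  Duplicate
    full sequences are collapsed to a single record (first by transcript_id).
    """
    regions = pd.read_csv(regions_path, sep="\t", dtype={"transcript_id": str})
    regions = regions.set_index("transcript_id")
    seqs = {
        rec.id: str(rec.seq).upper().replace("U", "T")
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    records: list[TranscriptRecord] = []
    seen_sequences: set[str] = set()
    for tid in sorted(seqs):
        if tid not in regions.index:
            raise RibofateError(f"transcript {tid} missing from region table")
        row = regions.loc[tid]
        u5, cl, u3 = int(row["utr5_len"]), int(row["cds_len"]), int(row["utr3_len"])
        seq = seqs[tid]
        if u5 + cl + u3 != len(seq):
            raise RibofateError(
                f"{tid}: region lengths {u5}+{cl}+{u3} != sequence length {len(seq)}"
            )
        if cl and (cl % 3 != 0 or cl < 3):
            logger.warning("%s: CDS length %d not divisible by 3; excluded", tid, cl)
            continue
        if seq in seen_sequences:
            logger.info("%s: duplicate sequence collapsed", tid)
            continue
        seen_sequences.add(seq)
        records.append(
            TranscriptRecord(
                transcript_id=tid,
                gene_id=str(row["gene_id"]),
                utr5=seq[:u5],
                cds=seq[u5 : u5 + cl],
                utr3=seq[u5 + cl :],
            )
        )
    return records


def write_transcriptome(records, fasta_path, regions_path) -> None:
    with open(fasta_path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.transcript_id}\n{rec.sequence}\n")
    pd.DataFrame(
        {
            "transcript_id": [r.transcript_id for r in records],
            "gene_id": [r.gene_id for r in records],
            "utr5_len": [len(r.utr5) for r in records],
            "cds_len": [len(r.cds) for r in records],
            "utr3_len": [len(r.utr3) for r in records],
        }
    ).to_csv(regions_path, sep="\t", index=False)


def read_counts(tsv_path, meta_path) -> CountMatrix:
    """Read a gene x sample count TSV and its sample-metadata TSV."""
    counts = pd.read_csv(tsv_path, sep="\t", index_col=0)
    if counts.shape[0] == 0:
        raise RibofateError("no genes in count table")
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise RibofateError("non-integer counts")
        counts = counts.round().astype(np.int64)
    if (counts.values < 0).any():
        raise RibofateError("negative counts")
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return CountMatrix(counts=counts, sample_meta=meta)


def write_counts(cm: CountMatrix, tsv_path, meta_path) -> None:
    cm.counts.to_csv(tsv_path, sep="\t")
    meta = cm.sample_meta.copy()
    meta["library_size"] = cm.library_sizes
    meta.to_csv(meta_path, sep="\t")


def read_read_positions(path) -> list[ReadPosition]:
    """Read the BED-like 3-column read-position TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    return [
        ReadPosition(t, int(p), int(ln))
        for t, p, ln in zip(df["transcript_id"], df["five_prime_pos"], df["length"])
    ]


def write_read_positions(reads, path) -> None:
    pd.DataFrame(
        {
            "transcript_id": [r.transcript_id for r in reads],
            "five_prime_pos": [r.five_prime_pos for r in reads],
            "length": [r.length for r in reads],
        }
    ).to_csv(path, sep="\t", index=False)


def read_peaks(path) -> list[InitiationPeakSet]:
    """Peaks TSV: transcript_id, annotated_start, peak_pos (one row per peak;
    peak_pos may be empty for transcripts with no detected initiation)."""
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    out = []
    for tid, sub in df.groupby("transcript_id", sort=True):
        start = int(sub["annotated_start"].iloc[0])
        peaks = frozenset(int(p) for p in sub["peak_pos"].dropna())
        out.append(InitiationPeakSet(tid, start, peaks))
    return out


def read_families(path, pct_threshold: float = 0.5) -> list[MirnaFamilyTargets]:
    """Families TSV: family_id, gene_id[, pct]. Rows with pct <= threshold
    are dropped when a pct column is present."""
    df = pd.read_csv(path, sep="\t", dtype={"family_id": str, "gene_id": str})
    if "pct" in df.columns:
        df = df[df["pct"] > pct_threshold]
    return [
        MirnaFamilyTargets(fid, frozenset(sub["gene_id"]))
        for fid, sub in df.groupby("family_id", sort=True)
    ]


def most_abundant_isoform(
    counts_by_transcript: pd.DataFrame, transcript_to_gene: dict[str, str]
) -> dict[str, str]:
    """Pick one representative transcript per gene: highest mean total-RNA
    count, ties broken lexicographically by transcript_id."""
    means = counts_by_transcript.mean(axis=1)
    chosen: dict[str, str] = {}
    by_gene: dict[str, list[str]] = {}
    for tid, gid in transcript_to_gene.items():
        by_gene.setdefault(gid, []).append(tid)
    for gid, tids in by_gene.items():
        tids = sorted(tids)
        vals = [means.get(t, 0.0) for t in tids]
        if max(vals) == 0:
            logger.warning("gene %s: all transcripts zero; taking %s", gid, tids[0])
            chosen[gid] = tids[0]
        else:
            chosen[gid] = tids[int(np.argmax(vals))]
    return chosen
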