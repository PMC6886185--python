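"""RPF downstream analysis: periodicity-based read-length selection, P-site
assignment (fixed offset), TPM normalization, CDS metagene profiles and
5'UTR occupancy.

A single fixed P-site offset (default 13 nt from the read 5' end) is applied
to all retained lengths.  Library-size normalization is reads-per-million
over the retained periodic reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ReadPosition, RibofateError, TranscriptRecord

logger = logging.getLogger(__name__)

CANDIDATE_LENGTHS = (28, 29, 30)


@dataclass
class RPFDataset:
    """Per-transcript per-nucleotide P-site coverage (reads per million) with
    matched mRNA abundance (TPM) and raw footprint totals."""

    vectors: dict[str, np.ndarray]
    tpm: pd.Series
    raw_rpf_total: pd.Series
    dropped_reads: int = 0
    excluded_zero_tpm: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class MetageneProfile:
    """Mean normalized per-codon occupancy aligned at AUG (start_profile,
    codons 1..n) and at STOP (stop_profile, codons -n..-1)."""

    start_profile: np.ndarray
    stop_profile: np.ndarray
    n_transcripts: int


def select_periodic_lengths(
    reads: list[ReadPosition],
    transcripts: dict[str, TranscriptRecord],
    offset: int = 13,
    threshold: float = 0.6,
    candidate_lengths=CANDIDATE_LENGTHS,
) -> list[int]:
    """Retain read lengths whose CDS-internal P-sites concentrate in one
    frame (modal-frame fraction >= threshold)."""
    frames: dict[int, np.ndarray] = {ln: np.zeros(3) for ln in candidate_lengths}
    for r in reads:
        if r.length not in frames:
            continue
        tx = transcripts.get(r.transcript_id)
        if tx is None or not tx.cds:
            continue
        psite = r.five_prime_pos + offset
        if tx.cds_start <= psite < tx.cds_end:
            frames[r.length][(psite - tx.cds_start) % 3] += 1
    retained = []
    for ln in candidate_lengths:
        total = frames[ln].sum()
        if total == 0:
            continue
        frac = frames[ln].max() / total
        logger.info("length %d: modal-frame fraction %.3f", ln, frac)
        if frac >= threshold:
            retained.append(ln)
    if not retained and all(frames[ln].sum() == 0 for ln in candidate_lengths):
        raise RibofateError("no reads of any candidate length")
    return retained


def psite_assign(
    reads: list[ReadPosition],
    transcript_lengths: dict[str, int],
    offset: int = 13,
    retained_lengths=None,
) -> tuple[dict[str, np.ndarray], int]:
    """Raw per-nucleotide P-site count vectors; out-of-bounds P-sites dropped
    and counted.  Returns (vectors, n_dropped)."""
    if offset < 0:
        raise RibofateError("offset must be >= 0")
    keep = set(retained_lengths) if retained_lengths is not None else None
    vectors = {
        tid: np.zeros(ln, dtype=np.int64) for tid, ln in transcript_lengths.items()
    }
    dropped = 0
    for r in reads:
        if keep is not None and r.length not in keep:
            continue
        vec = vectors.get(r.transcript_id)
        if vec is None:
            dropped += 1
            continue
        psite = r.five_prime_pos + offset
        if psite >= vec.size:
            dropped += 1
            continue
        vec[psite] += 1
    return vectors, dropped


def tpm(total_rna_counts, transcript_lengths) -> np.ndarray:
    """Transcripts per million: length-normalized rates scaled to sum 1e6."""
    counts = np.asarray(total_rna_counts, dtype=float)
    lengths = np.asarray(transcript_lengths, dtype=float)
    if np.any(lengths <= 0):
        raise RibofateError("transcript lengths must be positive")
    if counts.sum() == 0:
        raise RibofateError("all-zero total RNA counts")
    rate = counts / lengths
    return rate / rate.sum() * 1e6


def build_dataset(
    raw_vectors: dict[str, np.ndarray],
    total_rna_counts: pd.Series,
    transcript_lengths: dict[str, int],
    dropped_reads: int = 0,
) -> RPFDataset:
    """Library-size-normalize P-site vectors to reads per million and attach
    TPM computed from the matched total-RNA counts."""
    tids = sorted(raw_vectors)
    lib = float(sum(int(raw_vectors[t].sum()) for t in tids))
    if lib == 0:
        raise RibofateError("no P-site reads")
    vectors = {t: raw_vectors[t] / lib * 1e6 for t in tids}
    counts = total_rna_counts.reindex(tids, fill_value=0)
    lengths = np.array([transcript_lengths[t] for t in tids], dtype=float)
    tpms = pd.Series(tpm(counts.to_numpy(), lengths), index=tids)
    raw_totals = pd.Series(
        {t: int(raw_vectors[t].sum()) for t in tids}, dtype=np.int64
    )
    return RPFDataset(
        vectors=vectors,
        tpm=tpms,
        raw_rpf_total=raw_totals,
        dropped_reads=dropped_reads,
    )


def normalized_occupancy(dataset: RPFDataset, transcript_id: str) -> np.ndarray:
    """Per-nucleotide RPM divided by the transcript's TPM; None for TPM 0."""
    t = dataset.tpm[transcript_id]
    if t == 0:
        if transcript_id not in dataset.excluded_zero_tpm:
            dataset.excluded_zero_tpm.append(transcript_id)
            logger.warning("%s: TPM 0; excluded from occupancy", transcript_id)
        return None
    return dataset.vectors[transcript_id] / t


def _qualifying(
    dataset: RPFDataset,
    transcripts: dict[str, TranscriptRecord],
    group,
    min_rpf: int,
    min_cds: int | None = None,
    min_utr5: int | None = None,
) -> list[str]:
    keep = []
    for tid in sorted(group):
        tx = transcripts.get(tid)
        if tx is None or tid not in dataset.vectors:
            continue
        if dataset.raw_rpf_total.get(tid, 0) < min_rpf:
            continue
        if min_cds is not None and len(tx.cds) <= min_cds:
            continue
        if min_utr5 is not None and len(tx.utr5) <= min_utr5:
            continue
        if dataset.tpm[tid] == 0:
            continue
        keep.append(tid)
    return keep


def metagene_cds(
    dataset: RPFDataset,
    transcripts: dict[str, TranscriptRecord],
    group,
    n_codons: int = 75,
    min_rpf: int = 25,
    min_cds: int = 300,
) -> MetageneProfile:
    """Mean normalized per-codon occupancy over the first/last ``n_codons``
    codons of the CDS, across transcripts passing the inclusion filters
    (raw RPF total >= min_rpf, CDS length strictly > min_cds nt)."""
    keep = _qualifying(dataset, transcripts, group, min_rpf, min_cds=min_cds)
    if not keep:
        raise RibofateError(
            f"no transcripts pass filters (rpf >= {min_rpf}, cds > {min_cds} nt) "
            f"out of {len(list(group))} in group"
        )
    start = np.zeros(n_codons)
    stop = np.zeros(n_codons)
    for tid in keep:
        occ = normalized_occupancy(dataset, tid)
        tx = transcripts[tid]
        cds = occ[tx.cds_start : tx.cds_end]
        codons = cds.reshape(-1, 3).sum(axis=1)
        start += codons[:n_codons]
        stop += codons[-n_codons:]
    n = len(keep)
    return MetageneProfile(start / n, stop / n, n)


def utr5_occupancy(
    dataset: RPFDataset,
    transcripts: dict[str, TranscriptRecord],
    group,
    window: int = 50,
    min_utr5: int = 100,
    min_rpf: int = 0,
) -> pd.DataFrame:
    """Per-transcript mean normalized occupancy over the first and last
    ``window`` nt of the 5'UTR (5'UTR length strictly > min_utr5 nt), using
    reads from all frames."""
    keep = _qualifying(dataset, transcripts, group, min_rpf, min_utr5=min_utr5)
    if not keep:
        raise RibofateError(f"no transcripts with 5'UTR > {min_utr5} nt in group")
    rows = {}
    for tid in keep:
        occ = normalized_occupancy(dataset, tid)
        u5 = occ[: transcripts[tid].cds_start]
        rows[tid] = (float(u5[:window].mean()), float(u5[-window:].mean()))
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["first50", "last50"]
    )
    df.index.name = "transcript_id"
    return df
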