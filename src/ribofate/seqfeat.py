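"""Sequence-feature statistics: rolling GC content, purine-tetramer counting
(non-overlapping, greedy left-to-right), positional motif enrichment, and
Pumilio elements (TGTANATA) in 3'UTRs.

N bases never match a motif and never count as G/C.
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd

from .core import RibofateError
from .stats import kruskal_dunn, PairwiseTestResult

logger = logging.getLogger(__name__)

#: The eight purine tetramers associated with clamped helicase binding.
PURINE_TETRAMERS = ("AAGA", "AGAA", "GAAA", "GAGA", "AGAG", "GGAA", "AAAA", "GAAG")

PUMILIO_RE = re.compile("TGTA[ACGT]ATA")


class MotifSet:
    """A set of equal-length uppercase DNA motifs."""

    def __init__(self, motifs=PURINE_TETRAMERS):
        motifs = tuple(motifs)
        if not motifs:
            raise RibofateError("empty motif set")
        if len({len(m) for m in motifs}) != 1:
            raise RibofateError("motifs must have equal length")
        for m in motifs:
            if set(m) - set("ACGT"):
                raise RibofateError(f"motif {m!r} not over ACGT")
        self.motifs = motifs
        self.width = len(motifs[0])
        self._set = frozenset(motifs)

    def __contains__(self, s: str) -> bool:
        return s in self._set

    def __iter__(self):
        return iter(self.motifs)


def rolling_gc(sequence: str, window: int = 6) -> np.ndarray:
    """GC fraction of every length-``window`` substring; empty if too short."""
    seq = sequence.upper()
    L = len(seq)
    if L < window:
        logger.warning("sequence length %d < window %d", L, window)
        return np.empty(0)
    is_gc = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_gc = ((is_gc == ord("G")) | (is_gc == ord("C"))).astype(float)
    csum = np.concatenate([[0.0], np.cumsum(is_gc)])
    return (csum[window:] - csum[:-window]) / window


def match_starts(sequence: str, motifs: MotifSet) -> list[int]:
    """All (possibly overlapping) start positions where any motif matches."""
    w = motifs.width
    return [i for i in range(len(sequence) - w + 1) if sequence[i : i + w] in motifs]


def count_motifs_nonoverlap(sequence: str, motifs: MotifSet | None = None) -> int:
    """Greedy left-to-right non-overlapping motif count.  At each index, if
    any motif matches, one occurrence is counted and the scan jumps past it."""
    if motifs is None:
        motifs = MotifSet()
    seq = sequence.upper()
    w = motifs.width
    count = 0
    i = 0
    end = len(seq) - w
    while i <= end:
        if seq[i : i + w] in motifs:
            count += 1
            i += w
        else:
            i += 1
    return count


def motif_frequency(sequence: str, motifs: MotifSet | None = None) -> float:
    """Non-overlapping motif count per nucleotide of sequence."""
    if len(sequence) == 0:
        raise RibofateError("empty sequence")
    return count_motifs_nonoverlap(sequence, motifs) / len(sequence)


def _region_slice(seq: str, region: str, window: int = 50) -> str | None:
    if len(seq) < window:
        return None
    if region == "utr5_first50":
        return seq[:window]
    if region == "utr5_last50":
        return seq[-window:]
    raise RibofateError(f"unknown region {region!r}")


def _coverage(seq: str, motifs: MotifSet) -> np.ndarray:
    cov = np.zeros(len(seq), dtype=bool)
    for s in match_starts(seq, motifs):
        cov[s : s + motifs.width] = True
    return cov


def positional_profile(
    group_sequences,
    background_sequences,
    region: str,
    motifs: MotifSet | None = None,
    window: int = 50,
) -> pd.DataFrame:
    """Per-base motif occurrence in the chosen 5'UTR window and its
    enrichment over a background group.

    Occurrence at position p is the fraction of sequences in which a motif
    occurrence covers p.  Enrichment is group/background; NaN where the
    background occurrence is zero.  Sequences shorter than the window are
    excluded.
    """
    if motifs is None:
        motifs = MotifSet()

    def occurrence(seqs) -> np.ndarray:
        total = np.zeros(window)
        n = 0
        for seq in seqs:
            sub = _region_slice(seq.upper(), region, window)
            if sub is None:
                continue
            total += _coverage(sub, motifs)
            n += 1
        if n == 0:
            raise RibofateError(f"no sequences with 5'UTR >= {window} nt")
        return total / n

    grp = occurrence(group_sequences)
    bkg = occurrence(background_sequences)
    with np.errstate(divide="ignore", invalid="ignore"):
        enrich = np.where(bkg > 0, grp / bkg, np.nan)
    return pd.DataFrame(
        {"position": np.arange(window), "occurrence": grp,
         "background": bkg, "enrichment": enrich}
    )


def pumilio_sites(utr3_sequence: str) -> int:
    """Count of non-overlapping TGTANATA matches, scanned left to right."""
    return len(PUMILIO_RE.findall(utr3_sequence.upper()))


def group_motif_comparison(
    groups: dict[str, list[float]],
    correction: str = "bonferroni",
) -> tuple[list[PairwiseTestResult], dict[str, pd.DataFrame]]:
    """Dunn test over per-group motif-frequency distributions plus empirical
    CDF tables (for cumulative-frequency plots)."""
    results = kruskal_dunn(groups, correction=correction)
    ecdfs = {}
    for label, values in groups.items():
        v = np.sort(np.asarray(values, dtype=float))
        ecdfs[label] = pd.DataFrame(
            {"frequency": v, "ecdf": np.arange(1, v.size + 1) / v.size}
        )
    return results, ecdfs
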