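"""Translation-initiation-site classification from initiation-peak data and
miRNA-family target enrichment across binding groups."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .core import InitiationPeakSet, MirnaFamilyTargets, RibofateError
from .stats import benjamini_hochberg, fisher_exact_onesided

logger = logging.getLogger(__name__)

TIS_LABELS = ("annotated_only", "utis_only", "both", "none")


@dataclass(frozen=True)
class TisClassification:
    transcript_id: str
    label: str
    utis_positions: tuple[int, ...]
    in_frame_flags: tuple[bool, ...]


def utis_frame(utis_pos: int, annotated_start: int) -> bool:
    """True when the uTIS is in frame with the annotated start."""
    if utis_pos >= annotated_start:
        raise RibofateError("uTIS position must be strictly upstream of the start")
    return (annotated_start - utis_pos) % 3 == 0


def classify_tis(peaks: InitiationPeakSet) -> TisClassification:
    """Label a transcript by which initiation sites carry peaks.

    A peak 'at' the annotated start means exact coordinate equality; peaks
    downstream of the start are ignored for labeling.
    """
    at_start = peaks.annotated_start in peaks.peak_positions
    upstream = tuple(sorted(p for p in peaks.peak_positions if p < peaks.annotated_start))
    if at_start and upstream:
        label = "both"
    elif at_start:
        label = "annotated_only"
    elif upstream:
        label = "utis_only"
    else:
        label = "none"
    flags = tuple(utis_frame(p, peaks.annotated_start) for p in upstream)
    return TisClassification(peaks.transcript_id, label, upstream, flags)


def group_tis_proportions(
    classifications: list[TisClassification],
    partition: pd.Series,
) -> pd.DataFrame:
    """Per-group fractions of annotated_only / utis_only / both among
    transcripts with detected initiation (label != none)."""
    labels = pd.Series(
        {c.transcript_id: c.label for c in classifications}, name="tis_label"
    )
    df = pd.DataFrame({"tis_label": labels, "group": partition.reindex(labels.index)})
    df = df.dropna(subset=["group"])
    df = df[df["tis_label"] != "none"]
    rows = {}
    for group, sub in df.groupby("group"):
        if len(sub) == 0:
            logger.warning("group %s empty after filtering; omitted", group)
            continue
        frac = sub["tis_label"].value_counts(normalize=True)
        rows[group] = [
            float(frac.get("annotated_only", 0.0)),
            float(frac.get("utis_only", 0.0)),
            float(frac.get("both", 0.0)),
        ]
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=["annotated_only", "utis_only", "both"]
    )
    out.index.name = "group"
    return out


def _fdr_bin(fdr: float) -> str:
    if fdr < 0.05:
        return "<0.05"
    if fdr < 0.1:
        return "0.05-0.1"
    if fdr < 0.2:
        return "0.1-0.2"
    return "ns"


def mirna_family_enrichment(
    groups: dict[str, "set[str] | list[str]"],
    families: list[MirnaFamilyTargets],
    universe: "set[str] | list[str]",
) -> pd.DataFrame:
    """One-sided Fisher enrichment of each miRNA family's targets within each
    gene group, BH-corrected across families within a group.

    ``groups`` maps group label -> gene ids (any reference gene set works as
    a group); families with no targets in the universe are skipped.
    """
    universe = set(universe)
    N = len(universe)
    rows = []
    for label in sorted(groups):
        members = set(groups[label]) & universe
        n = len(members)
        fam_rows = []
        for fam in families:
            targets = fam.target_gene_ids & universe
            K = len(targets)
            if K == 0:
                logger.info("family %s: no targets in universe; skipped", fam.family_id)
                continue
            k = len(targets & members)
            p, odds = fisher_exact_onesided(k, n, K, N)
            fam_rows.append((fam.family_id, label, k, K, p, odds))
        if not fam_rows:
            continue
        fdrs = benjamini_hochberg([r[4] for r in fam_rows])
        for (fid, lab, k, K, p, odds), fdr in zip(fam_rows, fdrs):
            rows.append(
                {
                    "family_id": fid,
                    "group": lab,
                    "targets_in_group": k,
                    "targets_in_universe": K,
                    "p": p,
                    "fdr": float(fdr),
                    "odds_ratio": odds,
                    "fdr_bin": _fdr_bin(float(fdr)),
                }
            )
    return pd.DataFrame(rows)
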