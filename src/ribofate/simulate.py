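"""Synthetic-data generation with recorded ground truth.

Generates every input the pipeline consumes — transcript sequences with
planted motifs and GC gradients, negative-binomial count matrices with
planted IP enrichment and polysome shifts, 3-nt periodic footprints with
planted 5'UTR peaks, initiation peaks, miRNA-family target lists, and noisy
binding curves — so that every downstream stage can be validated against a
known truth table.

All randomness flows from one ``numpy.random.default_rng(seed)``; the same
seed yields byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    CountMatrix,
    InitiationPeakSet,
    MirnaFamilyTargets,
    ReadPosition,
    RibofateError,
    TranscriptRecord,
    write_counts,
    write_read_positions,
    write_transcriptome,
)
from .binding import solve_competition_equilibrium
from .seqfeat import PURINE_TETRAMERS

GROUPS = ("eIF4A1", "eIF4A2", "DDX6", "unbound")
BASES = np.array(list("ACGT"))


@dataclass
class SimParams:
    """Knobs of the synthetic experiment; defaults give the 'paperlike'
    structure at a configurable gene count."""

    n_genes: int = 1000
    group_fractions: dict = field(
        default_factory=lambda: {
            "eIF4A1": 0.15, "eIF4A2": 0.15, "DDX6": 0.10, "unbound": 0.60
        }
    )
    # sequences
    utr5_log_mean: float = np.log(180.0)
    utr5_log_sd: float = 0.30
    utr5_min: int = 110
    cds_log_mean: float = np.log(900.0)
    cds_log_sd: float = 0.35
    cds_min: int = 360
    utr3_log_mean: float = np.log(500.0)
    utr3_log_sd: float = 0.40
    utr3_min: int = 60
    gc_background: float = 0.45
    gc_eif4a1_tail: float = 0.70  # GC prob in eIF4A1 5'UTR last 50 nt
    tetramers_per_utr5_tail: float = 3.0  # planted in eIF4A2 5'UTR last 50 nt
    # counts
    expr_log_mean: float = np.log(200.0)
    expr_log_sd: float = 1.0
    rip_dispersion: float = 0.2
    rnaseq_dispersion: float = 0.1
    gradient_dispersion: float = 0.05
    rip_fold: float = 4.0
    n_rip_reps: int = 3
    n_gradient_reps: int = 4
    n_total_reps: int = 2
    poly_share: dict = field(
        default_factory=lambda: {
            # (control, knockdown) polysomal share per group
            "eIF4A1": (0.55, 0.55),
            "eIF4A2": (0.29, 0.71),
            "DDX6": (0.71, 0.29),
            "unbound": (0.50, 0.50),
        }
    )
    # footprints
    mean_cds_reads: float = 60.0
    utr5_read_fraction: float = 0.08  # 5'UTR rate relative to CDS per-nt rate
    utr5_peak_factor: float = 3.0  # eIF4A2 group, last 50 nt of 5'UTR
    translation_factor_repressed: float = 0.4  # eIF4A2 CDS scaling
    frame0_prob: float = 0.85
    psite_offset: int = 13
    total_depth: float = 0.05  # total-RNA reads per nt of transcript
    # initiation peaks: P(annotated_only, utis_only, both) per group
    tis_probs: dict = field(
        default_factory=lambda: {
            "eIF4A1": (0.75, 0.10, 0.15),
            "eIF4A2": (0.50, 0.28, 0.22),
            "DDX6": (0.70, 0.12, 0.18),
            "unbound": (0.75, 0.10, 0.15),
        }
    )
    # miRNA families
    n_families: int = 30
    n_planted_families: int = 5
    family_size: int = 60
    planted_target_fraction: float = 0.5  # of a planted family inside eIF4A2 group
    # binding assays
    kd_m: float = 0.5e-6
    hill_h: float = 1.0
    decay_k: float = 0.05  # per minute
    binding_noise: float = 0.02
    n_binding_reps: int = 3

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise RibofateError("n_genes must be >= 10")
        if abs(sum(self.group_fractions.values()) - 1.0) > 1e-9:
            raise RibofateError("group fractions must sum to 1")
        for probs in self.tis_probs.values():
            if abs(sum(probs) - 1.0) > 1e-9:
                raise RibofateError("TIS label probabilities must sum to 1")
        if self.rip_dispersion <= 0 or self.rnaseq_dispersion <= 0:
            raise RibofateError("dispersions must be positive")


def preset_params(name: str, n_genes: int | None = None) -> SimParams:
    if name == "paperlike":
        p = SimParams(n_genes=n_genes or 5000)
    elif name == "null":
        p = SimParams(n_genes=n_genes or 2000)
        p.rip_fold = 1.0
        p.gc_eif4a1_tail = p.gc_background
        p.tetramers_per_utr5_tail = 0.0
        p.utr5_peak_factor = 1.0
        p.translation_factor_repressed = 1.0
        p.poly_share = {g: (0.5, 0.5) for g in GROUPS}
        p.rip_fold = 1.0
        p.tis_probs = {g: (0.75, 0.10, 0.15) for g in GROUPS}
        p.n_planted_families = 0
    elif name == "minimal":
        p = SimParams(n_genes=n_genes or 200)
    else:
        raise RibofateError(f"unknown preset {name!r}")
    return p


def _nb(rng: np.random.Generator, mean, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mean + dispersion * mean^2."""
    mean = np.asarray(mean, dtype=float)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def _round3(x: int) -> int:
    return int(3 * round(x / 3.0))


def make_transcriptome(
    params: SimParams, rng: np.random.Generator
) -> tuple[list[TranscriptRecord], pd.DataFrame]:
    """Transcript sequences with planted features plus the truth table."""
    n = params.n_genes
    counts = {g: int(round(f * n)) for g, f in params.group_fractions.items()}
    counts["unbound"] += n - sum(counts.values())
    if any(c < 0 for c in counts.values()):
        raise RibofateError("group sizes exceed n_genes")
    groups = np.repeat(list(counts), list(counts.values()))
    rng.shuffle(groups)

    width = len(str(n - 1))
    gene_ids = [f"g{i:0{width}d}" for i in range(n)]
    tx_ids = [f"t{i:0{width}d}" for i in range(n)]

    utr5_len = np.maximum(
        params.utr5_min,
        rng.lognormal(params.utr5_log_mean, params.utr5_log_sd, n).astype(int),
    )
    cds_len = np.array(
        [
            max(params.cds_min, _round3(v))
            for v in rng.lognormal(params.cds_log_mean, params.cds_log_sd, n)
        ]
    )
    utr3_len = np.maximum(
        params.utr3_min,
        rng.lognormal(params.utr3_log_mean, params.utr3_log_sd, n).astype(int),
    )

    gc = params.gc_background
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    gc_tail = params.gc_eif4a1_tail
    tail_p = np.array([(1 - gc_tail) / 2, gc_tail / 2, gc_tail / 2, (1 - gc_tail) / 2])

    records: list[TranscriptRecord] = []
    planted_positions: list[str] = []
    for i in range(n):
        u5 = rng.choice(BASES, size=utr5_len[i], p=base_p)
        if groups[i] == "eIF4A1":
            u5[-50:] = rng.choice(BASES, size=50, p=tail_p)
        planted = []
        if groups[i] == "eIF4A2" and params.tetramers_per_utr5_tail > 0:
            n_plant = rng.poisson(params.tetramers_per_utr5_tail)
            # non-overlapping slots in the last 50 nt
            slots = np.arange(utr5_len[i] - 50, utr5_len[i] - 4, 4)
            chosen = rng.choice(
                slots, size=min(n_plant, slots.size), replace=False
            )
            for pos in sorted(chosen):
                motif = PURINE_TETRAMERS[rng.integers(len(PURINE_TETRAMERS))]
                u5[pos : pos + 4] = list(motif)
                planted.append(int(pos))
        planted_positions.append(",".join(map(str, planted)))
        cds = rng.choice(BASES, size=cds_len[i], p=base_p)
        cds[:3] = list("ATG")
        cds[-3:] = list("TAA")
        u3 = rng.choice(BASES, size=utr3_len[i], p=base_p)
        records.append(
            TranscriptRecord(
                transcript_id=tx_ids[i],
                gene_id=gene_ids[i],
                utr5="".join(u5),
                cds="".join(cds),
                utr3="".join(u3),
            )
        )

    expression = rng.lognormal(params.expr_log_mean, params.expr_log_sd, n)
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "transcript_id": tx_ids,
            "group": groups,
            "expression": expression,
            "utr5_len": utr5_len,
            "cds_len": cds_len,
            "utr3_len": utr3_len,
            "ip_fold_bound": np.where(groups != "unbound", params.rip_fold, 1.0),
            "translation_factor": np.where(
                groups == "eIF4A2", params.translation_factor_repressed, 1.0
            ),
            "utr5_peak_factor": np.where(
                groups == "eIF4A2", params.utr5_peak_factor, 1.0
            ),
            "planted_tetramer_positions": planted_positions,
        }
    ).set_index("gene_id")
    return records, truth


def simulate_counts(
    truth: pd.DataFrame, params: SimParams, rng: np.random.Generator
) -> dict[str, CountMatrix]:
    """RIP IP/input matrices per protein, gradient fraction matrices for
    control and knockdown, and total RNA counts."""
    genes = list(truth.index)
    expr = truth["expression"].to_numpy()
    out: dict[str, CountMatrix] = {}

    for protein in ("eIF4A1", "eIF4A2", "DDX6"):
        fold = np.where(truth["group"] == protein, truth["ip_fold_bound"], 1.0)
        cols, meta_rows, data = [], [], []
        # IP and input of one replicate come from the same lysate: they share
        # a per-replicate latent expression (gamma-Poisson), so marginals are
        # NB with the requested dispersion while IP/input noise is paired.
        lam = [
            rng.gamma(1.0 / params.rip_dispersion, params.rip_dispersion * expr)
            for _ in range(params.n_rip_reps)
        ]
        for rep in range(1, params.n_rip_reps + 1):
            cols.append(f"{protein}_input_{rep}")
            meta_rows.append(("rip_input", "control", rep))
            data.append(rng.poisson(lam[rep - 1]))
        for rep in range(1, params.n_rip_reps + 1):
            cols.append(f"{protein}_ip_{rep}")
            meta_rows.append(("rip_ip", "control", rep))
            data.append(rng.poisson(lam[rep - 1] * fold))
        counts = pd.DataFrame(
            np.column_stack(data), index=pd.Index(genes, name="gene_id"), columns=cols
        )
        meta = pd.DataFrame(
            meta_rows, columns=["assay", "condition", "replicate"],
            index=pd.Index(cols, name="sample_id"),
        )
        out[f"rip_{protein}"] = CountMatrix(counts=counts, sample_meta=meta)

    share = np.array(
        [params.poly_share[g] for g in truth["group"]], dtype=float
    )  # columns: control, knockdown
    cols, meta_rows, data = [], [], []
    for cond_idx, cond in enumerate(("control", "knockdown")):
        for assay, sh in (
            ("polysomal", share[:, cond_idx]),
            ("subpolysomal", 1.0 - share[:, cond_idx]),
        ):
            for rep in range(1, params.n_gradient_reps + 1):
                cols.append(f"{assay[:4]}_{cond}_{rep}")
                meta_rows.append((assay, cond, rep))
                data.append(_nb(rng, expr * sh, params.gradient_dispersion))
    counts = pd.DataFrame(
        np.column_stack(data), index=pd.Index(genes, name="gene_id"), columns=cols
    )
    meta = pd.DataFrame(
        meta_rows, columns=["assay", "condition", "replicate"],
        index=pd.Index(cols, name="sample_id"),
    )
    out["gradient"] = CountMatrix(counts=counts, sample_meta=meta)

    tx_len = (truth["utr5_len"] + truth["cds_len"] + truth["utr3_len"]).to_numpy()
    cols, meta_rows, data = [], [], []
    for rep in range(1, params.n_total_reps + 1):
        cols.append(f"total_{rep}")
        meta_rows.append(("total", "control", rep))
        data.append(
            _nb(rng, expr * tx_len * params.total_depth / 100.0, params.rnaseq_dispersion)
        )
    counts = pd.DataFrame(
        np.column_stack(data), index=pd.Index(genes, name="gene_id"), columns=cols
    )
    meta = pd.DataFrame(
        meta_rows, columns=["assay", "condition", "replicate"],
        index=pd.Index(cols, name="sample_id"),
    )
    out["total"] = CountMatrix(counts=counts, sample_meta=meta)
    return out


def simulate_rpf(
    truth: pd.DataFrame,
    records: list[TranscriptRecord],
    params: SimParams,
    rng: np.random.Generator,
) -> tuple[list[ReadPosition], pd.Series]:
    """Periodic footprints with planted 5'UTR peaks plus matched total-RNA
    counts per transcript (for TPM)."""
    by_tid = {r.transcript_id: r for r in records}
    reads: list[ReadPosition] = []
    totals = {}
    lengths = np.array([28, 29, 30])
    expr = truth["expression"]
    # abundance scale so the mean transcript gets ~mean_cds_reads CDS reads
    scale = params.mean_cds_reads / float(expr.mean())
    for gid, row in truth.iterrows():
        tx = by_tid[row["transcript_id"]]
        L5, Lc = len(tx.utr5), len(tx.cds)
        abundance = row["expression"] * scale
        t_factor = float(row["translation_factor"])
        per_nt_cds = abundance * t_factor / Lc * 3.0  # per codon
        n_codons = Lc // 3
        codon_counts = rng.poisson(per_nt_cds, n_codons)
        base_u5 = abundance * params.utr5_read_fraction / 50.0
        u5_rate = np.full(L5, base_u5 * 50.0 / L5)
        u5_rate[-50:] *= float(row["utr5_peak_factor"])
        u5_counts = rng.poisson(u5_rate)
        # total RNA counts proportional to abundance x length
        totals[tx.transcript_id] = rng.poisson(abundance * tx.length * 0.02)

        psites, counts_at = [], []
        nz = np.nonzero(codon_counts)[0]
        for j in nz:
            psites.append(L5 + 3 * j)
            counts_at.append(codon_counts[j])
        for pos in np.nonzero(u5_counts)[0]:
            psites.append(int(pos))
            counts_at.append(u5_counts[pos])
        for psite, c in zip(psites, counts_at):
            for _ in range(int(c)):
                shift = 0
                if psite >= L5 and rng.random() > params.frame0_prob:
                    shift = int(rng.integers(1, 3))
                p = psite + shift
                fp = p - params.psite_offset
                if fp < 0:
                    continue
                ln = int(lengths[rng.integers(3)])
                if fp + ln > tx.length:
                    ln = min(30, tx.length - fp)
                    if ln <= 0:
                        continue
                reads.append(ReadPosition(tx.transcript_id, fp, ln))
    return reads, pd.Series(totals, name="total_count")


def simulate_peaks_and_families(
    truth: pd.DataFrame, params: SimParams, rng: np.random.Generator
) -> tuple[list[InitiationPeakSet], list[MirnaFamilyTargets], list[str], pd.DataFrame]:
    """Initiation peaks per transcript, miRNA-family target lists with
    planted group bias, a TNRC6-style reference target list, and the
    family-truth table."""
    peaks: list[InitiationPeakSet] = []
    labels = []
    for gid, row in truth.iterrows():
        probs = params.tis_probs[row["group"]]
        start = int(row["utr5_len"])
        u = rng.random()
        positions: set[int] = set()
        if u < probs[0]:
            label = "annotated_only"
            positions.add(start)
        elif u < probs[0] + probs[1]:
            label = "utis_only"
        else:
            label = "both"
            positions.add(start)
        if label in ("utis_only", "both"):
            positions.add(int(rng.integers(max(0, start - 60), start - 2)))
        labels.append(label)
        peaks.append(
            InitiationPeakSet(row["transcript_id"], start, frozenset(positions))
        )
    truth = truth.copy()
    truth["tis_label"] = labels

    genes = np.array(truth.index)
    in_group = genes[truth["group"] == "eIF4A2"]
    families = []
    fam_rows = []
    for f in range(params.n_families):
        fid = f"fam{f:03d}"
        planted = f < params.n_planted_families and in_group.size > 0
        if planted:
            n_in = min(
                int(round(params.family_size * params.planted_target_fraction)),
                in_group.size,
            )
            chosen = set(rng.choice(in_group, size=n_in, replace=False))
            rest = rng.choice(
                genes, size=params.family_size - n_in, replace=False
            )
            chosen |= set(rest)
        else:
            chosen = set(rng.choice(genes, size=params.family_size, replace=False))
        families.append(MirnaFamilyTargets(fid, frozenset(chosen)))
        fam_rows.append({"family_id": fid, "planted": bool(planted)})

    # reference 'miRNA target' list: planted-family targets plus random genes
    ref = set()
    for fam, rowinfo in zip(families, fam_rows):
        if rowinfo["planted"]:
            ref |= set(fam.target_gene_ids)
    ref |= set(rng.choice(genes, size=max(1, len(genes) // 20), replace=False))
    return peaks, families, sorted(ref), truth


def simulate_binding(
    params: SimParams, rng: np.random.Generator
) -> dict[str, pd.DataFrame]:
    """Noisy triplicate titration, strand-release, and competition tables."""
    out = {}
    conc = np.concatenate([[0.0], np.geomspace(1e-8, 40e-6, 11)])
    amp, base = 0.15, 0.05
    rows = []
    for rep in range(1, params.n_binding_reps + 1):
        signal = base + amp * conc**params.hill_h / (
            params.kd_m**params.hill_h + conc**params.hill_h
        )
        noisy = signal + rng.normal(0, params.binding_noise * amp, conc.size)
        rows.append(pd.DataFrame({"conc_M": conc, "signal": noisy, "replicate": rep}))
    out["titration"] = pd.concat(rows, ignore_index=True)

    t = np.linspace(0, 60, 13)  # minutes
    plateau, amp_k = 0.05, 0.12
    rows = []
    for rep in range(1, params.n_binding_reps + 1):
        signal = plateau + amp_k * np.exp(-params.decay_k * t)
        noisy = signal + rng.normal(0, 0.03 * amp_k, t.size)
        rows.append(pd.DataFrame({"time_min": t, "signal": noisy, "replicate": rep}))
    out["decay"] = pd.concat(rows, ignore_index=True)

    rl_total = 25e-9
    kd_c = 100.0 * params.kd_m  # weak competitor
    prot = np.concatenate([[0.0], np.geomspace(2e-8, 7e-6, 9)])
    rows = []
    for excess in (0, 10, 50):
        for rep in range(1, params.n_binding_reps + 1):
            for p_tot in prot:
                if p_tot == 0:
                    frac = 0.0
                else:
                    frac = solve_competition_equilibrium(
                        p_tot, rl_total, excess * rl_total, params.kd_m, kd_c
                    )["frac_labeled_bound"]
                rows.append(
                    {
                        "conc_M": p_tot,
                        "fraction_bound": float(
                            np.clip(frac + rng.normal(0, 0.02), -0.05, 1.05)
                        ),
                        "competitor_excess": excess,
                        "replicate": rep,
                    }
                )
    out["competition"] = pd.DataFrame(rows)
    out["binding_truth"] = pd.DataFrame(
        [
            {
                "kd_m": params.kd_m,
                "hill_h": params.hill_h,
                "decay_k_per_min": params.decay_k,
                "competitor_kd_m": kd_c,
            }
        ]
    )
    return out


def simulate_all(
    preset: str, seed: int, out_dir, n_genes: int | None = None
) -> dict:
    """Run every generator and write all pipeline input files to out_dir."""
    params = preset_params(preset, n_genes)
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    records, truth = make_transcriptome(params, rng)
    matrices = simulate_counts(truth, params, rng)
    reads, totals = simulate_rpf(truth, records, params, rng)
    peaks, families, reference, truth = simulate_peaks_and_families(
        truth, params, rng
    )
    binding = simulate_binding(params, rng)

    write_transcriptome(records, out_dir / "transcripts.fa", out_dir / "regions.tsv")
    for name, cm in matrices.items():
        write_counts(cm, out_dir / f"counts_{name}.tsv", out_dir / f"meta_{name}.tsv")
    write_read_positions(reads, out_dir / "rpf_reads.tsv")
    totals.rename_axis("transcript_id").to_frame().to_csv(
        out_dir / "rpf_totals.tsv", sep="\t"
    )
    peak_rows = []
    for pk in peaks:
        if pk.peak_positions:
            for pos in sorted(pk.peak_positions):
                peak_rows.append((pk.transcript_id, pk.annotated_start, pos))
        else:
            peak_rows.append((pk.transcript_id, pk.annotated_start, None))
    pd.DataFrame(
        peak_rows, columns=["transcript_id", "annotated_start", "peak_pos"]
    ).to_csv(out_dir / "peaks.tsv", sep="\t", index=False)
    fam_rows = [
        {"family_id": fam.family_id, "gene_id": gid}
        for fam in families
        for gid in sorted(fam.target_gene_ids)
    ]
    pd.DataFrame(fam_rows).to_csv(out_dir / "families.tsv", sep="\t", index=False)
    pd.Series(reference, name="gene_id").to_csv(
        out_dir / "reference_targets.tsv", sep="\t", index=False
    )
    for name, df in binding.items():
        df.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)
    truth.to_csv(out_dir / "truth.tsv", sep="\t")
    manifest = {"preset": preset, "seed": seed, "n_genes": params.n_genes}
    pd.Series(manifest).to_csv(out_dir / "manifest.tsv", sep="\t", header=False)
    return {
        "params": params,
        "records": records,
        "truth": truth,
        "matrices": matrices,
        "reads": reads,
        "totals": totals,
        "peaks": peaks,
        "families": families,
        "reference": reference,
        "binding": binding,
    }
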