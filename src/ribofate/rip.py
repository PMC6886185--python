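"""RIP-Seq enrichment calling (IP vs input) and binding-group partition.

The enrichment test pools counts across replicates per side and applies a
one-sided exact binomial test against the library-size null: with pooled
counts c_ip, c_in and summed library sizes L_ip, L_in, a non-enriched gene's
IP count is Binomial(c_ip + c_in, L_ip / (L_ip + L_in)).  This is a
documented transparent stand-in for the under-specified published test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import CountMatrix, RibofateError
from .stats import benjamini_hochberg


@dataclass(frozen=True)
class RipResult:
    gene_id: str
    log2_enrichment: float
    p: float
    fdr: float
    enriched: bool


def cpm(counts, library_size) -> np.ndarray:
    """Counts per million: count / library_size * 1e6 (vector or matrix)."""
    ls = np.asarray(library_size, dtype=float)
    if np.any(ls <= 0):
        raise RibofateError("library size must be positive")
    return np.asarray(counts, dtype=float) / ls * 1e6


def cpm_matrix(cm: CountMatrix) -> pd.DataFrame:
    return cm.counts / cm.library_sizes.values * 1e6


def enrichment_test(
    ip: CountMatrix, inp: CountMatrix, fdr_threshold: float = 0.05
) -> pd.DataFrame:
    """Per-gene pooled binomial IP-vs-input enrichment test.

    Genes absent on one side count as 0 there.  Returns a DataFrame indexed
    by gene_id with log2_enrichment, p, fdr, enriched.
    """
    genes = sorted(set(ip.gene_ids) | set(inp.gene_ids))
    c_ip = ip.counts.sum(axis=1).reindex(genes, fill_value=0).to_numpy(float)
    c_in = inp.counts.sum(axis=1).reindex(genes, fill_value=0).to_numpy(float)
    L_ip = float(ip.library_sizes.sum())
    L_in = float(inp.library_sizes.sum())

    total = c_ip + c_in
    p_null = L_ip / (L_ip + L_in)
    # P(X >= c_ip), X ~ Binomial(total, p_null); sf(k-1) == P(X >= k)
    p = sps.binom.sf(c_ip - 1, total, p_null)
    log2_enr = np.log2((c_ip + 0.5) / L_ip) - np.log2((c_in + 0.5) / L_in)
    zero = total == 0
    p[zero] = 1.0
    log2_enr[zero] = 0.0
    fdr = benjamini_hochberg(p)
    enriched = (fdr < fdr_threshold) & (log2_enr > 0)
    return pd.DataFrame(
        {
            "log2_enrichment": log2_enr,
            "p": p,
            "fdr": fdr,
            "enriched": enriched,
        },
        index=pd.Index(genes, name="gene_id"),
    )


def assign_binding_groups(
    rip_results: dict[str, pd.DataFrame], fdr_threshold: float = 0.05
) -> pd.Series:
    """Label each gene with the set of proteins it is enriched for.

    ``rip_results`` maps protein name to an enrichment_test output over the
    same gene universe.  Labels are '+'-joined sorted protein names, or
    'unbound'.  Returns a Series gene_id -> label.
    """
    proteins = sorted(rip_results)
    universes = {p: set(rip_results[p].index) for p in proteins}
    universe = universes[proteins[0]]
    for p in proteins[1:]:
        if universes[p] != universe:
            missing = sorted(universe.symmetric_difference(universes[p]))
            raise RibofateError(
                f"inconsistent gene universes across proteins; differing ids: {missing[:10]}"
            )
    genes = sorted(universe)
    bound = pd.DataFrame(
        {
            p: (rip_results[p]["fdr"] < fdr_threshold)
            & (rip_results[p]["log2_enrichment"] > 0)
            for p in proteins
        }
    ).reindex(genes)
    labels = bound.apply(
        lambda row: "+".join(p for p in proteins if row[p]) or "unbound", axis=1
    )
    labels.index.name = "gene_id"
    return labels.rename("label")
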