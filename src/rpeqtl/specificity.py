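"""Two-step FDR classification of eGenes as tissue-selective.

Discovery: genes significant (q < q_discovery) in every study condition.
Replication: a reference panel of per-tissue gene-level q-values; a
discovery gene is tissue-selective when no reference tissue shows
q < q_replication (missing panel entries count as not significant).
"""

from __future__ import annotations

import pandas as pd


def shared_egenes(calls: pd.DataFrame, q: float = 0.05) -> list[str]:
    """Genes with gene-level q below ``q`` in every condition present.

    ``calls`` columns: ``gene, condition, q_gene``.
    """
    if calls.empty:
        return []
    n_conditions = calls["condition"].nunique()
    sig = calls[calls["q_gene"] < q]
    counts = sig.groupby("gene")["condition"].nunique()
    return sorted(counts.index[counts == n_conditions])


def tissue_selective_egenes(
    discovery: list[str], panel: pd.DataFrame, q_replication: float = 0.1
) -> list[str]:
    """Discovery genes with no reference-tissue q below ``q_replication``.

    ``panel`` is gene x tissue q-values (index = gene); NaN or absent
    entries are treated as not significant.
    """
    selective = []
    for gene in discovery:
        if gene not in panel.index:
            selective.append(gene)
            continue
        row = panel.loc[gene].dropna()
        if row.empty or not (row < q_replication).any():
            selective.append(gene)
    return sorted(selective)


def overlap_summary(set_a: list, set_b: list) -> tuple[int, float]:
    """``(|A ∩ B|, |A ∩ B| / |A|)``; fraction is 0.0 for empty A."""
    a, b = set(set_a), set(set_b)
    inter = len(a & b)
    return inter, (inter / len(a) if a else 0.0)
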