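"""Tissue-selectivity z-scores on a multi-tissue median-expression panel.

For each gene, the per-tissue median expression ``x`` is standardized
against the mean and sample standard deviation of the medians across
tissues: ``z = (x - mu) / sigma``.  A gene is called selective for a tissue
when its z-score there strictly exceeds a threshold (default 4), after
excluding sex-chromosome, mitochondrial, and HLA-region genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ConsistencyError, InsufficientDataError

#: hg19 extended MHC interval used for the HLA exclusion filter.
HLA_REGION = ("chr6", 28_477_797, 33_448_354)

SEX_CHROMS = {"chrX", "chrY", "X", "Y"}
MITO_CHROMS = {"chrM", "chrMT", "M", "MT"}


@dataclass
class TissuePanel:
    """Per-tissue median expression (genes x tissues) plus gene annotations.

    ``annotations`` has one row per gene: ``gene_id, chrom, start, end,
    gene_type`` (start/end 1-based inclusive).
    """

    medians: pd.DataFrame
    annotations: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if (self.medians.to_numpy(dtype=float) < 0).any():
            raise ValueError("median expression must be nonnegative")
        if not self.annotations.empty:
            missing = set(self.medians.index) - set(self.annotations["gene_id"])
            if missing:
                raise ConsistencyError(f"{len(missing)} genes lack annotations")

    @property
    def tissues(self) -> list[str]:
        return list(self.medians.columns)


def selectivity_zscores(panel: TissuePanel) -> pd.DataFrame:
    """Long-format table ``gene_id, tissue, x, mu, sigma, z``.

    Uses the sample (n-1) standard deviation; genes with sigma == 0 get
    ``z = NaN`` and are excluded from downstream calling.
    """
    if len(panel.tissues) < 3:
        raise InsufficientDataError("selectivity z-scores require >= 3 tissues")
    x = panel.medians.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sigma = x.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma > 0, (x - mu) / sigma, np.nan)
    out = pd.DataFrame({
        "gene_id": np.repeat(panel.medians.index.to_numpy(), len(panel.tissues)),
        "tissue": np.tile(np.array(panel.tissues, dtype=object), len(panel.medians)),
        "x": x.ravel(),
        "mu": np.repeat(mu.ravel(), len(panel.tissues)),
        "sigma": np.repeat(sigma.ravel(), len(panel.tissues)),
        "z": z.ravel(),
    })
    return out


def _excluded_genes(annotations: pd.DataFrame, hla_region=HLA_REGION) -> set:
    if annotations.empty:
        return set()
    chrom = annotations["chrom"].astype(str)
    bad = chrom.isin(SEX_CHROMS | MITO_CHROMS)
    hla_chrom, hla_start, hla_end = hla_region
    in_hla = (
        (chrom == hla_chrom)
        & (annotations["end"] >= hla_start)
        & (annotations["start"] <= hla_end)
    )
    return set(annotations.loc[bad | in_hla, "gene_id"])


def call_selective(
    scores: pd.DataFrame,
    tissue: str,
    z_threshold: float = 4.0,
    annotations: pd.DataFrame | None = None,
    hla_region: tuple = HLA_REGION,
) -> list[str]:
    """Genes with ``z > z_threshold`` (strict) in ``tissue`` after filtering
    sex-chromosome, mitochondrial, and HLA-region genes."""
    if tissue not in set(scores["tissue"]):
        raise ConfigurationError(f"unknown tissue {tissue!r}")
    sub = scores[(scores["tissue"] == tissue) & scores["z"].notna()]
    called = sub.loc[sub["z"] > z_threshold, "gene_id"]
    if annotations is not None and not annotations.empty:
        called = called[~called.isin(_excluded_genes(annotations, hla_region))]
    return sorted(called)


def expected_z_qq(scores: pd.DataFrame, tissue: str) -> pd.DataFrame:
    """Pair a tissue's ranked z-scores with the rank-average expectation.

    Expected value at rank k is the mean across tissues of the k-th order
    statistic of each tissue's z distribution (computed over genes scored in
    every tissue).
    """
    if tissue not in set(scores["tissue"]):
        raise ConfigurationError(f"unknown tissue {tissue!r}")
    usable = scores.dropna(subset=["z"])
    wide = usable.pivot(index="gene_id", columns="tissue", values="z").dropna(axis=0)
    counts = usable.groupby("tissue")["gene_id"].nunique()
    if counts.nunique() != 1 or len(wide) != counts.iloc[0]:
        raise ConsistencyError("tissues cover unequal gene sets; QQ expectation undefined")
    ordered = np.sort(wide.to_numpy(dtype=float), axis=0)
    expected = ordered.mean(axis=1)
    observed = np.sort(wide[tissue].to_numpy(dtype=float))
    return pd.DataFrame({"rank": np.arange(1, len(expected) + 1),
                         "observed_z": observed, "expected_z": expected})


def gene_set_specificity(
    scores: pd.DataFrame, tissue: str, gene_set: list, background: list
) -> tuple[float, float, float]:
    """Welch two-sided t-test of z in ``gene_set`` vs ``background`` for a
    tissue; returns ``(mean difference, t, p)``."""
    overlap = set(gene_set) & set(background)
    if overlap:
        raise ConsistencyError(f"gene set and background overlap: {sorted(overlap)[:5]}")
    sub = scores[(scores["tissue"] == tissue) & scores["z"].notna()].set_index("gene_id")
    zs = sub.loc[sub.index.intersection(gene_set), "z"].to_numpy(dtype=float)
    zb = sub.loc[sub.index.intersection(background), "z"].to_numpy(dtype=float)
    if len(zs) < 2 or len(zb) < 2:
        raise InsufficientDataError("need >= 2 scored genes in set and background")
    res = stats.ttest_ind(zs, zb, equal_var=False)
    if zs.std(ddof=1) == 0 and zb.std(ddof=1) == 0 and zs.mean() == zb.mean():
        return 0.0, 0.0, 1.0  # identical degenerate groups
    return float(zs.mean() - zb.mean()), float(res.statistic), float(res.pvalue)
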