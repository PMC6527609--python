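"""Genotype-level quality control and sample-level inference.

Variant filters follow the conventions: missingness removal is strict
(``> max_missing``), imputation quality retains at ``>= min_imputation_r2``,
and multi-allelic sites are removed when ``biallelic_only``.  Sample-level
routines call sex from chromosome-X heterozygosity relative to an autosomal
baseline, flag duplicate pairs by dosage correlation, and compute genotype
principal components on standardized dosages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InsufficientDataError
from .io import GenotypeTable

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass
class VariantQcReport:
    per_variant: pd.DataFrame   # variant_id, missingness, biallelic, ar2, pass each filter
    removed_counts: dict[str, int]
    tstv_by_chrom: dict[str, float]


@dataclass
class SampleQcReport:
    sex_calls: pd.DataFrame | None = None
    duplicate_pairs: pd.DataFrame | None = None
    pca_components: pd.DataFrame | None = None
    pca_variance_explained: np.ndarray | None = None


def filter_variants(
    table: GenotypeTable,
    max_missing: float = 0.05,
    min_imputation_r2: float | None = 0.8,
    biallelic_only: bool = True,
) -> tuple[GenotypeTable, VariantQcReport]:
    """Apply missingness, imputation-quality, and biallelic filters."""
    haps = table.haplotypes
    missing = (haps < 0).any(axis=2).mean(axis=0)
    variants = table.variants
    biallelic = (~variants["alt"].astype(str).str.contains(",")).to_numpy()

    pass_missing = missing <= max_missing
    pass_biallelic = biallelic | (not biallelic_only)
    if min_imputation_r2 is not None:
        ar2 = variants["ar2"].to_numpy(dtype=float) if "ar2" in variants else None
        if ar2 is None or np.isnan(ar2).all():
            raise ConfigurationError(
                "imputation-quality filter enabled but the AR2 key is absent; "
                "disable with min_imputation_r2=None or provide AR2"
            )
        pass_ar2 = ar2 >= min_imputation_r2
    else:
        pass_ar2 = np.ones(len(variants), dtype=bool)

    keep = pass_missing & pass_biallelic & pass_ar2
    per_variant = pd.DataFrame({
        "variant_id": variants["variant_id"],
        "missingness": missing,
        "biallelic": biallelic,
        "ar2": variants["ar2"] if "ar2" in variants else np.nan,
        "pass": keep,
    })
    removed = {
        "missingness": int((~pass_missing).sum()),
        "not_biallelic": int((~pass_biallelic).sum()),
        "imputation_quality": int((~pass_ar2).sum()),
        "total_removed": int((~keep).sum()),
    }
    filtered = table.subset_variants(keep)
    report = VariantQcReport(per_variant=per_variant, removed_counts=removed,
                             tstv_by_chrom=tstv_ratio(filtered))
    return filtered, report


def tstv_ratio(table: GenotypeTable) -> dict[str, float]:
    """Transition/transversion ratio per chromosome over biallelic SNVs."""
    variants = table.variants
    out: dict[str, float] = {}
    for chrom, grp in variants.groupby("chrom", sort=True):
        ts = tv = 0
        for ref, alt in zip(grp["ref"], grp["alt"]):
            ref, alt = str(ref).upper(), str(alt).upper()
            if len(ref) != 1 or len(alt) != 1 or "," in alt:
                continue
            if (ref, alt) in TRANSITIONS:
                ts += 1
            else:
                tv += 1
        if tv == 0:
            warnings.warn(f"{chrom}: zero transversions; Ts/Tv reported as +inf")
            out[str(chrom)] = float("inf") if ts > 0 else float("nan")
        else:
            out[str(chrom)] = ts / tv
    return out


def _het_proportion(table: GenotypeTable, chrom: str) -> np.ndarray:
    mask = (table.variants["chrom"] == chrom).to_numpy()
    if mask.sum() < 50:
        raise InsufficientDataError(
            f"{chrom}: {int(mask.sum())} variants (< 50) — cannot infer sex")
    haps = table.haplotypes[:, mask, :]
    known = (haps >= 0).all(axis=2)
    het = (haps[:, :, 0] != haps[:, :, 1]) & known
    with np.errstate(invalid="ignore"):
        return het.sum(axis=1) / np.maximum(known.sum(axis=1), 1)


def infer_sex(
    table: GenotypeTable,
    x_chrom: str = "chrX",
    baseline_chrom: str = "chr1",
    threshold: float = 0.1,
) -> pd.DataFrame:
    """Call male when chrX heterozygosity < threshold x autosomal baseline."""
    het_x = _het_proportion(table, x_chrom)
    het_base = _het_proportion(table, baseline_chrom)
    calls = np.where(het_x < threshold * het_base, "male", "female")
    return pd.DataFrame({
        "sample": table.samples,
        "het_prop_chrX": het_x,
        "het_prop_baseline": het_base,
        "sex_call": calls,
    })


def detect_duplicates(table: GenotypeTable, min_corr: float = 0.9) -> pd.DataFrame:
    """Flag sample pairs whose dosage Pearson correlation reaches ``min_corr``."""
    if table.n_samples < 2:
        raise InsufficientDataError("duplicate detection needs >= 2 samples")
    dos = table.dosages()
    col_mean = np.nanmean(dos, axis=0)
    nan_mask = np.isnan(dos)
    if nan_mask.any():
        dos[nan_mask] = np.take(col_mean, np.where(nan_mask)[1])
    rows = []
    for i in range(table.n_samples):
        for j in range(i + 1, table.n_samples):
            xi, xj = dos[i], dos[j]
            if xi.std() == 0 or xj.std() == 0:
                warnings.warn(
                    f"pair ({table.samples[i]}, {table.samples[j]}): constant dosage, skipped")
                continue
            corr = float(np.corrcoef(xi, xj)[0, 1])
            if corr >= min_corr:
                rows.append({"sample_a": table.samples[i], "sample_b": table.samples[j],
                             "correlation": corr})
    return pd.DataFrame(rows, columns=["sample_a", "sample_b", "correlation"])


def genotype_pca(table: GenotypeTable, n_components: int = 3):
    """PCA on standardized dosages: center at 2*MAF, scale by
    sqrt(2*maf*(1-maf)); zero-variance variants dropped.

    Returns ``(components DataFrame, variance_explained array)`` with
    variance-explained fractions non-increasing and summing to <= 1.
    """
    dos = table.dosages()
    col_mean = np.nanmean(dos, axis=0)
    nan_mask = np.isnan(dos)
    if nan_mask.any():
        dos[nan_mask] = np.take(col_mean, np.where(nan_mask)[1])
    n, m = dos.shape
    if n_components > min(n, m):
        raise ConfigurationError(
            f"n_components={n_components} exceeds min(samples, variants)={min(n, m)}")
    p_hat = dos.mean(axis=0) / 2.0
    var = 2.0 * p_hat * (1.0 - p_hat)
    keep = var > 0
    z = (dos[:, keep] - 2.0 * p_hat[keep]) / np.sqrt(var[keep])
    z = z - z.mean(axis=0)
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    total = (s ** 2).sum()
    comps = u[:, :n_components] * s[:n_components]
    var_explained = (s[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    frame = pd.DataFrame(comps, index=table.samples,
                         columns=[f"PC{k + 1}" for k in range(n_components)])
    return frame, var_explained
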