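"""Readers and writers for the plain-text formats used across the pipeline.

Conventions:

* genomic positions are 1-based inclusive everywhere in memory; the only
  0-based half-open representation is the junction BED dialect on disk,
  converted at the I/O boundary;
* TSV outputs carry ``#``-prefixed header comments (tool version, seed,
  parameter hash) which readers skip transparently;
* missing cells in count tables are written as ``NA``, never as zero.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MISSING_ALLELE = -1

_VCF_FIXED = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]


@dataclass
class GenotypeTable:
    """Phased genotypes for a cohort.

    Attributes
    ----------
    haplotypes:
        ``(n_samples, n_variants, 2)`` integer array of allele indices;
        ``-1`` marks a missing allele.
    variants:
        One row per variant: ``variant_id, chrom, pos, ref, alt, ar2``
        (``alt`` holds comma-joined alleles for multi-allelic sites,
        ``ar2`` is the imputation quality, NaN when absent).
    samples:
        Sample identifiers, in haplotype-array order.
    """

    haplotypes: np.ndarray
    variants: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        n_s, n_v, two = self.haplotypes.shape
        if two != 2:
            raise ValueError("haplotypes must have trailing dimension 2")
        if n_s != len(self.samples) or n_v != len(self.variants):
            raise ValueError("haplotype array shape inconsistent with metadata")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def dosages(self) -> np.ndarray:
        """``(n_samples, n_variants)`` count of non-reference alleles; NaN if missing."""
        h = self.haplotypes
        miss = (h < 0).any(axis=2)
        d = (h > 0).sum(axis=2).astype(float)
        d[miss] = np.nan
        return d

    def subset_variants(self, mask: np.ndarray) -> "GenotypeTable":
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeTable(
            haplotypes=self.haplotypes[:, idx, :],
            variants=self.variants.iloc[idx].reset_index(drop=True),
            samples=list(self.samples),
        )


def params_hash(params: Mapping) -> str:
    """Stable short hash of a parameter mapping, for output provenance lines."""
    blob = json.dumps({k: params[k] for k in sorted(params)}, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _meta_lines(meta: Mapping | None) -> list[str]:
    from . import __version__

    lines = [f"# rpeqtl_version={__version__}"]
    for key, val in (meta or {}).items():
        lines.append(f"# {key}={val}")
    return lines


def write_tsv(df: pd.DataFrame, path, meta: Mapping | None = None, index: bool = False) -> None:
    with open(path, "w") as fh:
        for line in _meta_lines(meta):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=index, na_rep="NA")


def read_tsv(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", comment="#", index_col=index_col,
        na_values=["NA"], keep_default_na=False,
    )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(table: GenotypeTable, path) -> None:
    """Write a phased VCF v4.2 with the AR2 INFO key for imputation quality."""
    chroms = list(dict.fromkeys(table.variants["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AR2,Number=1,Type=Float,'
                 'Description="Allelic r-squared (imputation quality)">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("\t".join(_VCF_FIXED + list(table.samples)) + "\n")
        haps = table.haplotypes
        for j, var in enumerate(table.variants.itertuples(index=False)):
            ar2 = var.ar2
            info = "." if ar2 is None or (isinstance(ar2, float) and np.isnan(ar2)) \
                else f"AR2={ar2:.4g}"
            gts = []
            for i in range(table.n_samples):
                a, b = haps[i, j]
                gts.append(f"{'.' if a < 0 else int(a)}|{'.' if b < 0 else int(b)}")
            row = [str(var.chrom), str(int(var.pos)), str(var.variant_id),
                   str(var.ref), str(var.alt), ".", "PASS", info, "GT"] + gts
            fh.write("\t".join(row) + "\n")


def read_vcf(path) -> GenotypeTable:
    """Read a (possibly phased) VCF into a :class:`GenotypeTable` using pysam."""
    import pysam

    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        rows = []
        hap_rows = []
        for rec in vcf:
            alts = rec.alts or ()
            ar2 = rec.info.get("AR2", None)
            rows.append({
                "variant_id": rec.id if rec.id not in (None, ".") else f"{rec.chrom}:{rec.pos}",
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": ",".join(a if a is not None else "." for a in alts),
                "ar2": float(ar2) if ar2 is not None else np.nan,
            })
            hap = np.full((len(samples), 2), MISSING_ALLELE, dtype=np.int8)
            for i, s in enumerate(samples):
                gt = rec.samples[s].get("GT")
                if gt is None:
                    continue
                for k, allele in enumerate(gt[:2]):
                    if allele is not None:
                        hap[i, k] = allele
            hap_rows.append(hap)
    variants = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "ref", "alt", "ar2"])
    haplotypes = (np.stack(hap_rows, axis=1) if hap_rows
                  else np.zeros((len(samples), 0, 2), dtype=np.int8))
    return GenotypeTable(haplotypes=haplotypes, variants=variants, samples=samples)


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------

def write_counts(counts: pd.DataFrame, path, meta: Mapping | None = None) -> None:
    """Gene x sample counts; the index holds gene identifiers."""
    df = counts.copy()
    df.index.name = "gene_id"
    write_tsv(df, path, meta=meta, index=True)


def read_counts(path) -> pd.DataFrame:
    return read_tsv(path, index_col="gene_id")


def write_allelic_counts(table: pd.DataFrame, path, meta: Mapping | None = None) -> None:
    cols = ["gene_id", "sample", "variant_id", "hap_ref_count", "hap_alt_count"]
    write_tsv(table[cols], path, meta=meta)


def read_allelic_counts(path) -> pd.DataFrame:
    return read_tsv(path)


# ---------------------------------------------------------------------------
# Junction BED (0-based half-open on disk, 1-based inclusive in memory)
# ---------------------------------------------------------------------------

def write_junction_bed(junctions: pd.DataFrame, path, cluster_hint: str = ".") -> None:
    """Write one sample's junctions as 6-column BED-like TSV.

    In-memory ``start``/``end`` are 1-based inclusive intron boundaries;
    on disk the interval is 0-based half-open.
    """
    with open(path, "w") as fh:
        for row in junctions.itertuples(index=False):
            hint = getattr(row, "cluster_hint", cluster_hint)
            fh.write("\t".join([
                str(row.chrom), str(int(row.start) - 1), str(int(row.end)),
                str(hint), str(int(row.count)), str(row.strand),
            ]) + "\n")


def read_junction_bed(path, sample: str) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "cluster_hint", "count", "strand"],
    )
    df["start"] = df["start"].astype(int) + 1  # back to 1-based inclusive
    df["end"] = df["end"].astype(int)
    df["sample"] = sample
    return df[["chrom", "start", "end", "strand", "sample", "count", "cluster_hint"]]


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

GWAS_COLUMNS = ["variant_id", "chrom", "pos", "ref", "alt", "beta", "se", "z", "p", "n"]


def write_gwas_summary(stats: pd.DataFrame, path, meta: Mapping | None = None) -> None:
    write_tsv(stats[GWAS_COLUMNS], path, meta=meta)


def read_gwas_summary(path) -> pd.DataFrame:
    return read_tsv(path)


# ---------------------------------------------------------------------------
# FASTA (motif target/background sequences)
# ---------------------------------------------------------------------------

def write_fasta(records: Sequence[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")
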