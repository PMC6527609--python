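"""Allele-aware cis-eQTL scan and hierarchical multi-condition FDR.

The association statistic integrates two information channels per
gene-variant pair:

* ``p_total``: two-sided t-test on the dosage coefficient of an OLS fit of
  normalized expression on dosage plus covariates;
* ``p_ase``: exact two-sided binomial test of aggregated alternative-
  haplotype read counts against 0.5 across heterozygous carriers;

combined by Fisher's method into ``p_combined``.  The allelic ratio
``pi = (alt + 1) / (alt + ref + 2)`` summarizes imbalance; |pi - 0.5| is the
allelic imbalance and delta|pi - 0.5| compares it across conditions.

FDR control is hierarchical: Simes p-values per gene, BH across genes, then
BH within selected genes at the Benjamini-Bogomolov propagated level
``q * R / m``.  The multi-condition variant inserts a per-condition Simes
level between gene and association.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ConsistencyError
from .mtc import bh_adjust, simes

log = logging.getLogger(__name__)

ASSOCIATION_COLUMNS = [
    "gene", "variant_id", "chrom", "pos", "condition",
    "beta", "se", "p_total", "p_ase", "p_combined", "pi", "n_het",
]

_P_FLOOR = 1e-300


@dataclass
class ExpressionMatrix:
    """Gene x sample integer counts plus TSS coordinates.

    ``tss`` columns: ``gene_id, chrom, tss`` (1-based).
    """

    counts: pd.DataFrame
    tss: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        missing = set(self.counts.index) - set(self.tss["gene_id"])
        if missing:
            raise ConsistencyError(f"{len(missing)} genes lack TSS coordinates")

    def size_factors(self) -> pd.Series:
        """Median-of-ratios size factors (genes with nonzero geometric mean).

        With fewer than two genes the estimator is degenerate (it would
        absorb the single gene's signal) and unit factors are returned.
        """
        if len(self.counts) < 2:
            return pd.Series(1.0, index=self.counts.columns)
        x = self.counts.to_numpy(dtype=float)
        with np.errstate(divide="ignore"):
            logx = np.log(x)
        ok = np.all(np.isfinite(logx), axis=1)
        if not ok.any():
            return pd.Series(1.0, index=self.counts.columns)
        ref = logx[ok].mean(axis=1, keepdims=True)
        sf = np.exp(np.median(logx[ok] - ref, axis=0))
        return pd.Series(sf, index=self.counts.columns)

    def normalized(self, rank_normal: bool = False) -> pd.DataFrame:
        """log2(count / size_factor + 1); optional rank-inverse-normal transform."""
        sf = self.size_factors()
        norm = np.log2(self.counts / sf + 1.0)
        if rank_normal:
            ranks = norm.rank(axis=1)
            n = norm.shape[1]
            norm = pd.DataFrame(
                stats.norm.ppf((ranks - 0.5) / n), index=norm.index, columns=norm.columns
            )
        return norm


def _design(n: int, covariates) -> np.ndarray:
    if covariates is None:
        x0 = np.ones((n, 1))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != n:
            raise ConsistencyError("covariate rows do not match sample count")
        x0 = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(x0) < x0.shape[1]:
        raise ConfigurationError("covariate matrix is rank deficient")
    return x0


def _dosage_tests(y: np.ndarray, g: np.ndarray, x0: np.ndarray):
    """Per-column dosage t-tests of the full OLS model via Frisch-Waugh.

    Returns (beta, se, p) arrays; columns with no residual dosage variance
    get NaN.
    """
    n = len(y)
    q, _ = np.linalg.qr(x0)
    ry = y - q @ (q.T @ y)
    rg = g - q @ (q.T @ g)
    den = np.einsum("ij,ij->j", rg, rg)
    df = n - x0.shape[1] - 1
    beta = np.full(g.shape[1], np.nan)
    se = np.full(g.shape[1], np.nan)
    p = np.full(g.shape[1], np.nan)
    ok = den > 1e-10
    if df <= 0 or not ok.any():
        return beta, se, p
    num = rg.T @ ry
    beta[ok] = num[ok] / den[ok]
    rss = (ry @ ry) - beta[ok] ** 2 * den[ok]
    sigma2 = np.maximum(rss, 0.0) / df
    se[ok] = np.sqrt(sigma2 / den[ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[ok] / se[ok]
    p[ok] = 2.0 * stats.t.sf(np.abs(t), df)
    return beta, se, p


def cis_scan(
    expr: ExpressionMatrix,
    geno,
    allelic: pd.DataFrame | None = None,
    covariates=None,
    window_bp: int = 500_000,
    condition: str = "condition1",
    min_het: int = 2,
    min_ase_depth: int = 10,
    genes: list | None = None,
    rank_normal: bool = False,
) -> pd.DataFrame:
    """Test every gene against every variant within ``window_bp`` of its TSS.

    ``geno`` is an :class:`rpeqtl.io.GenotypeTable` whose samples must match
    the expression columns (order is reconciled here).  ``allelic`` carries
    per-haplotype read counts for heterozygous carriers only.
    """
    samples = list(expr.counts.columns)
    if set(samples) != set(geno.samples):
        raise ConsistencyError("expression and genotype samples differ")
    order = [geno.samples.index(s) for s in samples]
    dos = geno.dosages()[order, :]
    # mean-impute missing dosages for the regression channel
    col_mean = np.nanmean(dos, axis=0)
    nan_mask = np.isnan(dos)
    if nan_mask.any():
        dos[nan_mask] = np.take(col_mean, np.where(nan_mask)[1])

    norm = expr.normalized(rank_normal=rank_normal)
    x0 = _design(len(samples), covariates)
    vmeta = geno.variants
    vpos = vmeta["pos"].to_numpy()
    vchrom = vmeta["chrom"].to_numpy()

    ase_groups = {}
    if allelic is not None and not allelic.empty:
        ase_groups = {k: v for k, v in allelic.groupby(["gene_id", "variant_id"])}

    tss = expr.tss.set_index("gene_id")
    gene_list = list(expr.counts.index) if genes is None else list(genes)
    rows = []
    for gene in gene_list:
        chrom, gtss = tss.loc[gene, "chrom"], tss.loc[gene, "tss"]
        cis = np.flatnonzero((vchrom == chrom) & (np.abs(vpos - gtss) <= window_bp))
        if cis.size == 0:
            continue
        y = norm.loc[gene].to_numpy(dtype=float)
        g = dos[:, cis]
        beta, se, p_total = _dosage_tests(y, g, x0)
        for k, j in enumerate(cis):
            vid = vmeta.iloc[j]["variant_id"]
            p_ase, pi, n_het = np.nan, np.nan, 0
            grp = ase_groups.get((gene, vid))
            if grp is not None:
                alt = int(grp["hap_alt_count"].sum())
                ref = int(grp["hap_ref_count"].sum())
                n_het = int(grp["sample"].nunique())
                tot = alt + ref
                pi = (alt + 1) / (tot + 2)
                if n_het >= min_het and tot >= min_ase_depth:
                    p_ase = stats.binomtest(alt, tot, 0.5).pvalue
            p_combined = _fisher_combine(p_total[k], p_ase)
            if np.isnan(p_combined):
                continue
            rows.append((gene, vid, chrom, int(vmeta.iloc[j]["pos"]), condition,
                         beta[k], se[k], p_total[k], p_ase, p_combined, pi, n_het))
    return pd.DataFrame(rows, columns=ASSOCIATION_COLUMNS)


def _fisher_combine(p_total: float, p_ase: float) -> float:
    have_t, have_a = not np.isnan(p_total), not np.isnan(p_ase)
    if have_t and have_a:
        x2 = -2.0 * (np.log(max(p_total, _P_FLOOR)) + np.log(max(p_ase, _P_FLOOR)))
        return float(stats.chi2.sf(x2, df=4))
    if have_t:
        return float(p_total)
    if have_a:
        return float(p_ase)
    return np.nan


@dataclass
class EqtlCallSet:
    """Selections from hierarchical FDR control.

    ``genes``: per gene, the Simes p, BH-adjusted q and selection flag
    (plus a shared/specific ``label`` in the multi-condition case).
    ``gene_conditions``: level-2 records (multi-condition only).
    ``associations``: selected associations with their adjusted level.
    """

    genes: pd.DataFrame
    associations: pd.DataFrame
    gene_conditions: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def egenes(self) -> list[str]:
        if self.genes.empty:
            return []
        return sorted(self.genes.loc[self.genes["selected"], "gene"])


def hierarchical_fdr(
    records: pd.DataFrame, q_gene: float = 0.05, q_assoc: float = 0.05
) -> EqtlCallSet:
    """Two-level gene -> association FDR (single condition)."""
    if records.empty:
        return EqtlCallSet(genes=pd.DataFrame(columns=["gene", "p_gene", "q_gene", "selected"]),
                           associations=records.copy())
    grouped = records.groupby("gene", sort=True)["p_combined"]
    gene_ids = list(grouped.groups)
    p_gene = np.array([simes(v) for _, v in grouped])
    q_adj = bh_adjust(p_gene)
    selected = q_adj <= q_gene
    genes = pd.DataFrame({"gene": gene_ids, "p_gene": p_gene,
                          "q_gene": q_adj, "selected": selected})
    m = len(gene_ids)
    r = int(selected.sum())
    level2 = q_assoc * r / m if m else 0.0
    out_assoc = []
    for gene in np.array(gene_ids)[selected]:
        sub = records[records["gene"] == gene].copy()
        sub["p_adj_assoc"] = bh_adjust(sub["p_combined"].to_numpy())
        sub["selected"] = sub["p_adj_assoc"] <= level2
        out_assoc.append(sub[sub["selected"]])
    associations = (pd.concat(out_assoc, ignore_index=True)
                    if out_assoc else records.iloc[0:0].copy())
    return EqtlCallSet(genes=genes, associations=associations)


def multi_condition_fdr(
    records_by_condition: dict[str, pd.DataFrame], q: float = 0.05
) -> EqtlCallSet:
    """Three-level gene -> condition -> association FDR with shared/specific
    labels.  Level-2 and level-3 BH run at Benjamini-Bogomolov propagated
    levels ``q * R1/m1`` and ``q * R2/m2``."""
    if len(records_by_condition) < 2:
        warnings.warn("single condition supplied; delegating to hierarchical_fdr")
        (records,) = records_by_condition.values()
        return hierarchical_fdr(records, q_gene=q, q_assoc=q)

    conditions = list(records_by_condition)
    frames = []
    for cond, df in records_by_condition.items():
        df = df.copy()
        df["condition"] = cond
        frames.append(df)
    records = pd.concat(frames, ignore_index=True)

    # level 1: gene
    grouped = records.groupby("gene", sort=True)["p_combined"]
    gene_ids = list(grouped.groups)
    p_gene = np.array([simes(v) for _, v in grouped])
    q_adj = bh_adjust(p_gene)
    sel_gene = q_adj <= q
    m1, r1 = len(gene_ids), int(sel_gene.sum())
    level2 = q * r1 / m1 if m1 else 0.0

    # level 2: condition within selected genes
    gc_rows = []
    for gene in np.array(gene_ids)[sel_gene]:
        sub = records[records["gene"] == gene]
        p_conds = {c: simes(sub.loc[sub["condition"] == c, "p_combined"])
                   for c in conditions if (sub["condition"] == c).any()}
        adj = bh_adjust(list(p_conds.values()))
        for (cond, p_gc), a in zip(p_conds.items(), adj):
            gc_rows.append((gene, cond, p_gc, a, bool(a <= level2)))
    gene_conditions = pd.DataFrame(
        gc_rows, columns=["gene", "condition", "p_gene_condition", "p_adj", "selected"])

    m2 = len(gene_conditions)
    r2 = int(gene_conditions["selected"].sum()) if m2 else 0
    level3 = q * r2 / m2 if m2 else 0.0

    # level 3: associations within selected gene-conditions
    out_assoc = []
    if m2:
        for gene, cond in gene_conditions.loc[gene_conditions["selected"],
                                              ["gene", "condition"]].itertuples(index=False):
            sub = records[(records["gene"] == gene) & (records["condition"] == cond)].copy()
            sub["p_adj_assoc"] = bh_adjust(sub["p_combined"].to_numpy())
            sub["selected"] = sub["p_adj_assoc"] <= level3
            out_assoc.append(sub[sub["selected"]])
    associations = (pd.concat(out_assoc, ignore_index=True)
                    if out_assoc else records.iloc[0:0].copy())

    labels = []
    sel_by_gene = (gene_conditions[gene_conditions["selected"]]
                   .groupby("gene")["condition"].agg(list)
                   if m2 else pd.Series(dtype=object))
    for gene, is_sel in zip(gene_ids, sel_gene):
        if not is_sel:
            labels.append("not_selected")
            continue
        conds = sel_by_gene.get(gene, [])
        if len(conds) == len(conditions):
            labels.append("shared")
        elif len(conds) == 1:
            labels.append(f"{conds[0]}-specific")
        else:
            labels.append("none" if not conds else ",".join(sorted(conds)) + "-specific")
    genes = pd.DataFrame({"gene": gene_ids, "p_gene": p_gene, "q_gene": q_adj,
                          "selected": sel_gene, "label": labels})
    return EqtlCallSet(genes=genes, associations=associations,
                       gene_conditions=gene_conditions)


def delta_imbalance(rec_a, rec_b) -> float:
    """| |pi_a - 0.5| - |pi_b - 0.5| | for the same gene/variant across
    conditions; NaN when either pi is missing."""
    if rec_a["gene"] != rec_b["gene"] or rec_a["variant_id"] != rec_b["variant_id"]:
        raise ConsistencyError("delta imbalance requires the same gene and variant")
    pi_a, pi_b = rec_a["pi"], rec_b["pi"]
    if pd.isna(pi_a) or pd.isna(pi_b):
        return np.nan
    return float(abs(abs(pi_a - 0.5) - abs(pi_b - 0.5)))


def rank_condition_specific(records_a: pd.DataFrame, records_b: pd.DataFrame) -> pd.DataFrame:
    """Merge two condition tables on (gene, variant) and rank by descending
    delta|pi - 0.5|; pairs with missing pi are excluded."""
    merged = records_a.merge(records_b, on=["gene", "variant_id"], suffixes=("_a", "_b"))
    merged["delta_imbalance"] = (
        (merged["pi_a"] - 0.5).abs() - (merged["pi_b"] - 0.5).abs()
    ).abs()
    merged = merged.dropna(subset=["delta_imbalance"])
    return merged.sort_values("delta_imbalance", ascending=False, ignore_index=True)


def select_covariates(
    expr: ExpressionMatrix,
    geno,
    candidate_covariates: list[tuple[str, np.ndarray]],
    allelic: pd.DataFrame | None = None,
    probe_genes: int = 50,
    seed: int = 0,
    window_bp: int = 500_000,
    q: float = 0.05,
) -> tuple[list[str], pd.DataFrame]:
    """Pick the nested covariate prefix maximizing significant associations
    on a seeded random probe-gene subset; ties favor the smaller set.

    Candidates collinear with the already-accepted design are dropped with a
    warning.  Returns (chosen names, per-set diagnostics).
    """
    rng = np.random.default_rng(seed)
    all_genes = list(expr.counts.index)
    probe = sorted(rng.choice(all_genes, size=min(probe_genes, len(all_genes)),
                              replace=False))
    n = expr.counts.shape[1]
    kept: list[tuple[str, np.ndarray]] = []
    base = np.ones((n, 1))
    for name, vec in candidate_covariates:
        cand = np.column_stack([base] + [v[:, None] if v.ndim == 1 else v
                                         for _, v in kept] + [np.asarray(vec).reshape(n, -1)])
        if np.linalg.matrix_rank(cand) <= np.linalg.matrix_rank(cand[:, :-1]):
            warnings.warn(f"covariate {name!r} is collinear with earlier ones; dropped")
            continue
        kept.append((name, np.asarray(vec, dtype=float)))

    results = []
    best_names: list[str] = []
    best_count = -1
    for k in range(len(kept) + 1):
        names = [nm for nm, _ in kept[:k]]
        cov = np.column_stack([v for _, v in kept[:k]]) if k else None
        recs = cis_scan(expr, geno, allelic=allelic, covariates=cov,
                        window_bp=window_bp, genes=probe)
        calls = hierarchical_fdr(recs, q_gene=q, q_assoc=q)
        count = len(calls.associations)
        results.append({"n_covariates": k, "covariates": ",".join(names),
                        "n_associations": count})
        if count > best_count:  # strict > keeps the smaller set on ties
            best_count, best_names = count, names
    return best_names, pd.DataFrame(results)


def build_motif_inputs(
    lead_records: pd.DataFrame,
    reference,
    flank: int = 15,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Build target/background sequences around lead variants.

    The target carries the expression-increasing allele (sign of beta), the
    background the decreasing one; sequences have length ``2*flank + 1``.
    ``reference`` maps chromosome name to sequence string.
    """
    targets, backgrounds = [], []
    for row in lead_records.itertuples(index=False):
        chrom_seq = reference.get(row.chrom) if hasattr(reference, "get") else reference[row.chrom]
        if chrom_seq is None:
            log.warning("variant %s: contig %s absent from reference", row.variant_id, row.chrom)
            continue
        pos0 = int(row.pos) - 1
        if pos0 - flank < 0 or pos0 + flank >= len(chrom_seq):
            log.warning("variant %s too close to contig edge; skipped", row.variant_id)
            continue
        ref_allele, alt_allele = str(row.ref), str(row.alt)
        if len(ref_allele) != 1 or len(alt_allele) != 1:
            log.warning("variant %s is not a SNV; skipped", row.variant_id)
            continue
        left = str(chrom_seq[pos0 - flank:pos0])
        right = str(chrom_seq[pos0 + 1:pos0 + flank + 1])
        inc, dec = (alt_allele, ref_allele) if row.beta > 0 else (ref_allele, alt_allele)
        targets.append((f"{row.variant_id}_target", left + inc + right))
        backgrounds.append((f"{row.variant_id}_background", left + dec + right))
    return targets, backgrounds
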