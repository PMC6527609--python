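"""Synthetic two-condition cohorts with known ground truth.

Every downstream stage (genotype QC, selectivity scoring, e/sQTL mapping,
fine-mapping colocalization, specificity classification) is testable
against cohorts produced here.  Generators are pure functions of their
configuration and seed.

Genotypes follow a haplotype copying model: the first variant of a locus is
drawn from its minor-allele frequency; each subsequent variant copies the
previous variant's allele on the same haplotype with probability
``ld_copy_prob`` and is otherwise drawn fresh, giving tunable LD decay.
Gene totals are negative binomial with a log2-linear dosage effect; allelic
counts at heterozygous carriers are binomial with alternative-haplotype
probability ``pi``.  Exon-skipping clusters use a three-junction topology
(two inclusion junctions plus one skipping junction sharing donor and
acceptor sites) with a multiplicative skip effect per causal-allele dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ConsistencyError
from .io import GenotypeTable

LOCUS_SPACING_BP = 2_000_000
VARIANT_SPACING_BP = 1_000

_TRANSITIONS = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass(frozen=True)
class SimulationConfig:
    n_samples: int = 23
    n_loci: int = 10
    variants_per_locus: int = 20
    maf_range: tuple[float, float] = (0.1, 0.5)
    ld_copy_prob: float = 0.9
    n_conditions: int = 2
    conditions: tuple[str, ...] = ("glucose", "galactose")
    depth_mean: float = 500.0
    depth_dispersion: float = 0.05
    ase_depth: float = 50.0
    junction_depth: float = 100.0
    gwas_n: int = 50_000
    n_populations: int = 1
    ar2_range: tuple[float, float] = (0.8, 1.0)
    ase_overdispersed: bool = False
    ase_bb_rho: float = 0.05
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_loci", "variants_per_locus", "n_conditions",
                     "gwas_n", "n_populations"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must be a subinterval of (0, 0.5]")
        if not 0.0 <= self.ld_copy_prob <= 1.0:
            raise ConfigurationError("ld_copy_prob must lie in [0, 1]")
        if len(self.conditions) < self.n_conditions:
            raise ConfigurationError("not enough condition labels")
        if self.depth_mean <= 0 or self.ase_depth <= 0 or self.junction_depth <= 0:
            raise ConfigurationError("depth parameters must be positive")
        if self.depth_dispersion < 0:
            raise ConfigurationError("depth_dispersion must be nonnegative")

    @property
    def condition_labels(self) -> tuple[str, ...]:
        return self.conditions[: self.n_conditions]


@dataclass
class SyntheticCohort:
    genotypes: GenotypeTable
    sample_meta: pd.DataFrame  # id, sex, population_label
    config: SimulationConfig

    @property
    def samples(self) -> list[str]:
        return list(self.genotypes.samples)

    def locus_variants(self, locus: int) -> np.ndarray:
        return np.flatnonzero(self.genotypes.variants["locus"].to_numpy() == locus)


@dataclass
class SyntheticTruth:
    """Ground truth of planted effects, consistent with a cohort.

    ``genes``: gene_id, chrom, tss, locus.
    ``eqtl_effects``: gene_id, condition, causal_variant, beta, pi.
    ``clusters``: cluster_id, chrom, strand, inc1_start, inc1_end,
    inc2_start, inc2_end (two inclusion introns; the skipping intron spans
    inc1_start..inc2_end, sharing the donor of inc1 and acceptor of inc2).
    ``sqtl_effects``: cluster_id, condition, causal_variant, skip_effect,
    baseline_skip (skip fraction multiplied by exp(skip_effect * dosage)).
    ``gwas_loci``: locus_id, locus (genomic locus index), causal_variants
    (list), effect_sizes (list, standardized), shared_with_qtl.
    """

    genes: pd.DataFrame
    eqtl_effects: pd.DataFrame = field(default_factory=pd.DataFrame)
    clusters: pd.DataFrame = field(default_factory=pd.DataFrame)
    sqtl_effects: pd.DataFrame = field(default_factory=pd.DataFrame)
    gwas_loci: pd.DataFrame = field(default_factory=pd.DataFrame)

    def validate(self, cohort: SyntheticCohort) -> None:
        vids = set(cohort.genotypes.variants["variant_id"])
        genes = set(self.genes["gene_id"])
        if not self.eqtl_effects.empty:
            bad = set(self.eqtl_effects["gene_id"]) - genes
            if bad:
                raise ConsistencyError(f"eQTL truth references unknown genes: {sorted(bad)[:5]}")
            cvs = self.eqtl_effects["causal_variant"].dropna()
            bad = set(cvs) - vids
            if bad:
                raise ConsistencyError(f"eQTL truth references unknown variants: {sorted(bad)[:5]}")
            pis = self.eqtl_effects["pi"].to_numpy(dtype=float)
            if np.any((pis <= 0) | (pis >= 1)):
                raise ConsistencyError("pi must lie strictly inside (0, 1)")
        if not self.sqtl_effects.empty:
            bad = set(self.sqtl_effects["cluster_id"]) - set(self.clusters["cluster_id"])
            if bad:
                raise ConsistencyError(f"sQTL truth references unknown clusters: {sorted(bad)[:5]}")
            bad = set(self.sqtl_effects["causal_variant"].dropna()) - vids
            if bad:
                raise ConsistencyError(f"sQTL truth references unknown variants: {sorted(bad)[:5]}")


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Haplotype-copying cohort; deterministic for a given config/seed."""
    rng = np.random.default_rng(config.seed)
    n, n_loci, vpl = config.n_samples, config.n_loci, config.variants_per_locus
    lo, hi = config.maf_range
    n_variants = n_loci * vpl

    pop = np.zeros(n, dtype=int)
    if config.n_populations > 1:
        pop = np.arange(n) * config.n_populations // n

    haps = np.zeros((n, n_variants, 2), dtype=np.int8)
    meta_rows = []
    bases = np.array(["A", "C", "G", "T"])
    for locus in range(n_loci):
        mafs = rng.uniform(lo, hi, size=(config.n_populations, vpl))
        for j in range(vpl):
            col = locus * vpl + j
            fresh = (rng.random((n, 2)) < mafs[pop, j][:, None]).astype(np.int8)
            if j == 0:
                haps[:, col, :] = fresh
            else:
                copy = rng.random((n, 2)) < config.ld_copy_prob
                haps[:, col, :] = np.where(copy, haps[:, col - 1, :], fresh)
            pos = locus * LOCUS_SPACING_BP + 10_000 + j * VARIANT_SPACING_BP
            ref = str(rng.choice(bases))
            alt = (_TRANSITIONS[ref] if rng.random() < 2 / 3
                   else str(rng.choice([b for b in bases if b != ref and b != _TRANSITIONS[ref]])))
            meta_rows.append({
                "variant_id": f"v{col:05d}", "chrom": config.chrom, "pos": pos,
                "ref": ref, "alt": alt,
                "ar2": float(rng.uniform(*config.ar2_range)), "locus": locus,
            })
    variants = pd.DataFrame(meta_rows)
    samples = [f"S{i:03d}" for i in range(n)]
    sample_meta = pd.DataFrame({
        "id": samples,
        "sex": rng.choice(["male", "female"], size=n),
        "population_label": [f"pop{p + 1}" for p in pop],
    })
    table = GenotypeTable(haplotypes=haps, variants=variants, samples=samples)
    return SyntheticCohort(genotypes=table, sample_meta=sample_meta, config=config)


def make_truth(
    cohort: SyntheticCohort,
    n_eqtl_genes: int | None = None,
    beta: float = 1.0,
    pi: float = 0.7,
    condition_specific_fraction: float = 0.0,
    n_sqtl_clusters: int = 0,
    skip_effect: float = np.log(3.0),
    baseline_skip: float = 0.05,
    n_gwas_loci: int = 0,
    gwas_effect: float = 0.05,
    shared_with_qtl: bool = True,
    seed: int | None = None,
) -> SyntheticTruth:
    """Convenience truth builder: one gene per genomic locus, causal variant
    in the middle of the locus, optionally condition-specific effects,
    exon-skipping clusters and GWAS loci tied to the first loci."""
    config = cohort.config
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    variants = cohort.genotypes.variants
    conditions = config.condition_labels

    gene_rows, eff_rows = [], []
    n_eqtl = config.n_loci if n_eqtl_genes is None else n_eqtl_genes
    for locus in range(config.n_loci):
        gene = f"G{locus:04d}"
        vloc = cohort.locus_variants(locus)
        tss = int(variants.iloc[vloc[0]]["pos"])
        gene_rows.append({"gene_id": gene, "chrom": config.chrom, "tss": tss, "locus": locus})
        causal = variants.iloc[vloc[len(vloc) // 2]]["variant_id"]
        active = locus < n_eqtl
        specific = active and rng.random() < condition_specific_fraction
        for k, cond in enumerate(conditions):
            on = active and (not specific or k == 0)
            eff_rows.append({
                "gene_id": gene, "condition": cond, "causal_variant": causal,
                "beta": beta if on else 0.0, "pi": pi if on else 0.5,
            })
    genes = pd.DataFrame(gene_rows)
    eqtl_effects = pd.DataFrame(eff_rows)

    clu_rows, sq_rows = [], []
    for c in range(n_sqtl_clusters):
        locus = c % config.n_loci
        vloc = cohort.locus_variants(locus)
        base = int(variants.iloc[vloc[0]]["pos"])
        clu_rows.append({
            "cluster_id": f"sc{c:03d}", "chrom": config.chrom, "strand": "+",
            "inc1_start": base + 100, "inc1_end": base + 600,
            "inc2_start": base + 900, "inc2_end": base + 1400,
        })
        causal = variants.iloc[vloc[len(vloc) // 2]]["variant_id"]
        for cond in conditions:
            sq_rows.append({
                "cluster_id": f"sc{c:03d}", "condition": cond,
                "causal_variant": causal, "skip_effect": skip_effect,
                "baseline_skip": baseline_skip,
            })
    gw_rows = []
    for g in range(n_gwas_loci):
        locus = g % config.n_loci
        vloc = cohort.locus_variants(locus)
        if shared_with_qtl:
            causal = variants.iloc[vloc[len(vloc) // 2]]["variant_id"]
        else:
            causal = variants.iloc[vloc[0]]["variant_id"]
        gw_rows.append({
            "locus_id": f"L{g:03d}", "locus": locus,
            "causal_variants": [causal], "effect_sizes": [gwas_effect],
            "shared_with_qtl": shared_with_qtl,
        })
    truth = SyntheticTruth(
        genes=genes, eqtl_effects=eqtl_effects,
        clusters=pd.DataFrame(clu_rows), sqtl_effects=pd.DataFrame(sq_rows),
        gwas_loci=pd.DataFrame(gw_rows),
    )
    truth.validate(cohort)
    return truth


# ---------------------------------------------------------------------------
# Expression / ASE
# ---------------------------------------------------------------------------

def _nb_draw(rng, mean, dispersion):
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-9)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def simulate_expression(
    cohort: SyntheticCohort, truth: SyntheticTruth, config: SimulationConfig | None = None
) -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame]]:
    """Per-condition gene count matrices and allelic count tables.

    Gene totals: NB with log2-mean ``log2(depth_mean) + beta * dosage`` at
    the causal variant.  Allelic counts: heterozygous carriers only, depth
    Poisson(``ase_depth``), alternative-haplotype reads Binomial(depth, pi)
    (beta-binomial when ``ase_overdispersed``).
    """
    config = config or cohort.config
    truth.validate(cohort)
    rng = np.random.default_rng(config.seed + 7919)
    geno = cohort.genotypes
    vindex = pd.Index(geno.variants["variant_id"])
    samples = cohort.samples
    n = len(samples)

    counts_by_cond: dict[str, pd.DataFrame] = {}
    allelic_by_cond: dict[str, pd.DataFrame] = {}
    eff = truth.eqtl_effects.set_index(["gene_id", "condition"])
    for cond in config.condition_labels:
        mat = np.zeros((len(truth.genes), n), dtype=int)
        ase_rows = []
        for gi, gene in enumerate(truth.genes["gene_id"]):
            key = (gene, cond)
            beta, pi, causal = 0.0, 0.5, None
            if key in eff.index:
                row = eff.loc[key]
                beta, pi, causal = float(row["beta"]), float(row["pi"]), row["causal_variant"]
            dosage = np.zeros(n)
            het = np.zeros(n, dtype=bool)
            if causal is not None and not pd.isna(causal):
                j = vindex.get_loc(causal)
                hap = geno.haplotypes[:, j, :]
                dosage = hap.sum(axis=1).astype(float)
                het = hap[:, 0] != hap[:, 1]
            mu = config.depth_mean * np.power(2.0, beta * dosage)
            mat[gi] = _nb_draw(rng, mu, config.depth_dispersion)
            if causal is not None and het.any():
                depth = rng.poisson(config.ase_depth, size=int(het.sum()))
                if config.ase_overdispersed and config.ase_bb_rho > 0:
                    rho = config.ase_bb_rho
                    a = pi * (1 - rho) / rho
                    b = (1 - pi) * (1 - rho) / rho
                    p_draw = rng.beta(a, b, size=depth.shape)
                else:
                    p_draw = np.full(depth.shape, pi)
                alt = rng.binomial(depth, p_draw)
                for s, d, a_cnt in zip(np.array(samples)[het], depth, alt):
                    ase_rows.append({
                        "gene_id": gene, "sample": s, "variant_id": causal,
                        "hap_ref_count": int(d - a_cnt), "hap_alt_count": int(a_cnt),
                    })
        counts_by_cond[cond] = pd.DataFrame(mat, index=list(truth.genes["gene_id"]),
                                            columns=samples)
        allelic_by_cond[cond] = pd.DataFrame(
            ase_rows, columns=["gene_id", "sample", "variant_id",
                               "hap_ref_count", "hap_alt_count"])
    return counts_by_cond, allelic_by_cond


# ---------------------------------------------------------------------------
# Junctions
# ---------------------------------------------------------------------------

def simulate_junctions(
    cohort: SyntheticCohort, truth: SyntheticTruth, config: SimulationConfig | None = None
) -> dict[str, pd.DataFrame]:
    """Per-condition junction tables for the planted three-junction clusters.

    The skipping junction spans inc1_start..inc2_end; its proportion is
    ``baseline_skip * exp(skip_effect * dosage)`` (capped at 0.9), with the
    remainder split evenly between the two inclusion junctions.
    """
    config = config or cohort.config
    truth.validate(cohort)
    if truth.clusters.empty:
        return {c: pd.DataFrame(columns=["chrom", "start", "end", "strand", "sample", "count"])
                for c in config.condition_labels}
    _check_topology(truth.clusters)
    rng = np.random.default_rng(config.seed + 104729)
    geno = cohort.genotypes
    vindex = pd.Index(geno.variants["variant_id"])
    samples = cohort.samples
    eff = truth.sqtl_effects.set_index(["cluster_id", "condition"])

    out: dict[str, pd.DataFrame] = {}
    for cond in config.condition_labels:
        rows = []
        for clu in truth.clusters.itertuples(index=False):
            key = (clu.cluster_id, cond)
            skip_effect, s0, causal = 0.0, 0.05, None
            if key in eff.index:
                erow = eff.loc[key]
                skip_effect = float(erow["skip_effect"])
                s0 = float(erow["baseline_skip"])
                causal = erow["causal_variant"]
            dosage = np.zeros(len(samples))
            if causal is not None and not pd.isna(causal):
                j = vindex.get_loc(causal)
                dosage = geno.haplotypes[:, j, :].sum(axis=1).astype(float)
            s = np.minimum(0.9, s0 * np.exp(skip_effect * dosage))
            depth = rng.poisson(config.junction_depth, size=len(samples))
            for i, sample in enumerate(samples):
                probs = [(1 - s[i]) / 2, (1 - s[i]) / 2, s[i]]
                inc1, inc2, skip = rng.multinomial(depth[i], probs)
                for (start, end), cnt in (
                    ((clu.inc1_start, clu.inc1_end), inc1),
                    ((clu.inc2_start, clu.inc2_end), inc2),
                    ((clu.inc1_start, clu.inc2_end), skip),
                ):
                    rows.append({"chrom": clu.chrom, "start": int(start), "end": int(end),
                                 "strand": clu.strand, "sample": sample, "count": int(cnt)})
        out[cond] = pd.DataFrame(rows)
    return out


def _check_topology(clusters: pd.DataFrame) -> None:
    from .errors import InvalidTopologyError

    for clu in clusters.itertuples(index=False):
        if not (clu.inc1_start < clu.inc1_end < clu.inc2_start < clu.inc2_end):
            raise InvalidTopologyError(
                f"cluster {clu.cluster_id}: junction coordinates must satisfy "
                "inc1_start < inc1_end < inc2_start < inc2_end"
            )


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

def simulate_gwas_summary(
    cohort: SyntheticCohort,
    truth: SyntheticTruth,
    locus_id: str,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Summary statistics under the standard model: ``z ~ MVN(sqrt(n) R
    lambda, R)`` with LD from the cohort and standardized effects from the
    truth."""
    config = config or cohort.config
    loci = truth.gwas_loci
    if loci.empty or locus_id not in set(loci["locus_id"]):
        raise KeyError(f"unknown GWAS locus {locus_id!r}")
    row = loci.set_index("locus_id").loc[locus_id]
    vloc = cohort.locus_variants(int(row["locus"]))
    geno = cohort.genotypes
    vmeta = geno.variants.iloc[vloc]
    dos = np.nan_to_num(geno.dosages()[:, vloc])
    sd = dos.std(axis=0)
    keep = sd > 0
    vmeta = vmeta[keep].reset_index(drop=True)
    dos = dos[:, keep]
    m = len(vmeta)
    if m == 0:
        raise ConsistencyError(f"locus {locus_id}: all variants monomorphic")
    r = np.corrcoef(dos, rowvar=False)
    r = np.atleast_2d(r)
    r = (r + 1e-3 * np.eye(m)) / (1 + 1e-3)

    lam = np.zeros(m)
    vid_list = list(vmeta["variant_id"])
    for v, e in zip(row["causal_variants"], row["effect_sizes"]):
        if v in vid_list:
            lam[vid_list.index(v)] = e
    mean = np.sqrt(config.gwas_n) * (r @ lam)
    if rng is None:
        rng = np.random.default_rng(config.seed + 224737 + abs(hash(locus_id)) % 100_000)
    chol = np.linalg.cholesky(r)
    z = mean + chol @ rng.standard_normal(m)
    from scipy import stats as sps

    se = 1.0 / np.sqrt(config.gwas_n)
    return pd.DataFrame({
        "variant_id": vmeta["variant_id"], "chrom": vmeta["chrom"], "pos": vmeta["pos"],
        "ref": vmeta["ref"], "alt": vmeta["alt"],
        "beta": z * se, "se": se, "z": z, "p": 2 * sps.norm.sf(np.abs(z)),
        "n": config.gwas_n,
    })


# ---------------------------------------------------------------------------
# Tissue panel
# ---------------------------------------------------------------------------

def simulate_tissue_panel(
    n_tissues: int,
    n_genes: int,
    selective_sets: dict[str, list[str]] | None = None,
    z_target: float = 5.0,
    seed: int = 0,
    background_sd: float = 0.3,
):
    """Median-expression panel with planted tissue-selective genes.

    Background tissue medians are exchangeable (log-normal noise around a
    per-gene baseline); planted genes are scaled up until their realized
    selectivity z-score exceeds ``z_target``.
    """
    from .selectivity import TissuePanel, selectivity_zscores

    if z_target <= 0:
        raise ConfigurationError("z_target must be positive")
    max_z = (n_tissues - 1) / np.sqrt(n_tissues)
    if z_target >= max_z:
        raise ConfigurationError(
            f"z_target={z_target} unreachable with {n_tissues} tissues (max {max_z:.2f})")
    selective_sets = selective_sets or {}
    seen: set[str] = set()
    for tissue, gene_list in selective_sets.items():
        dup = seen & set(gene_list)
        if dup:
            raise ConfigurationError(f"selective sets overlap: {sorted(dup)[:5]}")
        seen |= set(gene_list)

    rng = np.random.default_rng(seed)
    tissues = [f"tissue_{t:02d}" for t in range(n_tissues)]
    name_map = {t: t for t in tissues}
    for t in selective_sets:
        if t not in name_map:
            # allow custom names: replace generated names front to back
            for i, gen in enumerate(tissues):
                if gen not in selective_sets and gen in name_map:
                    tissues[i] = t
                    del name_map[gen]
                    name_map[t] = t
                    break
    genes = [f"PG{g:05d}" for g in range(n_genes)]
    gene_set_names = {g for gl in selective_sets.values() for g in gl}
    genes = list(gene_set_names) + [g for g in genes if g not in gene_set_names]
    genes = genes[:max(n_genes, len(gene_set_names))]

    baseline = rng.lognormal(mean=2.0, sigma=1.0, size=len(genes))
    x = baseline[:, None] * rng.lognormal(mean=0.0, sigma=background_sd,
                                          size=(len(genes), n_tissues))
    medians = pd.DataFrame(x, index=genes, columns=tissues)

    for tissue, gene_list in selective_sets.items():
        tcol = medians.columns.get_loc(tissue)
        for gene in gene_list:
            row = medians.loc[gene].to_numpy(dtype=float)
            for _ in range(200):
                mu, sd = row.mean(), row.std(ddof=1)
                z = (row[tcol] - mu) / sd if sd > 0 else 0.0
                if z > z_target:
                    break
                row[tcol] = max(row[tcol] * 2.0, row.max() * 2.0)
            medians.loc[gene] = row

    annotations = pd.DataFrame({
        "gene_id": genes, "chrom": "chr1",
        "start": np.arange(len(genes)) * 10_000 + 1,
        "end": np.arange(len(genes)) * 10_000 + 5_000,
        "gene_type": "protein_coding",
    })
    panel = TissuePanel(medians=medians, annotations=annotations)
    if selective_sets:
        scores = selectivity_zscores(panel)
        for tissue, gene_list in selective_sets.items():
            sub = scores[(scores["tissue"] == tissue) & scores["gene_id"].isin(gene_list)]
            if (sub["z"] <= z_target).any():
                raise ConfigurationError("failed to reach z_target for planted genes")
    return panel


# ---------------------------------------------------------------------------
# Truth export (for test harnesses)
# ---------------------------------------------------------------------------

def truth_tables(truth: SyntheticTruth) -> dict[str, pd.DataFrame]:
    gw = truth.gwas_loci.copy()
    if not gw.empty:
        gw["causal_variants"] = gw["causal_variants"].map(lambda v: ",".join(v))
        gw["effect_sizes"] = gw["effect_sizes"].map(
            lambda v: ",".join(f"{x:g}" for x in v))
    return {
        "genes": truth.genes,
        "eqtl_effects": truth.eqtl_effects,
        "clusters": truth.clusters,
        "sqtl_effects": truth.sqtl_effects,
        "gwas_loci": gw,
    }
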