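"""Intron clustering, excision-ratio phenotypes, and sQTL mapping.

Junctions sharing a splice donor or acceptor site are grouped into clusters
(connected components).  Filters are applied iteratively to a fixpoint:
junctions supported by less than a minimum fraction of their cluster total
and introns exceeding a maximum length are dropped, components re-formed,
and the process repeated; clusters below a minimum read total or with fewer
than two introns are removed.

The phenotype is the per-sample excision ratio (junction count / cluster
total).  sQTL mapping regresses the standardized ratio on dosage over cis
variants, takes the minimum nominal p per intron, and assesses it with
adaptive label permutations; within each cluster, permutation p-values are
Bonferroni-corrected over member introns and cluster p-values are taken to
BH across clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConsistencyError
from .mtc import bh_adjust

log = logging.getLogger(__name__)

JUNCTION_COLUMNS = ["chrom", "start", "end", "strand", "sample", "count"]


def _intron_key(row) -> str:
    return f"{row.chrom}:{int(row.start)}-{int(row.end)}:{row.strand}"


@dataclass
class IntronCluster:
    cluster_id: str
    introns: pd.DataFrame          # chrom, start, end, strand, total
    sample_totals: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    @property
    def intron_ids(self) -> list[str]:
        return [_intron_key(r) for r in self.introns.itertuples(index=False)]

    def midpoint(self) -> tuple[str, int]:
        chrom = self.introns["chrom"].iloc[0]
        lo = int(self.introns["start"].min())
        hi = int(self.introns["end"].max())
        return chrom, (lo + hi) // 2


def _connected_components(introns: pd.DataFrame) -> list[np.ndarray]:
    """Group intron rows by chains of shared (chrom, strand, start|end)."""
    n = len(introns)
    parent = np.arange(n)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    seen: dict[tuple, int] = {}
    for i, row in enumerate(introns.itertuples(index=False)):
        for key in ((row.chrom, row.strand, "s", int(row.start)),
                    (row.chrom, row.strand, "e", int(row.end))):
            if key in seen:
                union(i, seen[key])
            else:
                seen[key] = i
    roots = np.array([find(i) for i in range(n)])
    return [np.flatnonzero(roots == r) for r in np.unique(roots)]


def cluster_introns(
    junctions: pd.DataFrame,
    min_cluster_reads: int = 30,
    min_fraction: float = 0.001,
    max_intron_bp: int = 100_000,
) -> list[IntronCluster]:
    """Build intron clusters from a junction table (filters to fixpoint)."""
    agg = (junctions.groupby(["chrom", "start", "end", "strand"], as_index=False)["count"]
           .sum().rename(columns={"count": "total"})
           .sort_values(["chrom", "start", "end", "strand"], ignore_index=True))
    # length filter is static: apply once up front
    lengths = agg["end"] - agg["start"] + 1
    agg = agg[lengths <= max_intron_bp].reset_index(drop=True)

    while True:
        if agg.empty:
            break
        comps = _connected_components(agg)
        drop = np.zeros(len(agg), dtype=bool)
        for comp in comps:
            total = agg.loc[comp, "total"].sum()
            frac = agg.loc[comp, "total"] / total if total > 0 else 0.0
            drop[comp[np.asarray(frac < min_fraction)]] = True
        if not drop.any():
            break
        agg = agg[~drop].reset_index(drop=True)

    clusters = []
    if not agg.empty:
        comps = _connected_components(agg)
        comps.sort(key=lambda c: (agg.loc[c[0], "chrom"], int(agg.loc[c, "start"].min())))
        idx = 1
        for comp in comps:
            members = agg.loc[comp].reset_index(drop=True)
            if len(members) < 2 or members["total"].sum() < min_cluster_reads:
                continue
            clusters.append(IntronCluster(cluster_id=f"clu_{idx}", introns=members))
            idx += 1
    return clusters


def excision_ratios(clusters: list[IntronCluster], junctions: pd.DataFrame) -> "RatioMatrix":
    """Per-sample excision ratios r = count / cluster_total for every intron."""
    samples = sorted(junctions["sample"].unique())
    jidx = junctions.set_index(["chrom", "start", "end", "strand", "sample"])["count"]
    intron_ids, cluster_of, raw_rows = [], {}, []
    count_rows = []
    for clu in clusters:
        counts = np.zeros((len(clu.introns), len(samples)))
        for i, row in enumerate(clu.introns.itertuples(index=False)):
            for j, s in enumerate(samples):
                key = (row.chrom, row.start, row.end, row.strand, s)
                counts[i, j] = jidx.get(key, 0)
        totals = counts.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = np.where(totals > 0, counts / totals, np.nan)
        clu.sample_totals = pd.Series(totals, index=samples)
        for i, iid in enumerate(clu.intron_ids):
            intron_ids.append(iid)
            cluster_of[iid] = clu.cluster_id
            raw_rows.append(ratios[i])
            count_rows.append(counts[i])
    raw = pd.DataFrame(raw_rows, index=intron_ids, columns=samples)
    return RatioMatrix(ratios=raw, cluster_of=cluster_of, clusters=clusters)


@dataclass
class RatioMatrix:
    """Intron x sample excision ratios; NaN where the cluster total is 0."""

    ratios: pd.DataFrame
    cluster_of: dict[str, str]
    clusters: list[IntronCluster]

    def standardized(self) -> pd.DataFrame:
        """Ratios centered and scaled per intron across samples."""
        r = self.ratios
        mu = r.mean(axis=1)
        sd = r.std(axis=1, ddof=1)
        return r.sub(mu, axis=0).div(sd.replace(0, np.nan), axis=0)


def _nominal_min_p(y: np.ndarray, g: np.ndarray) -> tuple[float, int]:
    """Minimum two-sided slope-test p over dosage columns; returns (p, argmin)."""
    n = len(y)
    yc = y - y.mean()
    gc = g - g.mean(axis=0)
    sy = np.sqrt((yc ** 2).sum())
    sg = np.sqrt((gc ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (gc.T @ yc) / (sg * sy)
    r = np.clip(np.where(np.isfinite(r), r, 0.0), -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df / np.maximum(1e-300, 1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    j = int(np.argmin(p))
    return float(p[j]), j


def sqtl_scan(
    ratios: RatioMatrix,
    geno,
    window_bp: int = 100_000,
    min_perms: int = 100,
    max_perms: int = 10_000,
    seed: int = 0,
    early_stop_exceedances: int = 30,
    perm_batch: int = 100,
) -> pd.DataFrame:
    """Per-intron permutation sQTL scan.

    For each intron: nominal p = min over cis variants (window around the
    cluster midpoint) of the simple-regression slope test on standardized
    ratios; permutation p = (k+1)/(M+1) with adaptive stopping once
    ``early_stop_exceedances`` permuted minima beat the observed one (never
    before ``min_perms`` permutations).
    """
    samples = list(ratios.ratios.columns)
    if set(samples) - set(geno.samples):
        raise ConsistencyError("ratio samples missing from genotype table")
    order = [geno.samples.index(s) for s in samples]
    dos = geno.dosages()[order, :]
    col_mean = np.nanmean(dos, axis=0)
    nan_mask = np.isnan(dos)
    if nan_mask.any():
        dos[nan_mask] = np.take(col_mean, np.where(nan_mask)[1])
    vpos = geno.variants["pos"].to_numpy()
    vchrom = geno.variants["chrom"].to_numpy()
    vids = geno.variants["variant_id"].to_numpy()

    std = ratios.standardized()
    rng = np.random.default_rng(seed)
    rows = []
    for clu in ratios.clusters:
        chrom, mid = clu.midpoint()
        cis = np.flatnonzero((vchrom == chrom) & (np.abs(vpos - mid) <= window_bp))
        if cis.size == 0:
            continue
        for iid in clu.intron_ids:
            yfull = std.loc[iid].to_numpy(dtype=float)
            keep = ~np.isnan(yfull)
            if keep.sum() < 3:
                continue
            y = yfull[keep]
            if np.nanstd(y) == 0:
                continue
            g = dos[np.ix_(keep, cis)]
            p_obs, jbest = _nominal_min_p(y, g)
            k, m_done = 0, 0
            while m_done < max_perms:
                batch = min(perm_batch, max_perms - m_done)
                for _ in range(batch):
                    perm = rng.permutation(len(y))
                    p_perm, _ = _nominal_min_p(y[perm], g)
                    if p_perm <= p_obs:
                        k += 1
                m_done += batch
                if m_done >= min_perms and k >= early_stop_exceedances:
                    break
            rows.append({
                "cluster": clu.cluster_id, "intron": iid,
                "lead_variant": vids[cis[jbest]],
                "nominal_p": p_obs, "perm_p": (k + 1) / (m_done + 1),
                "n_perms": m_done, "n_samples": int(keep.sum()),
            })
    return pd.DataFrame(rows)


def cluster_correction(results: pd.DataFrame, q: float = 0.05) -> pd.DataFrame:
    """Bonferroni within cluster, min over members, BH across clusters."""
    if results.empty:
        return pd.DataFrame(columns=["cluster", "lead_intron", "lead_variant",
                                     "cluster_p", "q_value", "significant"])
    out = []
    for cluster, grp in results.groupby("cluster", sort=True):
        n = len(grp)
        adj = np.minimum(grp["perm_p"].to_numpy() * n, 1.0)
        # permutation p's are discrete and often tie; break ties by nominal p
        j = int(np.lexsort((grp["nominal_p"].to_numpy(), adj))[0])
        out.append({
            "cluster": cluster,
            "lead_intron": grp["intron"].iloc[j],
            "lead_variant": grp["lead_variant"].iloc[j],
            "cluster_p": float(adj[j]),
        })
    table = pd.DataFrame(out)
    table["q_value"] = bh_adjust(table["cluster_p"].to_numpy())
    table["significant"] = table["q_value"] <= q
    return table
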