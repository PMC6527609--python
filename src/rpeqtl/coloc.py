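"""Exhaustive Bayesian fine-mapping of summary statistics and CLPP-based
colocalization between GWAS and QTL signals.

Fine-mapping enumerates all causal configurations of size <= ``max_causal``
under the standard summary-statistic model: given a causal indicator set
``c``, the z-score vector is multivariate normal with mean 0 and covariance
``R + s^2 * R D_c R`` where ``R`` is the LD correlation matrix.  Posterior
inclusion probabilities (PIPs) are obtained by marginalizing configuration
posteriors (the null configuration is part of the normalization).  The
colocalization posterior probability (CLPP) of two fine-mapped signals over
the same variants is the sum over variants of the product of their PIPs.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .errors import ConfigurationError, ConsistencyError

log = logging.getLogger(__name__)


@dataclass
class LdMatrix:
    """Correlation matrix over locus variants, ridge-stabilized."""

    matrix: np.ndarray
    variant_ids: list[str]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(self.variant_ids):
            raise ValueError("LD matrix must be square and match the variant list")
        if not np.allclose(m, m.T, atol=1e-8):
            raise ValueError("LD matrix must be symmetric")
        self.matrix = (m + m.T) / 2.0

    @classmethod
    def from_dosages(cls, dosages: np.ndarray, variant_ids, ridge: float = 1e-3) -> "LdMatrix":
        """Pearson correlation of dosage columns, ridge-shrunk to unit diagonal."""
        d = np.asarray(dosages, dtype=float)
        sd = d.std(axis=0)
        if np.any(sd == 0):
            raise ValueError("monomorphic variant in LD computation")
        r = np.corrcoef(d, rowvar=False)
        r = np.atleast_2d(r)
        r = (r + ridge * np.eye(len(r))) / (1.0 + ridge)
        return cls(matrix=r, variant_ids=list(variant_ids))


@dataclass(frozen=True)
class FineMapConfig:
    max_causal: int = 2
    prior_prob: float | None = None   # per-variant prior; default 1/m
    effect_sd: float = 3.7            # prior sd of the per-causal non-centrality
    ridge: float = 1e-3
    max_variants: int = 1000

    def __post_init__(self) -> None:
        if self.max_causal < 1:
            raise ConfigurationError("max_causal must be >= 1")
        if self.prior_prob is not None and not 0 < self.prior_prob < 1:
            raise ConfigurationError("prior_prob must lie in (0, 1)")
        if self.effect_sd <= 0:
            raise ConfigurationError("effect_sd must be positive")


@dataclass
class PosteriorSet:
    variant_ids: list[str]
    pip: np.ndarray
    configurations: list[tuple[int, ...]]
    config_posterior: np.ndarray
    null_mass: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"variant_id": self.variant_ids, "pip": self.pip})


@dataclass
class Locus:
    locus_id: str
    lead_variant: str
    variant_ids: list[str]
    gwas: pd.DataFrame
    qtl: pd.DataFrame


def _mvn_logpdf(z: np.ndarray, cov: np.ndarray) -> float:
    m = len(z)
    try:
        cho = linalg.cho_factor(cov, lower=True)
    except linalg.LinAlgError as exc:
        raise ConsistencyError("covariance not positive definite; increase ridge") from exc
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    quad = z @ linalg.cho_solve(cho, z)
    return -0.5 * (m * math.log(2.0 * math.pi) + logdet + quad)


def finemap_posteriors(
    stats: pd.DataFrame, ld: LdMatrix, config: FineMapConfig = FineMapConfig()
) -> PosteriorSet:
    """Exhaustive configuration enumeration up to ``config.max_causal`` causals.

    ``stats`` must carry one row per variant in LD-matrix order with a ``z``
    column (or ``beta``/``se`` from which z is formed).
    """
    if list(stats["variant_id"]) != list(ld.variant_ids):
        raise ConsistencyError("summary-stat variants do not match the LD matrix")
    if "z" in stats.columns:
        z = stats["z"].to_numpy(dtype=float)
    else:
        z = (stats["beta"] / stats["se"]).to_numpy(dtype=float)
    if not np.all(np.isfinite(z)):
        raise ConsistencyError("non-finite z-scores")

    m = len(z)
    if m > config.max_variants:
        raise ConfigurationError(
            f"{m} variants exceed the exhaustive-enumeration limit "
            f"({config.max_variants}); reduce the locus or set max_causal=1"
        )
    n_configs = sum(math.comb(m, k) for k in range(config.max_causal + 1))
    if n_configs > 2_000_000:
        raise ConfigurationError(
            f"{n_configs} configurations are infeasible to enumerate; try max_causal=1"
        )

    base = (ld.matrix + config.ridge * np.eye(m)) / (1.0 + config.ridge)
    p_prior = config.prior_prob if config.prior_prob is not None else 1.0 / m
    s2 = config.effect_sd ** 2

    configs: list[tuple[int, ...]] = []
    log_weights: list[float] = []
    for k in range(config.max_causal + 1):
        log_prior_k = k * math.log(p_prior) + (m - k) * math.log1p(-p_prior)
        for c in itertools.combinations(range(m), k):
            cov = base
            if c:
                rc = base[:, list(c)]
                cov = base + s2 * (rc @ rc.T)
            configs.append(c)
            log_weights.append(_mvn_logpdf(z, cov) + log_prior_k)

    lw = np.array(log_weights)
    lw -= lw.max()
    post = np.exp(lw)
    post /= post.sum()

    pip = np.zeros(m)
    for c, w in zip(configs, post):
        for i in c:
            pip[i] += w
    null_mass = float(post[configs.index(())])
    return PosteriorSet(variant_ids=list(ld.variant_ids), pip=pip,
                        configurations=configs, config_posterior=post,
                        null_mass=null_mass)


def clpp(post_a: PosteriorSet, post_b: PosteriorSet) -> float:
    """Colocalization posterior probability: sum_i PIP_a(i) * PIP_b(i).

    Capped at 1: with multiple causal variants per signal the raw sum can
    marginally exceed 1 while remaining interpretable as "at least one
    shared causal variant".
    """
    if post_a.variant_ids != post_b.variant_ids:
        raise ConsistencyError("posterior sets cover different variant lists")
    return float(min(1.0, np.dot(post_a.pip, post_b.pip)))


def clpp_max(post_a: PosteriorSet, post_b: PosteriorSet) -> float:
    """Per-variant maximum variant of the locus score (optional convention)."""
    if post_a.variant_ids != post_b.variant_ids:
        raise ConsistencyError("posterior sets cover different variant lists")
    return float(np.max(post_a.pip * post_b.pip))


def classify_colocalization(
    clpp_by_condition: dict[str, float], threshold: float = 0.01, fold: float = 10.0
) -> str:
    """Label a two-condition CLPP pair.

    ``shared`` when both exceed the threshold; ``<condition>_specific`` when
    one exceeds it while the other is below the threshold and at least
    ``fold`` times smaller (inclusive); ``none`` otherwise.
    """
    if len(clpp_by_condition) != 2:
        raise ConfigurationError("classification requires exactly two conditions")
    (cond_a, a), (cond_b, b) = clpp_by_condition.items()
    if a < 0 or b < 0:
        raise ValueError("CLPP values must be nonnegative")
    if a > threshold and b > threshold:
        return "shared"
    hi_cond, hi, lo = (cond_a, a, b) if a >= b else (cond_b, b, a)
    if hi > threshold and lo < threshold and lo <= hi / fold:
        return f"{hi_cond}_specific"
    return "none"


def select_loci(
    gwas: pd.DataFrame,
    qtl: pd.DataFrame,
    gwas_p_max: float = 1e-4,
    qtl_p_max: float = 1e-5,
    window_bp: int = 500_000,
) -> list[Locus]:
    """Emit one candidate locus per QTL signal passing ``qtl_p_max`` that has
    a GWAS variant passing ``gwas_p_max`` within ``window_bp`` of the lead
    QTL variant.  The locus variant set is the GWAS/QTL intersection inside
    the window."""
    loci: list[Locus] = []
    for gene, grp in qtl.groupby("gene", sort=True):
        grp = grp.dropna(subset=["p_combined"])
        if grp.empty:
            continue
        lead = grp.loc[grp["p_combined"].idxmin()]
        if lead["p_combined"] > qtl_p_max:
            continue
        chrom, pos = lead["chrom"], lead["pos"]
        gw = gwas[(gwas["chrom"] == chrom) & (np.abs(gwas["pos"] - pos) <= window_bp)]
        if gw.empty or gw["p"].min() > gwas_p_max:
            continue
        qw = grp[np.abs(grp["pos"] - pos) <= window_bp]
        shared = sorted(set(gw["variant_id"]) & set(qw["variant_id"]),
                        key=list(qw["variant_id"]).index)
        if not shared:
            log.warning("locus %s skipped: no shared variants with GWAS", gene)
            continue
        loci.append(Locus(
            locus_id=str(gene),
            lead_variant=str(lead["variant_id"]),
            variant_ids=shared,
            gwas=gw[gw["variant_id"].isin(shared)].set_index("variant_id").loc[shared].reset_index(),
            qtl=qw[qw["variant_id"].isin(shared)].set_index("variant_id").loc[shared].reset_index(),
        ))
    return loci
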