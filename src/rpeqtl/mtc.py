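"""Multiple-testing primitives: Simes combination and Benjamini-Hochberg."""

from __future__ import annotations

import numpy as np


def simes(pvalues) -> float:
    """Simes combined p-value: min over k of m * p_(k) / k."""
    p = np.sort(np.asarray(pvalues, dtype=float))
    p = p[~np.isnan(p)]
    if p.size == 0:
        return np.nan
    m = p.size
    return float(min(1.0, np.min(m * p / np.arange(1, m + 1))))


def bh_adjust(pvalues) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1); NaNs propagate."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


def bh_reject(pvalues, q: float) -> np.ndarray:
    """Boolean rejection mask of the BH procedure at level ``q``."""
    adj = bh_adjust(pvalues)
    with np.errstate(invalid="ignore"):
        return np.asarray(adj <= q) & ~np.isnan(adj)
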