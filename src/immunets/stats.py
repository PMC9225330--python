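"""Shared statistical utilities: FDR correction and rank-based transforms.

These primitives are used by every testing stage of the pipeline
(ANOVA screen, correlation edge tests, Mann-Whitney differential
expression, log-rank survival screens), so they live in one module and
are tested once against brute-force definitions.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import special


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Parameters
    ----------
    pvalues : array-like of float
        Raw p-values in (0, 1]. NaNs are not allowed; callers decide how
        degenerate tests enter the family (this pipeline assigns p = 1).

    Returns
    -------
    numpy.ndarray
        q-values in the original order, ``q[i] = min_{j: p_j >= p_i}
        (m * p_j / rank_j)`` capped at 1. Monotone in p by construction.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and within [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    # step-up: running minimum from the largest p downwards
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def blom_transform(values, warn_on_constant: bool = True) -> np.ndarray:
    """Rank-based inverse-normal (Blom) transform.

    Maps values to normal scores ``z_i = Phi^{-1}((r_i - 3/8) / (n + 1/4))``
    where ``r_i`` is the 1-based rank of the i-th value (mean ranks for
    ties). Used to put FPKM/TPM-scale expression on a common Gaussian
    scale before Euclidean-distance clustering.

    An all-equal input collapses to mid-rank for every element, which the
    Blom offsets map exactly to zero; a warning is emitted because the
    transform then carries no information.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be one-dimensional")
    n = x.size
    if n < 2:
        raise ValueError("Blom transform needs at least 2 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    from scipy.stats import rankdata

    ranks = rankdata(x, method="average")
    if warn_on_constant and np.all(x == x[0]):
        warnings.warn("all-equal input: Blom transform is identically zero")
    return special.ndtri((ranks - 0.375) / (n + 0.25))
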