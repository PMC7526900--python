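"""Small shared statistical utilities."""

from __future__ import annotations

import numpy as np

__all__ = ["bh_adjust", "jensen_shannon_divergence"]


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Returns monotone adjusted p-values clipped to [0, 1]; input order is
    preserved.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj, 0.0, 1.0)
    return out


def jensen_shannon_divergence(p: np.ndarray, q: np.ndarray, base: float = 2.0) -> float:
    """Jensen-Shannon divergence between two distributions.

    With base-2 logarithms the value is bounded in [0, 1]: 0 for identical
    distributions, 1 for disjoint supports.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions must have the same shape")
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("negative probabilities")
    p = p / p.sum()
    q = q / q.sum()
    m = 0.5 * (p + q)

    def _kl(a, b):
        mask = a > 0
        return float(np.sum(a[mask] * (np.log(a[mask]) - np.log(b[mask]))))

    jsd_nats = 0.5 * _kl(p, m) + 0.5 * _kl(q, m)
    return jsd_nats / np.log(base)
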