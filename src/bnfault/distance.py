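"""KL-divergence-based distance between networks and the residual value.

Two BNps are compared through their steady-state distributions: the distance
is a symmetrized Kullback-Leibler divergence (natural log, nats).  The
residual of a candidate network against an observed cancerous SSD is the
distance between the candidate's own SSD and that vector; the true cancerous
chain has residual zero.
"""

from __future__ import annotations

import numpy as np

from .markov import network_ssd
from .networks import BooleanNetwork

__all__ = ["kl_divergence", "network_distance", "residual"]

# floor applied before taking logs; BNp SSDs are strictly positive for p > 0,
# this only guards hand-built fixtures with exact zeros
PROB_FLOOR = 1e-300


def kl_divergence(p1: np.ndarray, p2: np.ndarray) -> float:
    """Kullback-Leibler divergence ``sum p1 ln(p1/p2)`` in nats (>= 0)."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError("distributions must have the same length")
    a = np.maximum(p1, PROB_FLOOR)
    b = np.maximum(p2, PROB_FLOOR)
    return float(np.sum(np.where(p1 > 0.0, p1 * np.log(a / b), 0.0)))


def network_distance(p1: np.ndarray, p2: np.ndarray, method: str = "average") -> float:
    """Symmetric distance between two SSDs built from the two KL directions.

    ``method='average'`` (default) gives the Jeffreys-type mean
    ``(KL(p1, p2) + KL(p2, p1)) / 2``; ``'sum'`` and ``'max'`` are offered
    for sensitivity checks and differ only by a global scale/ordering.
    """
    f = kl_divergence(p1, p2)
    r = kl_divergence(p2, p1)
    if method == "average":
        return 0.5 * (f + r)
    if method == "sum":
        return f + r
    if method == "max":
        return max(f, r)
    raise ValueError(f"unknown method {method!r}")


def residual(net: BooleanNetwork, p: float, ssd_cancer: np.ndarray,
             method: str = "average") -> float:
    """Distance between the BNp ``(net, p)``'s SSD and the cancerous SSD."""
    ssd_cancer = np.asarray(ssd_cancer, dtype=float)
    if ssd_cancer.size != 1 << net.n:
        raise ValueError("cancerous SSD length must be 2**n")
    return network_distance(network_ssd(net, p), ssd_cancer, method=method)
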