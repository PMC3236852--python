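"""Markov-chain machinery for Boolean networks with perturbation (BNp).

A BNp augments a Boolean network with an i.i.d. per-gene flip probability
``p``: at each step the network either follows its deterministic rule (with
probability ``(1-p)**n``) or a random subset of genes flips.  The induced
2**n-state Markov chain is irreducible and ergodic for ``p > 0``, so it has
a unique steady-state distribution (SSD).  The transition probability matrix
(TPM) decomposes as

    P = (1-p)**n * Q + H

where ``Q`` is the 0/1 TPM of the deterministic network and ``H`` depends on
``n`` and ``p`` only.

A stuck-at mutation (i, k) acts on ``Q`` as right-multiplication by a
transformation matrix ``T_{i,k}`` that forces bit ``i`` of every destination
state to ``k``.  The TPM change ``(1-p)**n * Q (T - I)`` has rank at most
2**(n-1) and splits into rank-one terms, each of which updates the SSD in
closed form through the fundamental matrix ``Z = inv(I - P + e pi^T)``.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .networks import BooleanNetwork, Mutation, MutationPath

__all__ = [
    "build_H",
    "deterministic_tpm",
    "build_tpm",
    "stationary_distribution",
    "network_ssd",
    "transformation_matrix",
    "mutated_tpm",
    "fundamental_matrix",
    "rank_one_decompose",
    "ssd_rank_one_update",
    "ssd_after_mutation",
    "ssd_after_path",
]

ROW_SUM_TOL = 1e-12


@lru_cache(maxsize=64)
def _cached_H(n: int, p: float) -> np.ndarray:
    idx = np.arange(1 << n)
    h = np.bitwise_count(idx[:, None] ^ idx[None, :]).astype(np.float64)
    H = p ** h * (1.0 - p) ** (n - h)
    np.fill_diagonal(H, 0.0)
    H.setflags(write=False)
    return H

def build_H(n: int, p: float) -> np.ndarray:
    """Perturbation part of the TPM: ``H[x, y] = p**h (1-p)**(n-h)`` for
    ``y != x`` with ``h`` the Hamming distance, zero on the diagonal.

    Each row sums to ``1 - (1-p)**n``, the probability that at least one
    gene flips.  Cached per ``(n, p)``.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("perturbation probability must be in (0, 1)")
    return _cached_H(int(n), float(p))


def deterministic_tpm(net: BooleanNetwork) -> np.ndarray:
    """0/1 matrix ``Q`` with ``Q[x, y] = 1`` iff ``f(x) = y``."""
    nxt = net.transition_table()
    Q = np.zeros((nxt.size, nxt.size))
    Q[np.arange(nxt.size), nxt] = 1.0
    return Q


def build_tpm(net: BooleanNetwork, p: float) -> np.ndarray:
    """Full BNp transition matrix ``P = (1-p)**n Q + H`` (row-stochastic)."""
    n = net.n
    P = build_H(n, p).copy()
    nxt = net.transition_table()
    P[np.arange(nxt.size), nxt] += (1.0 - p) ** n
    return P


def _tpm_from_transitions(nxt: np.ndarray, H: np.ndarray, det_weight: float) -> np.ndarray:
    P = H.copy()
    P[np.arange(nxt.size), nxt] += det_weight
    return P


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary vector of an irreducible row-stochastic matrix.

    Solves ``pi (P - I) = 0`` with the normalisation ``sum(pi) = 1`` by a
    direct linear solve; falls back to the leading left eigenvector if the
    bordered system is numerically singular.
    """
    m = P.shape[0]
    A = P.T - np.eye(m)
    A[-1, :] = 1.0
    b = np.zeros(m)
    b[-1] = 1.0
    try:
        pi = np.linalg.solve(A, b)
        if np.all(np.isfinite(pi)) and abs(pi.sum() - 1.0) < 1e-8 \
                and np.linalg.norm(pi @ P - pi, np.inf) < 1e-8:
            return pi
    except np.linalg.LinAlgError:
        pass
    # eigen fallback
    w, v = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi = pi / pi.sum()
    if not np.all(np.isfinite(pi)) or np.linalg.norm(pi @ P - pi, np.inf) > 1e-6:
        raise np.linalg.LinAlgError("could not compute a stationary distribution")
    return pi


def network_ssd(net: BooleanNetwork, p: float) -> np.ndarray:
    """Steady-state distribution of the BNp ``(net, p)`` by direct solve."""
    return stationary_distribution(build_tpm(net, p))


def force_state(index: int | np.ndarray, n: int, gene: int, value: int):
    """Set bit ``gene`` (0-based, x_1 most significant) of state index to ``value``."""
    bit = 1 << (n - 1 - gene)
    return (index | bit) if value else (index & ~bit)


def transformation_matrix(n: int, m: Mutation | tuple[int, int]) -> np.ndarray:
    """Column-remapping matrix ``T_{i,k}``: ``T[s, force(s, i, k)] = 1``.

    Right-multiplying ``Q`` by ``T`` redirects every deterministic transition
    into the half-space ``x_i = k``; ``T`` is idempotent and moves exactly
    ``2**(n-1)`` columns.
    """
    gene, value = m
    if not 0 <= gene < n:
        raise ValueError("gene index out of range")
    if value not in (0, 1):
        raise ValueError("mutation value must be 0/1")
    idx = np.arange(1 << n)
    dest = force_state(idx, n, gene, value)
    T = np.zeros((idx.size, idx.size))
    T[idx, dest] = 1.0
    return T


def mutated_tpm(Q: np.ndarray, T: np.ndarray, n: int, p: float) -> np.ndarray:
    """TPM of the altered BNp: ``(1-p)**n Q T + H``.

    Identical to rebuilding the TPM from the truth-table-mutated network;
    mutations touch only the regulatory part ``Q``.
    """
    return (1.0 - p) ** n * (Q @ T) + build_H(n, p)


def fundamental_matrix(P: np.ndarray, pi: np.ndarray | None = None) -> np.ndarray:
    """Fundamental matrix ``Z = inv(I - P + e pi^T)`` of an ergodic chain."""
    if pi is None:
        pi = stationary_distribution(P)
    m = P.shape[0]
    return np.linalg.inv(np.eye(m) - P + np.outer(np.ones(m), pi))


def rank_one_decompose(Q: np.ndarray, T: np.ndarray, n: int, p: float
                       ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Split the TPM change of a single mutation into rank-one terms.

    Returns ``[(a_1, b_1), ...]`` with ``P_mut - P = sum_j outer(a_j, b_j)``,
    every ``b_j`` orthogonal to the all-one vector, and at most ``2**(n-1)``
    terms: one per moved column ``s -> s'`` of ``Q T``, namely
    ``a = (1-p)**n * Q[:, s]`` and ``b = e_{s'} - e_s``.  Columns carrying no
    probability mass are omitted.
    """
    m = Q.shape[0]
    dest = np.argmax(T, axis=1)
    terms = []
    w = (1.0 - p) ** n
    for s in range(m):
        d = int(dest[s])
        if d == s:
            continue
        col = Q[:, s]
        if not col.any():
            continue
        b = np.zeros(m)
        b[d] = 1.0
        b[s] = -1.0
        terms.append((w * col.copy(), b))
    return terms


def ssd_rank_one_update(pi: np.ndarray, P: np.ndarray, a: np.ndarray, b: np.ndarray,
                        denom_tol: float = 1e-12) -> np.ndarray:
    """Stationary distribution of ``P + outer(a, b)`` in closed form.

    Uses the fundamental matrix of the *current* chain:

        pi_new = pi + (pi . a) / (1 - b Z a) * (b Z)

    requiring ``b . e = 0`` so the perturbed matrix keeps unit row sums.
    Falls back to a direct solve when the denominator is numerically zero.
    """
    if abs(b.sum()) > 1e-9:
        raise ValueError("b must be orthogonal to the all-one vector")
    if not np.any(a):
        return pi.copy()
    Z = fundamental_matrix(P, pi)
    bZ = b @ Z
    denom = 1.0 - bZ @ a
    if abs(denom) < denom_tol:
        return stationary_distribution(P + np.outer(a, b))
    pi_new = pi + (pi @ a) / denom * bZ
    return pi_new / pi_new.sum()


def ssd_after_mutation(net: BooleanNetwork, p: float, pi: np.ndarray,
                       m: Mutation | tuple[int, int]) -> np.ndarray:
    """SSD of ``[net; {(i,k)}]`` via sequential rank-one updates.

    Applies the rank-one terms of the mutation one at a time, recomputing the
    fundamental matrix of the running chain after each term — at most
    ``2**(n-1)`` iterations.  Agrees with the direct stationary solve of the
    mutated TPM to ~1e-10; the direct solve remains the reference path.
    """
    Q = deterministic_tpm(net)
    T = transformation_matrix(net.n, m)
    P = build_tpm(net, p)
    cur = np.asarray(pi, dtype=float)
    for a, b in rank_one_decompose(Q, T, net.n, p):
        cur = ssd_rank_one_update(cur, P, a, b)
        P = P + np.outer(a, b)
    return cur


def ssd_after_path(net: BooleanNetwork, p: float, pi: np.ndarray,
                   path: MutationPath | list[tuple[int, int]]) -> np.ndarray:
    """SSD after a whole mutation path, one gene at a time (order-free)."""
    if not isinstance(path, MutationPath):
        path = MutationPath(path)
    cur_net, cur_pi = net, np.asarray(pi, dtype=float)
    for m in path:
        cur_pi = ssd_after_mutation(cur_net, p, cur_pi, m)
        cur_net = cur_net.apply_mutation(m)
    return cur_pi
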