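"""Sequential fault detection over an uncertainty class of Boolean networks.

Given a family of candidate healthy networks, the observed cancerous SSD and
the number of mutations ``M``, the algorithm runs ``M`` pruning steps.  At
step ``j`` every surviving (network, partial-path) pair is extended by each
admissible single stuck-at mutation, the residual of the altered BNp against
the cancerous SSD is computed, and only extensions with residual at or below
the step threshold ``beta_j`` are kept.  Thresholds for the early steps come
from quantiles of the mutation-distance CDF (the candidate still has
``M - j`` mutations to go, so it is compared against the distance a
``(M-j)``-mutation gap typically produces); the final threshold defaults to
0.1, generous enough that the true pair — whose residual is zero at step
``M`` — is never cut there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distance import network_distance
from .distance_cdf import DistanceCDF, quantile
from .markov import build_H, stationary_distribution, _tpm_from_transitions
from .networks import FamilySpec, Mutation, MutationPath

__all__ = [
    "CandidatePair",
    "DetectionConfig",
    "DetectionResult",
    "thresholds_from_probs",
    "expand_candidates",
    "detect",
    "count_residual_computations",
]

DEFAULT_FINAL_BETA = 0.1


@dataclass(frozen=True)
class CandidatePair:
    """A surviving (origin network, accumulated path) pair."""

    origin: int
    path: MutationPath
    residual: float


@dataclass
class DetectionConfig:
    """Parameters of one detection run.

    ``betas`` holds the per-step thresholds ``beta_1 >= ... >= beta_M`` (use
    :func:`thresholds_from_probs` to derive the early ones from selection
    probabilities and distance CDFs).  ``p`` is the perturbation probability
    the algorithm assumes, which may differ from the one that generated the
    cancerous SSD (model mismatch).
    """

    M: int
    p: float
    betas: list[float]
    distance_method: str = "average"

    def __post_init__(self):
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if len(self.betas) != self.M:
            raise ValueError("need one threshold per step")
        if not 0.0 < self.p < 1.0:
            raise ValueError("p must be in (0, 1)")


@dataclass
class DetectionResult:
    """Survivors and bookkeeping of a detection run.

    ``pairs`` are deduplicated (origin, unordered-path) survivors after the
    final step.  ``family_sizes[j]`` is the pair count entering step ``j+1``
    (``family_sizes[0]`` = initial family size); ``alphas[j]`` the surviving
    fraction at step ``j+1``; ``residual_computations`` counts every
    (pair, mutation) proposal evaluated, matching
    ``sum_j |F_{j-1}| * 2 * (n - j + 1)``.
    """

    pairs: list[CandidatePair]
    n: int
    M: int
    family_sizes: list[int]
    evaluated: list[int]
    survivors: list[int]
    alphas: list[float]
    residual_computations: int
    failed_step: int | None = None
    extras: dict = field(default_factory=dict)

    @property
    def origins(self) -> set[int]:
        """Distinct origin networks among the survivors (paper's '# networks')."""
        return {c.origin for c in self.pairs}

    @property
    def paths(self) -> set[MutationPath]:
        """Distinct mutation paths among the survivors (paper's '# paths')."""
        return {c.path for c in self.pairs}

    def contains(self, origin: int, path) -> bool:
        if not isinstance(path, MutationPath):
            path = MutationPath(path)
        return any(c.origin == origin and c.path == path for c in self.pairs)


def thresholds_from_probs(cdfs: dict[int, DistanceCDF], probs, M: int,
                          beta_final: float = DEFAULT_FINAL_BETA) -> list[float]:
    """Per-step thresholds from selection probabilities.

    At step ``j < M`` the surviving candidate still differs from the cancer
    chain by ``M - j`` mutations, so ``beta_j`` is the ``p_j``-quantile of
    the CDF of the ``(M-j)``-mutation distance: ``cdfs`` maps that remaining
    mutation count to its fitted CDF.  ``beta_M`` is set directly
    (default 0.1).  Derived thresholds are normally nonincreasing.
    """
    probs = list(probs)
    if len(probs) != M - 1:
        raise ValueError("need one selection probability per step before the last")
    betas = []
    for j in range(1, M):
        rem = M - j
        if rem not in cdfs:
            raise ValueError(f"missing distance CDF for remaining mutation count {rem}")
        pj = probs[j - 1]
        if not 0.0 < pj < 1.0:
            raise ValueError("selection probabilities must be in (0, 1)")
        betas.append(quantile(cdfs[rem], pj))
    betas.append(float(beta_final))
    if any(b1 < b2 - 1e-12 for b1, b2 in zip(betas, betas[1:])):
        import warnings
        warnings.warn("derived thresholds are not nonincreasing", stacklevel=2)
    return betas


def expand_candidates(pairs, n: int):
    """All single-mutation extensions of each pair: ``2 * (n - |path|)``
    proposals per pair — both stuck-at values for every not-yet-mutated gene,
    in deterministic (origin, gene, value) order."""
    out = []
    for pair in pairs:
        used = pair.path.genes
        for gene in range(n):
            if gene in used:
                continue
            for value in (0, 1):
                out.append((pair, Mutation(gene, value)))
    return out


def detect(family: FamilySpec, ssd_cancer: np.ndarray, config: DetectionConfig
           ) -> DetectionResult:
    """Run the M-step sequential fault-detection algorithm.

    Residuals are computed by a direct stationary solve of each altered BNp
    (the reference path; at n <= 8 each solve is sub-millisecond).  Pairs
    reaching the same (origin, unordered path) are merged at the end of each
    step; every proposal still counts one residual computation, and the
    residual of a duplicate altered chain is reused rather than re-solved.
    """
    n = family.n
    ssd_cancer = np.asarray(ssd_cancer, dtype=float)
    if ssd_cancer.size != 1 << n:
        raise ValueError("cancerous SSD length must be 2**n")
    p = config.p
    H = build_H(n, p)
    det_w = (1.0 - p) ** n
    base_tt = {i: net.transition_table() for i, net in enumerate(family.networks())}

    bits = [1 << (n - 1 - g) for g in range(n)]

    def forced_tt(origin: int, path: MutationPath) -> np.ndarray:
        tt = base_tt[origin]
        for gene, value in path:
            b = bits[gene]
            tt = (tt | b) if value else (tt & ~b)
        return tt

    current: list[CandidatePair] = [
        CandidatePair(i, MutationPath([]), float("nan")) for i in range(len(family))
    ]
    family_sizes = [len(current)]
    evaluated_counts, survivor_counts, alphas = [], [], []
    total_evals = 0
    failed_step = None
    residual_cache: dict[tuple[int, frozenset], float] = {}

    for j, beta in enumerate(config.betas, start=1):
        proposals = expand_candidates(current, n)
        kept: dict[tuple[int, frozenset], CandidatePair] = {}
        for pair, mut in proposals:
            total_evals += 1
            new_path = MutationPath(set(pair.path.mutations) | {mut})
            key = (pair.origin, new_path.mutations)
            r = residual_cache.get(key)
            if r is None:
                tt = forced_tt(pair.origin, new_path)
                P = _tpm_from_transitions(tt, H, det_w)
                pi = stationary_distribution(P)
                r = network_distance(pi, ssd_cancer, method=config.distance_method)
                residual_cache[key] = r
            if r <= beta and key not in kept:
                kept[key] = CandidatePair(pair.origin, new_path, r)
        evaluated_counts.append(len(proposals))
        survivor_counts.append(len(kept))
        alphas.append(len(kept) / len(proposals) if proposals else 0.0)
        current = list(kept.values())
        if not current:
            failed_step = j
            family_sizes.append(0)
            break
        family_sizes.append(len(current))

    return DetectionResult(
        pairs=current, n=n, M=config.M,
        family_sizes=family_sizes, evaluated=evaluated_counts,
        survivors=survivor_counts, alphas=alphas,
        residual_computations=total_evals, failed_step=failed_step,
    )


def count_residual_computations(result: DetectionResult) -> int:
    """Closed-form residual count ``sum_j |F_{j-1}| * 2 * (n - j + 1)``.

    ``|F_0|`` is the initial family size; identical to the instrumented
    counter because every pair at step ``j`` proposes exactly
    ``2 * (n - j + 1)`` extensions.
    """
    total = 0
    for j in range(1, len(result.evaluated) + 1):
        total += result.family_sizes[j - 1] * 2 * (result.n - j + 1)
    return total
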