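"""Performance metrics and Monte Carlo experiment drivers.

Two accuracy metrics are used.  ``P_miss`` is the probability that the
sequential algorithm eliminates the true (normal network, path) pair before
the final step; its closed form assumes that at step ``j`` each of the
``M - j + 1`` single-mutation extensions of the true path survives
independently with probability ``p_j`` (the selection probability behind the
threshold ``beta_j``), while the final step retains the zero-residual true
pair with certainty:

    P_miss = 1 - prod_{j=1}^{M-1} [1 - (1 - p_j)^(M-j+1)]

The second metric, ``P_c(eps)``, is the probability that no surviving origin
network lies within ``eps`` SSD-distance of the true normal network.

The experiment driver plants a canalizing normal network inside a random
family, mutates it along a random path, hands the resulting cancerous SSD to
the detection algorithm, and aggregates both metrics over replicate
families.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detection import DetectionConfig, detect, thresholds_from_probs
from .distance import network_distance
from .distance_cdf import cached_cdf, sample_mutation_path
from .markov import network_ssd
from .networks import (BooleanNetwork, DontCareMap, MutationPath,
                       enumerate_family_from_map, generate_family,
                       index_to_state, random_canalizing_network)

__all__ = [
    "theoretical_p_miss",
    "ExperimentConfig",
    "ExperimentReport",
    "empirical_metrics",
    "run_table_experiment",
    "run_case_study",
]


def theoretical_p_miss(M: int, probs) -> float:
    """Closed-form probability of missing the true network-path pair.

    ``probs`` are the selection probabilities ``p_1 .. p_{M-1}`` used to
    derive the step thresholds; for ``M = 2`` this reduces to
    ``(1 - p_1)**2``.
    """
    probs = list(probs)
    if M < 1:
        raise ValueError("M must be >= 1")
    if len(probs) != M - 1:
        raise ValueError("need M - 1 selection probabilities")
    keep = 1.0
    for j, pj in enumerate(probs, start=1):
        if not 0.0 < pj <= 1.0:
            raise ValueError("selection probabilities must be in (0, 1]")
        keep *= 1.0 - (1.0 - pj) ** (M - j + 1)
    return 1.0 - keep


@dataclass
class ExperimentConfig:
    """Settings for one synthetic-family Monte Carlo experiment.

    ``p_cancer`` generates the cancerous SSD; ``p`` is what the algorithm
    assumes (set them apart for model-mismatch studies).  ``probs`` are the
    step selection probabilities ``p_1 .. p_{M-1}``.  Replicate counts and
    family sizes default to a scaled-down study that preserves the design
    of the full experiment.
    """

    n: int = 6
    k: int = 2
    p_b: float = 0.3
    family_size: int = 20
    n_families: int = 100
    M: int = 2
    p_cancer: float = 0.001
    p: float = 0.001
    probs: tuple[float, ...] = (0.5,)
    beta_final: float = 0.1
    eps: tuple[float, ...] = (0.05, 0.1)
    cdf_networks: int = 4000
    seed: int = 0
    cache_dir: str | None = None


@dataclass
class ExperimentReport:
    """Aggregate of a Monte Carlo experiment over replicate families."""

    config: ExperimentConfig
    theoretical_p_miss: float
    empirical_p_miss: float
    p_miss_se: float
    empirical_p_c: dict[float, float]
    p_c_se: dict[float, float]
    mean_survivor_pairs: float
    mean_networks: float
    mean_paths: float
    mean_residual_computations: float
    n_replicates: int
    betas: list[float] = field(default_factory=list)


def _binom_se(p_hat: float, n: int) -> float:
    return float(np.sqrt(max(p_hat * (1.0 - p_hat), 0.0) / n))


def empirical_metrics(results, truths, eps, normal_ssds, survivor_origin_ssds) -> dict:
    """Empirical P_miss and P_c(eps) over replicates.

    ``results`` are DetectionResults; ``truths`` the planted
    ``(origin_index, MutationPath)`` per replicate; ``normal_ssds`` the SSD
    of each replicate's true normal BNp and ``survivor_origin_ssds`` a list
    (per replicate) of SSDs of the distinct surviving origin networks.
    """
    if not results:
        raise ValueError("need at least one replicate")
    n_rep = len(results)
    miss = 0
    miss_eps = {e: 0 for e in eps}
    for res, (origin, path), pi_true, origin_ssds in zip(
            results, truths, normal_ssds, survivor_origin_ssds):
        if not res.contains(origin, path):
            miss += 1
        for e in eps:
            if not any(network_distance(pi_true, pi_o) <= e for pi_o in origin_ssds):
                miss_eps[e] += 1
    p_miss = miss / n_rep
    out = {
        "p_miss": p_miss,
        "p_miss_se": _binom_se(p_miss, n_rep),
        "p_c": {e: miss_eps[e] / n_rep for e in eps},
        "p_c_se": {e: _binom_se(miss_eps[e] / n_rep, n_rep) for e in eps},
        "n_replicates": n_rep,
    }
    return out


def run_table_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Monte Carlo study of detection accuracy on random network families.

    Per replicate: draw a canalizing normal network and a family sharing its
    wiring, plant a random M-mutation path, compute the cancerous SSD at
    ``p_cancer``, derive thresholds from distance CDFs built at the
    algorithm's ``p``, run detection, and record whether the exact planted
    pair survived.
    """
    cfg = config
    root = np.random.SeedSequence(cfg.seed)
    cdf_seed, rep_seed = root.spawn(2)

    cdfs = {}
    for rem in range(1, cfg.M):
        s = int(cdf_seed.spawn(1)[0].generate_state(1)[0] % (2**31))
        cdfs[rem] = cached_cdf(cfg.n, cfg.k, cfg.p_b, cfg.p, rem,
                               cfg.cdf_networks, seed=s + rem,
                               cache_dir=cfg.cache_dir)
    betas = thresholds_from_probs(cdfs, cfg.probs, cfg.M, cfg.beta_final)
    det_cfg = DetectionConfig(M=cfg.M, p=cfg.p, betas=betas)

    rng = np.random.default_rng(rep_seed)
    results, truths, normal_ssds, survivor_ssds = [], [], [], []
    pair_counts, net_counts, path_counts, comp_counts = [], [], [], []
    for _ in range(cfg.n_families):
        normal = random_canalizing_network(cfg.n, cfg.k, cfg.p_b, rng)
        family = generate_family(normal, cfg.family_size, cfg.p_b, rng)
        path = sample_mutation_path(cfg.n, cfg.M, rng)
        cancer = normal.apply_path(path)
        ssd_cancer = network_ssd(cancer, cfg.p_cancer)
        res = detect(family, ssd_cancer, det_cfg)
        results.append(res)
        truths.append((0, path))
        normal_ssds.append(network_ssd(normal, cfg.p))
        survivor_ssds.append([network_ssd(family.network(i), cfg.p)
                              for i in res.origins])
        pair_counts.append(len(res.pairs))
        net_counts.append(len(res.origins))
        path_counts.append(len(res.paths))
        comp_counts.append(res.residual_computations)

    emp = empirical_metrics(results, truths, cfg.eps, normal_ssds, survivor_ssds)
    return ExperimentReport(
        config=cfg,
        theoretical_p_miss=theoretical_p_miss(cfg.M, cfg.probs),
        empirical_p_miss=emp["p_miss"],
        p_miss_se=emp["p_miss_se"],
        empirical_p_c=emp["p_c"],
        p_c_se=emp["p_c_se"],
        mean_survivor_pairs=float(np.mean(pair_counts)),
        mean_networks=float(np.mean(net_counts)),
        mean_paths=float(np.mean(path_counts)),
        mean_residual_computations=float(np.mean(comp_counts)),
        n_replicates=cfg.n_families,
        betas=betas,
    )


def run_case_study(dmap: DontCareMap, normal: BooleanNetwork, path,
                   p_values, betas, p_cancer: float = 0.001) -> list[dict]:
    """Pathway-map case study: detect a planted path inside the full
    uncertainty class enumerated from a don't-care map.

    ``betas`` has one threshold per mutation in ``path``.  Returns one row
    per ``p`` with the final family size (# networks), the number of
    surviving (network, path) pairs, the number of distinct paths, and a
    success flag (exact planted pair among the survivors).
    """
    if not isinstance(path, MutationPath):
        path = MutationPath(path)
    if not dmap.consistent_with(normal):
        raise ValueError("the designated normal network is inconsistent with the map")
    family = enumerate_family_from_map(dmap)
    # the normal network expressed as full-state-space truth columns, to
    # locate it among the map's completions
    normal_tt = tuple(
        tuple(int(normal.evaluate_gene(i, index_to_state(s, dmap.n)))
              for s in range(1 << dmap.n))
        for i in range(dmap.n))
    try:
        normal_idx = family.members.index(normal_tt)
    except ValueError:
        raise ValueError("normal network not found among the map's completions")
    ssd_cancer_net = normal.apply_path(path)
    rows = []
    for p in p_values:
        ssd_cancer = network_ssd(ssd_cancer_net, p_cancer)
        cfg = DetectionConfig(M=len(path), p=float(p), betas=list(betas))
        res = detect(family, ssd_cancer, cfg)
        rows.append({
            "p": float(p),
            "n_networks": len(res.origins),
            "n_pairs": len(res.pairs),
            "n_paths": len(res.paths),
            "success": res.contains(normal_idx, path),
            "residual_computations": res.residual_computations,
        })
    return rows
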