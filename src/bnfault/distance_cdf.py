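"""Ensemble estimation of the mutation-distance CDF.

``F_D^(m,p)`` is the distribution of the distance between a random BNp and a
copy altered by ``m`` stuck-at mutations on distinct genes.  It is estimated
from an ensemble of random networks (bias ``p_b``, in-degree ``k``) and
smoothed with a Gaussian-kernel CDF (Silverman bandwidth, reflected at zero
so no mass leaks to negative distances).  Its quantiles supply the step
thresholds of the detection algorithm.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import ndtr

from .distance import network_distance
from .markov import network_ssd
from .networks import MutationPath, random_network

__all__ = ["DistanceCDF", "sample_distances", "fit_cdf", "quantile",
           "cached_cdf", "sample_mutation_path"]


def sample_mutation_path(n: int, m: int, rng: np.random.Generator) -> MutationPath:
    """Uniform random path: ``m`` distinct genes, stuck-at values uniform."""
    genes = rng.choice(n, size=m, replace=False)
    values = rng.integers(0, 2, size=m)
    return MutationPath([(int(g), int(v)) for g, v in zip(genes, values)])


def sample_distances(n: int, k: int, p_b: float, p: float, m: int,
                     n_networks: int, seed=None, method: str = "average") -> np.ndarray:
    """Distances between ``n_networks`` random BNps and their m-mutation copies.

    Each draw builds a random network, samples a uniform m-mutation path and
    measures the SSD distance between the original and altered BNps.
    """
    if m > n:
        raise ValueError("cannot mutate more genes than the network has")
    if n_networks < 1:
        raise ValueError("need at least one network")
    rng = np.random.default_rng(seed)
    out = np.empty(n_networks)
    for i in range(n_networks):
        net = random_network(n, k, p_b, rng)
        if m == 0:
            out[i] = 0.0
            continue
        path = sample_mutation_path(n, m, rng)
        pi = network_ssd(net, p)
        pi_alt = network_ssd(net.apply_path(path), p)
        out[i] = network_distance(pi, pi_alt, method=method)
    return out


def _silverman_bandwidth(x: np.ndarray) -> float:
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    q75, q25 = np.percentile(x, [75, 25])
    iqr = float(q75 - q25)
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        return 0.0
    return 0.9 * spread * x.size ** (-0.2)


@dataclass
class DistanceCDF:
    """Kernel-smoothed CDF of the mutation-distance distribution.

    Gaussian kernels of common bandwidth ``h`` are placed at each sample and
    reflected at zero: F(d) = mean_i[Phi((d-x_i)/h) + Phi((d+x_i)/h) - 1]
    for d >= 0, which is nondecreasing with limits 0 and 1.  ``h = 0``
    (degenerate sample) falls back to the empirical step CDF.
    """

    samples: np.ndarray
    bandwidth: float
    params: dict = field(default_factory=dict)

    def __call__(self, d) -> np.ndarray | float:
        d = np.asarray(d, dtype=float)
        x = self.samples[None, ...]
        dd = np.atleast_1d(d)[..., None]
        if self.bandwidth > 0:
            vals = ndtr((dd - x) / self.bandwidth) + ndtr((dd + x) / self.bandwidth) - 1.0
            out = np.clip(vals.mean(axis=-1), 0.0, 1.0)
        else:
            out = (x <= dd).mean(axis=-1)
        out = np.where(np.atleast_1d(d) < 0, 0.0, out)
        return float(out[0]) if d.ndim == 0 else out

    @property
    def sample_size(self) -> int:
        return int(self.samples.size)

    def to_dict(self) -> dict:
        return {"params": self.params, "bandwidth": self.bandwidth,
                "samples": np.sort(self.samples).tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "DistanceCDF":
        return cls(np.asarray(d["samples"], dtype=float),
                   float(d["bandwidth"]), dict(d.get("params", {})))


def fit_cdf(samples: np.ndarray, params: dict | None = None,
            min_samples: int = 50) -> DistanceCDF:
    """Fit the smoothed CDF to observed distances.

    Requires at least ``min_samples`` draws for a usable estimate; an
    all-identical sample yields a step CDF.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    if x.size < min_samples:
        raise ValueError(f"need at least {min_samples} samples, got {x.size}")
    if np.any(x < 0):
        raise ValueError("distances must be nonnegative")
    return DistanceCDF(x, _silverman_bandwidth(x), dict(params or {}))


def quantile(cdf: DistanceCDF, prob: float, tol: float = 1e-9) -> float:
    """Smallest distance ``d`` with ``F(d) >= prob``, by bisection."""
    if not 0.0 < prob < 1.0:
        raise ValueError("prob must be in (0, 1)")
    lo = 0.0
    hi = float(cdf.samples.max()) + 6.0 * cdf.bandwidth + 1e-12
    while cdf(hi) < prob:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if cdf(mid) >= prob:
            hi = mid
        else:
            lo = mid
        if hi - lo < tol:
            break
    return hi


def cached_cdf(n: int, k: int, p_b: float, p: float, m: int, n_networks: int,
               seed: int, cache_dir: str | Path | None = None) -> DistanceCDF:
    """Build (or load) the CDF for one parameter combination.

    When ``cache_dir`` is given, the fitted sample is stored as JSON keyed by
    the full parameter tuple so repeated detection runs skip the ensemble.
    """
    params = {"n": n, "k": k, "p_b": p_b, "p": p, "m": m,
              "n_networks": n_networks, "seed": seed}
    path = None
    if cache_dir is not None:
        key = hashlib.sha256(json.dumps(params, sort_keys=True).encode()).hexdigest()[:16]
        path = Path(cache_dir) / f"cdf_{key}.json"
        if path.exists():
            with open(path) as fh:
                d = json.load(fh)
            if d.get("params") == params:
                return DistanceCDF.from_dict(d)
    samples = sample_distances(n, k, p_b, p, m, n_networks, seed=seed)
    cdf = fit_cdf(samples, params=params)
    if path is not None:
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(cdf.to_dict(), fh)
    return cdf
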