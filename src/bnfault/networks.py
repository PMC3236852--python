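"""Boolean network representation, mutations, and network-family generators.

A Boolean network on ``n`` genes assigns each gene ``i`` an ordered predictor
list and a truth table over its predictors; all genes update synchronously.
States are binary vectors ``(x_1, ..., x_n)`` indexed by their decimal value
with ``x_1`` as the most significant bit.  Gene indices are 0-based in memory
and 1-based in the JSON file format.

A gene mutation ``(i, k)`` is a stuck-at fault: gene ``i`` is permanently
forced to value ``k`` (tumour-suppressor deactivation for ``k=0``, oncogene
activation for ``k=1``), i.e. its Boolean function becomes the constant ``k``.
A mutation path is an unordered set of mutations on pairwise-distinct genes.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

__all__ = [
    "BooleanNetwork",
    "Mutation",
    "MutationPath",
    "FamilySpec",
    "DontCareMap",
    "state_to_index",
    "index_to_state",
    "is_canalizing",
    "random_network",
    "random_canalizing_network",
    "generate_family",
    "enumerate_family_from_map",
    "load_network",
    "save_network",
    "load_dontcare_map",
    "save_dontcare_map",
]


def state_to_index(state: Sequence[int]) -> int:
    """Decimal index of a binary state vector, ``x_1`` most significant."""
    idx = 0
    for x in state:
        if x not in (0, 1):
            raise ValueError(f"state entries must be 0/1, got {x!r}")
        idx = (idx << 1) | x
    return idx


def index_to_state(index: int, n: int) -> tuple[int, ...]:
    """Binary state vector of length ``n`` for a decimal state index."""
    if not 0 <= index < (1 << n):
        raise ValueError(f"index {index} out of range for n={n}")
    return tuple((index >> (n - 1 - i)) & 1 for i in range(n))


class Mutation(NamedTuple):
    """Stuck-at fault: ``gene`` (0-based) permanently forced to ``value``."""

    gene: int
    value: int


@dataclass(frozen=True)
class MutationPath:
    """Unordered set of mutations on pairwise-distinct genes.

    Equality and hashing are order-free: ``{(0,0), (1,1)}`` equals
    ``{(1,1), (0,0)}``, reflecting that the altered chain is the same
    regardless of the order in which stuck-at faults are applied.
    """

    mutations: frozenset[Mutation]

    def __init__(self, mutations: Iterable[tuple[int, int]]):
        muts = frozenset(Mutation(int(g), int(v)) for g, v in mutations)
        genes = [m.gene for m in muts]
        if len(set(genes)) != len(genes):
            raise ValueError("no two mutations in a path may affect the same gene")
        for m in muts:
            if m.value not in (0, 1):
                raise ValueError(f"mutation value must be 0/1, got {m.value}")
        object.__setattr__(self, "mutations", muts)

    @property
    def M(self) -> int:
        return len(self.mutations)

    @property
    def genes(self) -> frozenset[int]:
        return frozenset(m.gene for m in self.mutations)

    def __iter__(self):
        return iter(sorted(self.mutations))

    def __len__(self) -> int:
        return len(self.mutations)


@dataclass(frozen=True)
class BooleanNetwork:
    """Synchronous Boolean network: per-gene predictor lists and truth tables.

    Parameters
    ----------
    n
        Number of genes.
    predictors
        Per-gene ordered tuple of 0-based input gene indices (no duplicates).
    tables
        Per-gene output column of length ``2**k_i``; the row index is the
        decimal value of the predictor values in list order (first predictor
        most significant).
    """

    n: int
    predictors: tuple[tuple[int, ...], ...]
    tables: tuple[tuple[int, ...], ...]

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if len(self.predictors) != self.n or len(self.tables) != self.n:
            raise ValueError("predictors and tables must have one entry per gene")
        preds = tuple(tuple(int(g) for g in p) for p in self.predictors)
        tabs = tuple(tuple(int(v) for v in t) for t in self.tables)
        for i, (p, t) in enumerate(zip(preds, tabs)):
            if len(set(p)) != len(p):
                raise ValueError(f"gene {i}: duplicate predictor")
            if any(not 0 <= g < self.n for g in p):
                raise ValueError(f"gene {i}: predictor index out of range")
            if len(t) != 1 << len(p):
                raise ValueError(f"gene {i}: table length {len(t)} != 2**{len(p)}")
            if any(v not in (0, 1) for v in t):
                raise ValueError(f"gene {i}: non-binary table entry")
        object.__setattr__(self, "predictors", preds)
        object.__setattr__(self, "tables", tabs)

    def evaluate_gene(self, i: int, state: Sequence[int]) -> int:
        """Value of gene ``i`` at the next time step, given the current state."""
        row = 0
        for g in self.predictors[i]:
            row = (row << 1) | state[g]
        return self.tables[i][row]

    def next_state(self, state: Sequence[int]) -> tuple[int, ...]:
        """Synchronous update of all genes."""
        if len(state) != self.n or any(x not in (0, 1) for x in state):
            raise ValueError("state must be a binary vector of length n")
        return tuple(self.evaluate_gene(i, state) for i in range(self.n))

    def transition_table(self) -> np.ndarray:
        """Next-state index for every state index, shape ``(2**n,)``.

        This is the deterministic map f as an integer array; it is the
        workhorse behind TPM assembly and fast mutation application.
        """
        n = self.n
        idx = np.arange(1 << n)
        bits = (idx[:, None] >> (n - 1 - np.arange(n))[None, :]) & 1
        nxt = np.zeros(1 << n, dtype=np.int64)
        for i in range(n):
            p = self.predictors[i]
            k = len(p)
            if k:
                weights = 1 << (k - 1 - np.arange(k))
                rows = bits[:, list(p)] @ weights
            else:
                rows = np.zeros(1 << n, dtype=np.int64)
            out = np.asarray(self.tables[i], dtype=np.int64)[rows]
            nxt |= out << (n - 1 - i)
        return nxt

    def apply_mutation(self, m: Mutation | tuple[int, int]) -> "BooleanNetwork":
        """Network with gene ``m.gene``'s function replaced by the constant ``m.value``.

        Idempotent; predictor lists are left untouched so family wiring is
        preserved.
        """
        gene, value = m
        if not 0 <= gene < self.n:
            raise ValueError(f"gene index {gene} out of range")
        if value not in (0, 1):
            raise ValueError("mutation value must be 0/1")
        tables = list(self.tables)
        tables[gene] = (value,) * len(tables[gene])
        return BooleanNetwork(self.n, self.predictors, tuple(tables))

    def apply_path(self, path: MutationPath | Iterable[tuple[int, int]]) -> "BooleanNetwork":
        """Apply every mutation in an (unordered) path."""
        if not isinstance(path, MutationPath):
            path = MutationPath(path)
        net = self
        for m in path:
            net = net.apply_mutation(m)
        return net


def is_canalizing(table: Sequence[int], k: int) -> bool:
    """Exhaustive test: does some input with some value force the output?"""
    tab = np.asarray(table)
    if k == 0:
        return True  # constant function, trivially forced
    rows = np.arange(1 << k)
    for j in range(k):
        bit = (rows >> (k - 1 - j)) & 1
        for v in (0, 1):
            outs = tab[bit == v]
            if outs.min() == outs.max():
                return True
    return False


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def random_network(n: int, k: int, p_b: float, seed=None) -> BooleanNetwork:
    """Random Boolean network: each gene has exactly ``k`` distinct predictors
    chosen uniformly, and i.i.d. Bernoulli(``p_b``) truth-table entries.

    ``p_b`` is the bias of the Boolean functions; self-inputs are allowed.
    """
    if not 1 <= k <= n:
        raise ValueError("need 1 <= k <= n")
    if not 0 < p_b < 1:
        raise ValueError("need 0 < p_b < 1")
    rng = _rng(seed)
    predictors = tuple(tuple(int(g) for g in rng.choice(n, size=k, replace=False))
                       for _ in range(n))
    tables = tuple(tuple(int(v) for v in (rng.random(1 << k) < p_b).astype(int))
                   for _ in range(n))
    return BooleanNetwork(n, predictors, tables)


def random_canalizing_network(n: int, k: int, p_b: float, seed=None) -> BooleanNetwork:
    """Random network whose every function is canalizing.

    For each gene a canalizing input position, value and forced output are
    drawn uniformly; table rows where that input takes the canalizing value
    get the forced output, the remaining rows are i.i.d. Bernoulli(``p_b``).
    """
    if not 1 <= k <= n:
        raise ValueError("need 1 <= k <= n")
    if not 0 < p_b < 1:
        raise ValueError("need 0 < p_b < 1")
    rng = _rng(seed)
    predictors = []
    tables = []
    rows = np.arange(1 << k)
    for _ in range(n):
        predictors.append(tuple(int(g) for g in rng.choice(n, size=k, replace=False)))
        tab = (rng.random(1 << k) < p_b).astype(int)
        j = int(rng.integers(k))
        v = int(rng.integers(2))
        w = int(rng.integers(2))
        tab[((rows >> (k - 1 - j)) & 1) == v] = w
        tables.append(tuple(int(x) for x in tab))
    return BooleanNetwork(n, tuple(predictors), tuple(tables))


@dataclass
class FamilySpec:
    """Uncertainty class: networks sharing one predictor wiring.

    ``members`` hold the per-gene truth tables of each network; the shared
    ``predictors`` come from the designated base wiring.  ``normal_index``
    marks the true healthy network when known (synthetic experiments).
    """

    n: int
    predictors: tuple[tuple[int, ...], ...]
    members: list[tuple[tuple[int, ...], ...]]
    normal_index: int | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        seen = set()
        for tabs in self.members:
            if tabs in seen:
                raise ValueError("family members must be pairwise distinct")
            seen.add(tabs)
        if self.normal_index is not None and not 0 <= self.normal_index < len(self.members):
            raise ValueError("normal_index out of range")

    def __len__(self) -> int:
        return len(self.members)

    def network(self, i: int) -> BooleanNetwork:
        return BooleanNetwork(self.n, self.predictors, self.members[i])

    def networks(self) -> list[BooleanNetwork]:
        return [self.network(i) for i in range(len(self.members))]


def generate_family(normal: BooleanNetwork, size: int, p_b: float, seed=None) -> FamilySpec:
    """Family of ``size`` distinct networks sharing ``normal``'s wiring.

    ``normal`` is always a member (index 0); the rest get i.i.d.
    Bernoulli(``p_b``) truth tables on the same predictor sets, resampling
    on collision so members are pairwise distinct.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    total_bits = sum(len(t) for t in normal.tables)
    if total_bits < 63 and size > (1 << total_bits):
        raise ValueError("requested family size exceeds the number of distinct "
                         "truth-table assignments for this wiring")
    rng = _rng(seed)
    members: list[tuple[tuple[int, ...], ...]] = [normal.tables]
    seen = {normal.tables}
    while len(members) < size:
        tabs = tuple(tuple(int(v) for v in (rng.random(len(t)) < p_b).astype(int))
                     for t in normal.tables)
        if tabs not in seen:
            seen.add(tabs)
            members.append(tabs)
    return FamilySpec(normal.n, normal.predictors, members, normal_index=0,
                      params={"p_b": p_b, "size": size})


@dataclass(frozen=True)
class DontCareMap:
    """Partially specified truth tables over the full state space.

    ``columns[i]`` is a string of length ``2**n`` over ``{'0','1','X'}``:
    the next value of gene ``i`` for every current state (state-index order,
    ``x_1`` most significant).  ``X`` marks entries the available pathway
    knowledge does not determine; each completion of the ``X`` entries is one
    member of the induced uncertainty class, of size ``2**u_X``.
    """

    n: int
    columns: tuple[str, ...]

    def __post_init__(self):
        if len(self.columns) != self.n:
            raise ValueError("need one column per gene")
        for i, c in enumerate(self.columns):
            if len(c) != 1 << self.n:
                raise ValueError(f"column {i} must have length 2**n")
            if set(c) - {"0", "1", "X"}:
                raise ValueError(f"column {i} has entries outside 0/1/X")

    @property
    def u_x(self) -> int:
        """Number of undetermined entries across all genes."""
        return sum(c.count("X") for c in self.columns)

    def consistent_with(self, net: BooleanNetwork) -> bool:
        """Does ``net`` agree with every determined (non-X) entry?"""
        if net.n != self.n:
            return False
        nstates = 1 << self.n
        for i in range(self.n):
            for s in range(nstates):
                c = self.columns[i][s]
                if c != "X" and net.evaluate_gene(i, index_to_state(s, self.n)) != int(c):
                    return False
        return True


_ENUM_GUARD = 20


def enumerate_family_from_map(dmap: DontCareMap, max_u_x: int = _ENUM_GUARD) -> FamilySpec:
    """Enumerate all ``2**u_X`` networks consistent with a don't-care map.

    Every member uses the full predictor set ``(0, ..., n-1)`` for each gene,
    since the map specifies outputs over the whole state space.  Raises if
    ``u_X`` exceeds the enumeration guard (sample completions instead).
    """
    if dmap.u_x > max_u_x:
        raise ValueError(
            f"u_X = {dmap.u_x} exceeds the enumeration guard ({max_u_x}); "
            "enumerate is infeasible here - sample completions instead")
    n = dmap.n
    free = [(i, s) for i in range(n) for s, c in enumerate(dmap.columns[i]) if c == "X"]
    base = [[0 if c == "X" else int(c) for c in col] for col in dmap.columns]
    predictors = tuple(tuple(range(n)) for _ in range(n))
    members = []
    for bits in itertools.product((0, 1), repeat=len(free)):
        cols = [list(col) for col in base]
        for (i, s), b in zip(free, bits):
            cols[i][s] = b
        members.append(tuple(tuple(col) for col in cols))
    return FamilySpec(n, predictors, members, params={"u_x": dmap.u_x})


# ---------------------------------------------------------------------------
# JSON I/O (1-based gene indices on disk)

def network_to_dict(net: BooleanNetwork) -> dict:
    return {
        "n": net.n,
        "predictors": [[g + 1 for g in p] for p in net.predictors],
        "tables": [list(t) for t in net.tables],
    }


def network_from_dict(d: dict) -> BooleanNetwork:
    return BooleanNetwork(
        int(d["n"]),
        tuple(tuple(int(g) - 1 for g in p) for p in d["predictors"]),
        tuple(tuple(int(v) for v in t) for t in d["tables"]),
    )


def save_network(net: BooleanNetwork, path) -> None:
    with open(path, "w") as fh:
        json.dump(network_to_dict(net), fh, indent=1)


def load_network(path) -> BooleanNetwork:
    with open(path) as fh:
        return network_from_dict(json.load(fh))


def save_dontcare_map(dmap: DontCareMap, path) -> None:
    with open(path, "w") as fh:
        json.dump({"n": dmap.n, "columns": list(dmap.columns)}, fh, indent=1)


def load_dontcare_map(path) -> DontCareMap:
    with open(path) as fh:
        d = json.load(fh)
    return DontCareMap(int(d["n"]), tuple(str(c) for c in d["columns"]))
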