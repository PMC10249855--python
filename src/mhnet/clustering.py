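"""Community detection on signed networks: Leiden multiplex optimization,
iterated consensus clustering, and cross-indicator allegiance analysis.

The signed network is optimized as a two-layer multiplex — Newman–Girvan
(RB configuration-null) modularity on the positive layer with weight +1
and on the negative layer with weight −1 — so that communities gather
positively correlated states and separate anticorrelated ones.  Because
the optimizer is stochastic, a partition is stabilized by consensus
clustering: many runs, a co-assignment frequency matrix, re-clustering of
that matrix as a new (all-positive) network, iterated until the frequency
matrix is binary.  Consensus partitions from several indicators combine
into an allegiance matrix — the probability that two states share a
community across indicators — which is itself clustered the same way.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg as la
import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .errors import ValidationError
from .network import SignedLayers

__all__ = ["Partition", "ConsensusMatrix", "AllegianceMatrix",
           "ConsensusResult", "partition_signed", "consensus_cluster",
           "allegiance", "cluster_allegiance", "compare_partitions"]

#: Binary-convergence tolerance for consensus frequency matrices.
BINARY_TOL = 1e-12


def _canonical(membership: np.ndarray) -> np.ndarray:
    """Relabel community ids contiguously from 0 in order of first appearance."""
    seen: dict[int, int] = {}
    out = np.empty(len(membership), dtype=int)
    for i, m in enumerate(membership):
        out[i] = seen.setdefault(int(m), len(seen))
    return out


@dataclass
class Partition:
    """Hard assignment of each unit to exactly one community."""

    unit_ids: list[str]
    membership: np.ndarray

    def __post_init__(self) -> None:
        self.membership = _canonical(np.asarray(self.membership, dtype=int))
        if len(self.membership) != len(self.unit_ids):
            raise ValidationError("membership length != number of units")

    @property
    def n_communities(self) -> int:
        return int(self.membership.max()) + 1 if len(self.membership) else 0

    def as_dict(self) -> dict[str, int]:
        return {u: int(m) for u, m in zip(self.unit_ids, self.membership)}

    def community(self, label: int) -> list[str]:
        return [u for u, m in zip(self.unit_ids, self.membership) if m == label]

    def co_membership(self) -> np.ndarray:
        """0/1 indicator matrix: units in the same community (diagonal 1)."""
        m = self.membership
        return (m[:, None] == m[None, :]).astype(float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"state": self.unit_ids,
                             "community": self.membership})


@dataclass
class ConsensusMatrix:
    """Unit × unit co-assignment frequencies over repeated partition runs."""

    unit_ids: list[str]
    F: np.ndarray
    n_runs: int

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        n = len(self.unit_ids)
        if self.F.shape != (n, n):
            raise ValidationError(f"F shape {self.F.shape} != ({n}, {n})")
        if not np.allclose(self.F, self.F.T):
            raise ValidationError("F must be symmetric")
        if (self.F < -BINARY_TOL).any() or (self.F > 1 + BINARY_TOL).any():
            raise ValidationError("F entries must lie in [0, 1]")
        if not np.allclose(np.diag(self.F), 1.0):
            raise ValidationError("F diagonal must be 1")

    def is_binary(self, tol: float = BINARY_TOL) -> bool:
        return bool((np.minimum(np.abs(self.F), np.abs(self.F - 1.0)) <= tol).all())


@dataclass
class AllegianceMatrix:
    """Probability that two units share a community across indicators."""

    unit_ids: list[str]
    A: np.ndarray
    indicators: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        n = len(self.unit_ids)
        if self.A.shape != (n, n):
            raise ValidationError(f"A shape {self.A.shape} != ({n}, {n})")
        if not np.allclose(self.A, self.A.T):
            raise ValidationError("A must be symmetric")
        if not np.allclose(np.diag(self.A), 1.0):
            raise ValidationError("A diagonal must be 1")


@dataclass
class ConsensusResult:
    """Outcome of iterated consensus clustering.

    ``matrix`` is the first-level co-assignment frequency matrix (built
    from runs on the original network); ``converged`` is False when the
    frequency matrix never became binary within ``max_iter`` cycles.
    """

    partition: Partition
    matrix: ConsensusMatrix
    n_iterations: int
    converged: bool


def _layer_graph(W: np.ndarray) -> ig.Graph:
    """Weighted undirected graph from a nonnegative matrix (zero diagonal)."""
    n = W.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    keep = W[iu, ju] != 0
    g = ig.Graph(n=n, edges=list(zip(iu[keep].tolist(), ju[keep].tolist())))
    g.es["weight"] = W[iu, ju][keep].tolist()
    return g


def partition_signed(layers: SignedLayers, seed: int,
                     resolution: float = 1.0) -> Partition:
    """One Leiden-style optimization of the signed two-layer quality.

    Maximizes modularity on the positive layer minus modularity on the
    negative layer (layer weights +1 / −1), via leidenalg's multiplex
    optimizer.  Deterministic given ``seed``.
    """
    if layers.n_units == 0:
        raise ValidationError("empty network")
    g_pos = _layer_graph(layers.positive)
    g_neg = _layer_graph(layers.negative)
    membership, _ = la.find_partition_multiplex(
        [g_pos, g_neg], la.RBConfigurationVertexPartition,
        layer_weights=[1, -1], weights="weight",
        resolution_parameter=resolution, seed=int(seed) % (2**31 - 1),
        n_iterations=-1)
    return Partition(list(layers.unit_ids), np.asarray(membership))


def _run_seeds(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 2**31 - 1, size=n)


def _components_of_binary(F: np.ndarray) -> np.ndarray:
    """Membership from the connected components of a 0/1 co-assignment
    matrix (for a consistent matrix these are its cliques)."""
    n = F.shape[0]
    labels = np.full(n, -1, dtype=int)
    nxt = 0
    for i in range(n):
        if labels[i] < 0:
            stack = [i]
            labels[i] = nxt
            while stack:
                j = stack.pop()
                for k in np.flatnonzero(F[j] > 0.5):
                    if labels[k] < 0:
                        labels[k] = nxt
                        stack.append(int(k))
            nxt += 1
    return labels


def consensus_cluster(layers: SignedLayers, n_runs: int = 300,
                      seed: int = 0, max_iter: int = 10,
                      resolution: float = 1.0,
                      tau: float = 0.0) -> ConsensusResult:
    """Iterated consensus clustering of a signed network.

    Each cycle runs :func:`partition_signed` ``n_runs`` times with seeds
    derived from the master seed, accumulates the co-assignment frequency
    matrix F, and re-clusters F as an all-positive weighted network.
    Cycles repeat until F is binary (every entry within ``1e-12`` of 0 or
    1) or ``max_iter`` is reached; non-convergence returns the best
    partition with ``converged=False`` and a warning.

    ``tau`` optionally zeroes F entries below a threshold before
    re-clustering (Lancichinetti–Fortunato style); the default 0 keeps
    the frequency matrix untouched.
    """
    if n_runs < 1:
        raise ValidationError(f"n_runs must be >= 1, got {n_runs}")
    rng = np.random.default_rng(seed)
    current = layers
    first_F: ConsensusMatrix | None = None
    partition: Partition | None = None
    for iteration in range(1, max_iter + 1):
        seeds = _run_seeds(rng, n_runs)
        F = np.zeros((layers.n_units, layers.n_units))
        for s in seeds:
            part = partition_signed(current, seed=int(s), resolution=resolution)
            F += part.co_membership()
            partition = part
        F /= n_runs
        cons = ConsensusMatrix(list(layers.unit_ids), F, n_runs)
        if first_F is None:
            first_F = cons
        if cons.is_binary():
            membership = _components_of_binary(F)
            return ConsensusResult(
                Partition(list(layers.unit_ids), membership), first_F,
                iteration, True)
        W = F.copy()
        if tau > 0:
            W[W < tau] = 0.0
        current = SignedLayers.from_positive(layers.unit_ids, W)
    warnings.warn(
        f"consensus clustering did not converge in {max_iter} iterations",
        stacklevel=2)
    assert partition is not None and first_F is not None
    return ConsensusResult(partition, first_F, max_iter, False)


def allegiance(partitions: list[Partition],
               indicators: list[str] | None = None) -> AllegianceMatrix:
    """Fraction of partitions in which each pair shares a community."""
    if not partitions:
        raise ValidationError("no partitions supplied")
    ref = partitions[0].unit_ids
    A = np.zeros((len(ref), len(ref)))
    for p in partitions:
        if p.unit_ids != ref:
            if sorted(p.unit_ids) != sorted(ref):
                raise ValidationError("partitions cover different unit sets")
            order = [p.unit_ids.index(u) for u in ref]
            p = Partition(list(ref), p.membership[order])
        A += p.co_membership()
    A /= len(partitions)
    return AllegianceMatrix(list(ref), A,
                            list(indicators or []))


def cluster_allegiance(A: AllegianceMatrix, seed: int = 0,
                       n_runs: int = 300, max_iter: int = 10,
                       resolution: float = 1.0) -> Partition:
    """Consensus-cluster the allegiance matrix as an all-positive network."""
    layers = SignedLayers.from_positive(A.unit_ids, A.A)
    return consensus_cluster(layers, n_runs=n_runs, seed=seed,
                             max_iter=max_iter, resolution=resolution).partition


def compare_partitions(p1: Partition, p2: Partition) -> float:
    """Adjusted Rand index between two partitions of the same unit set;
    1 iff identical up to relabeling."""
    if sorted(p1.unit_ids) != sorted(p2.unit_ids):
        raise ValidationError("partitions cover different unit sets")
    order = [p2.unit_ids.index(u) for u in p1.unit_ids]
    return float(adjusted_rand_score(p1.membership, p2.membership[order]))
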