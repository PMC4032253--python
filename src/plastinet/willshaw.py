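"""Binary Willshaw/Steinbuch associative storage and retrieval.

Hebbian storage clips the superposition of outer products of address and
content patterns to binary weights: a synapse (i, j) that exists anatomically
is potentiated as soon as one stored memory activates both its neurons.
Retrieval propagates a binary query through the weight matrix and thresholds
the dendritic potentials, either by k-winners-take-all, by a per-neuron
threshold equal to the number of connected active inputs, or by a fixed
scalar threshold.  Iterative retrieval refines the one-step output through an
auto-associative network with silenced self-connections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .patterns import MemorySet

__all__ = [
    "WillshawNetwork",
    "store",
    "dendritic_potentials",
    "retrieve_onestep",
    "retrieve_iterative",
    "kwta",
]


@dataclass(frozen=True)
class WillshawNetwork:
    """Binary weight matrix W constrained to an anatomical mask A.

    ``A[i, j] = 1`` means a synapse from address neuron i to content neuron j
    exists; ``W <= A`` elementwise.  ``c_a`` is the density of A (anatomical
    connectivity, the chance that a random neuron pair is connected).
    """

    W: np.ndarray
    A: np.ndarray

    def __post_init__(self) -> None:
        W = np.ascontiguousarray(self.W, dtype=np.uint8)
        A = np.ascontiguousarray(self.A, dtype=np.uint8)
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "A", A)
        if W.shape != A.shape:
            raise ValueError("W and A must have the same shape")
        if np.any(W > A):
            raise ValueError("weights may only exist where synapses exist (W <= A)")

    @property
    def m(self) -> int:
        return self.W.shape[0]

    @property
    def n(self) -> int:
        return self.W.shape[1]

    @property
    def c_a(self) -> float:
        return float(self.A.mean())

    def save_text(self, path) -> None:
        np.savetxt(path, self.W, fmt="%d", delimiter=" ")

    @classmethod
    def from_text(cls, path, mask=None) -> "WillshawNetwork":
        W = np.loadtxt(path, dtype=np.uint8)
        A = np.ones_like(W) if mask is None else np.asarray(mask, dtype=np.uint8)
        return cls(W=W, A=A)


def full_mask(m: int, n: int) -> np.ndarray:
    return np.ones((m, n), dtype=np.uint8)


def random_mask(m: int, n: int, c_a: float, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Bernoulli(c_a) anatomical mask — each pair connected independently."""
    rng = np.random.default_rng(seed)
    return (rng.random((m, n)) < c_a).astype(np.uint8)


def store(memories: MemorySet, A: np.ndarray | None = None) -> WillshawNetwork:
    """Hebbian clipped storage: W[i,j] = A[i,j] AND (some memory has u_i = v_j = 1).

    Storing a memory twice equals storing it once (idempotent clipping), and
    adding memories never clears a weight.
    """
    if A is None:
        A = full_mask(memories.m, memories.n)
    A = np.asarray(A, dtype=np.uint8)
    if A.shape != (memories.m, memories.n):
        raise ValueError(
            f"mask shape {A.shape} does not match patterns ({memories.m}, {memories.n})"
        )
    if memories.M == 0:
        hebb = np.zeros_like(A)
    else:
        # float32 matmul hits BLAS; exact for counts far below 2**24
        hebb = (memories.U.T.astype(np.float32) @ memories.V.astype(np.float32) > 0)
    W = (hebb & (A > 0)).astype(np.uint8)
    return WillshawNetwork(W=W, A=A)


def dendritic_potentials(net: WillshawNetwork, query: np.ndarray) -> np.ndarray:
    """x_j = sum_i query_i * W[i, j] — integer potentials of the content units."""
    query = np.asarray(query)
    if query.shape[0] != net.m:
        raise ValueError(f"query length {query.shape[0]} != m={net.m}")
    support = np.flatnonzero(query)
    if support.size == 0:
        return np.zeros(net.n, dtype=np.int64)
    return net.W[support, :].sum(axis=0, dtype=np.int64)


def kwta(x: np.ndarray, l: int) -> np.ndarray:
    """k-winners-take-all: the l units with the largest potentials fire.

    Ties are broken deterministically in favour of the lowest unit index.
    """
    n = x.shape[0]
    if not 0 <= l <= n:
        raise ValueError("winner count out of range")
    out = np.zeros(n, dtype=np.uint8)
    if l:
        # stable sort on -x keeps lowest indices first among equal potentials
        winners = np.argsort(-x, kind="stable")[:l]
        out[winners] = 1
    return out


def retrieve_onestep(
    net: WillshawNetwork,
    query: np.ndarray,
    l: int,
    strategy: str = "kwta",
    theta: int | None = None,
) -> np.ndarray:
    """One synchronous propagation of the query with threshold control.

    strategy:
      - ``kwta``: exactly l units with the largest potentials fire.
      - ``per_neuron_connected``: unit j fires iff x_j >= Theta_j, where
        Theta_j counts the query-active units anatomically connected to j.
        With zero add noise this threshold cannot miss a stored unit, because
        every existing synapse from a correct query unit onto it is
        potentiated.
      - ``fixed``: scalar threshold ``theta``.
    """
    x = dendritic_potentials(net, query)
    if strategy == "kwta":
        return kwta(x, l)
    if strategy == "per_neuron_connected":
        support = np.flatnonzero(query)
        theta_j = net.A[support, :].sum(axis=0, dtype=np.int64)
        return (x >= theta_j).astype(np.uint8)
    if strategy == "fixed":
        if theta is None:
            raise ValueError("strategy 'fixed' requires a threshold theta")
        return (x >= theta).astype(np.uint8)
    raise ValueError(f"unknown threshold strategy: {strategy!r}")


def retrieve_iterative(
    hetero: WillshawNetwork,
    auto: WillshawNetwork | None,
    query: np.ndarray,
    l: int,
    n_iter: int = 3,
) -> np.ndarray:
    """kwta one-step retrieval followed by auto-associative cleanup iterations.

    The preliminary output of the hetero-associative step is propagated
    ``n_iter`` times through the n-by-n auto-associative network, each time
    keeping the l most excited units.  Each unit's own recurrent synapse is
    excluded (zero diagonal), so a stored pattern that is stable without
    self-excitation is a fixed point.
    """
    if n_iter < 0:
        raise ValueError("n_iter must be nonnegative")
    v = retrieve_onestep(hetero, query, l, strategy="kwta")
    if n_iter == 0 or auto is None:
        return v
    if auto.m != auto.n or auto.n != hetero.n:
        raise ValueError("auto network must be n x n")
    for _ in range(n_iter):
        support = np.flatnonzero(v)
        x = auto.W[support, :].sum(axis=0, dtype=np.int64)
        # remove each active unit's own recurrent contribution
        x[support] -= auto.W[support, support].astype(np.int64)
        v = kwta(x, l)
    return v
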