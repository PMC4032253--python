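"""Sparse binary memory patterns, noisy queries, and retrieval-quality metrics.

Memories are pairs of binary activity vectors: an *address* pattern ``u`` of
length ``m`` with exactly ``k`` active units, and a *content* pattern ``v`` of
length ``n`` with exactly ``l`` active units.  The ``k`` (or ``l``) active
units of a pattern form its Hebbian cell assembly.  Queries degrade an address
pattern by keeping only a fraction ``lambda_`` of its active units
(completeness) and adding a fraction ``kappa`` of false active units
(add noise).  Retrieval quality is the Hamming distance between a retrieval
output and the stored content pattern, normalised to the assembly size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MemorySet",
    "QuerySpec",
    "NoiseReport",
    "generate_memory_set",
    "make_query",
    "output_noise",
]


@dataclass(frozen=True)
class MemorySet:
    """A set of M address/content pattern pairs with fixed per-pattern activity.

    Attributes
    ----------
    U : (M, m) uint8 array
        Address patterns; every row has exactly ``k`` ones.
    V : (M, n) uint8 array
        Content patterns; every row has exactly ``l`` ones.
    k, l : int
        Address / content assembly sizes.
    """

    U: np.ndarray
    V: np.ndarray
    k: int
    l: int

    def __post_init__(self) -> None:
        U = np.ascontiguousarray(self.U, dtype=np.uint8)
        V = np.ascontiguousarray(self.V, dtype=np.uint8)
        object.__setattr__(self, "U", U)
        object.__setattr__(self, "V", V)
        if U.shape[0] != V.shape[0]:
            raise ValueError("U and V must hold the same number of memories")
        if U.shape[0]:
            if not np.all(U.sum(axis=1) == self.k):
                raise ValueError("every address pattern must have exactly k ones")
            if not np.all(V.sum(axis=1) == self.l):
                raise ValueError("every content pattern must have exactly l ones")

    @property
    def M(self) -> int:
        return self.U.shape[0]

    @property
    def m(self) -> int:
        return self.U.shape[1]

    @property
    def n(self) -> int:
        return self.V.shape[1]

    def to_text(self, path_u, path_v) -> None:
        """Write patterns as plain text, one 0/1 row per pattern."""
        np.savetxt(path_u, self.U, fmt="%d", delimiter="")
        np.savetxt(path_v, self.V, fmt="%d", delimiter="")

    def save(self, path) -> None:
        """Serialize to a compressed binary container."""
        np.savez_compressed(path, U=self.U, V=self.V, k=self.k, l=self.l)

    @classmethod
    def load(cls, path) -> "MemorySet":
        with np.load(path) as z:
            return cls(U=z["U"], V=z["V"], k=int(z["k"]), l=int(z["l"]))


@dataclass(frozen=True)
class QuerySpec:
    """Input-noise specification: completeness ``lambda_`` and add noise ``kappa``.

    A query built from an address pattern with ``k`` active units keeps
    ``round(lambda_ * k)`` of them and adds ``round(kappa * k)`` false ones.
    """

    lambda_: float = 1.0
    kappa: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_ <= 1.0:
            raise ValueError("lambda_ must lie in [0, 1]")
        if self.kappa < 0.0:
            raise ValueError("kappa must be nonnegative")

    def counts(self, k: int) -> tuple[int, int]:
        """Integer numbers of (correct, false) active units for assembly size k."""
        return int(round(self.lambda_ * k)), int(round(self.kappa * k))


@dataclass(frozen=True)
class NoiseReport:
    """Output noise decomposed into per-unit error rates.

    ``eps_hat`` is the Hamming distance between output and target normalised to
    the assembly size l; ``p01`` the false-positive rate per low (inactive)
    unit; ``p10`` the miss rate per high (active) unit.
    """

    eps_hat: float
    p01: float
    p10: float


def generate_memory_set(
    M: int, m: int, n: int, k: int, l: int, seed: int | np.random.Generator = 0
) -> MemorySet:
    """Draw M independent random memories with fixed activities k and l.

    Each address (content) pattern is drawn uniformly from all size-k subsets
    of m units (size-l subsets of n units), independently across memories —
    duplicates are possible, matching the random-pattern assumption of the
    capacity analysis.
    """
    if not (0 < k <= m):
        raise ValueError(f"need 0 < k <= m, got k={k}, m={m}")
    if not (0 < l <= n):
        raise ValueError(f"need 0 < l <= n, got l={l}, n={n}")
    if M < 0:
        raise ValueError("M must be nonnegative")
    rng = np.random.default_rng(seed)

    def sample(rows: int, width: int, active: int) -> np.ndarray:
        # rank random keys per row: the `active` smallest mark the assembly,
        # a uniform draw over all size-`active` subsets
        keys = rng.random((rows, width))
        idx = np.argpartition(keys, active - 1, axis=1)[:, :active]
        out = np.zeros((rows, width), dtype=np.uint8)
        np.put_along_axis(out, idx, 1, axis=1)
        return out

    U = sample(M, m, k) if M else np.zeros((0, m), dtype=np.uint8)
    V = sample(M, n, l) if M else np.zeros((0, n), dtype=np.uint8)
    return MemorySet(U=U, V=V, k=k, l=l)


def auto_associative(memories: MemorySet) -> MemorySet:
    """View a memory set auto-associatively (contents identical to addresses)."""
    return MemorySet(U=memories.U, V=memories.U, k=memories.k, l=memories.k)


def make_query(
    u: np.ndarray, k: int, spec: QuerySpec, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Build a noisy query from address pattern ``u`` with exactly k ones.

    The query keeps ``round(lambda_*k)`` active units chosen uniformly among
    u's ones and adds ``round(kappa*k)`` false ones chosen uniformly among u's
    zeros.  Deterministic for a fixed seed.
    """
    u = np.asarray(u)
    ones = np.flatnonzero(u)
    if ones.size != k:
        raise ValueError(f"address pattern has {ones.size} ones, expected {k}")
    n_correct, n_false = spec.counts(k)
    if n_correct < 1:
        raise ValueError("lambda_*k rounds to zero: query would be empty")
    zeros = np.flatnonzero(u == 0)
    if n_false > zeros.size:
        raise ValueError("kappa*k exceeds the number of inactive units")
    rng = np.random.default_rng(seed)
    query = np.zeros(u.shape[0], dtype=np.uint8)
    query[rng.choice(ones, size=n_correct, replace=False)] = 1
    if n_false:
        query[rng.choice(zeros, size=n_false, replace=False)] = 1
    return query


def output_noise(v_out: np.ndarray, v_true: np.ndarray, l: int) -> NoiseReport:
    """Output noise of a retrieval result against the stored content pattern.

    eps_hat = Hamming(v_out, v_true) / l, with the per-unit rates
    p01 = false ones / (n - l) and p10 = missed ones / l, so that
    eps_hat = ((n - l) * p01 + l * p10) / l.
    """
    v_out = np.asarray(v_out).astype(bool)
    v_true = np.asarray(v_true).astype(bool)
    if v_out.shape != v_true.shape:
        raise ValueError("output and target must have the same length")
    if l <= 0:
        raise ValueError("assembly size l must be positive")
    n = v_true.size
    false_ones = int(np.count_nonzero(v_out & ~v_true))
    misses = int(np.count_nonzero(~v_out & v_true))
    p01 = false_ones / (n - l) if n > l else 0.0
    p10 = misses / l
    return NoiseReport(eps_hat=(false_ones + misses) / l, p01=p01, p10=p10)
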