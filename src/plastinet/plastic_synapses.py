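"""Microscopic three-state potential-synapse simulator.

A *potential synapse* is a location where axon and dendrite pass close enough
that a real synapse could grow.  Each location is in one of three states:

- ``P``: potential but not realized (no synapse),
- ``0``: realized but silent (weight 0, unstable),
- ``1``: realized and consolidated (weight 1, stable).

Weight plasticity moves synapses between states 0 and 1 under the control of a
binary Hebbian consolidation signal Z (a location with Z=1 is requested by the
memories currently being rehearsed or replayed); structural plasticity moves
locations between P and 0, blindly with respect to Z, since there is no
plausible way to deliver a synapse-specific signal to a not-yet-existing
synapse.  Homeostatic structural plasticity balances generation against
elimination so the anatomical connectivity stays constant while synapses
"migrate" into requested locations.

Two model variants: ``single`` allows at most one synapse per neuron pair
(a binary state per pair); ``multi`` lets each of a fixed budget of synapses
sit at any potential pair location, so pairs can hold several synapses and a
pair counts as connected/consolidated if it holds at least one.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .patterns import MemorySet
from .willshaw import WillshawNetwork

__all__ = [
    "PlasticityParams",
    "ConsolidationSignal",
    "PlasticNetwork",
    "ConnectivityReport",
    "init_network",
    "signal_from_memories",
    "step",
    "measure_connectivity",
    "export_weights",
]


@dataclass(frozen=True)
class PlasticityParams:
    """Per-step transition probabilities of a potential synapse.

    p_gen  : P -> 0, synaptogenesis (ignored under count-matched homeostasis,
             where the generated count is tied to the eliminated count).
    p_elim : 0 -> P, elimination of a silent synapse.
    p_cons : 0 -> 1 where Z=1, Hebbian consolidation.
    p_dec  : 1 -> 0 where Z=0, deconsolidation; requested consolidated
             synapses (Z=1) are retained (immediately reconsolidated).
    """

    p_gen: float = 0.0
    p_elim: float = 0.0
    p_cons: float = 1.0
    p_dec: float = 0.0
    homeostasis: Literal["none", "count_matched"] = "count_matched"

    def __post_init__(self) -> None:
        for name in ("p_gen", "p_elim", "p_cons", "p_dec"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.homeostasis not in ("none", "count_matched"):
            raise ValueError(f"unknown homeostasis mode: {self.homeostasis!r}")


@dataclass(frozen=True)
class ConsolidationSignal:
    """Binary m-by-n matrix tagging the synapses requested by a memory set."""

    Z: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "Z", np.ascontiguousarray(self.Z, dtype=np.uint8))

    @property
    def load(self) -> float:
        """Consolidation load: density of requested locations."""
        return float(self.Z.mean())


@dataclass(frozen=True)
class ConnectivityReport:
    c_a: float
    c_p: float
    c_e: float
    load: float


@dataclass(frozen=True)
class PlasticNetwork:
    """Complete microscopic state of the potential synapses between two populations.

    single mode: ``silent`` and ``cons`` are binary masks over pairs
    (cons & silent disjoint, both subsets of ``potential``).
    multi mode:  ``silent`` and ``cons`` are per-pair synapse counts; the total
    count is the synapse budget ``N_syn`` (constant under count-matched
    homeostasis).  ``potential`` marks pairs with at least one potential
    location.
    """

    mode: Literal["single", "multi"]
    potential: np.ndarray  # uint8 mask
    silent: np.ndarray     # uint8 mask (single) or int32 counts (multi)
    cons: np.ndarray       # uint8 mask (single) or int32 counts (multi)
    t: int = 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.potential.shape

    @property
    def c_p(self) -> float:
        return float(self.potential.mean())

    @property
    def realized_pairs(self) -> np.ndarray:
        return ((self.silent > 0) | (self.cons > 0))

    @property
    def c_a(self) -> float:
        return float(self.realized_pairs.mean())

    @property
    def n_synapses(self) -> int:
        """Total number of actual synapses (equals realized pairs in single mode)."""
        return int(self.silent.sum(dtype=np.int64) + self.cons.sum(dtype=np.int64))

    @property
    def filling_fraction(self) -> float:
        return self.c_a / self.c_p if self.c_p > 0 else 0.0

    def state_counts(self) -> dict[str, int]:
        """Counts over states {P, 0, 1}; they partition the potential locations."""
        if self.mode == "single":
            n_silent = int(np.count_nonzero(self.silent))
            n_cons = int(np.count_nonzero(self.cons))
            n_pot = int(np.count_nonzero(self.potential))
            return {"P": n_pot - n_silent - n_cons, "0": n_silent, "1": n_cons}
        n_silent = int(self.silent.sum(dtype=np.int64))
        n_cons = int(self.cons.sum(dtype=np.int64))
        return {"0": n_silent, "1": n_cons}

    def save(self, path) -> None:
        np.savez_compressed(
            path, mode=self.mode, potential=self.potential,
            silent=self.silent, cons=self.cons, t=self.t,
        )

    @classmethod
    def load(cls, path) -> "PlasticNetwork":
        with np.load(path) as z:
            return cls(mode=str(z["mode"]), potential=z["potential"],
                       silent=z["silent"], cons=z["cons"], t=int(z["t"]))


def init_network(
    m: int,
    n: int,
    c_p: float,
    c_a: float,
    f1c: float = 0.0,
    mode: Literal["single", "multi"] = "single",
    seed: int | np.random.Generator = 0,
) -> PlasticNetwork:
    """Initialise a network with given potential/anatomical connectivity.

    Potential locations are Bernoulli(c_p) per pair.  round(m*n*c_a) synapses
    are placed uniformly on potential locations (at most one per pair in
    single mode; independently with multiplicity in multi mode), and a
    fraction f1c of them starts consolidated — these model stable synapses
    from previously learned, unrelated memories.
    """
    if not 0.0 <= c_a <= c_p <= 1.0:
        raise ValueError(f"need 0 <= c_a <= c_p <= 1, got c_a={c_a}, c_p={c_p}")
    if not 0.0 <= f1c <= 1.0:
        raise ValueError("f1c must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if c_p >= 1.0:
        potential = np.ones((m, n), dtype=np.uint8)
    else:
        potential = (rng.random((m, n)) < c_p).astype(np.uint8)
    pot_idx = np.flatnonzero(potential)
    n_real = int(round(m * n * c_a))

    if mode == "single":
        n_real = min(n_real, pot_idx.size)
        real_idx = rng.choice(pot_idx, size=n_real, replace=False)
        n_cons = int(round(n_real * f1c))
        cons_idx = rng.choice(real_idx, size=n_cons, replace=False)
        cons = np.zeros(m * n, dtype=np.uint8)
        cons[cons_idx] = 1
        silent = np.zeros(m * n, dtype=np.uint8)
        silent[real_idx] = 1
        silent[cons_idx] = 0
        return PlasticNetwork(mode="single", potential=potential,
                              silent=silent.reshape(m, n), cons=cons.reshape(m, n))
    if mode == "multi":
        if pot_idx.size == 0 and n_real > 0:
            raise ValueError("no potential locations to place synapses on")
        loc = rng.choice(pot_idx, size=n_real, replace=True)
        n_cons = int(round(n_real * f1c))
        cons = np.zeros(m * n, dtype=np.int32)
        silent = np.zeros(m * n, dtype=np.int32)
        np.add.at(cons, loc[:n_cons], 1)
        np.add.at(silent, loc[n_cons:], 1)
        return PlasticNetwork(mode="multi", potential=potential,
                              silent=silent.reshape(m, n), cons=cons.reshape(m, n))
    raise ValueError(f"unknown mode: {mode!r}")


def signal_from_memories(memories: MemorySet, shape: tuple[int, int] | None = None) -> ConsolidationSignal:
    """Consolidation signal of a memory block: its (unmasked) Willshaw matrix.

    Z[i, j] = 1 iff some memory in the block has u_i = v_j = 1.
    """
    m, n = shape if shape is not None else (memories.m, memories.n)
    if (m, n) != (memories.m, memories.n):
        raise ValueError("shape does not match the memory set")
    if memories.M == 0:
        return ConsolidationSignal(Z=np.zeros((m, n), dtype=np.uint8))
    Z = (memories.U.T.astype(np.float32) @ memories.V.astype(np.float32) > 0).astype(np.uint8)
    return ConsolidationSignal(Z=Z)


def step(
    net: PlasticNetwork,
    Z: ConsolidationSignal | None,
    params: PlasticityParams,
    seed: int | np.random.Generator = 0,
) -> PlasticNetwork:
    """Advance the network one time step.

    Sub-processes apply in fixed order: (a) consolidation of silent requested
    synapses, (b) deconsolidation of consolidated unrequested synapses
    (requested ones are retained), (c) elimination of silent synapses,
    (d) generation — under count-matched homeostasis exactly as many new
    silent synapses as were eliminated appear at uniformly chosen free
    potential locations, independent of Z; otherwise each free location
    realizes with probability p_gen.  Elimination is counted before
    generation so the homeostatic count match is exact.

    ``Z=None`` means no rehearsal this step (all-zero signal): structural
    turnover continues, nothing consolidates.
    """
    rng = np.random.default_rng(seed)
    zmask = None if Z is None else (Z.Z > 0)
    if zmask is not None and zmask.shape != net.shape:
        raise ValueError("consolidation signal shape mismatch")

    if net.mode == "single":
        silent = net.silent.astype(bool).copy()
        cons = net.cons.astype(bool).copy()
        # (a) consolidate requested silent synapses
        if zmask is not None and params.p_cons > 0:
            cand = silent & zmask
            hit = cand & (rng.random(net.shape) < params.p_cons)
            cons |= hit
            silent &= ~hit
        # (b) deconsolidate unrequested consolidated synapses
        if params.p_dec > 0:
            cand = cons if zmask is None else (cons & ~zmask)
            hit = cand & (rng.random(net.shape) < params.p_dec)
            silent |= hit
            cons &= ~hit
        # (c) eliminate silent synapses
        if params.p_elim > 0:
            gone = silent & (rng.random(net.shape) < params.p_elim)
            silent &= ~gone
            n_gone = int(np.count_nonzero(gone))
        else:
            n_gone = 0
        # (d) generate new silent synapses at free potential locations
        free = (net.potential > 0) & ~silent & ~cons
        if params.homeostasis == "count_matched":
            if n_gone:
                free_idx = np.flatnonzero(free)
                if free_idx.size < n_gone:
                    raise RuntimeError(
                        "count-matched homeostasis: not enough free potential locations"
                    )
                born = rng.choice(free_idx, size=n_gone, replace=False)
                silent.ravel()[born] = True
        elif params.p_gen > 0:
            born = free & (rng.random(net.shape) < params.p_gen)
            silent |= born
        return replace(net, silent=silent.astype(np.uint8),
                       cons=cons.astype(np.uint8), t=net.t + 1)

    # multi mode: integer synapse counts per pair
    silent = net.silent.astype(np.int64).copy()
    cons = net.cons.astype(np.int64).copy()
    if zmask is not None and params.p_cons > 0:
        moved = rng.binomial(silent, params.p_cons) * zmask
        silent -= moved
        cons += moved
    if params.p_dec > 0:
        cand = cons if zmask is None else cons * ~zmask
        moved = rng.binomial(cand, params.p_dec)
        cons -= moved
        silent += moved
    if params.p_elim > 0:
        gone = rng.binomial(silent, params.p_elim)
        silent -= gone
        n_gone = int(gone.sum())
    else:
        n_gone = 0
    pot_idx = np.flatnonzero(net.potential)
    if params.homeostasis == "count_matched":
        if n_gone:
            if pot_idx.size == 0:
                raise RuntimeError("count-matched homeostasis: no potential locations")
            born = rng.choice(pot_idx, size=n_gone, replace=True)
            np.add.at(silent.ravel(), born, 1)
    elif params.p_gen > 0:
        born = (rng.random(net.shape) < params.p_gen) & (net.potential > 0)
        silent += born
    return replace(net, silent=silent.astype(np.int32),
                   cons=cons.astype(np.int32), t=net.t + 1)


def measure_connectivity(net: PlasticNetwork, Z: ConsolidationSignal) -> ConnectivityReport:
    """Macroscopic connectivities of the current microscopic state.

    Effectual connectivity c_e is the fraction of requested pairs (Z=1) that
    hold at least one consolidated synapse; c_a and c_p are the densities of
    realized and potential pairs (a pair counts once even if it holds several
    synapses).
    """
    zmask = Z.Z > 0
    n_req = int(np.count_nonzero(zmask))
    if n_req == 0:
        raise ValueError("effectual connectivity is undefined for an all-zero signal")
    c_e = float(np.count_nonzero((net.cons > 0) & zmask)) / n_req
    return ConnectivityReport(c_a=net.c_a, c_p=net.c_p, c_e=c_e, load=Z.load)


def export_weights(net: PlasticNetwork) -> WillshawNetwork:
    """Snapshot the plastic network as a static binary Willshaw network.

    W marks pairs holding at least one consolidated synapse, A pairs holding
    at least one actual synapse.
    """
    W = (net.cons > 0).astype(np.uint8)
    A = net.realized_pairs.astype(np.uint8)
    return WillshawNetwork(W=W, A=A)
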