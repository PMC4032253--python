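"""Macroscopic (expected-value) dynamics of effectual connectivity.

During consolidation of a fixed memory set, homeostatic structural turnover
migrates synapses into requested locations: each step, the silent
(unconsolidated) synapses are eliminated at rate ``p_elim`` and the same
number of new silent synapses appears at uniformly chosen free potential
locations; those that happen to land on requested locations are consolidated
at the next rehearsal step and leave the migratable pool.

For a large network with at most a single synapse per pair, constant
anatomical connectivity c_a, a constant binary signal Z of density ``load``
presented every step, and immediate consolidation (p_cons = 1), the fraction
of requested pairs carrying a consolidated synapse follows an exact product
recurrence: writing G(t) for the probability that a requested *potential*
location is still unconsolidated,

    c_e(0) = c_a * f1c                (old, unrelated consolidated synapses)
    c_e(1) = c_a                      (first rehearsal consolidates all
                                       realized requested synapses)
    c_e(t) = c_p * (1 - G(t)),  G(t) = (1 - c_a/c_p) * prod_{s=1}^{t-1} (1 - q(s))

where q(s) = p_elim * s0(s) / (c_p - c_a) is the chance that a free potential
location receives a synapse at step s, and s0(s) — the migratable silent
fraction — is all real synapses minus surviving initially-consolidated ones
minus those newly consolidated at requested locations.  When the
consolidation load is large, the pool s0 runs dry and c_e converges to a
limit below c_p; otherwise c_e -> c_p.

For small load and negligible deconsolidation all product factors are equal
and the recurrence collapses to the exponential form

    c_e(t) ~= c_p - (c_p - c_a) * exp(-p_elim * c_a * (1 - f1c) / (c_p - c_a) * (t - 1)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MacroParams",
    "TheoryTrajectory",
    "effectual_trajectory_theory",
    "homeostatic_generation_rate",
]


@dataclass(frozen=True)
class MacroParams:
    """Parameters of the effectual-connectivity recurrence.

    c_a, c_p : anatomical / potential connectivity, 0 <= c_a <= c_p <= 1.
    load     : consolidation load (density of the signal Z), in (0, 1].
    f1c      : fraction of synapses initially consolidated (old memories).
    p_elim   : per-step elimination probability of a silent synapse.
    p_dec    : per-step deconsolidation probability of an unrequested
               consolidated synapse.
    T        : horizon in steps.
    """

    c_a: float
    c_p: float
    load: float
    f1c: float = 0.0
    p_elim: float = 0.0
    p_dec: float = 0.0
    T: int = 100

    def __post_init__(self) -> None:
        if not 0.0 <= self.c_a <= self.c_p <= 1.0:
            raise ValueError("need 0 <= c_a <= c_p <= 1")
        if not 0.0 < self.load <= 1.0:
            raise ValueError("load must lie in (0, 1]")
        if not 0.0 <= self.f1c <= 1.0:
            raise ValueError("f1c must lie in [0, 1]")
        if self.T < 0:
            raise ValueError("T must be nonnegative")


@dataclass(frozen=True)
class TheoryTrajectory:
    t: np.ndarray
    c_e: np.ndarray          # exact product recurrence
    c_e_approx: np.ndarray   # exponential approximation

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "c_e": self.c_e,
                             "c_e_approx": self.c_e_approx})


def effectual_trajectory_theory(p: MacroParams) -> TheoryTrajectory:
    """Effectual-connectivity trajectory c_e(t) for t = 0..T.

    Returns both the exact product recurrence and the exponential
    approximation (valid for small load and p_dec ~ 0).
    """
    T = p.T
    c_e = np.empty(T + 1)
    c_e[0] = p.c_a * p.f1c
    if T >= 1:
        c_e[1] = p.c_a
    free = p.c_p - p.c_a
    G = 1.0 - (p.c_a / p.c_p if p.c_p > 0 else 0.0)
    for t in range(1, T):
        # migratable silent pool after step t's consolidation/deconsolidation:
        # all real synapses, minus initially-consolidated ones that survived
        # (requested ones are retained, unrequested ones decay at p_dec),
        # minus synapses newly consolidated at requested locations.
        surviving_init = p.c_a * p.f1c * (
            p.load + (1.0 - p.load) * (1.0 - p.p_dec) ** t
        )
        newly_cons = p.load * (c_e[t] - p.c_a * p.f1c)
        s0 = max(p.c_a - surviving_init - newly_cons, 0.0)
        q = min(p.p_elim * s0 / free, 1.0) if free > 0 else 0.0
        G *= 1.0 - q
        c_e[t + 1] = p.c_p * (1.0 - G)

    # exponential approximation: constant pool s0 ~ c_a (1 - f1c)
    t_axis = np.arange(T + 1)
    approx = np.empty(T + 1)
    approx[0] = p.c_a * p.f1c
    if T >= 1:
        if free > 0:
            rate = p.p_elim * p.c_a * (1.0 - p.f1c) / free
            approx[1:] = p.c_p - free * np.exp(-rate * (t_axis[1:] - 1))
        else:
            approx[1:] = p.c_a
    return TheoryTrajectory(t=t_axis, c_e=c_e, c_e_approx=approx)


def homeostatic_generation_rate(n_silent: int, n_free: int, p_elim: float) -> float:
    """Generation probability balancing expected elimination, per free location.

    Solves p_gen * n_free = p_elim * n_silent for p_gen, the per-step
    realization probability of a free potential location that keeps the
    synapse count constant in expectation.
    """
    if n_silent < 0 or n_free < 0:
        raise ValueError("counts must be nonnegative")
    if n_silent == 0 or p_elim == 0.0:
        return 0.0
    if n_free == 0:
        raise ValueError("no free potential locations: homeostatic balance impossible")
    p_gen = p_elim * n_silent / n_free
    if p_gen > 1.0:
        raise ValueError(
            f"required generation rate {p_gen:.3g} exceeds 1: "
            "elimination outpaces the available potential locations"
        )
    return p_gen
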