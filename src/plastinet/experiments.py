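"""End-to-end simulation experiments on structurally plastic memory networks.

Four protocols, all built from the same ingredients — a plastic
hetero-associative projection from an address population to a content
population, a prewired static auto-associative cleanup network in the content
population, and hippocampus-style replay that presents each memory block's
consolidation signal for a number of time steps:

- ``run_consolidation``: a single block rehearsed continuously; records the
  microscopic effectual-connectivity trajectory and overlays the macroscopic
  theory curve.
- ``run_block_learning``: memory blocks consolidated one after the other;
  with frozen structure the network forgets catastrophically once its
  capacity is exceeded, with homeostatic structural plasticity early blocks
  stay stable while the ability to store new ones fades.
- ``run_lesion``: block learning followed by silencing a fixed random half
  of the address population; recently stored blocks suffer most (Ribot
  gradient), mirroring the gradient in effectual connectivity.
- ``run_spacing``: one memory block rehearsed either massed (one contiguous
  window) or spaced (several brief windows at equal total rehearsal time) on
  seed-matched networks.

Default parameters follow the published simulation table where values are
printed (population size 1000, assembly size 50, query completeness 0.9, add
noise 0.1, block counts, memories per block, elimination rates); connectivity
levels and schedule details are package defaults chosen to place each
protocol in its intended operating regime (see the methods note).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .patterns import MemorySet, QuerySpec, generate_memory_set, make_query, output_noise
from .willshaw import WillshawNetwork, random_mask, store, retrieve_iterative
from .plastic_synapses import (
    PlasticityParams, ConsolidationSignal, PlasticNetwork,
    init_network, signal_from_memories, step, measure_connectivity, export_weights,
)
from .macro_theory import MacroParams, effectual_trajectory_theory

logger = logging.getLogger("plastinet")

__all__ = [
    "ExperimentConfig",
    "TrajectoryRecord",
    "run_consolidation",
    "run_block_learning",
    "run_lesion",
    "run_spacing",
    "write_results",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Network, plasticity, pattern and schedule parameters of one experiment."""

    # network & patterns
    mode: str = "multi"           # synapse model: single | multi
    m: int = 1000
    n: int = 1000
    k: int = 50
    l: int = 50
    c_a: float = 0.1              # anatomical connectivity of the plastic projection
    c_p: float = 1.0              # potential connectivity
    f1c: float = 0.0              # fraction of synapses initially consolidated
    # plasticity
    p_elim: float = 1.0
    p_cons: float = 1.0
    p_dec: float = 0.0
    # queries
    lambda_: float = 0.9
    kappa: float = 0.1
    # schedule
    n_blocks: int = 25
    M_per_block: int = 4
    replay_steps: int = 5
    # retrieval evaluation
    auto_c: float | None = 1.0    # prewired auto-associative connectivity (None: no cleanup)
    n_iter: int = 3
    eval_stride: int = 1
    eval_retrieval: bool = True
    retained_threshold: float = 0.2
    # lesion protocol
    lesion_fraction: float = 0.5
    lesion_time: int | None = None   # default: right after the last block's replay
    # spacing protocol
    n_windows: int = 4
    window_len: int = 5
    gap: int = 45
    seed: int = 0

    def query_spec(self) -> QuerySpec:
        return QuerySpec(lambda_=self.lambda_, kappa=self.kappa)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    # --- canonical protocol parameter sets -------------------------------

    @classmethod
    def consolidation_defaults(cls, **over) -> "ExperimentConfig":
        """Single-block consolidation dynamics (single-synapse model, k = 10)."""
        base = dict(mode="single", m=1000, n=1000, k=10, l=10,
                    c_a=0.1, c_p=1.0, f1c=0.0,
                    p_elim=0.1, p_cons=1.0, p_dec=0.0,
                    lambda_=1.0, kappa=0.0,
                    n_blocks=1, M_per_block=100, replay_steps=200,
                    eval_retrieval=False, auto_c=None)
        base.update(over)
        return cls(**base)

    @classmethod
    def blocks_structural_defaults(cls, **over) -> "ExperimentConfig":
        """Sequential learning with homeostatic structural plasticity."""
        base = dict(mode="multi", c_a=0.04, c_p=1.0, f1c=0.0, p_elim=1.0,
                    n_blocks=25, M_per_block=4, replay_steps=5, auto_c=0.45)
        base.update(over)
        return cls(**base)

    @classmethod
    def blocks_static_defaults(cls, **over) -> "ExperimentConfig":
        """Sequential learning with frozen structure (weight plasticity only)."""
        base = dict(mode="single", c_a=0.1, c_p=0.1, f1c=0.0, p_elim=0.0,
                    n_blocks=25, M_per_block=12, replay_steps=5, auto_c=1.0)
        base.update(over)
        return cls(**base)

    @classmethod
    def lesion_defaults(cls, **over) -> "ExperimentConfig":
        """Ribot-gradient protocol: 6 blocks, then half the address units silenced."""
        base = dict(mode="multi", c_a=0.1, c_p=1.0, f1c=0.8, p_elim=1.0,
                    n_blocks=6, M_per_block=4, replay_steps=10,
                    auto_c=0.3, lesion_fraction=0.5)
        base.update(over)
        return cls(**base)

    @classmethod
    def spacing_defaults(cls, **over) -> "ExperimentConfig":
        """Massed vs spaced rehearsal of one block at equal total rehearsal time."""
        base = dict(mode="multi", c_a=0.1, c_p=1.0, f1c=0.7, p_elim=0.01,
                    n_blocks=1, M_per_block=20,
                    n_windows=4, window_len=5, gap=45, auto_c=0.45)
        base.update(over)
        return cls(**base)


@dataclass
class TrajectoryRecord:
    """Time series of connectivities and per-block output noise from one run."""

    t: np.ndarray                 # evaluation times (simulation steps)
    c_a: np.ndarray               # anatomical connectivity at each time
    c_e: np.ndarray               # (T, B) effectual connectivity per block, NaN before storage
    eps: np.ndarray               # (T, B) mean output noise per block, NaN where not evaluated
    events: list = field(default_factory=list)
    config: dict = field(default_factory=dict)
    theory: pd.DataFrame | None = None
    extra: dict = field(default_factory=dict)

    @property
    def n_blocks(self) -> int:
        return self.c_e.shape[1]

    def final_c_e(self) -> np.ndarray:
        if self.c_e.shape[0] == 0:
            return np.full(self.n_blocks, np.nan)
        return self.c_e[-1]

    def final_eps(self) -> np.ndarray:
        if self.eps.shape[0] == 0:
            return np.full(self.n_blocks, np.nan)
        return self.eps[-1]

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format (t, block, metric, value) table of all series."""
        rows = []
        for j, tt in enumerate(self.t):
            rows.append({"t": int(tt), "block": -1, "metric": "c_a",
                         "value": float(self.c_a[j])})
            for b in range(self.n_blocks):
                for name, arr in (("c_e", self.c_e), ("eps_hat", self.eps)):
                    v = arr[j, b]
                    if not np.isnan(v):
                        rows.append({"t": int(tt), "block": b, "metric": name,
                                     "value": float(v)})
        return pd.DataFrame(rows, columns=["t", "block", "metric", "value"])


def _split_rngs(seed: int) -> tuple[np.random.Generator, np.random.Generator, np.random.Generator]:
    """Independent streams for structure/patterns, plasticity, and evaluation."""
    ss = np.random.SeedSequence(seed).spawn(3)
    return tuple(np.random.default_rng(s) for s in ss)


def _build_blocks(cfg: ExperimentConfig, rng: np.random.Generator) -> list[MemorySet]:
    return [generate_memory_set(cfg.M_per_block, cfg.m, cfg.n, cfg.k, cfg.l, rng)
            for _ in range(cfg.n_blocks)]


def _build_auto(cfg: ExperimentConfig, blocks: list[MemorySet],
                rng: np.random.Generator) -> WillshawNetwork | None:
    """Prewired static auto-associative cleanup net over all content patterns."""
    if cfg.auto_c is None or cfg.n_iter == 0:
        return None
    mask = (np.ones((cfg.n, cfg.n), dtype=np.uint8) if cfg.auto_c >= 1.0
            else random_mask(cfg.n, cfg.n, cfg.auto_c, rng))
    V = np.concatenate([b.V for b in blocks], axis=0)
    mem = MemorySet(U=V, V=V, k=cfg.l, l=cfg.l)
    return store(mem, mask)


def _evaluate_blocks(
    hetero: WillshawNetwork,
    auto: WillshawNetwork | None,
    blocks: list[MemorySet],
    stored_upto: int,
    cfg: ExperimentConfig,
    eval_rng: np.random.Generator,
    alive: np.ndarray | None = None,
) -> np.ndarray:
    """Mean output noise per stored block from noisy queries; NaN for unstored."""
    spec = cfg.query_spec()
    eps = np.full(len(blocks), np.nan)
    for b in range(stored_upto):
        vals = []
        for mu in range(blocks[b].M):
            q = make_query(blocks[b].U[mu], cfg.k, spec, eval_rng)
            if alive is not None:
                q = q * alive
            v = retrieve_iterative(hetero, auto, q, cfg.l, n_iter=cfg.n_iter)
            vals.append(output_noise(v, blocks[b].V[mu], cfg.l).eps_hat)
        eps[b] = float(np.mean(vals))
    return eps


def run_consolidation(cfg: ExperimentConfig | None = None) -> TrajectoryRecord:
    """Single-block consolidation: microscopic c_e(t) with the theory overlay.

    The block's signal Z is presented at every step; homeostatic structural
    turnover migrates synapses into requested locations and effectual
    connectivity climbs from the anatomical level toward the potential level
    (or a lower limit when the consolidation load exhausts the migratable
    pool).
    """
    if cfg is None:
        cfg = ExperimentConfig.consolidation_defaults()
    struct_rng, sim_rng, _ = _split_rngs(cfg.seed)
    block = generate_memory_set(cfg.M_per_block, cfg.m, cfg.n, cfg.k, cfg.l, struct_rng)
    Z = signal_from_memories(block)
    net = init_network(cfg.m, cfg.n, cfg.c_p, cfg.c_a, cfg.f1c, cfg.mode, struct_rng)
    params = PlasticityParams(p_elim=cfg.p_elim, p_cons=cfg.p_cons,
                              p_dec=cfg.p_dec, homeostasis="count_matched")
    T = cfg.replay_steps
    t_axis = np.arange(T + 1)
    c_e = np.full((T + 1, 1), np.nan)
    c_a_t = np.empty(T + 1)
    c_e[0, 0] = measure_connectivity(net, Z).c_e
    c_a_t[0] = net.c_a
    for tt in range(1, T + 1):
        net = step(net, Z, params, sim_rng)
        rep = measure_connectivity(net, Z)
        c_e[tt, 0] = rep.c_e
        c_a_t[tt] = rep.c_a
    theory = effectual_trajectory_theory(MacroParams(
        c_a=c_a_t[0], c_p=net.c_p, load=Z.load, f1c=cfg.f1c,
        p_elim=cfg.p_elim, p_dec=cfg.p_dec, T=T)).to_frame()
    eps = np.full((T + 1, 1), np.nan)
    return TrajectoryRecord(t=t_axis, c_a=c_a_t, c_e=c_e, eps=eps,
                            events=[{"t": 0, "event": "replay_start", "block": 0}],
                            config=cfg.to_dict(), theory=theory)


def _block_learning_engine(
    cfg: ExperimentConfig,
) -> tuple[TrajectoryRecord, PlasticNetwork, list[MemorySet],
           WillshawNetwork | None, np.random.Generator]:
    """Shared core: sequential replay of blocks with per-step evaluation."""
    struct_rng, sim_rng, eval_rng = _split_rngs(cfg.seed)
    blocks = _build_blocks(cfg, struct_rng)
    Zs = [signal_from_memories(b) for b in blocks]
    net = init_network(cfg.m, cfg.n, cfg.c_p, cfg.c_a, cfg.f1c, cfg.mode, struct_rng)
    auto = _build_auto(cfg, blocks, struct_rng)
    params = PlasticityParams(p_elim=cfg.p_elim, p_cons=cfg.p_cons,
                              p_dec=cfg.p_dec, homeostasis="count_matched")
    total = cfg.n_blocks * cfg.replay_steps
    times, c_a_t, c_e_rows, eps_rows, events = [], [], [], [], []
    tt = 0
    for b in range(cfg.n_blocks):
        events.append({"t": tt, "event": "replay_start", "block": b})
        logger.info("block %d/%d replay starts at t=%d", b + 1, cfg.n_blocks, tt)
        for _ in range(cfg.replay_steps):
            net = step(net, Zs[b], params, sim_rng)
            tt += 1
            if tt % cfg.eval_stride == 0 or tt == total:
                times.append(tt)
                c_a_t.append(net.c_a)
                ce_row = np.full(cfg.n_blocks, np.nan)
                for bb in range(b + 1):
                    ce_row[bb] = measure_connectivity(net, Zs[bb]).c_e
                c_e_rows.append(ce_row)
                if cfg.eval_retrieval:
                    snap = export_weights(net)
                    eps_rows.append(_evaluate_blocks(snap, auto, blocks, b + 1,
                                                     cfg, eval_rng))
                else:
                    eps_rows.append(np.full(cfg.n_blocks, np.nan))
    rec = TrajectoryRecord(
        t=np.asarray(times), c_a=np.asarray(c_a_t),
        c_e=np.vstack(c_e_rows), eps=np.vstack(eps_rows),
        events=events, config=cfg.to_dict(),
    )
    return rec, net, blocks, auto, eval_rng


def run_block_learning(cfg: ExperimentConfig | None = None) -> TrajectoryRecord:
    """Sequential consolidation of memory blocks with per-step retrieval tests.

    Every block's signal is replayed for ``replay_steps`` steps; at each
    evaluated step all previously stored blocks are retrieved from noisy
    queries (completeness lambda_, add noise kappa) with iterative cleanup
    and their mean output noise recorded.
    """
    if cfg is None:
        cfg = ExperimentConfig.blocks_structural_defaults()
    rec, *_ = _block_learning_engine(cfg)
    return rec


def run_lesion(cfg: ExperimentConfig | None = None) -> TrajectoryRecord:
    """Block learning followed by silencing a random half of the address units.

    The lesion removes the chosen units from all subsequent queries (synapses
    are untouched).  Records pre- and post-lesion output noise and the
    per-block effectual connectivity at lesion time.
    """
    if cfg is None:
        cfg = ExperimentConfig.lesion_defaults()
    rec, net, blocks, auto, eval_rng = _block_learning_engine(cfg)
    t_lesion = cfg.lesion_time if cfg.lesion_time is not None \
        else cfg.n_blocks * cfg.replay_steps
    struct_rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(4)[3])
    n_out = int(round(cfg.lesion_fraction * cfg.m))
    dead = struct_rng.choice(cfg.m, size=n_out, replace=False)
    alive = np.ones(cfg.m, dtype=np.uint8)
    alive[dead] = 0
    rec.events.append({"t": int(t_lesion), "event": "lesion",
                       "fraction": cfg.lesion_fraction})
    logger.info("lesion at t=%d: %d of %d address units silenced",
                t_lesion, n_out, cfg.m)
    snap = export_weights(net)
    # identical query streams pre and post so the lesion is the only difference
    final_ss = np.random.SeedSequence(cfg.seed).spawn(5)[4]
    pre = _evaluate_blocks(snap, auto, blocks, cfg.n_blocks, cfg,
                           np.random.default_rng(final_ss))
    post = _evaluate_blocks(snap, auto, blocks, cfg.n_blocks, cfg,
                            np.random.default_rng(final_ss), alive=alive)
    rec.extra["pre_lesion_eps"] = pre
    rec.extra["post_lesion_eps"] = post
    rec.extra["c_e_at_lesion"] = rec.c_e[-1].copy()
    rec.extra["alive_mask"] = alive
    return rec


def _schedule(cfg: ExperimentConfig, spaced: bool) -> list[bool]:
    """Per-step rehearsal flags; massed and spaced share the same horizon."""
    total_rehearsal = cfg.n_windows * cfg.window_len
    horizon = total_rehearsal + (cfg.n_windows - 1) * cfg.gap
    flags = [False] * horizon
    if spaced:
        for w in range(cfg.n_windows):
            start = w * (cfg.window_len + cfg.gap)
            for s in range(start, start + cfg.window_len):
                flags[s] = True
    else:
        for s in range(total_rehearsal):
            flags[s] = True
    return flags


def _run_rehearsal(cfg: ExperimentConfig, spaced: bool) -> TrajectoryRecord:
    struct_rng, sim_rng, eval_rng = _split_rngs(cfg.seed)
    block = generate_memory_set(cfg.M_per_block, cfg.m, cfg.n, cfg.k, cfg.l, struct_rng)
    Z = signal_from_memories(block)
    net = init_network(cfg.m, cfg.n, cfg.c_p, cfg.c_a, cfg.f1c, cfg.mode, struct_rng)
    auto = _build_auto(cfg, [block], struct_rng)
    params = PlasticityParams(p_elim=cfg.p_elim, p_cons=cfg.p_cons,
                              p_dec=cfg.p_dec, homeostasis="count_matched")
    flags = _schedule(cfg, spaced)
    times, c_a_t, ce_rows, eps_rows, events = [], [], [], [], []
    for tt, rehearse in enumerate(flags, start=1):
        if rehearse and (tt == 1 or not flags[tt - 2]):
            events.append({"t": tt, "event": "rehearsal_window", "block": 0})
        net = step(net, Z if rehearse else None, params, sim_rng)
        if tt % cfg.eval_stride == 0 or tt == len(flags):
            times.append(tt)
            c_a_t.append(net.c_a)
            ce_rows.append([measure_connectivity(net, Z).c_e])
            if cfg.eval_retrieval:
                snap = export_weights(net)
                eps_rows.append(_evaluate_blocks(snap, auto, [block], 1, cfg, eval_rng))
            else:
                eps_rows.append([np.nan])
    return TrajectoryRecord(
        t=np.asarray(times), c_a=np.asarray(c_a_t),
        c_e=np.asarray(ce_rows, dtype=float), eps=np.asarray(eps_rows, dtype=float),
        events=events, config={**cfg.to_dict(), "spaced": spaced},
    )


def run_spacing(cfg: ExperimentConfig | None = None) -> tuple[TrajectoryRecord, TrajectoryRecord]:
    """Seed-matched massed vs spaced rehearsal at equal total rehearsal time.

    Returns (massed, spaced) records over the same horizon; with gap = 0 the
    two schedules coincide and the trajectories are identical.
    """
    if cfg is None:
        cfg = ExperimentConfig.spacing_defaults()
    massed = _run_rehearsal(cfg, spaced=False)
    spaced = _run_rehearsal(cfg, spaced=True)
    return massed, spaced


def write_results(record: TrajectoryRecord, out_dir) -> dict[str, Path]:
    """Write a run to disk: long-format series CSV, JSON summary, event log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "series": out / "series.csv",
        "summary": out / "summary.json",
        "events": out / "events.json",
    }
    record.to_long_frame().to_csv(paths["series"], index=False)
    with np.errstate(invalid="ignore"):
        summary = {
            "config": record.config,
            "final_c_e": [None if np.isnan(v) else float(v) for v in record.final_c_e()],
            "final_eps_hat": [None if np.isnan(v) else float(v) for v in record.final_eps()],
            "final_c_a": float(record.c_a[-1]) if record.c_a.size else None,
        }
    for key, val in record.extra.items():
        if isinstance(val, np.ndarray) and val.ndim == 1:
            summary[key] = [float(v) for v in val]
    with open(paths["summary"], "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    with open(paths["events"], "w") as fh:
        json.dump(record.events, fh, indent=2)
    if record.theory is not None:
        paths["theory"] = out / "theory.csv"
        record.theory.to_csv(paths["theory"], index=False)
    return paths
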