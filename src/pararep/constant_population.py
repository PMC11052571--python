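"""Constant-population (Moran) model of parabolic replication.

Only three reaction categories act — replication, association and
dissociation — and every newly synthesized strand replaces a strand chosen
uniformly at random from the rest of the population.  A simplex victim
keeps the total strand count at ``N0``; a duplex-resident victim removes
its whole duplex, so the population size drops to ``N0 - 1`` until the next
replication (which then skips the removal).  Monomer resources are not
represented explicitly.

The run starts from ``N0 / T`` simplex copies of each master type and
terminates after a fixed number of replication events (default ``10**7``),
sampling the observables every ``survival_cadence`` replication events.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _core
from .kinetics import (KineticParams, dissociation_table, duplex_decay_table)
from .observables import TrajectoryRecord, make_samples_frame
from .sequences import (MasterSet, encode_seq, generate_balanced_gc_set,
                        generate_gc_gradient_set, generate_master_set)
from .ssa import MoranRules, PopulationState, Simulation


@dataclass
class ConstantPopulationConfig:
    """Run configuration for the Moran model (defaults: Table-1 standard
    conditions at medium population size)."""

    n0: int = 10_000
    T: int = 10
    L: int = 10
    kinetics: KineticParams = field(default_factory=KineticParams)
    master_kind: str = "random"     #: random | gc_gradient | balanced_gc
    master_seed: int | None = None  #: None derives it from the run seed
    max_repl_events: int = 10_000_000
    survival_cadence: int = 2_000
    survival_window: int = 10_000
    no_cross_hybridization: bool = False
    max_total_events: int | None = None  #: hard SSA-event safety cap

    def validate(self) -> None:
        if self.n0 < 2 or self.T < 1 or self.L < 2:
            raise ValueError("need n0 >= 2, T >= 1, L >= 2")
        if self.survival_cadence < 1:
            raise ValueError("survival cadence must be >= 1")
        if self.survival_window % self.survival_cadence:
            raise ValueError("survival window must be a cadence multiple")
        if self.max_repl_events < self.survival_window:
            raise ValueError("run shorter than the survival window")
        if self.max_repl_events % self.survival_cadence:
            raise ValueError("event cap must be a cadence multiple")

    def scaled(self, factor: float) -> "ConstantPopulationConfig":
        from .experiments import scale_down
        return scale_down(self, factor)


def build_master_set(cfg, seed: int | None) -> MasterSet:
    """Generate the master set named by *cfg* (kind, T, L, kinetics)."""
    kp = cfg.kinetics
    kind = cfg.master_kind
    if kind == "random":
        return generate_master_set(cfg.T, cfg.L, seed, phi_min=kp.phi_min,
                                   delta=kp.delta,
                                   reverse_complement=kp.reverse_complement)
    if kind == "gc_gradient":
        return generate_gc_gradient_set(
            cfg.T, cfg.L, seed, phi_equal=kp.phi_min,
            reverse_complement=kp.reverse_complement)
    if kind == "balanced_gc":
        return generate_balanced_gc_set(
            cfg.T, cfg.L, kp.delta, seed, phi_min=kp.phi_min,
            reverse_complement=kp.reverse_complement)
    raise ValueError(f"unknown master kind {kind!r}")


def equal_split(n0: int, T: int) -> np.ndarray:
    """Nearest-equal initial copy numbers (the first ``n0 % T`` types get
    one extra copy when n0 is not divisible by T)."""
    counts = np.full(T, n0 // T, dtype=np.int64)
    counts[: n0 % T] += 1
    return counts


def fire_replication_moran(state: PopulationState, template: str,
                           ms: MasterSet, kp: KineticParams,
                           rng: np.random.Generator, n0: int) -> set:
    """One Moran replication event on a reference state (template copying
    with mutation, duplex formation, and random replacement)."""
    return MoranRules(ms, kp, n0).fire_replication(state, template, rng)


def initial_state(ms: MasterSet, n0: int) -> PopulationState:
    counts = equal_split(n0, ms.T)
    state = PopulationState()
    for m, k in zip(ms.masters, counts):
        if k:
            state.add_simplex(m, int(k))
    return state


def _spawn_seeds(seed: int | None) -> tuple[int, int]:
    ss = np.random.SeedSequence(seed)
    master_seed, core_seed = ss.generate_state(2)
    return int(master_seed % (2**31)), int(core_seed % (2**31))


def run_constant(config: ConstantPopulationConfig, seed: int | None = None,
                 master_set: MasterSet | None = None,
                 engine: str = "fast") -> TrajectoryRecord:
    """Run the constant-population model to its replication-event cap.

    The run seed deterministically derives both the master-set seed (unless
    ``config.master_seed`` or an explicit *master_set* pins it) and the SSA
    stream, so a (config, seed) pair is exactly reproducible.
    """
    config.validate()
    master_seed, core_seed = _spawn_seeds(seed)
    if master_set is None:
        master_set = build_master_set(
            config, config.master_seed if config.master_seed is not None
            else master_seed)
    kp = config.kinetics

    params = {
        "model": "constant_population",
        "n0": config.n0,
        "seed": seed,
        "survival_cadence": config.survival_cadence,
        "survival_window": config.survival_window,
        "max_repl_events": config.max_repl_events,
        **kp.to_dict(),
    }

    if engine == "reference":
        return _run_reference(config, master_set, core_seed, params)
    if engine != "fast":
        raise ValueError(f"unknown engine {engine!r}")

    masters = np.array([encode_seq(m) for m in master_set.masters], np.int64)
    comps = np.array([encode_seq(c) for c in master_set.complements], np.int64)
    phis = np.array(master_set.replicabilities, float)
    cap = (config.max_total_events if config.max_total_events is not None
           else max(10**7, 10_000 * config.max_repl_events))
    out_master, out_extra, out_time, counters = _core._run_core(
        _core.MODE_MORAN, config.L, config.n0,
        masters, comps, phis,
        kp.phi_min, kp.eps1, kp.eps2, kp.baseline_factor,
        kp.p_mut, kp.ca,
        dissociation_table(config.L, kp), duplex_decay_table(config.L, kp),
        kp.min_pairs, config.no_cross_hybridization,
        kp.reverse_complement, kp.include_complements,
        0.0, 0.0, 0.0,
        equal_split(config.n0, config.T),
        np.zeros(4, np.int64),
        config.max_repl_events, config.survival_cadence, cap,
        core_seed)
    return TrajectoryRecord(
        make_samples_frame(out_master, out_extra, out_time), master_set,
        params, _counters_dict(counters))


def _counters_dict(counters: np.ndarray) -> dict:
    return {
        "total_events": int(counters[0]),
        "rejected_associations": int(counters[1]),
        "infeasible_replications": int(counters[2]),
        "truncated": int(counters[3]),
        "replication_events": int(counters[4]),
    }


def _run_reference(config, master_set, core_seed, params) -> TrajectoryRecord:
    """Same run through the pure-Python direct-method engine (small scales
    only; used for cross-validation)."""
    from .ssa import HaltSimulation

    kp = config.kinetics
    rules = MoranRules(master_set, kp, config.n0,
                       config.no_cross_hybridization)
    state = initial_state(master_set, config.n0)
    rng = np.random.default_rng(core_seed)
    sim = Simulation(rules, state, rng)
    rows_master, rows_extra, rows_time = [], [], []

    def record():
        counts = [0] * master_set.T
        targets = {}
        for i, (m, c) in enumerate(zip(master_set.masters,
                                       master_set.complements)):
            targets.setdefault(m, i)
            targets.setdefault(c, i)
        for s, k in state.simplex.items():
            if s in targets:
                counts[targets[s]] += k
        for (a, b), k in state.duplexes.items():
            if a in targets:
                counts[targets[a]] += k
            if b in targets:
                counts[targets[b]] += k
        rows_master.append(counts)
        rows_extra.append([state.replication_events, state.n_simplex,
                           state.n_duplex_strands, 0, 0, 0, 0])
        rows_time.append(state.time)

    record()
    next_sample = config.survival_cadence
    total_events = 0
    truncated = 0
    while state.replication_events < config.max_repl_events:
        try:
            sim.step()
        except HaltSimulation:
            truncated = 1
            break
        total_events += 1
        if state.replication_events >= next_sample:
            record()
            next_sample += config.survival_cadence
    counters = np.array([total_events, 0, 0, truncated,
                         state.replication_events], np.int64)
    return TrajectoryRecord(
        make_samples_frame(np.array(rows_master, np.int64),
                           np.array(rows_extra, np.int64),
                           np.array(rows_time, float)),
        master_set, params, _counters_dict(counters))
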