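"""Exact stochastic simulation (Gillespie direct method) over replicator
populations.

The engine is generic: a :class:`ModelRules` object enumerates the reaction
channels implied by a :class:`PopulationState` and applies the state change
when a channel fires.  Channels are kept in an insertion-ordered registry
with cached propensities; after an event only the channels touching the
affected species are recomputed, and :meth:`Simulation.audit` verifies the
incremental table against a from-scratch recomputation.

This is the reference implementation: transparent, exhaustively tested, and
convenient for small systems.  Production runs go through the compiled core
(:mod:`pararep._core`), which realizes the same stochastic process and is
cross-validated against this engine in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from .kinetics import (KineticParams, binding_energy, association_allowed,
                       dissociation_table, duplex_decay_table, mutate_copy,
                       replicability)
from .sequences import MasterSet

RESOURCE_BASES = ("A", "U", "G", "C")


def pair_key(a: str, b: str) -> tuple[str, str]:
    """Canonical unordered key for a duplex of strands *a* and *b*."""
    return (a, b) if a <= b else (b, a)


@dataclass
class PopulationState:
    """Multisets of simplex strands and duplexes, plus (chemostat only) the
    four nucleotide resource pools."""

    simplex: dict[str, int] = field(default_factory=dict)
    duplexes: dict[tuple[str, str], int] = field(default_factory=dict)
    resources: dict[str, int] | None = None
    time: float = 0.0
    replication_events: int = 0

    @property
    def n_simplex(self) -> int:
        return sum(self.simplex.values())

    @property
    def n_duplexes(self) -> int:
        return sum(self.duplexes.values())

    @property
    def n_duplex_strands(self) -> int:
        return 2 * self.n_duplexes

    @property
    def N(self) -> int:
        """Total strand count (duplexes hold two strands)."""
        return self.n_simplex + self.n_duplex_strands

    def add_simplex(self, s: str, k: int = 1) -> None:
        self.simplex[s] = self.simplex.get(s, 0) + k
        if self.simplex[s] < 0:
            raise ValueError(f"negative simplex count for {s}")
        if self.simplex[s] == 0:
            del self.simplex[s]

    def add_duplex(self, a: str, b: str, k: int = 1) -> None:
        key = pair_key(a, b)
        self.duplexes[key] = self.duplexes.get(key, 0) + k
        if self.duplexes[key] < 0:
            raise ValueError(f"negative duplex count for {key}")
        if self.duplexes[key] == 0:
            del self.duplexes[key]

    def copy(self) -> "PopulationState":
        return PopulationState(dict(self.simplex), dict(self.duplexes),
                               None if self.resources is None
                               else dict(self.resources),
                               self.time, self.replication_events)


@dataclass
class ReactionChannel:
    """One SSA event type: kind, participants and rate constant.  The
    combinatorial count ``h`` and propensity ``alpha = h * c`` are functions
    of the current state."""

    kind: str
    participants: object  # seq str | (a, b) pair | resource base | None
    rate_constant: float

    @property
    def key(self) -> tuple:
        return (self.kind, self.participants)


def combinatorial_count(channel: ReactionChannel, state: PopulationState) -> int:
    """Number of combinatorially distinct molecular configurations able to
    undergo the reaction of *channel* in *state*."""
    kind, p = channel.kind, channel.participants
    if kind == "replication":
        return state.simplex.get(p, 0)
    if kind == "association":
        a, b = p
        if a == b:
            n = state.simplex.get(a, 0)
            return n * (n - 1) // 2
        return state.simplex.get(a, 0) * state.simplex.get(b, 0)
    if kind in ("dissociation", "decay_ds", "outflow_ds"):
        return state.duplexes.get(p, 0)
    if kind in ("decay_ss", "outflow_ss"):
        return state.simplex.get(p, 0)
    if kind == "outflow_r":
        return state.resources.get(p, 0)
    if kind == "inflow":
        return 1
    raise ValueError(f"unknown channel kind {kind!r}")


def propensity(channel: ReactionChannel, state: PopulationState) -> float:
    return combinatorial_count(channel, state) * channel.rate_constant


def sample_waiting_time(total_propensity: float, rng: np.random.Generator) -> float:
    """Exponential waiting time ``ln(1/r)/sum(alpha)``; raises on a dead
    state (no reaction possible)."""
    if total_propensity <= 0:
        raise HaltSimulation("total propensity is zero")
    r = rng.random()
    while r == 0.0:  # open interval (0, 1)
        r = rng.random()
    return math.log(1.0 / r) / total_propensity


def select_channel(channels: Iterable[ReactionChannel],
                   propensities: Iterable[float],
                   rng: np.random.Generator) -> ReactionChannel:
    """Direct-method channel choice: one uniform draw against the running
    cumulative propensity sum, channels scanned in stable order."""
    channels = list(channels)
    alphas = np.fromiter(propensities, dtype=float, count=len(channels))
    total = alphas.sum()
    if total <= 0:
        raise HaltSimulation("total propensity is zero")
    u = rng.random() * total
    acc = 0.0
    for ch, a in zip(channels, alphas):
        acc += a
        if u < acc:
            return ch
    return channels[-1]  # guard against floating-point shortfall


class HaltSimulation(RuntimeError):
    """No reaction channel can fire."""


class ModelRules:
    """Interface: channel enumeration and event application for one model."""

    def channels_for_state(self, state: PopulationState) -> Iterator[ReactionChannel]:
        raise NotImplementedError

    def channels_involving(self, state: PopulationState,
                           key: object) -> Iterator[ReactionChannel]:
        raise NotImplementedError

    def apply(self, channel: ReactionChannel, state: PopulationState,
              rng: np.random.Generator) -> set:
        """Fire *channel*; return the set of affected species keys."""
        raise NotImplementedError


class _SequenceRulesBase(ModelRules):
    """Shared machinery: replicability/pair caches and the three core
    reactions (replication product handling differs per model)."""

    def __init__(self, ms: MasterSet, kp: KineticParams,
                 no_cross_hybridization: bool = False):
        self.ms = ms
        self.kp = kp
        self.no_cross_hybridization = no_cross_hybridization
        self._cd = dissociation_table(ms.L, kp)
        self._cr_cache: dict[str, float] = {}
        self._pair_cache: dict[tuple[str, str], tuple[bool, int]] = {}
        # sequence -> (type index, role) for the cross-hybridization filter
        self._class = {m: (i, 0) for i, m in enumerate(ms.masters)}
        self._class.update({c: (i, 1) for i, c in enumerate(ms.complements)})

    def cr(self, s: str) -> float:
        try:
            return self._cr_cache[s]
        except KeyError:
            v = replicability(s, self.ms, self.kp)
            self._cr_cache[s] = v
            return v

    def pair_info(self, a: str, b: str) -> tuple[bool, int]:
        """(association allowed, binding energy) for a strand pair."""
        key = pair_key(a, b)
        try:
            return self._pair_cache[key]
        except KeyError:
            e = binding_energy(key[0], key[1], self.kp.reverse_complement)
            ok = association_allowed(e, self.kp.min_pairs)
            if ok and self.no_cross_hybridization:
                ca, cb = self._class.get(key[0]), self._class.get(key[1])
                if ca is not None and cb is not None:
                    # only a master with its own complement may hybridize
                    ok = ca[0] == cb[0] and ca[1] != cb[1]
            info = (ok, e.eb)
            self._pair_cache[key] = info
            return info

    # -- channel enumeration ----------------------------------------------

    def _core_channels_for_state(self, state) -> Iterator[ReactionChannel]:
        seqs = list(state.simplex)
        for s in seqs:
            if self.cr(s) > 0:
                yield ReactionChannel("replication", s, self.cr(s))
        for i, a in enumerate(seqs):
            for b in seqs[i:]:
                if a == b and state.simplex[a] < 2:
                    continue
                ok, _ = self.pair_info(a, b)
                if ok:
                    yield ReactionChannel("association", pair_key(a, b), self.kp.ca)
        for key in state.duplexes:
            _, eb = self.pair_info(*key)
            yield ReactionChannel("dissociation", key, self._cd[eb])

    def _core_channels_involving(self, state, key) -> Iterator[ReactionChannel]:
        if isinstance(key, tuple):
            if key in state.duplexes:
                _, eb = self.pair_info(*key)
                yield ReactionChannel("dissociation", key, self._cd[eb])
            return
        if key not in state.simplex:
            return
        s = key
        if self.cr(s) > 0:
            yield ReactionChannel("replication", s, self.cr(s))
        for b in state.simplex:
            if b == s and state.simplex[s] < 2:
                continue
            ok, _ = self.pair_info(s, b)
            if ok:
                yield ReactionChannel("association", pair_key(s, b), self.kp.ca)

    # -- core reaction application ----------------------------------------

    def _fire_association(self, channel, state) -> set:
        a, b = channel.participants
        state.add_simplex(a, -1)
        state.add_simplex(b, -1)
        state.add_duplex(a, b, +1)
        return {a, b, channel.participants}

    def _fire_dissociation(self, channel, state) -> set:
        a, b = channel.participants
        state.add_duplex(a, b, -1)
        state.add_simplex(a, +1)
        state.add_simplex(b, +1)
        return {a, b, channel.participants}

    def _make_product(self, template: str, state, rng) -> tuple[str, bool]:
        """Mutated complementary copy and whether it duplexes with the
        template (fewer than two WC pairs leaves the product free)."""
        product = mutate_copy(template, self.kp.p_mut, rng,
                              self.kp.reverse_complement)
        ok, _ = self.pair_info(template, product)
        return product, ok


class MoranRules(_SequenceRulesBase):
    """Constant-population (Moran) model: replication, association and
    dissociation only; each newborn strand replaces a randomly chosen
    strand, keeping the total count at ``n0`` (transiently ``n0 - 1`` after
    a duplex-resident victim is removed)."""

    def __init__(self, ms, kp, n0: int, no_cross_hybridization: bool = False):
        super().__init__(ms, kp, no_cross_hybridization)
        self.n0 = n0

    def channels_for_state(self, state):
        yield from self._core_channels_for_state(state)

    def channels_involving(self, state, key):
        yield from self._core_channels_involving(state, key)

    def apply(self, channel, state, rng):
        if channel.kind == "association":
            return self._fire_association(channel, state)
        if channel.kind == "dissociation":
            return self._fire_dissociation(channel, state)
        if channel.kind == "replication":
            return self.fire_replication(state, channel.participants, rng)
        raise ValueError(channel.kind)

    def fire_replication(self, state, template: str, rng) -> set:
        if state.simplex.get(template, 0) < 1:
            raise ValueError(f"template {template} not present as simplex")
        n_pre = state.N
        product, duplexed = self._make_product(template, state, rng)
        affected = {template, product}
        if duplexed:
            state.add_simplex(template, -1)
            state.add_duplex(template, product, +1)
            affected.add(pair_key(template, product))
        else:
            state.add_simplex(product, +1)
        state.replication_events += 1
        if n_pre < self.n0:
            return affected  # replacement skipped until size is restored
        affected |= self._remove_victim(state, template, product, duplexed, rng)
        return affected

    def _remove_victim(self, state, template, product, duplexed, rng) -> set:
        """Delete one strand chosen uniformly among all strands except the
        template and the newborn product; a duplex-resident victim takes its
        whole duplex with it."""
        newborn = pair_key(template, product) if duplexed else None
        eligible = []  # (kind, key, weight)
        for s, n in state.simplex.items():
            w = n
            if not duplexed:
                if s == template:
                    w -= 1
                if s == product:
                    w -= 1
            if w > 0:
                eligible.append(("simplex", s, w))
        for key, n in state.duplexes.items():
            w = 2 * n - (2 if key == newborn else 0)
            if w > 0:
                eligible.append(("duplex", key, w))
        total = sum(w for _, _, w in eligible)
        if total <= 0:
            return set()
        u = rng.integers(0, total)
        acc = 0
        for kind, key, w in eligible:
            acc += w
            if u < acc:
                if kind == "simplex":
                    state.add_simplex(key, -1)
                    return {key}
                state.add_duplex(*key, k=-1)
                return {key[0], key[1], key}
        raise AssertionError("victim scan fell through")


class ChemostatRules(_SequenceRulesBase):
    """Open-system model: replication consumes explicit monomer pools;
    monomers flow in at ``c_in`` per base; simplexes and duplexes decay;
    all molecular species (simplexes, duplexes, monomers) flow out at
    ``c_out``.  Replication channels are gated on every pool holding at
    least ``L`` monomers, which guarantees feasibility of any product."""

    def __init__(self, ms, kp, c_in: float, c_out: float,
                 no_cross_hybridization: bool = False):
        super().__init__(ms, kp, no_cross_hybridization)
        self.c_in = c_in
        self.c_out = c_out
        self._cdds = duplex_decay_table(ms.L, kp)
        self.infeasible_replications = 0

    def pools_sufficient(self, state) -> bool:
        return all(state.resources.get(b, 0) >= self.ms.L
                   for b in RESOURCE_BASES)

    def channels_for_state(self, state):
        if self.pools_sufficient(state):
            for s in state.simplex:
                if self.cr(s) > 0:
                    yield ReactionChannel("replication", s, self.cr(s))
        yield from (ch for ch in self._core_channels_for_state(state)
                    if ch.kind != "replication")
        for b in RESOURCE_BASES:
            yield ReactionChannel("inflow", b, self.c_in)
            if state.resources.get(b, 0) > 0:
                yield ReactionChannel("outflow_r", b, self.c_out)
        for s in state.simplex:
            yield ReactionChannel("decay_ss", s, self.kp.c_decay_ss)
            yield ReactionChannel("outflow_ss", s, self.c_out)
        for key in state.duplexes:
            _, eb = self.pair_info(*key)
            yield ReactionChannel("decay_ds", key, self._cdds[eb])
            yield ReactionChannel("outflow_ds", key, self.c_out)

    def channels_involving(self, state, key):
        if key == "GATE":
            # the monomer-sufficiency gate flipped: all replication channels
            if self.pools_sufficient(state):
                for s in state.simplex:
                    if self.cr(s) > 0:
                        yield ReactionChannel("replication", s, self.cr(s))
            return
        if key in RESOURCE_BASES:
            yield ReactionChannel("inflow", key, self.c_in)
            if state.resources.get(key, 0) > 0:
                yield ReactionChannel("outflow_r", key, self.c_out)
            return
        if isinstance(key, tuple):
            if key in state.duplexes:
                _, eb = self.pair_info(*key)
                yield ReactionChannel("dissociation", key, self._cd[eb])
                yield ReactionChannel("decay_ds", key, self._cdds[eb])
                yield ReactionChannel("outflow_ds", key, self.c_out)
            return
        if key in state.simplex:
            gate = self.pools_sufficient(state)
            for ch in self._core_channels_involving(state, key):
                if ch.kind != "replication" or gate:
                    yield ch
            yield ReactionChannel("decay_ss", key, self.kp.c_decay_ss)
            yield ReactionChannel("outflow_ss", key, self.c_out)

    def apply(self, channel, state, rng):
        kind = channel.kind
        if kind == "association":
            return self._fire_association(channel, state)
        if kind == "dissociation":
            return self._fire_dissociation(channel, state)
        if kind == "replication":
            return self.fire_replication(state, channel.participants, rng)
        if kind == "inflow":
            state.resources[channel.participants] = (
                state.resources.get(channel.participants, 0) + 1)
            return self._resource_affected(channel.participants)
        if kind == "outflow_r":
            state.resources[channel.participants] -= 1
            return self._resource_affected(channel.participants)
        if kind in ("decay_ss", "outflow_ss"):
            state.add_simplex(channel.participants, -1)
            return {channel.participants}
        if kind in ("decay_ds", "outflow_ds"):
            a, b = channel.participants
            state.add_duplex(a, b, -1)
            return {channel.participants}
        raise ValueError(kind)

    def _resource_affected(self, base: str) -> set:
        # resource changes can flip the replication gate; callers refresh it
        return {base, "GATE"}

    def fire_replication(self, state, template: str, rng) -> set:
        if state.simplex.get(template, 0) < 1:
            raise ValueError(f"template {template} not present as simplex")
        product, duplexed = self._make_product(template, state, rng)
        need: dict[str, int] = {}
        for b in product:
            need[b] = need.get(b, 0) + 1
        if any(state.resources.get(b, 0) < k for b, k in need.items()):
            # cannot happen behind the >= L gate; kept as an audited no-op
            self.infeasible_replications += 1
            return set()
        for b, k in need.items():
            state.resources[b] -= k
        affected = {template, product, "GATE"} | set(need)
        if duplexed:
            state.add_simplex(template, -1)
            state.add_duplex(template, product, +1)
            affected.add(pair_key(template, product))
        else:
            state.add_simplex(product, +1)
        state.replication_events += 1
        return affected


@dataclass
class EventRecord:
    time: float
    kind: str
    participants: object


class Simulation:
    """Direct-method SSA with an insertion-ordered channel registry and
    incremental propensity updates."""

    def __init__(self, rules: ModelRules, state: PopulationState,
                 rng: np.random.Generator):
        self.rules = rules
        self.state = state
        self.rng = rng
        self.channels: dict[tuple, ReactionChannel] = {}
        self.alphas: dict[tuple, float] = {}
        for ch in rules.channels_for_state(state):
            self._insert(ch)

    def _insert(self, ch: ReactionChannel) -> None:
        a = propensity(ch, self.state)
        if a > 0:
            self.channels[ch.key] = ch
            self.alphas[ch.key] = a
        else:
            self.channels.pop(ch.key, None)
            self.alphas.pop(ch.key, None)

    def total_propensity(self) -> float:
        return sum(self.alphas.values())

    def propensity_table(self) -> dict[tuple, float]:
        return dict(self.alphas)

    def _refresh(self, affected: set) -> None:
        stale = [key for key, ch in self.channels.items()
                 if _touches(ch, affected)]
        for key in stale:
            del self.channels[key]
            del self.alphas[key]
        for a in affected:
            for ch in self.rules.channels_involving(self.state, a):
                self._insert(ch)

    def step(self) -> EventRecord:
        """Fire one reaction: sample the waiting time, select a channel,
        apply it, and refresh only the affected channels."""
        total = self.total_propensity()
        tau = sample_waiting_time(total, self.rng)
        ch = select_channel(self.channels.values(), self.alphas.values(),
                            self.rng)
        self.state.time += tau
        affected = self.rules.apply(ch, self.state, self.rng)
        self._refresh(affected)
        return EventRecord(self.state.time, ch.kind, ch.participants)

    def audit(self, atol: float = 1e-9) -> None:
        """Verify the incremental propensity table against a brute-force
        recomputation from the current state."""
        fresh = {}
        for ch in self.rules.channels_for_state(self.state):
            a = propensity(ch, self.state)
            if a > 0:
                fresh[ch.key] = a
        if set(fresh) != set(self.alphas):
            missing = set(fresh) - set(self.alphas)
            extra = set(self.alphas) - set(fresh)
            raise AssertionError(
                f"channel registry drift: missing={missing} extra={extra}")
        for key, a in fresh.items():
            if abs(a - self.alphas[key]) > atol:
                raise AssertionError(
                    f"propensity drift for {key}: {self.alphas[key]} != {a}")


def _touches(ch: ReactionChannel, affected: set) -> bool:
    p = ch.participants
    if ch.kind == "replication" and "GATE" in affected:
        return True
    if isinstance(p, tuple):
        if ch.kind == "association":
            # h = n_a * n_b depends on both constituent simplex counts
            return p in affected or p[0] in affected or p[1] in affected
        # duplex-count channels depend only on the duplex species itself
        return p in affected
    return p in affected
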