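import itertools
import math

import numpy as np
import pytest

from pararep.constant_population import (ConstantPopulationConfig,
                                         initial_state, run_constant)
from pararep.kinetics import KineticParams
from pararep.sequences import generate_master_set
from pararep.ssa import (ChemostatRules, HaltSimulation, MoranRules,
                         PopulationState, ReactionChannel, Simulation,
                         combinatorial_count, pair_key, propensity,
                         sample_waiting_time, select_channel)


def brute_force_configurations(channel, state):
    """Independent oracle: enumerate the distinct molecular configurations
    compatible with a channel by explicit expansion of the multisets."""
    kind, p = channel.kind, channel.participants
    if kind == "replication":
        return state.simplex.get(p, 0)
    if kind == "association":
        strands = list(itertools.chain.from_iterable(
            [s] * k for s, k in state.simplex.items()))
        a, b = p
        return sum(1 for i in range(len(strands))
                   for j in range(i + 1, len(strands))
                   if pair_key(strands[i], strands[j]) == p)
    if kind == "dissociation":
        return state.duplexes.get(p, 0)
    raise ValueError(kind)


def test_combinatorial_count_examples():
    state = PopulationState()
    state.add_simplex("A" * 10, 3)
    state.add_simplex("U" * 10, 5)
    state.add_simplex("G" * 10, 2)
    self_assoc = ReactionChannel("association",
                                 pair_key("A" * 10, "A" * 10), 1.0)
    assert combinatorial_count(self_assoc, state) == 3  # C(3,2)
    cross = ReactionChannel("association", pair_key("G" * 10, "U" * 10), 1.0)
    assert combinatorial_count(cross, state) == 10
    rep = ReactionChannel("replication", "U" * 10, 0.005)
    assert combinatorial_count(rep, state) == 5


def test_combinatorial_count_matches_brute_force(rng):
    state = PopulationState()
    seqs = ["".join("AUGC"[i] for i in rng.integers(0, 4, 10))
            for _ in range(5)]
    for s in seqs:
        state.add_simplex(s, int(rng.integers(1, 6)))
    state.add_duplex(seqs[0], seqs[1], 2)
    for a in seqs:
        for b in seqs:
            ch = ReactionChannel("association", pair_key(a, b), 1.0)
            assert combinatorial_count(ch, state) == \
                brute_force_configurations(ch, state)
        ch = ReactionChannel("replication", a, 1.0)
        assert combinatorial_count(ch, state) == \
            brute_force_configurations(ch, state)


class _FixedRandom:
    def __init__(self, value):
        self.value = value

    def random(self):
        return self.value


def test_sample_waiting_time_plugin():
    # total propensity 2, r = e^-1  ->  tau = ln(1/r)/2 = 0.5
    assert sample_waiting_time(2.0, _FixedRandom(math.exp(-1))) == \
        pytest.approx(0.5)


def test_sample_waiting_time_statistics(rng):
    n = 100_000
    draws = np.array([sample_waiting_time(4.0, rng) for _ in range(n)])
    assert (draws > 0).all()
    se = draws.std(ddof=1) / math.sqrt(n)
    assert abs(draws.mean() - 0.25) < 4 * se


def test_sample_waiting_time_halts_on_dead_state(rng):
    with pytest.raises(HaltSimulation):
        sample_waiting_time(0.0, rng)


def test_select_channel_frequencies(rng):
    chans = [ReactionChannel("replication", "a", 1.0),
             ReactionChannel("replication", "b", 3.0),
             ReactionChannel("replication", "c", 0.0)]
    alphas = [1.0, 3.0, 0.0]
    n = 50_000
    counts = {"a": 0, "b": 0, "c": 0}
    for _ in range(n):
        counts[select_channel(chans, alphas, rng).participants] += 1
    assert counts["c"] == 0
    p = counts["b"] / n
    se = math.sqrt(0.75 * 0.25 / n)
    assert abs(p - 0.75) < 4 * se
    only = [ReactionChannel("dissociation", ("x", "y"), 2.0)]
    assert select_channel(only, [2.0], rng) is only[0]


def _moran_sim(seed, n0=40, p_mut=0.05):
    ms = generate_master_set(4, 10, seed=11)
    kp = KineticParams(p_mut=p_mut)
    rules = MoranRules(ms, kp, n0)
    state = initial_state(ms, n0)
    rng = np.random.default_rng(seed)
    return Simulation(rules, state, rng)


def test_association_and_dissociation_state_updates():
    sim = _moran_sim(0)
    state = sim.state
    a, b = list(state.simplex)[:2]
    ch = ReactionChannel("association", pair_key(a, b), 1.0)
    na, nb, nd = state.simplex[a], state.simplex[b], state.n_duplexes
    sim.rules.apply(ch, state, sim.rng)
    assert state.simplex[a] == na - 1
    assert state.simplex[b] == nb - 1
    assert state.duplexes[pair_key(a, b)] == 1
    sim.rules.apply(ReactionChannel("dissociation", pair_key(a, b), 1.0),
                    state, sim.rng)
    assert state.simplex[a] == na and state.simplex[b] == nb
    assert state.n_duplexes == nd


def test_incremental_propensities_match_recomputation_moran():
    sim = _moran_sim(1)
    for step in range(300):
        sim.step()
        if step % 10 == 0:
            sim.audit()
    sim.audit()


def test_incremental_propensities_match_recomputation_chemostat():
    ms = generate_master_set(3, 10, seed=12)
    kp = KineticParams(p_mut=0.05, f=0.5)
    rules = ChemostatRules(ms, kp, c_in=0.5, c_out=1e-3)
    state = PopulationState(resources={b: 40 for b in "AUGC"})
    for m in ms.masters:
        state.add_simplex(m, 8)
    sim = Simulation(rules, state, np.random.default_rng(2))
    for step in range(300):
        sim.step()
        if step % 10 == 0:
            sim.audit()
    sim.audit()


class _PureBirthRules:
    """Minimal model: one species replicating at rate c (no duplexes)."""

    def __init__(self, c):
        self.c = c

    def channels_for_state(self, state):
        for s in state.simplex:
            yield ReactionChannel("replication", s, self.c)

    def channels_involving(self, state, key):
        if key in state.simplex:
            yield ReactionChannel("replication", key, self.c)

    def apply(self, channel, state, rng):
        state.add_simplex(channel.participants, 1)
        return {channel.participants}


def test_birth_process_matches_exponential_mean(rng):
    """For a linear birth process the SSA ensemble mean must follow
    n0 * exp(c*t) — the classic exactness check for Gillespie dynamics."""
    n0, c, t_end, reps = 4, 1.0, 1.0, 600
    finals = []
    for _ in range(reps):
        state = PopulationState()
        state.add_simplex("A" * 10, n0)
        sim = Simulation(_PureBirthRules(c), state, rng)
        while True:
            before = state.n_simplex
            sim.step()
            if state.time > t_end:  # event landed past the horizon
                finals.append(before)
                break
    finals = np.asarray(finals, float)
    expected = n0 * math.exp(c * t_end)
    se = finals.std(ddof=1) / math.sqrt(reps)
    assert abs(finals.mean() - expected) < 3 * se


def test_fast_core_is_deterministic_per_seed():
    cfg = ConstantPopulationConfig(n0=200, max_repl_events=500,
                                   survival_cadence=25,
                                   survival_window=125)
    t1 = run_constant(cfg, seed=9)
    t2 = run_constant(cfg, seed=9)
    assert t1.samples.equals(t2.samples)
    t3 = run_constant(cfg, seed=10)
    assert not t1.samples.equals(t3.samples)


def test_fast_core_consistent_with_reference_engine():
    """The compiled core and the pure-Python direct-method engine realize
    the same stochastic process: ensemble statistics must agree."""
    cfg = ConstantPopulationConfig(n0=60, max_repl_events=200,
                                   survival_cadence=10, survival_window=50)
    reps = 12
    stats = {"fast": [], "reference": []}
    for engine in stats:
        for s in range(reps):
            tr = run_constant(cfg, seed=100 + s, engine=engine)
            last = tr.samples.iloc[-1]
            chi = (last["n_simplex"] - last["n_duplex_strands"]) / last["N"]
            msum = tr.frequencies().iloc[-1].sum()
            stats[engine].append((chi, msum))
    fast = np.array(stats["fast"])
    ref = np.array(stats["reference"])
    for col in range(2):
        se = math.sqrt(fast[:, col].var(ddof=1) / reps
                       + ref[:, col].var(ddof=1) / reps)
        assert abs(fast[:, col].mean() - ref[:, col].mean()) < \
            4 * se + 0.05
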