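import numpy as np
import pytest

from pararep.chemostat import (ChemostatConfig, fire_replication_chemostat,
                               run_chemostat)
from pararep.kinetics import KineticParams
from pararep.sequences import MasterSet, generate_master_set
from pararep.ssa import ChemostatRules, PopulationState, Simulation


def _make_sim(seed=0, c_in=0.5, c_out=1e-3, copies=8, pools=60, T=3,
              p_mut=0.05, f=0.5):
    ms = generate_master_set(T, 10, seed=31)
    kp = KineticParams(p_mut=p_mut, f=f)
    rules = ChemostatRules(ms, kp, c_in, c_out)
    state = PopulationState(resources={b: pools for b in "AUGC"})
    for m in ms.masters:
        state.add_simplex(m, copies)
    return Simulation(rules, state, np.random.default_rng(seed)), ms, kp


def test_event_ledger_per_kind():
    """Strand count changes only by +1 (replication), -1 (simplex
    decay/outflow), -2 (duplex decay/outflow) or 0; monomer pools change
    exactly by inflow - consumption - outflow."""
    sim, ms, kp = _make_sim()
    state = sim.state
    for _ in range(600):
        n_before = state.N
        r_before = sum(state.resources.values())
        ev = sim.step()
        dn = state.N - n_before
        dr = sum(state.resources.values()) - r_before
        if ev.kind == "replication":
            assert dn == 1 and dr == -ms.L
        elif ev.kind in ("decay_ss", "outflow_ss"):
            assert dn == -1 and dr == 0
        elif ev.kind in ("decay_ds", "outflow_ds"):
            assert dn == -2 and dr == 0
        elif ev.kind == "inflow":
            assert dn == 0 and dr == 1
        elif ev.kind == "outflow_r":
            assert dn == 0 and dr == -1
        else:  # association / dissociation shuffle strands between states
            assert dn == 0 and dr == 0


def test_replication_consumes_product_composition():
    ms = MasterSet(["G" * 10], ["C" * 10], [0.005])
    kp = KineticParams(p_mut=0.0)
    state = PopulationState(resources={b: 20 for b in "AUGC"})
    state.add_simplex("G" * 10, 3)
    fire_replication_chemostat(state, "G" * 10, ms, kp,
                               np.random.default_rng(1))
    # the realized product is the all-C complement: only the C pool pays
    assert state.resources["C"] == 10
    assert state.resources["A"] == state.resources["U"] == \
        state.resources["G"] == 20
    assert state.duplexes[("C" * 10, "G" * 10)] == 1


def test_replication_gated_on_pool_sufficiency():
    sim, ms, kp = _make_sim(pools=5)  # below L = 10
    kinds = {ch.kind for ch in
             sim.rules.channels_for_state(sim.state)}
    assert "replication" not in kinds
    sim2, *_ = _make_sim(pools=60)
    kinds2 = {ch.kind for ch in sim2.rules.channels_for_state(sim2.state)}
    assert "replication" in kinds2


def test_inflow_only_growth_rate():
    """Without replicators each pool accumulates at rate c_in in
    expectation."""
    ms = generate_master_set(1, 10, seed=32)
    rules = ChemostatRules(ms, KineticParams(), c_in=2.0, c_out=0.0)
    state = PopulationState(resources={b: 0 for b in "AUGC"})
    sim = Simulation(rules, state, np.random.default_rng(7))
    while state.time < 50.0:
        sim.step()
    total = sum(state.resources.values())
    expected = 4 * 2.0 * 50.0  # 4 pools x c_in x t; Poisson sd = sqrt(400)
    assert abs(total - expected) < 5 * np.sqrt(expected)


def test_closed_system_strand_and_monomer_ledger():
    """With inflow, decay and outflow all off, every replication adds
    exactly one strand and consumes exactly L monomers: the fast core's
    totals must balance to the event count."""
    ms = MasterSet(["G" * 10], ["C" * 10], [0.005])
    kp = KineticParams(p_mut=0.0, c_decay_ss=0.0)
    cfg = ChemostatConfig(T=1, kinetics=kp, c_in=0.0, c_out=0.0,
                          init_copies_per_type=10, init_resources=100_000,
                          max_repl_events=1000, survival_cadence=50,
                          survival_window=250)
    tr = run_chemostat(cfg, seed=13, master_set=ms)
    last = tr.samples.iloc[-1]
    n_repl = tr.counters["replication_events"]
    assert last["N"] == 10 + n_repl
    consumed = 4 * 100_000 - sum(last[f"R_{b}"] for b in "AUGC")
    assert consumed == 10 * n_repl


def test_duplex_dominated_regime_has_negative_chi():
    cfg = ChemostatConfig(kinetics=KineticParams(f=1.0),
                          c_in=0.1, c_out=1e-5, init_copies_per_type=30,
                          max_repl_events=1500, survival_cadence=150,
                          survival_window=750)
    tr = run_chemostat(cfg, seed=14)
    assert tr.final_chi() < 0


def test_config_validation():
    with pytest.raises(ValueError):
        ChemostatConfig(c_in=-1.0).validate()
    with pytest.raises(ValueError):
        ChemostatConfig(c_out=0.0).validate()  # needs explicit pools
    cfg = ChemostatConfig(init_resources=1000, c_out=0.0)
    cfg.validate()
    assert cfg.initial_pools().tolist() == [1000] * 4


def test_initial_pools_default_to_inflow_balance():
    cfg = ChemostatConfig(c_in=1.0, c_out=1e-5)
    assert cfg.initial_pools().tolist() == [100_000] * 4
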