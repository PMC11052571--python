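import math

import numpy as np
import pytest

from pararep.kinetics import (DuplexEnergy, KineticParams, association_allowed,
                              binding_energy, calibrate_kappa,
                              dissociation_probability, dissociation_table,
                              duplex_decay_rate, mutate_copy, replicability)
from pararep.sequences import complement, generate_master_set


class TestReplicability:
    def test_exact_master_gets_its_phi(self, master_set, kp):
        for i, m in enumerate(master_set.masters):
            assert replicability(m, master_set, kp) == pytest.approx(
                0.005 + i * 0.005)

    def test_one_error_copy_of_master5(self, master_set, kp):
        # phi_5 = 0.025; a one-error copy replicates at 0.2 * phi_5 = 0.005
        m = master_set.masters[4]
        mutant = ("A" if m[0] != "A" else "U") + m[1:]
        got = replicability(mutant, master_set, kp)
        # the highest value over all types applies; it is at least 0.2*phi_5
        assert got >= 0.2 * 0.025 - 1e-12
        single = generate_master_set(1, 10, seed=1, phi_min=0.025)
        mm = single.masters[0]
        mut = ("A" if mm[0] != "A" else "U") + mm[1:]
        assert replicability(mut, single, kp) == pytest.approx(0.2 * 0.025)

    def test_distant_sequence_gets_baseline(self, kp):
        ms = generate_master_set(1, 10, seed=2)
        far = complement(ms.masters[0], reverse=False)  # distance 10 to master
        if min(
            sum(a != b for a, b in zip(far, ms.masters[0])),
            sum(a != b for a, b in zip(far, ms.complements[0])),
        ) > 2:
            assert replicability(far, ms, kp) == pytest.approx(0.05 * 0.005)

    def test_minus_strand_inherits_master_rate(self, master_set, kp):
        for i, c in enumerate(master_set.complements):
            assert replicability(c, master_set, kp) == pytest.approx(
                master_set.replicabilities[i])

    def test_plus_strand_only_mode(self, master_set):
        kp = KineticParams(include_complements=False)
        c = master_set.complements[0]
        dplus = min(sum(a != b for a, b in zip(c, m))
                    for m in master_set.masters)
        if dplus > 2:
            assert replicability(c, master_set, kp) == pytest.approx(
                0.05 * 0.005)

    def test_output_bounds(self, master_set, kp, rng):
        lo = 0.05 * kp.phi_min
        hi = 0.005 + 9 * 0.005
        for _ in range(100):
            s = "".join("AUGC"[i] for i in rng.integers(0, 4, 10))
            v = replicability(s, master_set, kp)
            assert lo - 1e-15 <= v <= hi + 1e-15


class TestBindingEnergy:
    def test_extremes(self):
        assert binding_energy("G" * 10, "C" * 10).eb == 20
        assert binding_energy("A" * 10, "U" * 10).eb == 10
        e = binding_energy("A" * 10, "A" * 10)
        assert e.n_pairs == 0 and e.eb == 0
        assert not association_allowed(e)

    def test_symmetry(self, rng):
        for _ in range(30):
            a = "".join("AUGC"[i] for i in rng.integers(0, 4, 10))
            b = "".join("AUGC"[i] for i in rng.integers(0, 4, 10))
            ea, eb_ = binding_energy(a, b), binding_energy(b, a)
            assert (ea.n_au, ea.n_gc) == (eb_.n_au, eb_.n_gc)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            binding_energy("AAA", "AAAA")

    def test_association_threshold_is_pair_count_not_energy(self):
        assert not association_allowed(DuplexEnergy(n_au=1, n_gc=0))
        assert not association_allowed(DuplexEnergy(n_au=0, n_gc=1))  # Eb=2
        assert association_allowed(DuplexEnergy(n_au=2, n_gc=0))


class TestDissociation:
    def test_calibrated_endpoints(self):
        assert dissociation_probability(20, convention="calibrated") == \
            pytest.approx(0.01)
        assert dissociation_probability(2, convention="calibrated") == \
            pytest.approx(0.6309, abs=1e-4)

    def test_normalized_matches_direct_summation(self):
        kappa = 0.15
        denom = sum(math.exp(-kappa * e) for e in range(2, 21))
        for eb in (2, 11, 20):
            assert dissociation_probability(eb, kappa, 10, "normalized") == \
                pytest.approx(math.exp(-kappa * eb) / denom)
        assert dissociation_probability(20, 0.15, 10, "normalized") == \
            pytest.approx(0.00993, abs=1e-5)

    def test_normalized_distribution_sums_to_one(self):
        total = sum(dissociation_probability(e, 0.15, 10, "normalized")
                    for e in range(2, 21))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_strictly_decreasing(self):
        for conv in ("calibrated", "normalized"):
            vals = [dissociation_probability(e, convention=conv)
                    for e in range(2, 21)]
            assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            dissociation_probability(1)
        with pytest.raises(ValueError):
            dissociation_probability(21)

    def test_calibrate_kappa_closed_form(self):
        assert calibrate_kappa(10, 0.01, "calibrated") == \
            pytest.approx(math.log(100) / 20)

    def test_calibrate_kappa_normalized_roundtrip(self):
        target = dissociation_probability(20, 0.15, 10, "normalized")
        assert calibrate_kappa(10, target, "normalized") == \
            pytest.approx(0.15, abs=1e-9)

    def test_calibrate_kappa_monotone(self):
        for conv in ("calibrated", "normalized"):
            k1 = calibrate_kappa(10, 0.01, conv)
            k2 = calibrate_kappa(10, 0.001, conv)
            assert k2 > k1


class TestDuplexDecay:
    def test_table_range_extremes(self):
        assert duplex_decay_rate(2, 1.0, 1e-4) == pytest.approx(6.4e-5)
        assert duplex_decay_rate(20, 0.01, 1e-4) == \
            pytest.approx(1.15e-8, rel=5e-3)

    def test_always_below_simplex_decay(self):
        for f in (0.01, 0.1, 0.5, 1.0):
            for eb in range(2, 21):
                assert duplex_decay_rate(eb, f, 1e-4) < 1e-4

    def test_monotone_in_eb(self):
        vals = [duplex_decay_rate(e, 0.5, 1e-4) for e in range(2, 21)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestMutateCopy:
    def test_zero_rate_gives_exact_complement(self, rng):
        s = "GAUCGGAUCC"
        assert mutate_copy(s, 0.0, rng) == complement(s)

    def test_full_rate_never_complementary(self, rng):
        s = "GAUCGGAUCC"
        comp = complement(s)
        for _ in range(20):
            out = mutate_copy(s, 1.0, rng)
            assert all(o != c for o, c in zip(out, comp))

    def test_empirical_substitution_rate(self, rng):
        s = "GAUCGGAUCC"
        comp = complement(s)
        p = 0.1
        n = 3000
        subs = sum(o != c for _ in range(n)
                   for o, c in zip(mutate_copy(s, p, rng), comp))
        total = n * len(s)
        se = math.sqrt(p * (1 - p) / total)
        assert abs(subs / total - p) < 4 * se


def test_kinetic_params_validation():
    with pytest.raises(ValueError):
        KineticParams(f=0.0)
    with pytest.raises(ValueError):
        KineticParams(f=1.5)
    with pytest.raises(ValueError):
        KineticParams(eps1=0.05, eps2=0.2)
    with pytest.raises(ValueError):
        KineticParams(p_mut=1.5)
    with pytest.raises(ValueError):
        KineticParams(diss_convention="boltzmann")


def test_dissociation_table_matches_table1_range(kp):
    table = dissociation_table(10, kp)
    assert table[2] == pytest.approx(0.6309, abs=1e-4)
    assert table[20] == pytest.approx(0.01)
    assert table[0] == 0.0 and table[1] == 0.0
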