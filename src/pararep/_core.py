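"""Compiled stochastic simulation core.

This module implements the same stochastic process as the reference engine
in :mod:`pararep.ssa` — exact Gillespie dynamics of replication,
association, dissociation and (in the chemostat) resource inflow, decay and
outflow — as a single numba-compiled event loop, so that runs with tens of
millions of SSA events complete in seconds.

Representation choices:

* sequences are packed into ``int64`` with two bits per base
  (``A=0, U=1, G=2, C=3``; the Watson-Crick partner of code ``x`` is
  ``x ^ 1``), so Hamming distances, complements and duplex pairing are a
  handful of integer operations;
* simplex species counts live in a dense array over the full sequence space
  (``4**L`` entries; L <= 12) plus an active-species list; duplex species
  are tracked in flat arrays behind an open-addressing hash on the
  canonical strand pair, compacted when extinct species accumulate;
* weighted channel selection (replication by ``c_r * n``, dissociation by
  ``c_d * n``, victim/decay/outflow by copy number) goes through Fenwick
  trees over the active-species and duplex slots, so every event costs
  O(log capacity) rather than a linear scan — essential once the mutant
  cloud holds hundreds of species;
* association fires through exact thinning: the total association
  propensity is ``ca * C(A, 2)`` over *all* simplex strand pairs and a
  sampled pair that cannot form a stable duplex (fewer than two WC pairs,
  or a pairing forbidden by the cross-hybridization filter) is a null event
  that advances time only.  By superposition/thinning of Poisson processes
  the law of the realized reactions is exactly that of the direct method
  restricted to stable pairs (cross-checked against the reference engine in
  the tests);
* running propensity sums and the float-weighted trees are refreshed from
  scratch periodically to keep floating-point drift negligible.  Mutable
  scalars shared with the helper closures live in two small arrays (``si``
  integers, ``sf`` floats) because numba closures may not rebind nonlocal
  scalars.

The RNG is numba's per-process generator, seeded at the top of every run,
so trajectories are bit-reproducible for a given seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: sample-row layout: event, n_simplex, n_duplex_strands, R_A, R_U, R_G, R_C
N_EXTRA_COLS = 7

MODE_MORAN = 0
MODE_CHEMOSTAT = 1

# truncation codes
OK = 0
HALTED = 1          # total propensity reached zero
OVERFLOW_SPECIES = 2
OVERFLOW_DUPLEX = 3
EVENT_CAP = 4       # hard total-event cap hit before the replication target

_CAP_BITS = 16
_CAP = 1 << _CAP_BITS          # slots for active simplex / duplex species

# indices into the shared scalar arrays
_N_ACT, _N_DUP, _A, _ND = 0, 1, 2, 3
_P_REP, _P_DISS, _P_DDS = 0, 1, 2


@njit(cache=True)
def _hamming(a, b, L):
    d = 0
    x = a ^ b
    for _ in range(L):
        if x & 3:
            d += 1
        x >>= 2
    return d


@njit(cache=True)
def _revcomp(s, L):
    out = 0
    for k in range(L):
        base = (s >> (2 * k)) & 3
        out |= (base ^ 1) << (2 * (L - 1 - k))
    return out


@njit(cache=True)
def _poscomp(s, L):
    out = 0
    for k in range(L):
        base = (s >> (2 * k)) & 3
        out |= (base ^ 1) << (2 * k)
    return out


@njit(cache=True)
def _bonds(a, b, L, use_revcomp):
    """(n_AU, n_GC) Watson-Crick pairs of the duplex in the fixed register."""
    n_au = 0
    n_gc = 0
    for k in range(L):
        xa = (a >> (2 * k)) & 3
        j = (L - 1 - k) if use_revcomp else k
        xb = (b >> (2 * j)) & 3
        if xb == xa ^ 1:
            if xa < 2:
                n_au += 1
            else:
                n_gc += 1
    return n_au, n_gc


# ---- Fenwick trees over fixed 2**_CAP_BITS slot ranges --------------------

@njit(cache=True)
def _fw_add(tree, slot, delta):
    i = slot + 1
    while i <= _CAP:
        tree[i] += delta
        i += i & (-i)


@njit(cache=True)
def _fw_find(tree, target):
    """Largest slot with prefix sum <= target."""
    idx = 0
    rem = target
    bit = _CAP
    while bit:
        nxt = idx + bit
        if nxt <= _CAP and tree[nxt] <= rem:
            idx = nxt
            rem -= tree[nxt]
        bit >>= 1
    return idx  # 0-based slot


@njit(cache=True)
def _run_core(mode, L, n0,
              masters, complements, phis,
              phi_min, eps1, eps2, baseline_factor,
              p_mut, ca_rate,
              cd_table, cdds_table,
              min_pairs, no_cross_hyb, use_revcomp, include_complements,
              c_in, c_decay_ss, c_out,
              init_counts, init_res,
              max_repl_events, sample_cadence, max_total_events,
              seed):
    np.random.seed(seed)
    T = masters.shape[0]
    NSEQ = 1 << (2 * L)
    HASH_SIZE = 1 << 18
    HASH_MASK = HASH_SIZE - 1

    simp = np.zeros(NSEQ, np.int64)       # simplex copy number per sequence
    act = np.zeros(_CAP, np.int64)        # active simplex species list
    act_pos = np.full(NSEQ, -1, np.int64)
    cr_cache = np.full(NSEQ, -1.0)
    class_id = np.full(NSEQ, -1, np.int16)  # 2*type + role for masters/comps

    dup_a = np.zeros(_CAP, np.int64)
    dup_b = np.zeros(_CAP, np.int64)
    dup_n = np.zeros(_CAP, np.int64)
    dup_cd = np.zeros(_CAP)
    dup_dd = np.zeros(_CAP)
    hkey = np.full(HASH_SIZE, -1, np.int64)
    hval = np.zeros(HASH_SIZE, np.int64)

    # Fenwick trees: simplex counts / cr-weights by active slot, duplex
    # counts / dissociation / decay weights by duplex slot
    fw_sn = np.zeros(_CAP + 1, np.int64)
    fw_sc = np.zeros(_CAP + 1)
    fw_dn = np.zeros(_CAP + 1, np.int64)
    fw_dc = np.zeros(_CAP + 1)
    fw_dd = np.zeros(_CAP + 1)

    # cross-hybridization-disabled mode: the thinning envelope over all
    # C(A,2) pairs would be almost entirely null events (master-master
    # pairs are forbidden), so association splits into an exact
    # master(i)+complement(i) channel and a channel over pairs with at
    # least one unclassed (mutant) strand, tracked by its own count tree
    fw_su = np.zeros(_CAP + 1, np.int64)   # unclassed simplex counts
    n_plus = np.zeros(T, np.int64)         # simplex copies of master i
    n_minus = np.zeros(T, np.int64)        # simplex copies of complement i
    cls_state = np.zeros(2, np.int64)      # [M classed strands, unused]
    s_mc = np.zeros(1)                     # sum_i n_plus[i] * n_minus[i]

    R = init_res.astype(np.int64).copy()

    # shared mutable scalars: si = [n_act, n_dup, A, ND],
    # sf = [P_rep, P_diss, P_dds]
    si = np.zeros(4, np.int64)
    sf = np.zeros(3)

    t = 0.0
    repl_events = 0
    total_events = 0
    rejected = 0
    infeasible = 0
    trunc = OK

    n_rows_cap = int(max_repl_events // sample_cadence) + 2
    out_master = np.zeros((n_rows_cap, T), np.int64)
    out_extra = np.zeros((n_rows_cap, N_EXTRA_COLS), np.int64)
    out_time = np.zeros(n_rows_cap)
    n_rows = 0

    # ---- closures over the state ----------------------------------------

    def get_cr(s):
        v = cr_cache[s]
        if v >= 0.0:
            return v
        best = baseline_factor * phi_min
        for i in range(T):
            d = _hamming(s, masters[i], L)
            if include_complements:
                d2 = _hamming(s, complements[i], L)
                if d2 < d:
                    d = d2
            if d <= 2:
                if d == 0:
                    cand = phis[i]
                elif d == 1:
                    cand = eps1 * phis[i]
                else:
                    cand = eps2 * phis[i]
                if cand > best:
                    best = cand
        cr_cache[s] = best
        return best

    def pair_ok_eb(x, y):
        n_au, n_gc = _bonds(x, y, L, use_revcomp)
        eb = n_au + 2 * n_gc
        if n_au + n_gc < min_pairs:
            return False, eb
        if no_cross_hyb:
            cx = class_id[x]
            cy = class_id[y]
            if cx >= 0 and cy >= 0:
                if (cx >> 1) != (cy >> 1) or (cx & 1) == (cy & 1):
                    return False, eb
        return True, eb

    def simp_change(s, d):
        """Change the simplex count of sequence s by d, maintaining the
        active list, the Fenwick trees and the running replication sum.
        Returns False on species-capacity overflow."""
        c = get_cr(s)
        p = act_pos[s]
        if p < 0:
            if si[_N_ACT] >= _CAP:
                return False
            p = si[_N_ACT]
            act[p] = s
            act_pos[s] = p
            si[_N_ACT] += 1
        simp[s] += d
        si[_A] += d
        sf[_P_REP] += d * c
        _fw_add(fw_sn, p, d)
        _fw_add(fw_sc, p, d * c)
        if no_cross_hyb:
            cid = class_id[s]
            if cid >= 0:
                cls_state[0] += d
                i = cid >> 1
                if cid & 1:
                    n_minus[i] += d
                    s_mc[0] += d * n_plus[i]
                else:
                    n_plus[i] += d
                    s_mc[0] += d * n_minus[i]
            else:
                _fw_add(fw_su, p, d)
        if simp[s] == 0:
            # swap-remove from the active list (move last slot into p)
            last = si[_N_ACT] - 1
            q = act[last]
            if q != s:
                w = simp[q]
                cq = cr_cache[q]
                _fw_add(fw_sn, last, -w)
                _fw_add(fw_sc, last, -w * cq)
                _fw_add(fw_sn, p, w)
                _fw_add(fw_sc, p, w * cq)
                if no_cross_hyb and class_id[q] < 0:
                    _fw_add(fw_su, last, -w)
                    _fw_add(fw_su, p, w)
                act[p] = q
                act_pos[q] = p
            act_pos[s] = -1
            si[_N_ACT] = last
        return True

    def dup_change(idx, d):
        dup_n[idx] += d
        si[_ND] += d
        sf[_P_DISS] += d * dup_cd[idx]
        sf[_P_DDS] += d * dup_dd[idx]
        _fw_add(fw_dn, idx, d)
        _fw_add(fw_dc, idx, d * dup_cd[idx])
        _fw_add(fw_dd, idx, d * dup_dd[idx])

    def find_or_create_dup(x, y, eb):
        """Duplex-species slot for the canonical pair, creating it (with
        its energy-dependent rates) on first sight; -1 on overflow."""
        aa = x if x <= y else y
        bb = y if x <= y else x
        key = aa * NSEQ + bb
        h = (key * np.int64(0x9E3779B9)) & HASH_MASK
        while hkey[h] != -1:
            if hkey[h] == key:
                return hval[h]
            h = (h + 1) & HASH_MASK
        if si[_N_DUP] >= _CAP:
            return -1
        idx = si[_N_DUP]
        si[_N_DUP] += 1
        dup_a[idx] = aa
        dup_b[idx] = bb
        dup_n[idx] = 0
        dup_cd[idx] = cd_table[eb]
        dup_dd[idx] = cdds_table[eb]
        hkey[h] = key
        hval[h] = idx
        return idx

    def rebuild_weights():
        """Recompute the running sums and float trees from scratch
        (bounds floating-point drift)."""
        for i in range(_CAP + 1):
            fw_sc[i] = 0.0
            fw_dc[i] = 0.0
            fw_dd[i] = 0.0
        sf[_P_REP] = 0.0
        for p in range(si[_N_ACT]):
            s = act[p]
            w = simp[s] * cr_cache[s]
            sf[_P_REP] += w
            _fw_add(fw_sc, p, w)
        sf[_P_DISS] = 0.0
        sf[_P_DDS] = 0.0
        for i in range(si[_N_DUP]):
            sf[_P_DISS] += dup_n[i] * dup_cd[i]
            sf[_P_DDS] += dup_n[i] * dup_dd[i]
            _fw_add(fw_dc, i, dup_n[i] * dup_cd[i])
            _fw_add(fw_dd, i, dup_n[i] * dup_dd[i])

    def compact_duplexes():
        """Drop extinct duplex species, rebuild the hash and count tree."""
        m = 0
        for i in range(si[_N_DUP]):
            if dup_n[i] > 0:
                dup_a[m] = dup_a[i]
                dup_b[m] = dup_b[i]
                dup_n[m] = dup_n[i]
                dup_cd[m] = dup_cd[i]
                dup_dd[m] = dup_dd[i]
                m += 1
        for i in range(m, si[_N_DUP]):
            dup_n[i] = 0
        si[_N_DUP] = m
        hkey[:] = -1
        for i in range(_CAP + 1):
            fw_dn[i] = 0
        for i in range(si[_N_DUP]):
            key = dup_a[i] * NSEQ + dup_b[i]
            h = (key * np.int64(0x9E3779B9)) & HASH_MASK
            while hkey[h] != -1:
                h = (h + 1) & HASH_MASK
            hkey[h] = key
            hval[h] = i
            _fw_add(fw_dn, i, dup_n[i])

    # ---- initialization --------------------------------------------------

    for i in range(T):
        class_id[masters[i]] = 2 * i
        class_id[complements[i]] = 2 * i + 1
    for i in range(T):
        if init_counts[i] > 0:
            simp_change(masters[i], init_counts[i])

    refresh_every = 1 << 20
    next_refresh = refresh_every

    # ---- event loop ------------------------------------------------------

    while True:
        if repl_events % sample_cadence == 0 and \
                (n_rows == 0 or out_extra[n_rows - 1, 0] != repl_events):
            for i2 in range(si[_N_ACT]):
                s2 = act[i2]
                c2 = class_id[s2]
                if c2 >= 0:
                    out_master[n_rows, c2 >> 1] += simp[s2]
            for i2 in range(si[_N_DUP]):
                if dup_n[i2] > 0:
                    c2 = class_id[dup_a[i2]]
                    if c2 >= 0:
                        out_master[n_rows, c2 >> 1] += dup_n[i2]
                    c2 = class_id[dup_b[i2]]
                    if c2 >= 0:
                        out_master[n_rows, c2 >> 1] += dup_n[i2]
            out_extra[n_rows, 0] = repl_events
            out_extra[n_rows, 1] = si[_A]
            out_extra[n_rows, 2] = 2 * si[_ND]
            for b2 in range(4):
                out_extra[n_rows, 3 + b2] = R[b2]
            out_time[n_rows] = t
            n_rows += 1
        if repl_events >= max_repl_events:
            break
        if total_events >= max_total_events:
            trunc = EVENT_CAP
            break

        if total_events >= next_refresh or si[_N_DUP] >= _CAP - 4:
            next_refresh = total_events + refresh_every
            live = 0
            for i2 in range(si[_N_DUP]):
                if dup_n[i2] > 0:
                    live += 1
            if si[_N_DUP] >= _CAP - 4 or \
                    (si[_N_DUP] > 1024 and live < si[_N_DUP] // 2):
                compact_duplexes()
                if si[_N_DUP] >= _CAP - 4:
                    trunc = OVERFLOW_DUPLEX
                    break
            rebuild_weights()

        # ---- total propensity -------------------------------------------
        A = si[_A]
        ND = si[_ND]
        if no_cross_hyb:
            M = cls_state[0]
            U = A - M
            p_assoc = ca_rate * (s_mc[0] + U * M + 0.5 * U * (U - 1))
        else:
            M = 0
            U = A
            p_assoc = ca_rate * 0.5 * A * (A - 1)
        gate = True
        if mode == MODE_CHEMOSTAT:
            for b2 in range(4):
                if R[b2] < L:
                    gate = False
        p_rep_eff = sf[_P_REP] if (gate and sf[_P_REP] > 0.0) else 0.0
        p_diss_eff = sf[_P_DISS] if sf[_P_DISS] > 0.0 else 0.0
        total = p_rep_eff + p_assoc + p_diss_eff
        p_in = 0.0
        p_dec_ss = 0.0
        p_dds_eff = 0.0
        p_out = 0.0
        r_tot = 0
        if mode == MODE_CHEMOSTAT:
            r_tot = R[0] + R[1] + R[2] + R[3]
            p_in = 4.0 * c_in
            p_dec_ss = c_decay_ss * A
            p_dds_eff = sf[_P_DDS] if sf[_P_DDS] > 0.0 else 0.0
            p_out = c_out * (A + ND + r_tot)
            total += p_in + p_dec_ss + p_dds_eff + p_out
        if total <= 0.0:
            trunc = HALTED
            break

        total_events += 1
        r = np.random.random()
        while r <= 0.0:
            r = np.random.random()
        t += -np.log(r) / total
        u = np.random.random() * total

        # ================= replication ===================================
        if u < p_rep_eff:
            slot = _fw_find(fw_sc, u)
            if slot >= si[_N_ACT]:
                slot = si[_N_ACT] - 1
            tmpl = act[slot]

            if use_revcomp:
                prod = _revcomp(tmpl, L)
            else:
                prod = _poscomp(tmpl, L)
            if p_mut > 0.0:
                for k in range(L):
                    if np.random.random() < p_mut:
                        cur = (prod >> (2 * k)) & 3
                        nb = (cur + 1 + np.random.randint(0, 3)) & 3
                        prod = (prod & ~(np.int64(3) << (2 * k))) | \
                               (np.int64(nb) << (2 * k))

            if mode == MODE_CHEMOSTAT:
                feasible = True
                for k in range(L):
                    if R[(prod >> (2 * k)) & 3] <= 0:
                        feasible = False
                if not feasible:
                    infeasible += 1  # no-op event; cannot occur behind gate
                    continue
                for k in range(L):
                    R[(prod >> (2 * k)) & 3] -= 1

            n_pre = A + 2 * ND
            ok, eb = pair_ok_eb(tmpl, prod)
            newborn_idx = -1
            if ok:
                # template simplex converts into the template-product duplex
                simp_change(tmpl, -1)
                idx = find_or_create_dup(tmpl, prod, eb)
                if idx < 0:
                    trunc = OVERFLOW_DUPLEX
                    break
                dup_change(idx, 1)
                newborn_idx = idx
            else:
                # unstable pairing: the product is released as a simplex
                if not simp_change(prod, 1):
                    trunc = OVERFLOW_SPECIES
                    break
            repl_events += 1

            # Moran replacement: only when the population was at capacity
            if mode == MODE_MORAN and n_pre >= n0:
                # exclude the template and the newborn strand (two strands,
                # in the new duplex or still free) from the victim draw
                if newborn_idx >= 0:
                    _fw_add(fw_dn, newborn_idx, -1)
                    nd_excl = 1
                    a_eff = si[_A]
                else:
                    _fw_add(fw_sn, act_pos[tmpl], -1)
                    _fw_add(fw_sn, act_pos[prod], -1)
                    nd_excl = 0
                    a_eff = si[_A] - 2
                eligible = a_eff + 2 * (si[_ND] - nd_excl)
                victim = np.int64(-1)
                vdup = -1
                if eligible > 0:
                    v = np.random.randint(0, eligible)
                    if v < a_eff:
                        victim = act[_fw_find(fw_sn, v)]
                    else:
                        vdup = _fw_find(fw_dn, (v - a_eff) >> 1)
                # restore the exclusions before applying the removal
                if newborn_idx >= 0:
                    _fw_add(fw_dn, newborn_idx, 1)
                else:
                    _fw_add(fw_sn, act_pos[tmpl], 1)
                    _fw_add(fw_sn, act_pos[prod], 1)
                if victim >= 0:
                    simp_change(victim, -1)
                elif vdup >= 0:
                    dup_change(vdup, -1)
            continue
        u -= p_rep_eff

        # ================= association (with exact thinning) =============
        if u < p_assoc:
            if no_cross_hyb:
                # exact sub-channels: (a) master+own complement,
                # (b) one unclassed + one classed, (c) two unclassed
                w = u / ca_rate
                if w < s_mc[0]:
                    i2sel = T - 1
                    accm = 0.0
                    for i2 in range(T):
                        accm += n_plus[i2] * n_minus[i2]
                        if w < accm:
                            i2sel = i2
                            break
                    x = masters[i2sel]
                    y = complements[i2sel]
                else:
                    w -= s_mc[0]
                    if w < U * M:
                        x = act[_fw_find(fw_su, np.random.randint(0, U))]
                        j = np.random.randint(0, M)
                        y = complements[T - 1]
                        accc = 0
                        done = False
                        for i2 in range(T):
                            accc += n_plus[i2]
                            if j < accc:
                                y = masters[i2]
                                done = True
                                break
                        if not done:
                            for i2 in range(T):
                                accc += n_minus[i2]
                                if j < accc:
                                    y = complements[i2]
                                    break
                    else:
                        x = act[_fw_find(fw_su, np.random.randint(0, U))]
                        _fw_add(fw_su, act_pos[x], -1)
                        y = act[_fw_find(fw_su, np.random.randint(0, U - 1))]
                        _fw_add(fw_su, act_pos[x], 1)
            else:
                x = act[_fw_find(fw_sn, np.random.randint(0, A))]
                # second strand drawn among the remaining A - 1
                _fw_add(fw_sn, act_pos[x], -1)
                y = act[_fw_find(fw_sn, np.random.randint(0, A - 1))]
                _fw_add(fw_sn, act_pos[x], 1)
            ok, eb = pair_ok_eb(x, y)
            if not ok:
                rejected += 1  # null event: time advanced, state unchanged
                continue
            idx = find_or_create_dup(x, y, eb)
            if idx < 0:
                trunc = OVERFLOW_DUPLEX
                break
            simp_change(x, -1)
            simp_change(y, -1)
            dup_change(idx, 1)
            continue
        u -= p_assoc

        # ================= dissociation ==================================
        if u < p_diss_eff:
            idx = _fw_find(fw_dc, u)
            if idx >= si[_N_DUP]:
                idx = si[_N_DUP] - 1
            while dup_n[idx] <= 0 and idx > 0:
                idx -= 1
            if dup_n[idx] <= 0:
                continue  # float-drift guard; no duplex actually present
            a2 = dup_a[idx]
            b2s = dup_b[idx]
            dup_change(idx, -1)
            ok1 = simp_change(a2, 1)
            ok2 = simp_change(b2s, 1)
            if not (ok1 and ok2):
                trunc = OVERFLOW_SPECIES
                break
            continue
        u -= p_diss_eff

        # ================= chemostat-only channels =======================
        if u < p_in:
            R[np.random.randint(0, 4)] += 1
            continue
        u -= p_in

        if u < p_dec_ss:
            s2 = act[_fw_find(fw_sn, np.random.randint(0, A))]
            simp_change(s2, -1)
            continue
        u -= p_dec_ss

        if u < p_dds_eff:
            idx = _fw_find(fw_dd, u)
            if idx >= si[_N_DUP]:
                idx = si[_N_DUP] - 1
            while dup_n[idx] <= 0 and idx > 0:
                idx -= 1
            if dup_n[idx] > 0:
                dup_change(idx, -1)
            continue
        u -= p_dds_eff

        # outflow: one molecule (simplex strand, duplex unit, or monomer)
        i1 = np.random.randint(0, A + ND + r_tot)
        if i1 < A:
            simp_change(act[_fw_find(fw_sn, i1)], -1)
            continue
        i1 -= A
        if i1 < ND:
            dup_change(_fw_find(fw_dn, i1), -1)
            continue
        i1 -= ND
        accs = 0
        for b2 in range(4):
            accs += R[b2]
            if i1 < accs:
                R[b2] -= 1
                break

    counters = np.zeros(5, np.int64)
    counters[0] = total_events
    counters[1] = rejected
    counters[2] = infeasible
    counters[3] = trunc
    counters[4] = repl_events
    return (out_master[:n_rows], out_extra[:n_rows], out_time[:n_rows],
            counters)
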