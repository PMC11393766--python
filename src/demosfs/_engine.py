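"""Numba kernels for the structured-coalescent engine.

One genealogy is simulated backward in time under piecewise-constant deme
sizes, divergence events (all lineages of a source deme relocate into a sink
deme), and a recent migration epoch.  Waiting times are exponential with the
per-generation probabilities used as rates (the continuous-time limit of the
discrete backward process, accurate to O(m^2 + 1/N^2)):

    coalescence in deme d: k_d (k_d - 1) / (4 N_d)  per generation
    migration of a lineage out of deme d: sum_c M[d, c]

where ``M[j, i]`` is the backward probability that a lineage in deme ``j``
traces its parent to deme ``i`` — numerically the forward fraction of deme
``j`` founded by ``i``-migrants each generation.

Each simulated genealogy is seeded individually with a hash of (base seed,
genealogy index), so re-evaluating under perturbed parameters reuses the same
underlying randomness (common random numbers — the likelihood surface is
smooth in the parameters) while different base seeds yield disjoint streams.

Lineages carry (a) per-deme descendant-leaf counts, giving joint SFS cell
assignments in O(1) per branch, and (b) an intrusive linked list of leaf ids,
giving derived-carrier sets for mutation placement in O(#carriers).  Active
lineages are held in per-deme swap-remove lists so every event is O(D).
"""

import numpy as np
from numba import njit

_MOD = 2147483647  # seeds kept below 2^31


@njit(cache=True)
def _mix_seed(base, g):
    """Decorrelate per-genealogy seeds across base seeds.

    A splitmix-style 64-bit hash of (base, index): sequential bases with
    sequential indices must not produce overlapping streams, or independent
    evaluations (and data vs. likelihood surfaces) share genealogies.
    """
    x = (np.uint64(base) * np.uint64(0x9E3779B97F4A7C15)
         + np.uint64(g) * np.uint64(0xBF58476D1CE4E5B9))
    x ^= x >> np.uint64(30)
    x *= np.uint64(0xD6E8FEB86659FD93)
    x ^= x >> np.uint64(27)
    x *= np.uint64(0xC2B2AE3D27D4EB4F)
    x ^= x >> np.uint64(31)
    return np.int64(x & np.uint64(0x7FFFFFFF))


@njit(cache=True)
def _one_genealogy(
    samples, sizes0,
    ev_time, ev_kind, ev_a, ev_b, ev_size,
    mig_end, mig,
    lin_birth, lin_cnt, lin_head, lin_tail, lin_nleaf, nxt,
    deme_list, deme_cnt, lin_deme, lin_slot,
    dead_id, dead_len,
):
    """Simulate one genealogy in place; returns n_dead (branch count).

    n_dead == -1 signals a structurally stuck model (isolated lineages with
    no remaining divergence events).
    """
    D = samples.shape[0]
    ntot = 0
    for d in range(D):
        deme_cnt[d] = 0
        ntot += samples[d]
    li = 0
    for d in range(D):
        for _s in range(samples[d]):
            lin_birth[li] = 0.0
            for dd in range(D):
                lin_cnt[li, dd] = 0
            lin_cnt[li, d] = 1
            lin_head[li] = li
            lin_tail[li] = li
            lin_nleaf[li] = 1
            nxt[li] = -1
            lin_deme[li] = d
            lin_slot[li] = deme_cnt[d]
            deme_list[d, deme_cnt[d]] = li
            deme_cnt[d] += 1
            li += 1
    n_act = ntot
    next_lin = ntot
    N = sizes0.copy()
    alive = np.ones(D, np.bool_)
    mrow = np.zeros(D)  # per-lineage out-migration rate by deme
    for d in range(D):
        rs = 0.0
        for c in range(D):
            if c != d:
                rs += mig[d, c]
        mrow[d] = rs
    t = 0.0
    ev_i = 0
    nE = ev_time.shape[0]
    n_dead = 0

    while n_act > 1:
        mig_on = t < mig_end
        coal_tot = 0.0
        mig_tot = 0.0
        for d in range(D):
            kd = deme_cnt[d]
            if kd > 1:
                coal_tot += kd * (kd - 1) / (4.0 * N[d])
            if mig_on and kd > 0:
                mig_tot += kd * mrow[d]
        tot = coal_tot + mig_tot
        tb = np.inf
        if ev_i < nE:
            tb = ev_time[ev_i]
        if mig_on and mig_end < tb:
            tb = mig_end

        event_now = False
        if tot <= 0.0:
            if tb == np.inf:
                return -1
            t = tb
        else:
            dt = -np.log(np.random.random()) / tot
            if t + dt >= tb:
                if tb == np.inf:
                    return -1
                t = tb
            else:
                t = t + dt
                event_now = True

        if event_now:
            u = np.random.random() * tot
            if u < coal_tot:
                # coalescence: choose deme proportionally, then a uniform pair
                acc = 0.0
                dsel = -1
                for d in range(D):
                    kd = deme_cnt[d]
                    if kd > 1:
                        acc += kd * (kd - 1) / (4.0 * N[d])
                        dsel = d
                        if u < acc:
                            break
                kd = deme_cnt[dsel]
                r1 = np.random.randint(0, kd)
                r2 = np.random.randint(0, kd - 1)
                if r2 >= r1:
                    r2 += 1
                i1 = deme_list[dsel, r1]
                i2 = deme_list[dsel, r2]
                nl = next_lin
                next_lin += 1
                lin_birth[nl] = t
                for dd in range(D):
                    lin_cnt[nl, dd] = lin_cnt[i1, dd] + lin_cnt[i2, dd]
                lin_head[nl] = lin_head[i1]
                nxt[lin_tail[i1]] = lin_head[i2]
                lin_tail[nl] = lin_tail[i2]
                lin_nleaf[nl] = lin_nleaf[i1] + lin_nleaf[i2]
                dead_id[n_dead] = i1
                dead_len[n_dead] = t - lin_birth[i1]
                n_dead += 1
                dead_id[n_dead] = i2
                dead_len[n_dead] = t - lin_birth[i2]
                n_dead += 1
                # remove i1 and i2 from the deme list (higher slot first),
                # then append the parent
                s1 = lin_slot[i1]
                s2 = lin_slot[i2]
                if s1 > s2:
                    s1, s2 = s2, s1
                last = deme_cnt[dsel] - 1
                moved = deme_list[dsel, last]
                deme_list[dsel, s2] = moved
                lin_slot[moved] = s2
                deme_cnt[dsel] = last
                last = deme_cnt[dsel] - 1
                moved = deme_list[dsel, last]
                deme_list[dsel, s1] = moved
                lin_slot[moved] = s1
                deme_cnt[dsel] = last
                lin_deme[nl] = dsel
                lin_slot[nl] = deme_cnt[dsel]
                deme_list[dsel, deme_cnt[dsel]] = nl
                deme_cnt[dsel] += 1
                n_act -= 1
            else:
                # migration: deme, then lineage, then destination
                u2 = u - coal_tot
                acc = 0.0
                dsel = -1
                for d in range(D):
                    if deme_cnt[d] > 0 and mrow[d] > 0.0:
                        acc += deme_cnt[d] * mrow[d]
                        dsel = d
                        if u2 < acc:
                            break
                if dsel >= 0:
                    r = np.random.randint(0, deme_cnt[dsel])
                    sel = deme_list[dsel, r]
                    u3 = np.random.random() * mrow[dsel]
                    acc = 0.0
                    for c in range(D):
                        if alive[c] and c != dsel:
                            acc += mig[dsel, c]
                            if u3 < acc:
                                # move sel: dsel -> c
                                last = deme_cnt[dsel] - 1
                                moved = deme_list[dsel, last]
                                deme_list[dsel, r] = moved
                                lin_slot[moved] = r
                                deme_cnt[dsel] = last
                                lin_deme[sel] = c
                                lin_slot[sel] = deme_cnt[c]
                                deme_list[c, deme_cnt[c]] = sel
                                deme_cnt[c] += 1
                                break
        else:
            # boundary reached: apply all events scheduled at/before t
            while ev_i < nE and ev_time[ev_i] <= t:
                if ev_kind[ev_i] == 0:
                    a = ev_a[ev_i]
                    b = ev_b[ev_i]
                    for p in range(deme_cnt[a]):
                        lid = deme_list[a, p]
                        lin_deme[lid] = b
                        lin_slot[lid] = deme_cnt[b]
                        deme_list[b, deme_cnt[b]] = lid
                        deme_cnt[b] += 1
                    deme_cnt[a] = 0
                    alive[a] = False
                    # migration out of / into a dead deme stops
                    mrow[a] = 0.0
                    for d in range(D):
                        if d != a and mig[d, a] > 0.0:
                            rs = 0.0
                            for c in range(D):
                                if alive[c] and c != d:
                                    rs += mig[d, c]
                            mrow[d] = rs
                else:
                    N[ev_a[ev_i]] = ev_size[ev_i]
                ev_i += 1

    return n_dead


@njit(cache=True)
def _alloc(samples):
    D = samples.shape[0]
    ntot = 0
    for d in range(D):
        ntot += samples[d]
    maxL = 2 * ntot
    lin_birth = np.empty(maxL, np.float64)
    lin_cnt = np.empty((maxL, D), np.int64)
    lin_head = np.empty(maxL, np.int64)
    lin_tail = np.empty(maxL, np.int64)
    lin_nleaf = np.empty(maxL, np.int64)
    nxt = np.empty(ntot, np.int64)
    deme_list = np.empty((D, ntot), np.int64)
    deme_cnt = np.empty(D, np.int64)
    lin_deme = np.empty(maxL, np.int64)
    lin_slot = np.empty(maxL, np.int64)
    dead_id = np.empty(maxL, np.int64)
    dead_len = np.empty(maxL, np.float64)
    return (lin_birth, lin_cnt, lin_head, lin_tail, lin_nleaf, nxt,
            deme_list, deme_cnt, lin_deme, lin_slot, dead_id, dead_len)


@njit(cache=True)
def _pair_tables(
    samples, sizes0,
    ev_time, ev_kind, ev_a, ev_b, ev_size,
    mig_end, mig,
    pairs, offsets, mu_l, n_sims, seed, flat,
):
    """Accumulate unfolded joint-SFS probability mass for each deme pair.

    Per genealogy, cell (i, j) of pair (a, b) receives branch-length mass
    (1 - exp(-mu_l L)) * len / L for every branch with i descendants in a and
    j in b; cell (0, 0) receives exp(-mu_l L).  Each pair's table sums to one
    per genealogy.  Returns the number of successfully simulated genealogies.
    """
    work = _alloc(samples)
    (lin_birth, lin_cnt, lin_head, lin_tail, lin_nleaf, nxt,
     deme_list, deme_cnt, lin_deme, lin_slot, dead_id, dead_len) = work
    P = pairs.shape[0]
    n_ok = 0
    for g in range(n_sims):
        np.random.seed(_mix_seed(seed, g))
        n_dead = _one_genealogy(
            samples, sizes0, ev_time, ev_kind, ev_a, ev_b, ev_size,
            mig_end, mig,
            lin_birth, lin_cnt, lin_head, lin_tail, lin_nleaf, nxt,
            deme_list, deme_cnt, lin_deme, lin_slot, dead_id, dead_len,
        )
        if n_dead < 0:
            continue
        L = 0.0
        for i in range(n_dead):
            L += dead_len[i]
        if L <= 0.0:
            pmono = 1.0
            w = 0.0
        else:
            pmono = np.exp(-mu_l * L)
            w = (1.0 - pmono) / L
        for p in range(P):
            a = pairs[p, 0]
            b = pairs[p, 1]
            nb1 = samples[b] + 1
            off = offsets[p]
            flat[off] += pmono
            for i in range(n_dead):
                lid = dead_id[i]
                flat[off + lin_cnt[lid, a] * nb1 + lin_cnt[lid, b]] += w * dead_len[i]
        n_ok += 1
    return n_ok


@njit(cache=True)
def _simulate_loci(
    samples, sizes0,
    ev_time, ev_kind, ev_a, ev_b, ev_size,
    mig_end, mig,
    mu_l, n_loci, seed, one_snp,
    ind_of_hap, geno, locus_id,
):
    """Simulate unlinked loci and write diploid alt-allele counts into geno.

    one_snp: each locus yields exactly one site record, carrying its first
    mutation if any (monomorphic otherwise).  Otherwise every mutation gets
    its own record and mutation-free loci yield one monomorphic record.
    Returns the number of site records written, -1 for a stuck model, or
    -2 on buffer overflow.
    """
    work = _alloc(samples)
    (lin_birth, lin_cnt, lin_head, lin_tail, lin_nleaf, nxt,
     deme_list, deme_cnt, lin_deme, lin_slot, dead_id, dead_len) = work
    cap = geno.shape[0]
    n_sites = 0
    for g in range(n_loci):
        np.random.seed(_mix_seed(seed, g))
        n_dead = _one_genealogy(
            samples, sizes0, ev_time, ev_kind, ev_a, ev_b, ev_size,
            mig_end, mig,
            lin_birth, lin_cnt, lin_head, lin_tail, lin_nleaf, nxt,
            deme_list, deme_cnt, lin_deme, lin_slot, dead_id, dead_len,
        )
        if n_dead < 0:
            return -1
        L = 0.0
        for i in range(n_dead):
            L += dead_len[i]
        nmut = 0
        if L > 0.0:
            nmut = np.random.poisson(mu_l * L)
        if one_snp == 1:
            n_place = 1 if nmut > 0 else 0
            n_records = 1
        else:
            n_place = nmut
            n_records = nmut if nmut > 0 else 1
        if n_sites + n_records > cap:
            return -2
        if n_place == 0:
            locus_id[n_sites] = g
            n_sites += 1
        else:
            for _m in range(n_place):
                x = np.random.random() * L
                acc = 0.0
                bsel = 0
                for i in range(n_dead):
                    acc += dead_len[i]
                    bsel = i
                    if x < acc:
                        break
                lid = dead_id[bsel]
                h = lin_head[lid]
                for _j in range(lin_nleaf[lid]):
                    geno[n_sites, ind_of_hap[h]] += 1
                    h = nxt[h]
                locus_id[n_sites] = g
                n_sites += 1
    return n_sites
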