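"""Numba kernels for the biased Monte Carlo moves and the inner run loop.

Move indices (fixed order used everywhere):

    0 cluster translation   3 local
    1 chain translation     4 reptation (slithering snake)
    2 rotation              5 double pivot

All moves act on flat int64 arrays compiled by :class:`~sslattice.system.
LatticeSystem`.  Orientational (Rosenbluth) biases follow the configurational
bias scheme: a sticker's weight is W = 1 + sum_l exp(-beta eps) over its
available partners, bond states are re-drawn by heat-bath selection, and
position moves are accepted with min{1, W_new / W_old}.

The RNG is xoshiro256** with a splitmix64 seeder; its 4-word uint64 state is
passed in explicitly so every wrapper is reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# 26-site unit-cube neighborhood and the +/-2 search cube for double pivot
_OFF26 = np.array([(dx, dy, dz)
                   for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
                   if (dx, dy, dz) != (0, 0, 0)], dtype=np.int64)
_OFF124 = np.array([(dx, dy, dz)
                    for dx in range(-2, 3) for dy in range(-2, 3) for dz in range(-2, 3)
                    if (dx, dy, dz) != (0, 0, 0)], dtype=np.int64)

N_MOVES = 6
MOVE_NAMES = ("cluster_translation", "chain_translation", "rotation",
              "local", "reptation", "double_pivot")


# ----------------------------------------------------------------------
# RNG: xoshiro256**
# ----------------------------------------------------------------------

@njit(cache=True)
def _splitmix64(x):
    x = np.uint64(x + np.uint64(0x9E3779B97F4A7C15))
    z = x
    z = np.uint64((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9))
    z = np.uint64((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB))
    return x, np.uint64(z ^ (z >> np.uint64(31)))


@njit(cache=True)
def seed_rng(seed):
    s = np.empty(4, dtype=np.uint64)
    x = np.uint64(seed)
    for i in range(4):
        x, z = _splitmix64(x)
        s[i] = z
    return s


@njit(inline="always")
def _rotl(x, k):
    return np.uint64((x << np.uint64(k)) | (x >> np.uint64(64 - k)))


@njit(inline="always")
def _next(s):
    result = np.uint64(_rotl(np.uint64(s[1] * np.uint64(5)), 7) * np.uint64(9))
    t = np.uint64(s[1] << np.uint64(17))
    s[2] ^= s[0]
    s[3] ^= s[1]
    s[1] ^= s[2]
    s[0] ^= s[3]
    s[2] ^= t
    s[3] = _rotl(s[3], 45)
    return result


@njit(inline="always")
def rand_double(s):
    return (_next(s) >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(inline="always")
def rand_below(s, n):
    # modulo bias is O(n / 2^64): negligible for lattice-sized n
    return int(_next(s) % np.uint64(n))


# ----------------------------------------------------------------------
# geometry helpers
# ----------------------------------------------------------------------

@njit(inline="always")
def _flat(x, y, z, L):
    return (x * L + y) * L + z


@njit(inline="always")
def _d2(ax, ay, az, bx, by, bz, L):
    dx = ax - bx
    if dx < 0:
        dx = -dx
    if dx > L - dx:
        dx = L - dx
    dy = ay - by
    if dy < 0:
        dy = -dy
    if dy > L - dy:
        dy = L - dy
    dz = az - bz
    if dz < 0:
        dz = -dz
    if dz > L - dz:
        dz = L - dz
    return dx * dx + dy * dy + dz * dz


# ----------------------------------------------------------------------
# bonds
# ----------------------------------------------------------------------

@njit(inline="always")
def _unbind(u, partner, bond_count, btype):
    v = partner[u]
    if v >= 0:
        partner[u] = -1
        partner[v] = -1
        a = btype[u]
        b = btype[v]
        if a > b:
            a, b = b, a
        bond_count[a, b] -= 1


@njit(inline="always")
def _bind(u, v, partner, bond_count, btype):
    partner[u] = v
    partner[v] = u
    a = btype[u]
    b = btype[v]
    if a > b:
        a, b = b, a
    bond_count[a, b] += 1


@njit(cache=True)
def _collect(u, px, py, pz, occ, partner, btype, candw, L, cand, wbuf):
    """Available partners of a sticker placed at (px,py,pz); returns (count, W).

    A bead is available if it sits on one of the 26 adjacent sites, the
    type pair has nonzero eps, and it is unbonded or already bonded to u.
    W includes the unit weight of the dissociated state.
    """
    tu = btype[u]
    n = 0
    W = 1.0
    for k in range(26):
        x = (px + _OFF26[k, 0]) % L
        y = (py + _OFF26[k, 1]) % L
        z = (pz + _OFF26[k, 2]) % L
        v = occ[_flat(x, y, z, L)]
        if v >= 0 and v != u:
            w = candw[tu, btype[v]]
            if w > 0.0 and (partner[v] == -1 or partner[v] == u):
                cand[n] = v
                wbuf[n] = w
                n += 1
                W += w
    return n, W


@njit(cache=True)
def _weight_at(u, px, py, pz, occ, partner, btype, candw, L):
    """Rosenbluth weight W = 1 + sum exp(-beta eps) without storing candidates."""
    tu = btype[u]
    W = 1.0
    for k in range(26):
        x = (px + _OFF26[k, 0]) % L
        y = (py + _OFF26[k, 1]) % L
        z = (pz + _OFF26[k, 2]) % L
        v = occ[_flat(x, y, z, L)]
        if v >= 0 and v != u:
            w = candw[tu, btype[v]]
            if w > 0.0 and (partner[v] == -1 or partner[v] == u):
                W += w
    return W


@njit(cache=True)
def _rebond_heat_bath(u, pos, occ, partner, bond_count, btype, candw, L, rng,
                      cand, wbuf):
    """Redraw u's rotational state among {unbound} + candidates, heat bath."""
    n, W = _collect(u, pos[u, 0], pos[u, 1], pos[u, 2], occ, partner, btype,
                    candw, L, cand, wbuf)
    r = rand_double(rng) * W
    chosen = np.int64(-1)
    if r >= 1.0 and n > 0:
        r -= 1.0
        chosen = cand[n - 1]  # fallback absorbs rounding at the top edge
        for i in range(n):
            if r < wbuf[i]:
                chosen = cand[i]
                break
            r -= wbuf[i]
    if chosen != partner[u]:
        _unbind(u, partner, bond_count, btype)
        if chosen >= 0:
            _bind(u, chosen, partner, bond_count, btype)


# ----------------------------------------------------------------------
# individual moves: each returns True when accepted
# ----------------------------------------------------------------------

@njit(cache=True)
def move_rotation(pos, occ, partner, bond_count, btype, is_sticker, candw, L,
                  rng, cand, wbuf):
    u = rand_below(rng, len(btype))
    if not is_sticker[btype[u]]:
        return False  # rejected outright for spacers
    _rebond_heat_bath(u, pos, occ, partner, bond_count, btype, candw, L, rng,
                      cand, wbuf)
    return True


@njit(cache=True)
def move_local(pos, occ, partner, bond_count, btype, is_sticker, candw, L,
               adj_start, adj_nbr, adj_l2, rng, cand, wbuf):
    u = rand_below(rng, len(btype))
    dx = rand_below(rng, 5) - 2
    dy = rand_below(rng, 5) - 2
    dz = rand_below(rng, 5) - 2
    nx = (pos[u, 0] + dx) % L
    ny = (pos[u, 1] + dy) % L
    nz = (pos[u, 2] + dz) % L
    nf = _flat(nx, ny, nz, L)
    ov = occ[nf]
    if ov >= 0 and ov != u:
        return False  # hard-core clash
    for k in range(adj_start[u], adj_start[u + 1]):
        v = adj_nbr[k]
        if _d2(nx, ny, nz, pos[v, 0], pos[v, 1], pos[v, 2], L) > adj_l2[k]:
            return False  # tether would snap
    sticker = is_sticker[btype[u]]
    of = _flat(pos[u, 0], pos[u, 1], pos[u, 2], L)
    if sticker:
        w_old = _weight_at(u, pos[u, 0], pos[u, 1], pos[u, 2], occ, partner,
                           btype, candw, L)
        occ[of] = -1  # vacate so u is not its own neighbor at the new site
        w_new = _weight_at(u, nx, ny, nz, occ, partner, btype, candw, L)
        if w_new < w_old and rand_double(rng) * w_old >= w_new:
            occ[of] = u
            return False
    else:
        occ[of] = -1
    pos[u, 0] = nx
    pos[u, 1] = ny
    pos[u, 2] = nz
    occ[nf] = u
    if sticker:
        _rebond_heat_bath(u, pos, occ, partner, bond_count, btype, candw, L,
                          rng, cand, wbuf)
    elif partner[u] >= 0:
        _unbind(u, partner, bond_count, btype)  # unreachable: spacers never bond
    return True


@njit(cache=True)
def _chain_weight(c, chain_start, pos, occ, partner, btype, is_sticker, candw, L):
    W = 1.0
    for u in range(chain_start[c], chain_start[c + 1]):
        if is_sticker[btype[u]]:
            W *= _weight_at(u, pos[u, 0], pos[u, 1], pos[u, 2], occ, partner,
                            btype, candw, L)
    return W


@njit(cache=True)
def _rebond_chain(c, chain_start, pos, occ, partner, bond_count, btype,
                  is_sticker, candw, L, rng, cand, wbuf):
    """Break every bond touching chain c, then heat-bath rebond its stickers."""
    for u in range(chain_start[c], chain_start[c + 1]):
        if partner[u] >= 0:
            _unbind(u, partner, bond_count, btype)
    for u in range(chain_start[c], chain_start[c + 1]):
        if is_sticker[btype[u]]:
            _rebond_heat_bath(u, pos, occ, partner, bond_count, btype, candw,
                              L, rng, cand, wbuf)


@njit(cache=True)
def move_reptation(pos, occ, partner, bond_count, btype, is_sticker, candw, L,
                   chain_start, chain_mt, mt_rept_ok, mt_rept_reach,
                   mt_rept_l2, rept_order, rng, cand, wbuf, save):
    c = rand_below(rng, len(chain_mt))
    mt = chain_mt[c]
    if not mt_rept_ok[mt]:
        return False  # branched or heterogeneous-linker molecule
    s = chain_start[c]
    nb = chain_start[c + 1] - s
    reach = mt_rept_reach[mt]
    l2max = mt_rept_l2[mt]
    forward = rand_below(rng, 2) == 0
    # path-ordered global ids; head slithers, tail vacates
    if forward:
        head = s + rept_order[s]
        tail = s + rept_order[s + nb - 1]
    else:
        head = s + rept_order[s + nb - 1]
        tail = s + rept_order[s]
    span = 2 * reach + 1
    tf = _flat(pos[tail, 0], pos[tail, 1], pos[tail, 2], L)
    nx = ny = nz = np.int64(0)
    found = False
    for _trial in range(10):
        dx = rand_below(rng, span) - reach
        dy = rand_below(rng, span) - reach
        dz = rand_below(rng, span) - reach
        d2 = dx * dx + dy * dy + dz * dz
        if d2 == 0 or d2 > l2max:
            continue
        tx = (pos[head, 0] + dx) % L
        ty = (pos[head, 1] + dy) % L
        tz = (pos[head, 2] + dz) % L
        f = _flat(tx, ty, tz, L)
        ov = occ[f]
        if ov == -1 or ov == tail:  # tail site is vacated by the slide
            nx, ny, nz = tx, ty, tz
            found = True
            break
    if not found:
        return False
    w_old = _chain_weight(c, chain_start, pos, occ, partner, btype, is_sticker,
                          candw, L)
    # save and apply the slide
    for k in range(nb):
        g = s + rept_order[s + k]
        save[k, 0] = pos[g, 0]
        save[k, 1] = pos[g, 1]
        save[k, 2] = pos[g, 2]
        occ[_flat(pos[g, 0], pos[g, 1], pos[g, 2], L)] = -1
    if forward:
        # bead at path slot k takes the old position of slot k-1; slot 0 -> new
        for k in range(nb - 1, 0, -1):
            g = s + rept_order[s + k]
            pos[g, 0] = save[k - 1, 0]
            pos[g, 1] = save[k - 1, 1]
            pos[g, 2] = save[k - 1, 2]
        pos[head, 0] = nx
        pos[head, 1] = ny
        pos[head, 2] = nz
    else:
        for k in range(nb - 1):
            g = s + rept_order[s + k]
            pos[g, 0] = save[k + 1, 0]
            pos[g, 1] = save[k + 1, 1]
            pos[g, 2] = save[k + 1, 2]
        pos[head, 0] = nx
        pos[head, 1] = ny
        pos[head, 2] = nz
    for k in range(nb):
        g = s + k
        occ[_flat(pos[g, 0], pos[g, 1], pos[g, 2], L)] = g
    w_new = _chain_weight(c, chain_start, pos, occ, partner, btype, is_sticker,
                          candw, L)
    if w_new < w_old and rand_double(rng) * w_old >= w_new:
        # revert
        for k in range(nb):
            g = s + k
            occ[_flat(pos[g, 0], pos[g, 1], pos[g, 2], L)] = -1
        for k in range(nb):
            g = s + rept_order[s + k]
            pos[g, 0] = save[k, 0]
            pos[g, 1] = save[k, 1]
            pos[g, 2] = save[k, 2]
            occ[_flat(save[k, 0], save[k, 1], save[k, 2], L)] = g
        return False
    _rebond_chain(c, chain_start, pos, occ, partner, bond_count, btype,
                  is_sticker, candw, L, rng, cand, wbuf)
    return True


@njit(inline="always")
def _draw_displacement(rng, L):
    """Per-component uniform on [-ceil(3L/8), ceil(3L/8)]."""
    D = (3 * L + 7) // 8
    span = 2 * D + 1
    dx = rand_below(rng, span) - D
    dy = rand_below(rng, span) - D
    dz = rand_below(rng, span) - D
    return dx, dy, dz


@njit(cache=True)
def move_chain_translation(pos, occ, partner, bond_count, btype, is_sticker,
                           candw, L, chain_start, chain_of, rng, cand, wbuf,
                           save):
    c = rand_below(rng, len(chain_start) - 1)
    s = chain_start[c]
    e = chain_start[c + 1]
    nb = e - s
    found = False
    dx = dy = dz = np.int64(0)
    for _trial in range(10):
        tx, ty, tz = _draw_displacement(rng, L)
        if 16 * (tx * tx + ty * ty + tz * tz) > 9 * L * L:
            continue  # |dr| must stay within 3L/4
        ok = True
        for g in range(s, e):
            x = (pos[g, 0] + tx) % L
            y = (pos[g, 1] + ty) % L
            z = (pos[g, 2] + tz) % L
            ov = occ[_flat(x, y, z, L)]
            if ov >= 0 and chain_of[ov] != c:
                ok = False
                break
        if ok:
            dx, dy, dz = tx, ty, tz
            found = True
            break
    if not found:
        return False
    w_old = _chain_weight(c, chain_start, pos, occ, partner, btype, is_sticker,
                          candw, L)
    for k in range(nb):
        g = s + k
        save[k, 0] = pos[g, 0]
        save[k, 1] = pos[g, 1]
        save[k, 2] = pos[g, 2]
        occ[_flat(pos[g, 0], pos[g, 1], pos[g, 2], L)] = -1
    for k in range(nb):
        g = s + k
        pos[g, 0] = (save[k, 0] + dx) % L
        pos[g, 1] = (save[k, 1] + dy) % L
        pos[g, 2] = (save[k, 2] + dz) % L
        occ[_flat(pos[g, 0], pos[g, 1], pos[g, 2], L)] = g
    w_new = _chain_weight(c, chain_start, pos, occ, partner, btype, is_sticker,
                          candw, L)
    if w_new < w_old and rand_double(rng) * w_old >= w_new:
        for k in range(nb):
            g = s + k
            occ[_flat(pos[g, 0], pos[g, 1], pos[g, 2], L)] = -1
        for k in range(nb):
            g = s + k
            pos[g, 0] = save[k, 0]
            pos[g, 1] = save[k, 1]
            pos[g, 2] = save[k, 2]
            occ[_flat(save[k, 0], save[k, 1], save[k, 2], L)] = g
        return False
    _rebond_chain(c, chain_start, pos, occ, partner, bond_count, btype,
                  is_sticker, candw, L, rng, cand, wbuf)
    return True


@njit(cache=True)
def _gather_cluster(c0, chain_start, chain_of, partner, stamp, stamp_val, queue):
    """BFS over chains connected by inter-chain bonds; returns cluster size."""
    stamp[c0] = stamp_val
    queue[0] = c0
    head = 0
    size = 1
    while head < size:
        c = queue[head]
        head += 1
        for g in range(chain_start[c], chain_start[c + 1]):
            p = partner[g]
            if p >= 0:
                cn = chain_of[p]
                if stamp[cn] != stamp_val:
                    stamp[cn] = stamp_val
                    queue[size] = cn
                    size += 1
    return size


@njit(cache=True)
def move_cluster_translation(pos, occ, partner, L, chain_start, chain_of,
                             rng, stamp, stamp_val, queue):
    c0 = rand_below(rng, len(chain_start) - 1)
    size = _gather_cluster(c0, chain_start, chain_of, partner, stamp,
                           stamp_val, queue)
    dx, dy, dz = _draw_displacement(rng, L)
    if 16 * (dx * dx + dy * dy + dz * dz) > 9 * L * L:
        return False
    # single proposal: accepted iff no displaced bead hits a non-cluster bead
    for ci in range(size):
        c = queue[ci]
        for g in range(chain_start[c], chain_start[c + 1]):
            x = (pos[g, 0] + dx) % L
            y = (pos[g, 1] + dy) % L
            z = (pos[g, 2] + dz) % L
            ov = occ[_flat(x, y, z, L)]
            if ov >= 0 and stamp[chain_of[ov]] != stamp_val:
                return False
    for ci in range(size):
        c = queue[ci]
        for g in range(chain_start[c], chain_start[c + 1]):
            occ[_flat(pos[g, 0], pos[g, 1], pos[g, 2], L)] = -1
    for ci in range(size):
        c = queue[ci]
        for g in range(chain_start[c], chain_start[c + 1]):
            pos[g, 0] = (pos[g, 0] + dx) % L
            pos[g, 1] = (pos[g, 1] + dy) % L
            pos[g, 2] = (pos[g, 2] + dz) % L
            occ[_flat(pos[g, 0], pos[g, 1], pos[g, 2], L)] = g
    # bonds translate rigidly: partner map and E_rot are exactly invariant
    return True


@njit(cache=True)
def move_double_pivot(pos, occ, partner, L, chain_start, chain_of, chain_mt,
                      mt_nbeads, mt_linear, mt_bond_start, bond_a, bond_b,
                      bond_l2, strict, rng, cand, op1, op2):
    u = rand_below(rng, len(chain_of))
    m = chain_of[u]
    mt = chain_mt[m]
    if strict and not mt_linear[mt]:
        return False
    nb = mt_nbeads[mt]
    sm = chain_start[m]
    i = u - sm
    if i >= nb - 1:
        return False  # no (i+1) partner slot
    ncand = 0
    for k in range(124):
        x = (pos[u, 0] + _OFF124[k, 0]) % L
        y = (pos[u, 1] + _OFF124[k, 1]) % L
        z = (pos[u, 2] + _OFF124[k, 2]) % L
        v = occ[_flat(x, y, z, L)]
        if v < 0:
            continue
        n = chain_of[v]
        if n == m or chain_mt[n] != mt:
            continue
        sn = chain_start[n]
        if v - sn != i + 1:
            continue
        # all bonds crossing the cut (a <= i < b) must hold under the swap
        ok = True
        for bi in range(mt_bond_start[mt], mt_bond_start[mt + 1]):
            a = bond_a[bi]
            b = bond_b[bi]
            if a <= i < b:
                if _d2(pos[sm + a, 0], pos[sm + a, 1], pos[sm + a, 2],
                       pos[sn + b, 0], pos[sn + b, 1], pos[sn + b, 2], L) > bond_l2[bi]:
                    ok = False
                    break
                if _d2(pos[sn + a, 0], pos[sn + a, 1], pos[sn + a, 2],
                       pos[sm + b, 0], pos[sm + b, 1], pos[sm + b, 2], L) > bond_l2[bi]:
                    ok = False
                    break
        if ok:
            cand[ncand] = n
            ncand += 1
    if ncand == 0:
        return False
    n = cand[rand_below(rng, ncand)]
    sn = chain_start[n]
    # suffix swap is a pure relabeling: geometry, bonds and E are unchanged
    for k in range(i + 1, nb):
        op1[k] = partner[sm + k]
        op2[k] = partner[sn + k]
    for k in range(i + 1, nb):
        g1 = sm + k
        g2 = sn + k
        for d in range(3):
            t = pos[g1, d]
            pos[g1, d] = pos[g2, d]
            pos[g2, d] = t
        occ[_flat(pos[g1, 0], pos[g1, 1], pos[g1, 2], L)] = g1
        occ[_flat(pos[g2, 0], pos[g2, 1], pos[g2, 2], L)] = g2
    for k in range(i + 1, nb):
        g1 = sm + k
        g2 = sn + k
        p1 = op2[k]  # bead g1 inherits old g2's bond
        p2 = op1[k]
        if p1 >= 0 and sn + i + 1 <= p1 < sn + nb:
            p1 = sm + (p1 - sn)
        elif p1 >= 0 and sm + i + 1 <= p1 < sm + nb:
            p1 = sn + (p1 - sm)
        if p2 >= 0 and sn + i + 1 <= p2 < sn + nb:
            p2 = sm + (p2 - sn)
        elif p2 >= 0 and sm + i + 1 <= p2 < sm + nb:
            p2 = sn + (p2 - sm)
        partner[g1] = p1
        partner[g2] = p2
    for k in range(i + 1, nb):
        for g in (sm + k, sn + k):
            p = partner[g]
            if p >= 0:
                in_swap = (sm + i + 1 <= p < sm + nb) or (sn + i + 1 <= p < sn + nb)
                if not in_swap:
                    partner[p] = g
    return True


# ----------------------------------------------------------------------
# state check (kernel-side, for periodic debug verification)
# ----------------------------------------------------------------------

@njit(cache=True)
def check_state(pos, occ, partner, bond_count, btype, is_sticker, eps, L,
                adj_start, adj_nbr, adj_l2):
    """Return 0 when all invariants hold, else a small error code."""
    n = len(btype)
    nocc = 0
    for f in range(len(occ)):
        if occ[f] >= 0:
            nocc += 1
    if nocc != n:
        return 1
    for u in range(n):
        if occ[_flat(pos[u, 0], pos[u, 1], pos[u, 2], L)] != u:
            return 2
    T = eps.shape[0]
    counts = np.zeros((T, T), dtype=np.int64)
    for u in range(n):
        v = partner[u]
        if v >= 0:
            if v == u or partner[v] != u:
                return 3
            if not is_sticker[btype[u]]:
                return 4
            if eps[btype[u], btype[v]] == 0.0:
                return 5
            if _d2(pos[u, 0], pos[u, 1], pos[u, 2],
                   pos[v, 0], pos[v, 1], pos[v, 2], L) > 3:
                return 6
            if v > u:
                a = btype[u]
                b = btype[v]
                if a > b:
                    a, b = b, a
                counts[a, b] += 1
        for k in range(adj_start[u], adj_start[u + 1]):
            w = adj_nbr[k]
            if _d2(pos[u, 0], pos[u, 1], pos[u, 2],
                   pos[w, 0], pos[w, 1], pos[w, 2], L) > adj_l2[k]:
                return 7
    for a in range(T):
        for b in range(T):
            if counts[a, b] != bond_count[a, b]:
                return 8
    return 0


# ----------------------------------------------------------------------
# run loop
# ----------------------------------------------------------------------

@njit(cache=True)
def run_kernel(pos, occ, partner, bond_count,
               btype, chain_of, chain_start, chain_mt, mt_nbeads, mt_linear,
               adj_start, adj_nbr, adj_l2,
               mt_bond_start, bond_a, bond_b, bond_l2,
               mt_rept_ok, mt_rept_reach, mt_rept_l2, rept_order,
               is_sticker, candw, eps, L,
               move_cum, n_steps, equil, sample_every, strict_dp, check_every,
               rng,
               snap_pos, snap_partner, snap_steps,
               attempts, accepts):
    n_beads = len(btype)
    n_chains = len(chain_mt)
    cand = np.empty(130, dtype=np.int64)
    wbuf = np.empty(130, dtype=np.float64)
    save = np.empty((n_beads if n_beads > 0 else 1, 3), dtype=np.int64)
    stamp = np.full(n_chains if n_chains > 0 else 1, -1, dtype=np.int64)
    queue = np.empty(n_chains if n_chains > 0 else 1, dtype=np.int64)
    op1 = np.empty(n_beads if n_beads > 0 else 1, dtype=np.int64)
    op2 = np.empty(n_beads if n_beads > 0 else 1, dtype=np.int64)
    nsnap = 0
    max_snap = snap_steps.shape[0]
    for step in range(1, n_steps + 1):
        r = rand_double(rng)
        kind = N_MOVES - 1
        for k in range(N_MOVES):
            if r < move_cum[k]:
                kind = k
                break
        attempts[kind] += 1
        acc = False
        if kind == 2:
            acc = move_rotation(pos, occ, partner, bond_count, btype,
                                is_sticker, candw, L, rng, cand, wbuf)
        elif kind == 3:
            acc = move_local(pos, occ, partner, bond_count, btype, is_sticker,
                             candw, L, adj_start, adj_nbr, adj_l2, rng, cand,
                             wbuf)
        elif kind == 1:
            acc = move_chain_translation(pos, occ, partner, bond_count, btype,
                                         is_sticker, candw, L, chain_start,
                                         chain_of, rng, cand, wbuf, save)
        elif kind == 0:
            acc = move_cluster_translation(pos, occ, partner, L, chain_start,
                                           chain_of, rng, stamp, step, queue)
        elif kind == 4:
            acc = move_reptation(pos, occ, partner, bond_count, btype,
                                 is_sticker, candw, L, chain_start, chain_mt,
                                 mt_rept_ok, mt_rept_reach, mt_rept_l2,
                                 rept_order, rng, cand, wbuf, save)
        else:
            acc = move_double_pivot(pos, occ, partner, L, chain_start,
                                    chain_of, chain_mt, mt_nbeads, mt_linear,
                                    mt_bond_start, bond_a, bond_b, bond_l2,
                                    strict_dp, rng, cand, op1, op2)
        if acc:
            accepts[kind] += 1
        if check_every > 0 and step % check_every == 0:
            code = check_state(pos, occ, partner, bond_count, btype,
                               is_sticker, eps, L, adj_start, adj_nbr, adj_l2)
            if code != 0:
                return -code, step, nsnap
        if (sample_every > 0 and step > equil
                and (step - equil) % sample_every == 0 and nsnap < max_snap):
            for b in range(n_beads):
                snap_pos[nsnap, b, 0] = pos[b, 0]
                snap_pos[nsnap, b, 1] = pos[b, 1]
                snap_pos[nsnap, b, 2] = pos[b, 2]
                snap_partner[nsnap, b] = partner[b]
            snap_steps[nsnap] = step
            nsnap += 1
    return 0, n_steps, nsnap
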