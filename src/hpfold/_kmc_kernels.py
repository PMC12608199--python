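"""Numba kernels for Gillespie kinetic Monte Carlo on the cubic lattice.

The move set is corner flips (an interior bead whose two bonds are
perpendicular hops to the free diagonal site) and 90-degree end flips
(a terminal bead rotates to one of the four sites perpendicular to its
terminal bond); 180-degree end reversals are excluded.  Rates are
Metropolis, W = min(1, exp(-dE/T)), the waiting time for an event is
exponential with rate W_T = sum(W_i), and the move is chosen with
probability W_i / W_T.

Randomness comes from an explicit xoshiro256++ generator seeded through
splitmix64, so trajectories are bit-reproducible across platforms and
per-(temperature, run) streams are independent.
"""

from __future__ import annotations

import numpy as np
from numba import njit, uint64

U64 = np.uint64


@njit(cache=True)
def _splitmix64(state):
    z = uint64(state + uint64(0x9E3779B97F4A7C15))
    z = (z ^ (z >> uint64(30))) * uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> uint64(27))) * uint64(0x94D049BB133111EB)
    return z ^ (z >> uint64(31))


@njit(cache=True)
def seed_state(seed):
    s = np.empty(4, dtype=np.uint64)
    z = uint64(seed)
    for i in range(4):
        z = uint64(z + uint64(0x9E3779B97F4A7C15))
        s[i] = _splitmix64(z)
    return s


@njit(cache=True)
def _rotl(x, k):
    return uint64((x << uint64(k)) | (x >> uint64(64 - k)))


@njit(cache=True)
def _next_u64(s):
    result = uint64(_rotl(uint64(s[0] + s[3]), 23) + s[0])
    t = uint64(s[1] << uint64(17))
    s[2] ^= s[0]
    s[3] ^= s[1]
    s[1] ^= s[2]
    s[0] ^= s[3]
    s[2] ^= t
    s[3] = _rotl(s[3], 45)
    return result


@njit(cache=True)
def _uniform_open(s):
    """Uniform on the open interval (0, 1); a raw zero is redrawn."""
    while True:
        u = (_next_u64(s) >> uint64(11)) * (1.0 / 9007199254740992.0)
        if u > 0.0:
            return u


@njit(cache=True)
def _delta_e(i, oldp, newp, occ, types, emat, deltas):
    """Contact-energy change when bead i hops oldp -> newp."""
    de = np.int64(0)
    for d in range(6):
        j = occ[oldp + deltas[d]]
        if j != 0:
            jj = j - 1
            if jj < i - 1 or jj > i + 1:
                de -= emat[types[i], types[jj]]
        j = occ[newp + deltas[d]]
        if j != 0:
            jj = j - 1
            if jj < i - 1 or jj > i + 1:
                de += emat[types[i], types[jj]]
    return de


@njit(cache=True)
def build_catalog(n, posf, occ, types, emat, deltas, mb, mt, mde):
    """All legal corner/end-flip proposals; returns the move count K."""
    K = 0
    # 90-degree end flips: 4 sites adjacent to the pivot, perpendicular to
    # the terminal bond (current site and its 180-degree antipode excluded)
    for e in range(2):
        endi = 0 if e == 0 else n - 1
        pivot = posf[1] if e == 0 else posf[n - 2]
        cur = posf[endi]
        anti = 2 * pivot - cur
        for d in range(6):
            t = pivot + deltas[d]
            if t == cur or t == anti or occ[t] != 0:
                continue
            mb[K] = endi
            mt[K] = t
            mde[K] = _delta_e(endi, cur, t, occ, types, emat, deltas)
            K += 1
    # corner flips: interior bead with perpendicular bonds
    for i in range(1, n - 1):
        d1 = posf[i - 1] - posf[i]
        d2 = posf[i + 1] - posf[i]
        if d1 + d2 != 0:
            t = posf[i] + d1 + d2
            if occ[t] == 0:
                mb[K] = i
                mt[K] = t
                mde[K] = _delta_e(i, posf[i], t, occ, types, emat, deltas)
                K += 1
    return K


@njit(cache=True)
def _total_energy(n, posf, occ, types, emat, deltas):
    e = np.int64(0)
    for i in range(n):
        for d in range(6):
            j = occ[posf[i] + deltas[d]]
            if j != 0:
                jj = j - 1
                if jj > i + 1:
                    e += emat[types[i], types[jj]]
    return e


@njit(cache=True)
def _recenter(n, posf, occ, box):
    cx = 0
    cy = 0
    cz = 0
    b2 = box * box
    for i in range(n):
        p = posf[i]
        cz += p // b2
        cy += (p % b2) // box
        cx += p % box
    sx = box // 2 - cx // n
    sy = box // 2 - cy // n
    sz = box // 2 - cz // n
    shift = sx + box * sy + b2 * sz
    for i in range(n):
        occ[posf[i]] = 0
    for i in range(n):
        posf[i] += shift
        occ[posf[i]] = np.uint8(i + 1)


@njit(cache=True)
def _near_edge(p, box):
    b2 = box * box
    z = p // b2
    y = (p % b2) // box
    x = p % box
    m = 3
    return x < m or x >= box - m or y < m or y >= box - m or z < m or z >= box - m


@njit(cache=True)
def init_rod(n, box, posf, occ):
    b2 = box * box
    x0 = box // 2 - n // 2
    for i in range(n):
        p = (x0 + i) + box * (box // 2) + b2 * (box // 2)
        posf[i] = p
        occ[p] = np.uint8(i + 1)


@njit(cache=True)
def run_fpt(n, types, emat, wtab, woff, e0_target, seed, max_events, check_every):
    """One first-passage trajectory from the straight rod.

    Returns (time, events, status, energy) where status is
    1 = reached the target energy, 0 = censored at max_events,
    -1 = trapped (no legal move), -2 = incremental-energy self-check
    failed (only possible with check_every > 0).

    The catalog construction is an unrolled in-line copy of
    :func:`build_catalog` (same move ordering, shared old-site term per
    end bead) — this loop runs ~10^6 times per trajectory.
    """
    box = 4 * n
    b2 = box * box
    posf = np.zeros(n, dtype=np.int64)
    occ = np.zeros(box * box * box, dtype=np.uint8)
    deltas = np.empty(6, dtype=np.int64)
    deltas[0] = 1
    deltas[1] = -1
    deltas[2] = box
    deltas[3] = -box
    deltas[4] = b2
    deltas[5] = -b2
    init_rod(n, box, posf, occ)

    mb = np.zeros(n + 8, dtype=np.int64)
    mt = np.zeros(n + 8, dtype=np.int64)
    mde = np.zeros(n + 8, dtype=np.int64)
    mw = np.zeros(n + 8, dtype=np.float64)
    rng = seed_state(seed)

    t = 0.0
    events = np.int64(0)
    ecur = np.int64(0)
    while True:
        if ecur == e0_target:
            return t, events, np.int64(1), ecur
        if events >= max_events:
            return t, events, np.int64(0), ecur
        K = 0
        wt = 0.0
        for e in range(2):
            endi = 0 if e == 0 else n - 1
            pivot = posf[1] if e == 0 else posf[n - 2]
            cur = posf[endi]
            anti = 2 * pivot - cur
            ti = types[endi]
            loss = np.int64(0)
            for q in (cur + 1, cur - 1, cur + box, cur - box, cur + b2, cur - b2):
                j = occ[q]
                if j != 0:
                    jj = j - 1
                    if jj < endi - 1 or jj > endi + 1:
                        loss += emat[ti, types[jj]]
            for tp in (
                pivot + 1, pivot - 1, pivot + box, pivot - box, pivot + b2, pivot - b2
            ):
                if tp == cur or tp == anti or occ[tp] != 0:
                    continue
                gain = np.int64(0)
                for q in (tp + 1, tp - 1, tp + box, tp - box, tp + b2, tp - b2):
                    j = occ[q]
                    if j != 0:
                        jj = j - 1
                        if jj < endi - 1 or jj > endi + 1:
                            gain += emat[ti, types[jj]]
                de = gain - loss
                mb[K] = endi
                mt[K] = tp
                mde[K] = de
                w = wtab[de + woff]
                mw[K] = w
                wt += w
                K += 1
        for i in range(1, n - 1):
            pi = posf[i]
            dd = posf[i - 1] + posf[i + 1] - 2 * pi
            if dd != 0:
                tp = pi + dd
                if occ[tp] == 0:
                    ti = types[i]
                    de = np.int64(0)
                    for q in (pi + 1, pi - 1, pi + box, pi - box, pi + b2, pi - b2):
                        j = occ[q]
                        if j != 0:
                            jj = j - 1
                            if jj < i - 1 or jj > i + 1:
                                de -= emat[ti, types[jj]]
                    for q in (tp + 1, tp - 1, tp + box, tp - box, tp + b2, tp - b2):
                        j = occ[q]
                        if j != 0:
                            jj = j - 1
                            if jj < i - 1 or jj > i + 1:
                                de += emat[ti, types[jj]]
                    mb[K] = i
                    mt[K] = tp
                    mde[K] = de
                    w = wtab[de + woff]
                    mw[K] = w
                    wt += w
                    K += 1
        if K == 0:
            return t, events, np.int64(-1), ecur
        r = _uniform_open(rng) * wt
        acc = 0.0
        chosen = K - 1
        for k in range(K):
            acc += mw[k]
            if r <= acc:
                chosen = k
                break
        t += -np.log(_uniform_open(rng)) / wt
        i = mb[chosen]
        occ[posf[i]] = 0
        posf[i] = mt[chosen]
        occ[posf[i]] = np.uint8(i + 1)
        ecur += mde[chosen]
        events += 1
        if _near_edge(posf[i], box):
            _recenter(n, posf, occ, box)
        if check_every > 0 and events % check_every == 0:
            if _total_energy(n, posf, occ, types, emat, deltas) != ecur:
                return t, events, np.int64(-2), ecur


@njit(cache=True)
def catalog_snapshot(n, coords, types, emat):
    """Catalog for an arbitrary conformation given as (N, 3) coordinates.

    Returns (K, bead, target_xyz, dE) with targets decoded back to
    coordinates; used to cross-check the kernel's move generation against
    the pure-Python reference.
    """
    box = 4 * n + 8
    b2 = box * box
    occ = np.zeros(box * box * box, dtype=np.uint8)
    posf = np.zeros(n, dtype=np.int64)
    lo0 = coords[:, 0].min()
    lo1 = coords[:, 1].min()
    lo2 = coords[:, 2].min()
    for i in range(n):
        p = (
            (coords[i, 0] - lo0 + box // 3)
            + box * (coords[i, 1] - lo1 + box // 3)
            + b2 * (coords[i, 2] - lo2 + box // 3)
        )
        posf[i] = p
        occ[p] = np.uint8(i + 1)
    deltas = np.empty(6, dtype=np.int64)
    deltas[0] = 1
    deltas[1] = -1
    deltas[2] = box
    deltas[3] = -box
    deltas[4] = b2
    deltas[5] = -b2
    mb = np.zeros(n + 8, dtype=np.int64)
    mt = np.zeros(n + 8, dtype=np.int64)
    mde = np.zeros(n + 8, dtype=np.int64)
    K = build_catalog(n, posf, occ, types, emat, deltas, mb, mt, mde)
    txyz = np.zeros((K, 3), dtype=np.int64)
    for k in range(K):
        p = mt[k]
        txyz[k, 0] = p % box - (box // 3) + lo0
        txyz[k, 1] = (p % b2) // box - (box // 3) + lo1
        txyz[k, 2] = p // b2 - (box // 3) + lo2
    return K, mb[:K].copy(), txyz, mde[:K].copy()
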