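"""Numba kernels for exhaustive conformation enumeration.

Walks are grown depth-first on the simple cubic lattice with incremental
contact-energy bookkeeping.  Two traversal modes share one code path:

``symmetry`` mode enumerates one representative per point-group symmetry
class (first step +x, first non-x step +y, first out-of-plane step +z) and
weights it by its orientation multiplicity — 1 for the straight rod, 4 for
planar walks, 8 for three-dimensional walks.  ``fixed`` mode enumerates
every walk whose first step is +x with weight 1.  Both produce the same
density of states; symmetry mode visits ~8x fewer leaves.

Occupancy is tracked in a flat uint8 grid over a box of side 2N+1 centered
on the start bead, so no walk coordinate can leave the addressable region.
"""

from __future__ import annotations

import numpy as np
from numba import njit, uint64

# Direction order matches hpfold.core.DIRECTIONS = "RLUDFB":
# +x, -x, +y, -y, +z, -z.

_HASH_EMPTY = np.uint64(0xFFFFFFFFFFFFFFFF)
_HASH_MULT = np.uint64(0x9E3779B97F4A7C15)


@njit(cache=True)
def _popcount64(x):
    x = uint64(x)
    x = x - ((x >> uint64(1)) & uint64(0x5555555555555555))
    x = (x & uint64(0x3333333333333333)) + ((x >> uint64(2)) & uint64(0x3333333333333333))
    x = (x + (x >> uint64(4))) & uint64(0x0F0F0F0F0F0F0F0F)
    return int((x * uint64(0x0101010101010101)) >> uint64(56))


@njit(cache=True)
def dos_kernel(n_beads, types, emat, symmetry_mode, hist, best_dirs):
    """Exact density of states for one or more sequences in a single pass.

    Parameters
    ----------
    n_beads : int
    types : (S, N) uint8 — residue type codes per sequence (P=0, H=1)
    emat : (S, 2, 2) int64 — contact-energy lookup per sequence
    symmetry_mode : bool — symmetry-weighted vs fixed-first-step traversal
    hist : (S, HB) int64, zeroed by caller — counts indexed by -E
    best_dirs : (N-1,) int8, out — direction string of a minimum-energy
        conformation for sequence 0 (direction indices into "RLUDFB")

    Returns the ground-state energy of sequence 0.
    """
    n = n_beads
    n_seq = types.shape[0]
    L = 2 * n + 1
    center = n + L * n + L * L * n
    occ = np.zeros(L * L * L, dtype=np.uint8)

    deltas = np.empty(6, dtype=np.int64)
    deltas[0] = 1
    deltas[1] = -1
    deltas[2] = L
    deltas[3] = -L
    deltas[4] = L * L
    deltas[5] = -L * L

    choice = np.full(n, np.int8(-1), dtype=np.int8)
    state = np.zeros(n, dtype=np.uint8)  # 0 axial, 1 planar, 2 three-dimensional
    posf = np.zeros(n, dtype=np.int64)
    edelta = np.zeros((n, n_seq), dtype=np.int64)
    ecur = np.zeros(n_seq, dtype=np.int64)

    posf[0] = center
    occ[center] = 1
    best_e = np.int64(0)

    k = 1
    while k >= 1:
        c = choice[k] + 1
        st = state[k - 1]
        found = -1
        tgt = np.int64(0)
        while c < 6:
            ok = True
            if k == 1:
                ok = c == 0  # first step is +x
            elif symmetry_mode:
                if st == 0:
                    ok = c <= 2  # +/-x or the first bend, +y
                elif st == 1:
                    ok = c <= 4  # in-plane moves or the first +z step
            if ok:
                t = posf[k - 1] + deltas[c]
                if occ[t] == 0:
                    found = c
                    tgt = t
                    break
            c += 1
        if found < 0:
            choice[k] = -1
            k -= 1
            if k >= 1:
                occ[posf[k]] = 0
                for s in range(n_seq):
                    ecur[s] -= edelta[k, s]
            continue

        choice[k] = found
        if found >= 4:
            state[k] = 2
        elif found >= 2:
            state[k] = 1 if st < 1 else st
        else:
            state[k] = st

        # place bead k: add contact energies with nonconsecutive occupied
        # neighbors (the bonded predecessor has occ value k)
        for s in range(n_seq):
            edelta[k, s] = 0
        tk_row = k
        for d in range(6):
            j = occ[tgt + deltas[d]]
            if j != 0 and j != k:
                for s in range(n_seq):
                    edelta[k, s] += emat[s, types[s, tk_row], types[s, j - 1]]
        occ[tgt] = np.uint8(k + 1)
        posf[k] = tgt
        for s in range(n_seq):
            ecur[s] += edelta[k, s]

        if k == n - 1:
            if symmetry_mode:
                stf = state[k]
                w = 1 if stf == 0 else (4 if stf == 1 else 8)
            else:
                w = 1
            for s in range(n_seq):
                hist[s, -ecur[s]] += w
            if ecur[0] < best_e:
                best_e = ecur[0]
                for i in range(1, n):
                    best_dirs[i - 1] = choice[i]
            # retract the leaf bead and keep scanning at this level
            occ[tgt] = 0
            for s in range(n_seq):
                ecur[s] -= edelta[k, s]
        else:
            k += 1

    return best_e


@njit(cache=True)
def mask_kernel(n_beads, pair_bit, table_keys, table_counts):
    """One symmetry-weighted pass recording contact-set signatures.

    Each complete walk contributes its set of nonconsecutive
    nearest-neighbor pairs, encoded as a bitmask over the feasible pair
    slots (``pair_bit[i, j]`` = bit index, -1 if infeasible), with its
    1/4/8 orientation weight into an open-addressing hash table.

    Returns the number of distinct signatures, or -1 if the table
    overflowed (caller should retry with a larger table).
    """
    n = n_beads
    L = 2 * n + 1
    center = n + L * n + L * L * n
    occ = np.zeros(L * L * L, dtype=np.uint8)

    deltas = np.empty(6, dtype=np.int64)
    deltas[0] = 1
    deltas[1] = -1
    deltas[2] = L
    deltas[3] = -L
    deltas[4] = L * L
    deltas[5] = -L * L

    cap = table_keys.shape[0]
    cap_mask = uint64(cap - 1)
    limit = (cap * 7) // 8
    n_used = 0

    choice = np.full(n, np.int8(-1), dtype=np.int8)
    state = np.zeros(n, dtype=np.uint8)
    posf = np.zeros(n, dtype=np.int64)
    mdelta = np.zeros(n, dtype=np.uint64)
    mcur = uint64(0)

    posf[0] = center
    occ[center] = 1

    k = 1
    while k >= 1:
        c = choice[k] + 1
        st = state[k - 1]
        found = -1
        tgt = np.int64(0)
        while c < 6:
            ok = True
            if k == 1:
                ok = c == 0
            elif st == 0:
                ok = c <= 2
            elif st == 1:
                ok = c <= 4
            if ok:
                t = posf[k - 1] + deltas[c]
                if occ[t] == 0:
                    found = c
                    tgt = t
                    break
            c += 1
        if found < 0:
            choice[k] = -1
            k -= 1
            if k >= 1:
                occ[posf[k]] = 0
                mcur ^= mdelta[k]
            continue

        choice[k] = found
        if found >= 4:
            state[k] = 2
        elif found >= 2:
            state[k] = 1 if st < 1 else st
        else:
            state[k] = st

        md = uint64(0)
        for d in range(6):
            j = occ[tgt + deltas[d]]
            if j != 0 and j != k:
                md |= uint64(1) << uint64(pair_bit[j - 1, k])
        occ[tgt] = np.uint8(k + 1)
        posf[k] = tgt
        mdelta[k] = md
        mcur ^= md

        if k == n - 1:
            stf = state[k]
            w = 1 if stf == 0 else (4 if stf == 1 else 8)
            h = (uint64(mcur) * _HASH_MULT) & cap_mask
            while True:
                key = table_keys[h]
                if key == mcur:
                    table_counts[h] += w
                    break
                if key == _HASH_EMPTY:
                    if n_used >= limit:
                        return -1
                    table_keys[h] = mcur
                    table_counts[h] = w
                    n_used += 1
                    break
                h = (h + uint64(1)) & cap_mask
            occ[tgt] = 0
            mcur ^= md
        else:
            k += 1

    return n_used


@njit(cache=True)
def screen_kernel(
    masks, counts, group_start, group_pc, eHH, eHP, ePP, pair_i, pair_j, out_e0, out_n0
):
    """Ground-state energy and degeneracy of every sequence of length N.

    ``masks``/``counts`` are the distinct contact-set signatures and their
    weighted conformation counts, ordered by decreasing contact number;
    ``group_start``/``group_pc`` delimit the blocks of equal contact
    number.  For sequence code ``s`` (bit i = residue i type, H=1) the
    energy of a signature is recovered from three popcounts against the
    sequence-induced HH/HP/PP pair masks.  Blocks are scanned densest
    first and abandoned once even an all-HH block could not reach the
    current minimum, which keeps the scan short for well-designed
    sequences.
    """
    n_pairs = pair_i.shape[0]
    n_groups = group_start.shape[0] - 1
    n_seq = out_e0.shape[0]
    for s in range(n_seq):
        hh = uint64(0)
        hp = uint64(0)
        pp = uint64(0)
        for p in range(n_pairs):
            ti = (s >> pair_i[p]) & 1
            tj = (s >> pair_j[p]) & 1
            bit = uint64(1) << uint64(p)
            if ti == 1 and tj == 1:
                hh |= bit
            elif ti == 0 and tj == 0:
                pp |= bit
            else:
                hp |= bit
        best = np.int64(1)
        cnt = np.int64(0)
        for g in range(n_groups):
            pc = group_pc[g]
            if best <= 0 and eHH * pc > best:
                break
            for idx in range(group_start[g], group_start[g + 1]):
                m = masks[idx]
                e = (
                    eHH * _popcount64(m & hh)
                    + eHP * _popcount64(m & hp)
                    + ePP * _popcount64(m & pp)
                )
                if e < best:
                    best = e
                    cnt = counts[idx]
                elif e == best:
                    cnt += counts[idx]
        out_e0[s] = best
        out_n0[s] = cnt


@njit(cache=True)
def eval_sequence_on_masks(masks, counts, eHH, eHP, ePP, pair_i, pair_j, tcodes, hist):
    """Full density of states of one sequence from the signature table."""
    n_pairs = pair_i.shape[0]
    hh = uint64(0)
    hp = uint64(0)
    pp = uint64(0)
    for p in range(n_pairs):
        ti = tcodes[pair_i[p]]
        tj = tcodes[pair_j[p]]
        bit = uint64(1) << uint64(p)
        if ti == 1 and tj == 1:
            hh |= bit
        elif ti == 0 and tj == 0:
            pp |= bit
        else:
            hp |= bit
    for idx in range(masks.shape[0]):
        m = masks[idx]
        e = (
            eHH * _popcount64(m & hh)
            + eHP * _popcount64(m & hp)
            + ePP * _popcount64(m & pp)
        )
        hist[-e] += counts[idx]
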