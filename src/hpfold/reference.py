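"""Naive reference enumerator used as an independent oracle.

Walks are generated by plain recursive growth with no incremental energy
bookkeeping, no symmetry weighting beyond fixing the first step, and the
energy of each complete walk recomputed from scratch via
:func:`hpfold.core.energy`.  Deliberately unoptimized: its only job is to
cross-check the production enumerator on small chains (N <= 8).
"""

from __future__ import annotations

from collections import Counter

import numpy as np

from .core import (
    DEFAULT_PARAMS,
    Conformation,
    DIRECTION_VECTORS,
    HPSequence,
    InteractionParams,
    energy,
)

__all__ = ["enumerate_walks_naive", "dos_naive"]


def enumerate_walks_naive(n_beads: int) -> list[Conformation]:
    """All self-avoiding walks of ``n_beads`` beads with first step +x."""
    if n_beads < 2:
        raise ValueError("need at least 2 beads")
    vecs = list(DIRECTION_VECTORS.values())
    walks: list[Conformation] = []

    def grow(path: list[tuple[int, int, int]]) -> None:
        if len(path) == n_beads:
            walks.append(Conformation(np.array(path, dtype=np.int64)))
            return
        x, y, z = path[-1]
        for dx, dy, dz in vecs:
            nxt = (x + dx, y + dy, z + dz)
            if nxt not in path:  # linear scan: naive on purpose
                grow(path + [nxt])

    grow([(0, 0, 0), (1, 0, 0)])
    return walks


def dos_naive(
    seq: HPSequence | str,
    params: InteractionParams = DEFAULT_PARAMS,
) -> dict[int, int]:
    """Exact density of states by brute force, energies recomputed per walk."""
    seq = HPSequence(str(seq))
    counts: Counter[int] = Counter()
    for conf in enumerate_walks_naive(len(seq)):
        counts[energy(conf, seq, params)] += 1
    return dict(counts)
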