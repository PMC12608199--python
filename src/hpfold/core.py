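"""Lattice geometry, HP sequences, conformations, and the contact energy.

The HP model represents a protein as a self-avoiding walk on the simple
cubic lattice whose beads are either hydrophobic (H) or polar (P).  The
energy of a conformation is the sum of pairwise contact energies over all
nonconsecutive nearest-neighbor bead pairs,

    E = sum over contacts (i, j) of eps(A_i, A_j),   |i - j| > 1,

with eps(H,H) < eps(H,P) < eps(P,P) and eps(H,H) + eps(P,P) < 2 eps(H,P),
so that H-H contacts are most favorable and unlike contacts are penalized
relative to the mean of the like ones.  The default integer-scaled set is
eps = (-10, -6, -3).  Integer energies make the canonical partition
function a polynomial in x = exp(1/kB T), which the rest of the package
exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "DIRECTIONS",
    "DIRECTION_VECTORS",
    "HPSequence",
    "InteractionParams",
    "Conformation",
    "ConformationError",
    "contacts",
    "energy",
]

#: Direction letters for bond vectors on the simple cubic lattice.
#: R/L = +x/-x, U/D = +y/-y, F/B = +z/-z.
DIRECTIONS = "RLUDFB"

DIRECTION_VECTORS = {
    "R": (1, 0, 0),
    "L": (-1, 0, 0),
    "U": (0, 1, 0),
    "D": (0, -1, 0),
    "F": (0, 0, 1),
    "B": (0, 0, -1),
}

_VECTOR_TO_DIRECTION = {v: k for k, v in DIRECTION_VECTORS.items()}


class ConformationError(ValueError):
    """Raised when a walk breaks a bond or overlaps itself."""


@dataclass(frozen=True)
class HPSequence:
    """An ordered string of H/P residue labels.

    Parameters
    ----------
    residues
        String over the alphabet ``{H, P}``; at least 3 residues (shorter
        chains admit neither contacts nor corner moves).
    """

    residues: str

    def __post_init__(self) -> None:
        for pos, ch in enumerate(self.residues):
            if ch not in "HP":
                raise ValueError(
                    f"invalid residue {ch!r} at position {pos}: alphabet is H/P"
                )
        if len(self.residues) < 3:
            raise ValueError(f"need at least 3 residues, got {len(self.residues)}")

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[str]:
        return iter(self.residues)

    def __str__(self) -> str:
        return self.residues

    @property
    def type_codes(self) -> np.ndarray:
        """Residue types as uint8 codes, H -> 1, P -> 0."""
        return np.frombuffer(self.residues.encode(), dtype=np.uint8) == ord("H")

    @property
    def n_hydrophobic(self) -> int:
        return self.residues.count("H")


@dataclass(frozen=True)
class InteractionParams:
    """Contact energies (eHH, eHP, ePP), integer-valued.

    The ordering eHH < eHP < ePP and the convexity condition
    eHH + ePP < 2 eHP are enforced; they make hydrophobic collapse the
    dominant driving force and favor H/P segregation.
    """

    eHH: int = -10
    eHP: int = -6
    ePP: int = -3

    def __post_init__(self) -> None:
        for name in ("eHH", "eHP", "ePP"):
            v = getattr(self, name)
            if not float(v).is_integer():
                raise ValueError(f"{name}={v!r} must be an integer")
        if not (self.eHH < self.eHP < self.ePP):
            raise ValueError(
                f"require eHH < eHP < ePP, got {self.eHH}, {self.eHP}, {self.ePP}"
            )
        if not (self.eHH + self.ePP < 2 * self.eHP):
            raise ValueError(
                f"require eHH + ePP < 2*eHP, got "
                f"{self.eHH} + {self.ePP} >= 2*{self.eHP}"
            )

    @property
    def matrix(self) -> np.ndarray:
        """2x2 energy lookup indexed by type codes (P=0, H=1)."""
        return np.array(
            [[self.ePP, self.eHP], [self.eHP, self.eHH]], dtype=np.int64
        )

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.eHH, self.eHP, self.ePP)


DEFAULT_PARAMS = InteractionParams()


@dataclass(frozen=True)
class Conformation:
    """A self-avoiding walk on the simple cubic lattice.

    Stored as an ``(N, 3)`` integer coordinate array; interconvertible with
    a direction string over :data:`DIRECTIONS`.  The canonical form starts
    at the origin with first step +x (``R``).
    """

    positions: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.int64)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ConformationError(f"positions must be (N, 3), got {pos.shape}")
        object.__setattr__(self, "positions", pos)
        self.validate()

    def validate(self) -> None:
        """Check unit bonds and self-avoidance; name the first bad bead."""
        pos = self.positions
        steps = np.abs(np.diff(pos, axis=0)).sum(axis=1)
        bad = np.nonzero(steps != 1)[0]
        if bad.size:
            raise ConformationError(
                f"bond between beads {bad[0]} and {bad[0] + 1} is not a unit step"
            )
        seen: dict[tuple[int, int, int], int] = {}
        for i, p in enumerate(map(tuple, pos)):
            if p in seen:
                raise ConformationError(
                    f"bead {i} overlaps bead {seen[p]} at position {p}"
                )
            seen[p] = i

    def __len__(self) -> int:
        return len(self.positions)

    @classmethod
    def from_directions(cls, dirs: str) -> "Conformation":
        """Build a walk from a direction string, starting at the origin."""
        pos = np.zeros((len(dirs) + 1, 3), dtype=np.int64)
        for i, d in enumerate(dirs):
            try:
                vec = DIRECTION_VECTORS[d]
            except KeyError:
                raise ValueError(
                    f"invalid direction {d!r} at position {i}: alphabet is {DIRECTIONS}"
                ) from None
            pos[i + 1] = pos[i] + vec
        return cls(pos)

    def to_directions(self) -> str:
        steps = np.diff(self.positions, axis=0)
        return "".join(_VECTOR_TO_DIRECTION[tuple(s)] for s in steps)

    @property
    def is_canonical(self) -> bool:
        p = self.positions
        return bool(np.all(p[0] == 0) and tuple(p[1]) == (1, 0, 0))

    def translated(self, offset: Sequence[int]) -> "Conformation":
        return Conformation(self.positions + np.asarray(offset, dtype=np.int64))

    def transformed(self, matrix: np.ndarray) -> "Conformation":
        """Apply a lattice point-group operation (3x3 signed permutation)."""
        return Conformation(self.positions @ np.asarray(matrix, dtype=np.int64).T)


def lattice_symmetries() -> list[np.ndarray]:
    """All 48 signed-permutation matrices of the cubic point group."""
    from itertools import permutations, product

    eye = np.eye(3, dtype=np.int64)
    out = []
    for perm in permutations(range(3)):
        for signs in product((1, -1), repeat=3):
            out.append(np.diag(signs) @ eye[list(perm)])
    return out


def contacts(conf: Conformation) -> list[tuple[int, int]]:
    """All nonconsecutive nearest-neighbor bead pairs, sorted.

    A contact is a pair (i, j) with j > i + 1 whose positions are at unit
    Euclidean distance.  Bonded neighbors (j = i + 1) are excluded by
    definition of the contact energy.
    """
    pos = conf.positions
    n = len(pos)
    out = []
    # Lattice parity: beads at odd |i - j| only can be at unit distance,
    # but a direct O(N^2) distance check is clearest and fast enough here.
    for i in range(n):
        d = np.abs(pos[i + 2 :] - pos[i]).sum(axis=1)
        for k in np.nonzero(d == 1)[0]:
            out.append((i, i + 2 + int(k)))
    return out


def energy(
    conf: Conformation,
    seq: HPSequence,
    params: InteractionParams = DEFAULT_PARAMS,
) -> int:
    """Contact energy of a conformation for a given HP sequence."""
    if len(seq) != len(conf):
        raise ValueError(
            f"sequence length {len(seq)} != conformation length {len(conf)}"
        )
    mat = params.matrix
    t = seq.type_codes.astype(np.intp)
    return int(sum(mat[t[i], t[j]] for i, j in contacts(conf)))
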