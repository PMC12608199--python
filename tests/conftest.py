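"""Shared fixtures.

The N=16 enumeration and root-finding for the two exemplar sequences
(fast folder A, slow folder B) and the Table-1 row-1 sequence are
session-scoped: one exact enumeration pass scores all three sequences,
and the zeros/decomposition products are reused across test modules.
"""

from __future__ import annotations

import pytest

from hpfold.core import DEFAULT_PARAMS
from hpfold.enumeration import build_polynomial, enumerate_dos_multi
from hpfold.reference_data import SEQUENCE_A, SEQUENCE_B, TABLE1
from hpfold.zeros import (
    band_zeros,
    classify_foldability,
    decompose,
    find_zeros,
    transition_temperatures,
)

SEQUENCE_1 = TABLE1[0].sequence

#: N=8 sequence with a unique ground state (E0 = -43, n(E0) = 8); folds in
#: milliseconds, used for fast kinetic tests.
SMALL_FOLDER = "HHHPHHPH"
SMALL_FOLDER_E0 = -43


@pytest.fixture(scope="session")
def dos16():
    """Exact densities of states of sequences A, B and row 1 (one pass)."""
    seqs = [SEQUENCE_A, SEQUENCE_B, SEQUENCE_1]
    return dict(zip(seqs, enumerate_dos_multi(seqs, DEFAULT_PARAMS)))


@pytest.fixture(scope="session")
def analyses16(dos16):
    """Polynomial, banded zeros, component profiles and classified report
    for each of the three reference 16-mers."""
    out = {}
    for seq, dos in dos16.items():
        poly = build_polynomial(dos)
        zs = band_zeros(find_zeros(poly, 60))
        profiles = decompose(zs)
        report = classify_foldability(transition_temperatures(zs, profiles))
        out[seq] = {
            "poly": poly,
            "zeros": zs,
            "profiles": profiles,
            "report": report,
        }
    return out
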