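"""Published reference values for 16-mer HP sequences.

Twenty sample sequences with ground-state energy E0 and the folding and
collapse temperatures obtained from the first-zero heat-capacity
component peaks, under the default contact energies (-10, -6, -3).
These serve as ground truth for validation; sequences 6 and 18 are the
fast-folder/slow-folder exemplars used throughout (aliases A and B).

Note: row 20 as published repeats the sequence string of row 12 but
lists a different E0 (-112 vs -95); exact enumeration of that string
gives -95, so row 20's sequence string is a known typo in the source
table and its E0/Tf/Ttheta should not be attributed to it.
"""

from __future__ import annotations

from typing import NamedTuple

__all__ = ["Table1Row", "TABLE1", "SEQUENCE_A", "SEQUENCE_B"]


class Table1Row(NamedTuple):
    number: int
    sequence: str
    n_h: int
    e0: int
    t_f: float
    t_theta: float


TABLE1: tuple[Table1Row, ...] = (
    Table1Row(1, "PHPPPPHPPHPHPPPP", 4, -72, 0.811420, 5.140083),
    Table1Row(2, "HPPPHPPPPPPHHPHP", 5, -78, 0.861228, 5.275736),
    Table1Row(3, "PHPPPHPPPPPPHPHH", 5, -78, 0.631339, 5.341242),
    Table1Row(4, "PHPHHPPHHHPPPPPP", 6, -81, 0.632632, 6.053996),
    Table1Row(5, "PHPHHPHPPHPPPPHP", 6, -87, 1.646424, 5.776825),
    Table1Row(6, "HPPHPPPHPHPPHPHP", 6, -91, 1.763969, 5.876219),
    Table1Row(7, "PHHHPPPHPPHHPPHP", 7, -90, 1.193511, 6.236811),
    Table1Row(8, "PHPHHPPHPPPHHPHP", 7, -90, 1.471768, 6.260434),
    Table1Row(9, "HPPPPHPPPHHPHPHH", 7, -93, 0.235701, 6.140142),
    Table1Row(10, "HHHPPHPPPPHPHHPP", 7, -93, 1.069987, 6.278046),
    Table1Row(11, "HHHPHPPPPHPPHHPP", 7, -93, 1.790133, 6.379248),
    Table1Row(12, "HHHPHHPHHPPPHPPP", 8, -95, 0.788043, 6.769531),
    Table1Row(13, "HHPPHHPPHHHPPPHP", 8, -96, 0.810405, 6.598124),
    Table1Row(14, "HHHHPHPHPPHPPHPP", 8, -97, 1.226218, 6.722472),
    Table1Row(15, "HHHPPHPPPHPHPPHH", 8, -100, 0.943834, 6.640664),
    Table1Row(16, "HPHHPHHHPPHPHPHP", 9, -100, 0.820632, 7.186494),
    Table1Row(17, "HHHPHHPPHHHPPHPP", 9, -103, 1.008023, 7.196576),
    Table1Row(18, "HHHHPHHPHPHPHPHP", 10, -103, 0.758160, 7.512336),
    Table1Row(19, "HPHHHHPHHPHPHPHP", 10, -103, 0.725455, 7.638136),
    Table1Row(20, "HHHPHHPHHPPPHPPP", 11, -112, 0.236975, 7.923537),
)

#: Fast folder (group 1): collapses and folds without intermediate crossovers.
SEQUENCE_A = TABLE1[5].sequence
#: Slow folder (group 2): metastable compact globules between Tf and Ttheta.
SEQUENCE_B = TABLE1[17].sequence
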