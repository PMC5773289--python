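"""Bundled published data used by the worked examples and analyses.

``bone_length_summaries`` is a compilation, from the comparative anatomy
literature, of adult baubellum (female) and baculum (male) length summary
statistics for the 13 mammal species for which both sexes have been measured
in multiple adults.  Lengths are in mm.  Notes: the Neovison (Mustela) vison
female count is the number of baubella found (6) among 50 dissected females;
the Taxidea taxus male SD is an estimate at 10% of the mean, the source
stating only that the two bacula measured were nearly equal in length.
"""

from __future__ import annotations

import pandas as pd

from .cv import GroupSummary

__all__ = ["bone_length_summaries", "cv_table_rows", "TALPA_ALIAS"]

# species, n_f, mean_f, sd_f, n_m, mean_m, sd_m
_BONE_LENGTHS = [
    ("Cryptoprocta ferox",        4, 5.5,   3.3,   17, 72.2,   9.6),
    ("Lemur catta",               6, 0.38,  0.06,   4, 1.4,    0.14),
    ("Leptonychotes weddellii",   5, 35.0,  6.67,  58, 186.31, 38.86),
    ("Lontra canadensis",         2, 10.35, 10.11, 55, 94.92,  4.46),
    ("Mormopterus planiceps",     6, 1.62,  0.05,   9, 7.9,    0.18),
    ("Mustela vison",             6, 1.02,  0.45,  99, 44.6,   2.18),
    ("Parascalops breweri",       2, 0.68,  0.11,   2, 0.68,   0.05),
    ("Phoca vitulina",            2, 7.5,   2.12,   3, 127.33, 2.52),
    ("Procyon lotor",             3, 13.84, 6.58,  36, 102.85, 0.06),
    ("Sciurus niger",             4, 3.38,  0.55,  11, 12.36,  0.01),
    ("Spermophilus mexicanus",    2, 2.15,  0.78,   2, 4.45,   0.49),
    ("Taxidea taxus",             4, 10.71, 1.97,   2, 98.7,   9.87),
    ("Urocyon cinereoargenteus",  3, 6.33,  1.44,  11, 50.94,  4.5),
]

# Parascalops breweri is commonly missing from mammal supertrees; the hairy-
# tailed mole is then represented by the European mole for tree-based tests.
TALPA_ALIAS = {"Parascalops breweri": "Talpa europaea"}


def bone_length_summaries() -> pd.DataFrame:
    """The 13-species bone-length summary table as a DataFrame."""
    return pd.DataFrame(
        _BONE_LENGTHS,
        columns=["species", "n_f", "mean_f", "sd_f", "n_m", "mean_m", "sd_m"])


def cv_table_rows() -> list[tuple[str, GroupSummary, GroupSummary]]:
    """The same data shaped for :func:`labile.cv.build_cv_table`."""
    return [(sp, GroupSummary(nf, mf, sf), GroupSummary(nm, mm, sm))
            for sp, nf, mf, sf, nm, mm, sm in _BONE_LENGTHS]
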