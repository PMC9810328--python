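"""Published example data: neoplasia counts in xenarthrans.

Necropsy and neoplasia counts for sloths, anteaters and armadillos
compiled from published mortality surveys and a pathology-report series
from a managed nine-banded armadillo colony, as reported in the
comparative-oncology literature. Counts are the analysis inputs; the
``printed_*`` columns carry the originally published point prevalence and
95% interval for cross-checking. A few published cells are internally
inconsistent with their own counts (flagged in ``TABLE_ANOMALIES``): two
point prevalences that disagree with their own x/n (Southern tamandua,
printed 0.07 where 1/60 = 0.017; Vermilingua, printed 0.023 where
5/202 = 0.025) and one upper bound off by two units in the last digit
(three-toed sloths, printed 0.050 where the exact interval gives 0.052).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "xenarthra_neoplasia",
    "nine_banded_armadillo_surveys",
    "TABLE_ANOMALIES",
]

# (taxon, level, n necropsies, x neoplasia, printed prevalence, printed CI)
_ROWS = [
    ("Southern tamandua", "species", 60, 1, "0.07", "0.0004", "0.089"),
    ("Giant anteater", "species", 139, 4, "0.029", "0.008", "0.072"),
    ("Silky anteater", "species", 3, 0, "0", "0", "0.708"),
    ("Maned three-toed sloth", "species", 25, 0, "0", "0", "0.137"),
    ("Pale-throated sloth", "species", 2, 0, "0", "0", "0.841"),
    ("Brown-throated sloth", "species", 8, 0, "0", "0", "0.369"),
    ("Three-toed sloths", "genus-pool", 69, 0, "0", "0", "0.050"),
    ("Linne's two-toed sloth", "species", 23, 2, "0.087", "0.011", "0.28"),
    ("Two-toed sloths", "genus-pool", 40, 2, "0.050", "0.006", "0.169"),
    ("Nine-banded armadillo", "species", 275, 2, "0.007", "0.0009", "0.026"),
    ("Six-banded armadillo", "species", 48, 0, "0", "0", "0.074"),
    ("Naked-tailed armadillos", "genus-pool", 5, 0, "0", "0", "0.522"),
    ("Three-banded armadillo", "genus-pool", 4, 0, "0", "0", "0.602"),
    ("Giant armadillo", "species", 1, 0, "0", "0", "0.975"),
    ("Vermilingua", "clade", 202, 5, "0.023", "0.008", "0.057"),
    ("Folivora", "clade", 109, 2, "0.018", "0.002", "0.065"),
    ("Pilosa", "clade", 311, 7, "0.022", "0.009", "0.046"),
    ("Cingulata", "clade", 333, 2, "0.006", "0.0007", "0.021"),
    ("Xenarthra", "clade", 644, 9, "0.014", "0.006", "0.026"),
]

#: Published cells inconsistent with their own counts beyond one unit in
#: the last printed digit (kept as printed, never reproduced):
#: taxon -> offending column.
TABLE_ANOMALIES = {
    "Southern tamandua": "printed_prevalence",  # 1/60 = 0.017, printed 0.07
    "Three-toed sloths": "printed_hi",          # exact upper 0.052, printed 0.050
    "Vermilingua": "printed_prevalence",        # 5/202 = 0.025, printed 0.023
}


def xenarthra_neoplasia() -> pd.DataFrame:
    """Neoplasia counts per taxon with the originally published intervals."""
    return pd.DataFrame(
        _ROWS,
        columns=["taxon", "level", "n", "x", "printed_prevalence",
                 "printed_lo", "printed_hi"],
    )


def nine_banded_armadillo_surveys() -> pd.DataFrame:
    """The three survey components pooled into the nine-banded armadillo row.

    A published necropsy series (2 neoplasia cases in 69 animals), a decade
    of colony pathology reports (0 in 153), and further published mortality
    data (0 in 53); pooled: 2/275.
    """
    return pd.DataFrame(
        [("necropsy series", 69, 2), ("colony pathology reports", 153, 0),
         ("published mortality data", 53, 0)],
        columns=["source", "n", "x"],
    )
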