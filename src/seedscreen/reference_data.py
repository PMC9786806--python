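"""Bundled reference dataset: a Central-European hawthorn seed-screen survey.

Machine-readable copies of the published per-tree sampling/success counts
and the per-category seed counts of a mixed-ploidy (2x/3x/4x) *Crataegus*
population survey.  They serve as desk-scale fixtures for the acceptance
tests and as worked examples for the CLI.

Two documented corrections to the printed per-category table (see
``PRINTED_DISCREPANCIES``):

* the 457-seed 3x_emb/8x_end cell prints 38.13% although 457/1168 = 39.13%
  (every neighbouring cell back-calculates exactly);
* the composite polyspermy cell prints 27 seeds (2.31%), which is
  inconsistent with the survey's own totals (category counts would sum to
  1169 over 1168 successful seeds, and the B_III cells to 72 over a stated
  71); back-calculation from the per-embryo-level B_III counts (53 + 6 + 12)
  gives 26, which is the count shipped here.

Derived statistics always use computed values, never the printed
percentages.
"""

from __future__ import annotations

import pandas as pd

#: cytotype proportions (%) per surveyed population (2x, 3x, 4x)
POPULATION_CYTOTYPES: dict[str, tuple[int, tuple[float, float, float]]] = {
    # code: (n_plants, (pct_2x, pct_3x, pct_4x))
    "HERM": (47, (0.00, 34.04, 65.96)),
    "LIP": (40, (100.00, 0.00, 0.00)),
    "CIC": (28, (35.71, 46.43, 17.86)),
    "C": (18, (100.00, 0.00, 0.00)),
    "MK": (18, (77.78, 22.22, 0.00)),
    "LL": (11, (90.91, 9.09, 0.00)),
    "GOC": (10, (30.00, 20.00, 50.00)),
    "BOTZ": (9, (88.89, 11.11, 0.00)),
    "RAZNH": (9, (33.33, 22.22, 44.44)),
    "KAV": (8, (12.50, 25.00, 62.50)),
    "BIEL": (7, (100.00, 0.00, 0.00)),
    "MAJ": (2, (0.00, 0.00, 100.00)),
    "DOBRA": (1, (100.00, 0.00, 0.00)),
    "PO": (1, (100.00, 0.00, 0.00)),
    "KO": (1, (100.00, 0.00, 0.00)),
}

# (mother_id, maternal_level, n_fruits, n_fcss_seeds, n_fcss_success);
# None marks quantities not assessed for that tree.
_TREES: list[tuple[str, int, int | None, int | None, int | None]] = [
    ("MKT", 2, 22, 10, 10),
    ("MONOG1", 2, 29, 20, 18),
    ("MONOG3", 2, 28, 20, 20),
    ("KVP4", 2, 26, 20, 20),
    ("BOTZ1", 2, 23, 20, 20),
    ("BOTZ2", 2, None, 10, 10),
    ("KO VETER", 2, None, 10, 10),
    ("BIEL15-3", 2, None, 10, 10),
    ("DOBRA1", 2, None, 10, 10),
    ("CIERNANT1", 2, None, 10, 7),
    ("PO1", 2, 31, 20, 18),
    ("KVP1", 2, 33, 10, 10),
    ("GOCAL15-1", 2, 12, 10, 10),
    ("GOCAL15-2", 2, 14, 10, 9),
    ("GOCAL15-3", 2, 11, 10, 10),
    ("LIP15-1", 2, 32, 20, 20),
    ("LIP15-2", 2, 28, 20, 20),
    ("LIP15-5", 2, 15, None, None),
    ("RAZNH15-1", 2, 15, 10, 10),
    ("RAZNH15-2", 2, None, 8, 5),
    ("1518/11", 3, 58, 29, 29),
    ("kyrtoA", 3, 121, 5, 5),
    ("1447/11", 3, 76, 5, 5),
    ("1453/11", 3, 58, 47, 46),
    ("Vyhon3", 3, 198, 98, 97),
    ("1445/11", 3, 88, 18, 18),
    ("1472/11", 3, 103, 61, 59),
    ("1478/11", 3, 59, 44, 44),
    ("1531/11", 3, 80, 34, 34),
    ("1537/11", 3, 62, 54, 52),
    ("1539/11", 3, 70, 65, 63),
    ("1521/11", 3, 32, 20, 19),
    ("1525/11", 3, 54, 31, 31),
    ("1527/11", 3, 105, 88, 88),
    ("Hurka1", 3, 239, 114, 110),
    ("RaznH2", 3, 121, 104, 100),
    ("RaznH1", 3, 117, 100, 95),
    ("Sosen3", 3, 140, 135, 133),
    ("Vyhon4", 3, 215, 73, 67),
    ("Vyhon8", 3, 87, 77, 73),
    ("PS-Vyh16-1", 4, None, 5, 5),
    ("PS-Vyh16-2", 4, None, 8, 7),
    ("Vyhon2", 4, None, 8, 8),
    ("Vyhon16-16", 4, None, 10, 10),
    ("Vyhon16-15", 4, None, 17, 16),
    ("RaznH16-3", 4, None, 15, 15),
    ("MAJ16-1", 4, None, 27, 27),
    ("MAJ16-2", 4, None, 24, 22),
]

# Per-category seed counts.  embryo_level / endosperm_level are the
# representative grid levels used when running the pathway engine on a
# category; *_lo/_hi give the category's full level band.  printed_pct is the
# percentage as published (kept for the documented-discrepancy checks).
_CATEGORIES: list[dict] = [
    # maternal 2x (247 successful seeds)
    dict(maternal=2, embryo=2.0, endo=3.0, endo_lo=3.0, endo_hi=3.0, count=240, printed_pct=97.17),
    dict(maternal=2, embryo=3.0, endo=4.0, endo_lo=4.0, endo_hi=4.0, count=5, printed_pct=2.02),
    dict(maternal=2, embryo=2.0, endo=6.0, endo_lo=6.0, endo_hi=6.0, count=2, printed_pct=0.81),
    # maternal 3x (1168 successful seeds)
    dict(maternal=3, embryo=3.0, endo=8.0, endo_lo=8.0, endo_hi=8.0, count=457, printed_pct=38.13),
    dict(maternal=3, embryo=3.0, endo=9.0, endo_lo=8.5, endo_hi=9.5, count=289, printed_pct=24.74),
    dict(maternal=3, embryo=3.0, endo=10.0, endo_lo=10.0, endo_hi=10.0, count=136, printed_pct=11.64),
    dict(maternal=3, embryo=3.0, endo=7.0, endo_lo=7.0, endo_hi=7.0, count=83, printed_pct=7.11),
    dict(maternal=3, embryo=3.0, endo=7.5, endo_lo=7.5, endo_hi=7.5, count=54, printed_pct=4.62),
    dict(maternal=3, embryo=3.0, endo=6.0, endo_lo=6.0, endo_hi=6.5, count=4, printed_pct=0.34),
    dict(maternal=3, embryo=3.0, endo=12.0, endo_lo=10.5, endo_hi=13.0, count=61, printed_pct=5.22),
    dict(maternal=3, embryo=3.5, endo=9.0, endo_lo=9.0, endo_hi=12.0, count=3, printed_pct=0.26),
    dict(maternal=3, embryo=4.0, endo=7.0, endo_lo=7.0, endo_hi=7.0, count=31, printed_pct=2.65),
    dict(maternal=3, embryo=4.5, endo=7.0, endo_lo=6.5, endo_hi=7.5, count=9, printed_pct=0.77),
    dict(maternal=3, embryo=5.0, endo=8.0, endo_lo=8.0, endo_hi=8.0, count=5, printed_pct=0.43),
    dict(maternal=3, embryo=4.0, endo=10.0, endo_lo=8.0, endo_hi=10.0, count=26, printed_pct=2.31),
    dict(maternal=3, embryo=6.0, endo=14.0, endo_lo=14.0, endo_hi=19.5, count=6, printed_pct=0.51),
    dict(maternal=3, embryo=3.5, endo=5.0, endo_lo=5.0, endo_hi=5.0, count=1, printed_pct=0.09),
    dict(maternal=3, embryo=3.0, endo=5.5, endo_lo=5.5, endo_hi=5.5, count=3, printed_pct=0.26),
    # maternal 4x (110 successful seeds)
    dict(maternal=4, embryo=4.0, endo=12.0, endo_lo=12.0, endo_hi=12.0, count=56, printed_pct=50.91),
    dict(maternal=4, embryo=4.0, endo=11.5, endo_lo=11.5, endo_hi=12.5, count=17, printed_pct=15.45),
    dict(maternal=4, embryo=4.0, endo=10.0, endo_lo=10.0, endo_hi=10.5, count=9, printed_pct=8.18),
    dict(maternal=4, embryo=4.0, endo=14.0, endo_lo=13.5, endo_hi=19.5, count=14, printed_pct=12.73),
    dict(maternal=4, embryo=4.0, endo=11.0, endo_lo=10.5, endo_hi=11.0, count=2, printed_pct=1.82),
    dict(maternal=4, embryo=2.0, endo=8.0, endo_lo=8.0, endo_hi=9.5, count=6, printed_pct=5.45),
    dict(maternal=4, embryo=4.0, endo=6.0, endo_lo=6.0, endo_hi=6.0, count=4, printed_pct=3.64),
    dict(maternal=4, embryo=6.0, endo=10.0, endo_lo=10.0, endo_hi=10.0, count=2, printed_pct=1.82),
]

#: printed values the computed statistics deliberately disagree with
PRINTED_DISCREPANCIES = {
    "3x_emb/8x_end": {"printed_pct": 38.13, "computed_pct": round(100 * 457 / 1168, 2)},
    "4x+5x_emb/8x+10x_end": {"printed_count": 27, "fixture_count": 26,
                             "printed_pct": 2.31, "computed_pct": round(100 * 26 / 1168, 2)},
}


def tree_table() -> pd.DataFrame:
    """Per-tree sampling table: fruits scored, seeds screened, screens succeeded."""
    df = pd.DataFrame(
        _TREES,
        columns=["mother_id", "maternal_level", "n_fruits", "n_fcss_seeds", "n_fcss_success"],
    )
    return df.astype(
        {"n_fruits": "Int64", "n_fcss_seeds": "Int64", "n_fcss_success": "Int64"}
    )


def category_table() -> pd.DataFrame:
    """Per-category seed counts with representative embryo/endosperm levels."""
    df = pd.DataFrame(_CATEGORIES).rename(
        columns={
            "maternal": "maternal_level",
            "embryo": "embryo_level",
            "endo": "endosperm_level",
            "endo_lo": "endosperm_lo",
            "endo_hi": "endosperm_hi",
        }
    )
    return df


def cytotype_totals() -> pd.DataFrame:
    """Screened / successful seed totals per maternal cytotype."""
    trees = tree_table()
    out = (
        trees.groupby("maternal_level")[["n_fruits", "n_fcss_seeds", "n_fcss_success"]]
        .sum()
        .reset_index()
    )
    return out


def fixture_tables() -> dict[str, pd.DataFrame]:
    """All bundled tables keyed by name (``trees``, ``seed_categories``,
    ``cytotype_totals``)."""
    return {
        "trees": tree_table(),
        "seed_categories": category_table(),
        "cytotype_totals": cytotype_totals(),
    }
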