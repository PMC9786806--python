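"""Aggregation of classified seeds and fruit counts into survey tables.

All operations consume tidy per-seed frames (one row per seed, or one row
per seed category with a ``count`` weight column) as produced by
:func:`classify_seed_frame`, and emit tidy tables: per-tree category
matrices, per-cytotype category frequencies, headline pathway-rate
summaries, and fruit/pyrene statistics.

Percentage conventions (fixed by back-calculation against the bundled
reference survey): category percentages and pathway rates use the
*successfully screened* seeds of the cytotype as denominator; screening
success rates use all analyzed seeds.  Seeds flagged ``questionable_meiosis``
stay in denominators but are excluded from meiosis / egg-fertilization /
central-cell-fertilization numerators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError
from . import pathways
from .pathways import (
    EndospermMode,
    Label,
    PathwayPriors,
    QUESTIONABLE_ENDOSPERM_NEAR_2M,
    QUESTIONABLE_MEIOSIS,
    Sac,
    SeedStatus,
    SpermCandidateSet,
    category_label,
)

#: canonical columns of a classified-seed frame
CLASSIFIED_COLUMNS = [
    "seed_id", "mother_id", "maternal_level", "status",
    "embryo_level", "endosperm_level", "category_label", "label",
    "endosperm_mode", "sac", "egg_fate", "sperm_to_egg", "sperm_to_central",
    "endoreplication", "polyspermy", "mp_m", "mp_p", "tie_count", "flags",
]


def classify_seed_frame(
    seeds: pd.DataFrame,
    sperm_set: SpermCandidateSet | None = None,
    tolerance: float = 0.25,
) -> pd.DataFrame:
    """Classify a frame of screened seeds through the pathway engine.

    Required columns: ``seed_id, mother_id, maternal_level, status``, and for
    ok rows ``embryo_level, endosperm_level``.  An optional ``count`` column
    carries category weights and is passed through.  Enumeration is memoised
    per distinct ploidy triple, so large families are cheap.
    """
    rows = []
    for rec in seeds.to_dict("records"):
        status = SeedStatus(rec.get("status", "ok"))
        out = {
            "seed_id": rec["seed_id"],
            "mother_id": rec["mother_id"],
            "maternal_level": float(rec["maternal_level"]),
            "status": status.value,
            "embryo_level": np.nan, "endosperm_level": np.nan,
            "category_label": "", "label": "", "endosperm_mode": "",
            "sac": "", "egg_fate": "", "sperm_to_egg": np.nan,
            "sperm_to_central": "", "endoreplication": False,
            "polyspermy": False, "mp_m": np.nan, "mp_p": np.nan,
            "tie_count": 0, "flags": "",
        }
        if "count" in rec:
            out["count"] = int(rec["count"])
        if status is SeedStatus.OK:
            m = float(rec["maternal_level"])
            e, n = float(rec["embryo_level"]), float(rec["endosperm_level"])
            explanations = pathways.enumerate_explanations(
                m, e, n, sperm_set=sperm_set, tolerance=tolerance
            )
            tops = pathways.top_explanations(explanations)
            flags = pathways.flag_questionable(m, e, n)
            out.update(
                embryo_level=e, endosperm_level=n,
                category_label=category_label(e, n),
                flags=";".join(sorted(flags)),
            )
            if tops:
                best = tops[0]
                m_dose, p_dose = best.mp_ratio
                out.update(
                    label=best.label.value,
                    endosperm_mode=best.endosperm_mode.value,
                    sac=best.sac.value,
                    egg_fate=best.egg_fate.value,
                    sperm_to_egg=best.sperm_to_egg if best.sperm_to_egg is not None else np.nan,
                    sperm_to_central="+".join(f"{s:g}" for s in best.sperm_to_central),
                    endoreplication=bool(best.endoreplication or best.sac_endoreplication),
                    polyspermy=any(x.polyspermy for x in tops),
                    mp_m=m_dose, mp_p=p_dose,
                    tie_count=len(tops),
                )
            else:
                out["endosperm_mode"] = EndospermMode.UNRESOLVED.value
        rows.append(out)
    return pd.DataFrame(rows)


def _weights(df: pd.DataFrame) -> pd.Series:
    if "count" in df.columns:
        return df["count"].astype(float)
    return pd.Series(1.0, index=df.index)


@dataclass(frozen=True)
class CategoryMatrix:
    """Mother trees x seed-category counts, with a row-percentage companion."""

    counts: pd.DataFrame  # index mother_id, columns category labels

    @property
    def percentages(self) -> pd.DataFrame:
        """Per-row percentages; denominator is the row's screened-seed total."""
        row_sums = self.counts.sum(axis=1)
        return self.counts.div(row_sums.replace(0, np.nan), axis=0) * 100.0

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)


def tabulate_categories(classified: pd.DataFrame) -> CategoryMatrix:
    """Count successfully screened seeds per (mother tree, category)."""
    ok = classified[classified["status"] == SeedStatus.OK.value]
    if ok.empty:
        return CategoryMatrix(pd.DataFrame())
    w = _weights(ok)
    counts = (
        ok.assign(_w=w)
        .pivot_table(
            index="mother_id", columns="category_label", values="_w",
            aggfunc="sum", fill_value=0.0,
        )
        .astype(float)
    )
    counts.columns.name = None
    counts.index.name = "mother_id"
    return CategoryMatrix(counts)


def cytotype_category_table(classified: pd.DataFrame) -> pd.DataFrame:
    """Pool trees of equal maternal ploidy; percentages over the cytotype's
    successfully screened seeds."""
    ok = classified[classified["status"] == SeedStatus.OK.value].copy()
    ok["_w"] = _weights(ok)
    grouped = (
        ok.groupby(["maternal_level", "category_label"], as_index=False)["_w"]
        .sum()
        .rename(columns={"_w": "count"})
    )
    totals = grouped.groupby("maternal_level")["count"].transform("sum")
    grouped["pct"] = 100.0 * grouped["count"] / totals
    return grouped.sort_values(
        ["maternal_level", "count"], ascending=[True, False]
    ).reset_index(drop=True)


def _not_questionable(df: pd.DataFrame) -> pd.Series:
    return ~df["flags"].fillna("").str.contains(QUESTIONABLE_MEIOSIS)


def summarize_pathways(
    classified: pd.DataFrame, *, wide_balance_band: bool = True
) -> pd.DataFrame:
    """Headline reproduction-pathway rates per maternal cytotype.

    One row per maternal ploidy with:

    * ``success_pct`` — both tissues determined, over analyzed seeds;
    * ``pct_unreduced_sac_evidence`` — embryo >= m and endosperm >= 2m, the
      screen's direct evidence for an unreduced sac (meaningful for
      polyploid mothers; diploid 2x-sperm seeds also satisfy it), over
      successful seeds;
    * ``pct_meiotic_sac`` — top explanation has a reduced sac, questionable
      seeds excluded from the numerator;
    * ``pct_egg_fertilized`` / ``pct_b3`` / ``pct_parthenogenetic`` — by top
      label, questionable excluded from numerators;
    * ``pct_central_fertilized`` — top endosperm mode is anything but
      strictly autonomous; seeds whose near-2m endosperm makes the reading
      ambiguous are excluded from the numerator.  ``pct_autonomous`` —
      strictly autonomous (no sperm, no endoreplication);
    * ``pct_mp_balanced`` — embryo = m with endosperm at the cytotype's
      canonical 2m:1p dose (3m for apomictic-prior cytotypes, 1.5m for
      sexual-prior ones; wide band: +- 0.5 to absorb measurement error).
    """
    priors = PathwayPriors()
    rows = []
    for level, grp in classified.groupby("maternal_level"):
        w = _weights(grp)
        n_analyzed = float(w.sum())
        ok = grp["status"] == SeedStatus.OK.value
        n_success = float(w[ok].sum())
        g, wok = grp[ok], w[ok]
        if n_success == 0:
            rows.append({"maternal_level": level, "n_analyzed": n_analyzed,
                         "n_success": 0.0, "success_pct": 0.0})
            continue
        good = _not_questionable(g)
        clear_endosperm = ~g["flags"].fillna("").str.contains(
            QUESTIONABLE_ENDOSPERM_NEAR_2M
        )
        unreduced_evidence = (g["embryo_level"] >= level) & (
            g["endosperm_level"] >= 2.0 * level
        )
        reduced_label = g["sac"].eq(Sac.REDUCED.value) & good
        egg_fert = g["label"].isin([Label.SEXUAL.value, Label.B_III.value]) & good
        b3 = g["label"].eq(Label.B_III.value) & good
        partheno = g["label"].isin(
            [Label.PARTHENOGENETIC.value, Label.REDUCED_PARTHENOGENESIS.value]
        ) & good
        autonomous = g["endosperm_mode"].eq(EndospermMode.AUTONOMOUS.value)
        central_fert = ~autonomous & clear_endosperm
        band = 0.5 if wide_balance_band else 0.0
        balanced_dose = (
            3.0 * level
            if priors.expected(level)[0] is Sac.UNREDUCED
            else 1.5 * level
        )
        balanced = (
            g["embryo_level"].eq(float(level))
            & (g["endosperm_level"] >= balanced_dose - band)
            & (g["endosperm_level"] <= balanced_dose + band)
        )

        def pct(mask: pd.Series) -> float:
            return 100.0 * float(wok[mask].sum()) / n_success

        rows.append({
            "maternal_level": level,
            "n_analyzed": n_analyzed,
            "n_success": n_success,
            "success_pct": 100.0 * n_success / n_analyzed,
            "pct_unreduced_sac_evidence": pct(unreduced_evidence),
            "pct_meiotic_sac": pct(reduced_label),
            "pct_egg_fertilized": pct(egg_fert),
            "pct_b3": pct(b3),
            "pct_parthenogenetic": pct(partheno),
            "pct_central_fertilized": pct(central_fert),
            "pct_autonomous": pct(autonomous),
            "pct_mp_balanced": pct(balanced),
        })
    return pd.DataFrame(rows)


def fruit_statistics(fruits: pd.DataFrame, *, sterile_threshold: float = 50.0) -> pd.DataFrame:
    """Per-tree fruit/seed set statistics.

    Input columns: ``mother_id, n_pyrenes, n_seeds`` (0 <= n_seeds <=
    n_pyrenes <= 4; violations raise).  Returns per-tree fruit counts, the
    percentage of fruits with 0/1/2+ seeds, the percentage of fruits whose
    pyrenes were all empty, the pyrene-count distribution, and a
    ``putatively_seed_sterile`` flag for trees whose empty-fruit share
    exceeds ``sterile_threshold``.
    """
    f = fruits.copy()
    bad = (
        (f["n_seeds"] < 0)
        | (f["n_pyrenes"] < 1)
        | (f["n_pyrenes"] > 4)
        | (f["n_seeds"] > f["n_pyrenes"])
    )
    if bad.any():
        idx = f.index[bad].tolist()[:5]
        raise ContractError(
            f"invalid fruit records (need 0 <= n_seeds <= n_pyrenes <= 4) at rows {idx}"
        )
    rows = []
    for mother, grp in f.groupby("mother_id"):
        n = len(grp)
        empty_pct = 100.0 * (grp["n_seeds"] == 0).sum() / n
        row = {
            "mother_id": mother,
            "n_fruits": n,
            "pct_zero_seed": empty_pct,
            "pct_one_seed": 100.0 * (grp["n_seeds"] == 1).sum() / n,
            "pct_two_plus_seed": 100.0 * (grp["n_seeds"] >= 2).sum() / n,
            "pct_empty_pyrene_fruits": empty_pct,
            "putatively_seed_sterile": empty_pct > sterile_threshold,
        }
        for k in range(1, 5):
            row[f"pct_pyrenes_{k}"] = 100.0 * (grp["n_pyrenes"] == k).sum() / n
        rows.append(row)
    return pd.DataFrame(rows)
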