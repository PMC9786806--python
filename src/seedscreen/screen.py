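"""Per-seed screening: peak table -> QC -> tissue ploidy calls -> records.

Connects the quantification layer to the pathway engine.  Embryo ploidy is
called relative to the maternal (exocarp) peak when present — cancelling
accession-level genome-size variation — otherwise via absolute 2C against
the internal standard; endosperm is always called relative to the embryo.
"""

from __future__ import annotations

import pandas as pd

from .fcm_quant import (
    PeakMeasurement,
    QcThresholds,
    ReferenceStandard,
    Tissue,
    compute_2c,
    qc_filter,
)
from .pathways import SeedStatus
from .ploidy import PloidyCategory, call_seed_tissue_ploidy

SEED_COLUMNS = [
    "seed_id", "mother_id", "maternal_level", "status",
    "embryo_level", "endosperm_level", "qc_reason",
]


def screen_seed(
    peaks: pd.DataFrame,
    maternal_level: float,
    *,
    maternal_2c_pg: float | None = None,
    standard: ReferenceStandard | None = None,
    thresholds: QcThresholds | None = None,
) -> dict:
    """Screen one seed's peak table into status + embryo/endosperm levels."""
    maternal = PloidyCategory(maternal_level)
    by_tissue: dict[str, list] = {}
    for row in peaks.itertuples(index=False):
        by_tissue.setdefault(str(row.tissue), []).append(row)

    out = {
        "status": SeedStatus.OK.value,
        "embryo_level": None,
        "endosperm_level": None,
        "qc_reason": "",
    }
    embryo_rows = by_tissue.get(Tissue.EMBRYO.value, [])
    endo_rows = by_tissue.get(Tissue.ENDOSPERM.value, [])
    if len(embryo_rows) != 1 or len(endo_rows) == 0:
        out["status"] = (
            SeedStatus.EXCLUDED_MULTIPLE_SIGNALS.value
            if len(embryo_rows) > 1
            else SeedStatus.EXCLUDED_MISSING_SIGNAL.value
        )
        return out
    if len(endo_rows) > 1:
        out["status"] = SeedStatus.EXCLUDED_MULTIPLE_SIGNALS.value
        return out

    measurements = [
        PeakMeasurement(Tissue(str(r.tissue)), float(r.peak_mean), float(r.cv), int(r.n_nuclei))
        for rows in by_tissue.values()
        for r in rows
    ]
    failed = [v for v in qc_filter(measurements, thresholds) if not v.passed]
    if failed:
        out["status"] = SeedStatus.EXCLUDED_QC.value
        out["qc_reason"] = ";".join(f"{v.peak.tissue.value}:{v.reason}" for v in failed)
        return out

    embryo_peak = float(embryo_rows[0].peak_mean)
    endo_peak = float(endo_rows[0].peak_mean)
    maternal_rows = by_tissue.get(Tissue.MATERNAL.value, [])
    standard_rows = by_tissue.get(Tissue.STANDARD.value, [])
    if maternal_rows:
        emb_call = call_seed_tissue_ploidy(embryo_peak, float(maternal_rows[0].peak_mean), maternal)
    elif standard_rows and standard is not None and maternal_2c_pg is not None:
        emb_2c = compute_2c(embryo_peak, float(standard_rows[0].peak_mean), standard)
        per_x = maternal_2c_pg / maternal_level
        emb_call = call_seed_tissue_ploidy(emb_2c.value_pg, per_x, PloidyCategory(1.0))
    else:
        out["status"] = SeedStatus.EXCLUDED_MISSING_SIGNAL.value
        out["qc_reason"] = "no maternal or standard reference peak"
        return out
    if not emb_call.resolvable:
        out["status"] = SeedStatus.EXCLUDED_QC.value
        out["qc_reason"] = f"embryo level unresolvable (raw {emb_call.raw_level:.2f})"
        return out
    end_call = call_seed_tissue_ploidy(endo_peak, embryo_peak, emb_call.category)
    if not end_call.resolvable:
        out["status"] = SeedStatus.EXCLUDED_QC.value
        out["qc_reason"] = f"endosperm level unresolvable (raw {end_call.raw_level:.2f})"
        return out
    out["embryo_level"] = emb_call.category.level_x
    out["endosperm_level"] = end_call.category.level_x
    return out


def screen_family(
    peaks: pd.DataFrame,
    maternal_levels: dict[str, float] | float,
    *,
    mother_of: dict[str, str] | None = None,
    maternal_2c_pg: float | None = None,
    standard: ReferenceStandard | None = None,
    thresholds: QcThresholds | None = None,
) -> pd.DataFrame:
    """Screen a multi-seed peak table (grouped by ``sample_id``) into a
    seed-record frame ready for classification.

    ``maternal_levels`` is either one level for all seeds or a mapping
    mother_id -> level together with ``mother_of`` (seed -> mother).
    """
    rows = []
    for seed_id, grp in peaks.groupby("sample_id", sort=False):
        mother = (mother_of or {}).get(str(seed_id), str(seed_id).rsplit("_s", 1)[0])
        level = (
            maternal_levels
            if isinstance(maternal_levels, (int, float))
            else maternal_levels[mother]
        )
        result = screen_seed(
            grp,
            float(level),
            maternal_2c_pg=maternal_2c_pg,
            standard=standard,
            thresholds=thresholds,
        )
        rows.append({"seed_id": seed_id, "mother_id": mother, "maternal_level": float(level), **result})
    return pd.DataFrame(rows, columns=SEED_COLUMNS)
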