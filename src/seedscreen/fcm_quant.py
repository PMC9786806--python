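"""Quantification of flow-cytometry peak data into 2C DNA amounts.

Inputs are either fitted G0/G1 peak summaries (mean channel, CV %, nuclei
count) or raw per-event fluorescence value lists.  Absolute DNA amounts are
anchored by a co-processed internal reference standard of known 2C value.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .errors import InsufficientDataError, InvalidMeasurementError


class Tissue(str, enum.Enum):
    EMBRYO = "embryo"
    ENDOSPERM = "endosperm"
    MATERNAL = "maternal"
    STANDARD = "standard"


@dataclass(frozen=True)
class PeakMeasurement:
    """One fitted G0/G1 peak: tissue role, mean channel, CV (%), nuclei count."""

    tissue: Tissue
    peak_mean: float
    cv: float
    n_nuclei: int = 0

    def __post_init__(self) -> None:
        if self.peak_mean <= 0:
            raise InvalidMeasurementError(f"peak_mean must be > 0, got {self.peak_mean}")
        if self.cv < 0:
            raise InvalidMeasurementError(f"cv must be >= 0, got {self.cv}")
        if self.n_nuclei < 0:
            raise InvalidMeasurementError(f"n_nuclei must be >= 0, got {self.n_nuclei}")


@dataclass(frozen=True)
class ReferenceStandard:
    """Internal reference standard with known 2C DNA amount (pg)."""

    name: str
    twoC_pg: float

    def __post_init__(self) -> None:
        if self.twoC_pg <= 0:
            raise InvalidMeasurementError(f"standard 2C must be > 0, got {self.twoC_pg}")


PISUM = ReferenceStandard("Pisum sativum cv. Ctirad", 9.09)
SOLANUM = ReferenceStandard("Solanum pseudocapsicum", 2.59)
BUILTIN_STANDARDS = {"pisum": PISUM, "solanum": SOLANUM}


@dataclass(frozen=True)
class GenomeSize2C:
    """An absolute 2C DNA amount (pg) for one tissue, with QC verdict."""

    value_pg: float
    tissue: Tissue
    qc_pass: bool = True
    qc_reason: str = ""


@dataclass(frozen=True)
class QcThresholds:
    """CV / nuclei-count quality thresholds.

    Thresholds are strict: a peak fails only when its CV is *above* the
    threshold, so boundary measurements pass.
    """

    max_cv_embryo_standard: float = 6.0
    max_cv_endosperm: float = 9.0
    min_nuclei_embryo: int = 1300

    def __post_init__(self) -> None:
        if self.max_cv_endosperm < self.max_cv_embryo_standard:
            raise InvalidMeasurementError(
                "endosperm CV threshold must be >= embryo/standard threshold"
            )


@dataclass(frozen=True)
class QcVerdict:
    peak: PeakMeasurement
    passed: bool
    reason: str  # machine-readable: "", "cv_above_6", "cv_above_9", "too_few_nuclei"


def compute_2c(
    sample_peak_mean: float,
    standard_peak_mean: float,
    standard: ReferenceStandard,
    tissue: Tissue = Tissue.EMBRYO,
) -> GenomeSize2C:
    """2C of sample = 2C of standard x (sample peak mean / standard peak mean)."""
    if sample_peak_mean <= 0 or standard_peak_mean <= 0:
        raise InvalidMeasurementError("peak means must be positive")
    return GenomeSize2C(
        value_pg=standard.twoC_pg * (sample_peak_mean / standard_peak_mean),
        tissue=tissue,
    )


def qc_filter(
    peaks: Iterable[PeakMeasurement], thresholds: QcThresholds | None = None
) -> list[QcVerdict]:
    """Annotate each peak with a pass/fail verdict.  Never raises.

    Embryo and standard peaks fail when cv > max_cv_embryo_standard;
    endosperm peaks when cv > max_cv_endosperm; embryo peaks additionally
    when fewer than min_nuclei_embryo nuclei were collected (only checked
    when a count was recorded).
    """
    thresholds = thresholds or QcThresholds()
    verdicts = []
    for peak in peaks:
        passed, reason = True, ""
        if peak.tissue in (Tissue.EMBRYO, Tissue.STANDARD, Tissue.MATERNAL):
            if peak.cv > thresholds.max_cv_embryo_standard:
                passed = False
                reason = f"cv_above_{thresholds.max_cv_embryo_standard:g}"
        elif peak.tissue is Tissue.ENDOSPERM:
            if peak.cv > thresholds.max_cv_endosperm:
                passed = False
                reason = f"cv_above_{thresholds.max_cv_endosperm:g}"
        if (
            passed
            and peak.tissue is Tissue.EMBRYO
            and 0 < peak.n_nuclei < thresholds.min_nuclei_embryo
        ):
            passed = False
            reason = "too_few_nuclei"
        verdicts.append(QcVerdict(peak, passed, reason))
    return verdicts


MIN_EVENTS = 200


def fit_peaks(
    events: Sequence[float] | np.ndarray,
    expected_peaks: int = 3,
    tissue: Tissue = Tissue.EMBRYO,
) -> list[PeakMeasurement]:
    """Locate G0/G1-style peaks in a raw fluorescence event list.

    Histogram the events, smooth, pick prominent modes, then assign each
    event to its nearest mode and iterate mean re-estimation.  Returns peaks
    sorted by ascending mean; at most ``expected_peaks + 2`` are returned
    (extras accommodate G2 peaks), keeping the most populated ones.
    """
    values = np.asarray(events, dtype=float)
    if values.size < MIN_EVENTS:
        raise InsufficientDataError(
            f"need at least {MIN_EVENTS} events to fit peaks, got {values.size}"
        )
    if np.ptp(values) == 0:  # degenerate: all events identical
        return [PeakMeasurement(tissue, float(values[0]), 0.0, int(values.size))]

    counts, edges = np.histogram(values, bins=128)
    centers = 0.5 * (edges[:-1] + edges[1:])
    smooth = gaussian_filter1d(counts.astype(float), sigma=2.0)
    # zero-pad so modes at the histogram edges are detectable
    padded = np.concatenate([[0.0], smooth, [0.0]])
    idx, _ = find_peaks(padded, prominence=max(1.0, 0.05 * padded.max()))
    idx = idx - 1
    if idx.size == 0:
        idx = np.array([int(np.argmax(smooth))])
    means = centers[idx]

    # keep the most populated modes, capped at expected_peaks + 2
    max_peaks = expected_peaks + 2
    if means.size > max_peaks:
        order = np.argsort(smooth[idx])[::-1][:max_peaks]
        means = np.sort(means[order])

    # 3 rounds of nearest-mean assignment + re-estimation
    for _ in range(3):
        assign = np.argmin(np.abs(values[:, None] - means[None, :]), axis=1)
        new_means = []
        for k in range(means.size):
            members = values[assign == k]
            new_means.append(members.mean() if members.size else means[k])
        means = np.sort(np.asarray(new_means))

    assign = np.argmin(np.abs(values[:, None] - means[None, :]), axis=1)
    peaks = []
    for k in range(means.size):
        members = values[assign == k]
        if members.size == 0:
            continue
        mean = float(members.mean())
        sd = float(members.std(ddof=0))
        peaks.append(
            PeakMeasurement(tissue, mean, 100.0 * sd / mean, int(members.size))
        )
    peaks.sort(key=lambda p: p.peak_mean)
    return peaks


def drop_standard_g2(
    peaks: list[PeakMeasurement], standard_mean: float, *, rel_tol: float = 0.05
) -> list[PeakMeasurement]:
    """Remove peaks within ±rel_tol of twice the standard mean (standard G2)."""
    return [
        p for p in peaks if not (abs(p.peak_mean - 2.0 * standard_mean) <= rel_tol * 2.0 * standard_mean)
    ]
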