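"""Synthetic populations, seed families and cytometry measurements.

Every stage of the pipeline is testable offline: trees are drawn with known
cytotype and genome size, seeds are drawn from per-tree scenario
distributions, and each seed emits noisy embryo/endosperm/maternal/standard
peak measurements while its true scenario is retained for recovery scoring.
Peak noise is Gaussian with sd = cv * mean (cytometry convention); missing
and multiple endosperm signals are injected at configurable rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ContractError
from .fcm_quant import PISUM, ReferenceStandard
from .pathways import EggFate, PathwayExplanation, Sac, make_scenario
from .ploidy import DEFAULT_CYTOTYPE_RANGES


@dataclass(frozen=True)
class MeasurementModel:
    """Per-tissue CV (%) and signal-failure rates.

    The CV is the width of the fluorescence peak (single-nucleus spread).
    The *fitted peak mean* of a measurement jitters far less than the CV:
    its sd is ``mean * cv/100 * sqrt(position_drift^2 + 1/n_nuclei)`` — the
    standard error of the mean plus a between-measurement drift expressed as
    a fraction of the CV.
    """

    cv_embryo: float = 2.0
    cv_endosperm: float = 2.0
    cv_maternal: float = 2.0
    cv_standard: float = 2.0
    p_missing_endosperm: float = 0.0
    p_multiple_endosperm: float = 0.0
    position_drift: float = 0.25

    def __post_init__(self) -> None:
        for name in ("cv_embryo", "cv_endosperm", "cv_maternal", "cv_standard"):
            if getattr(self, name) < 0:
                raise ContractError(f"{name} must be >= 0")
        for name in ("p_missing_endosperm", "p_multiple_endosperm"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ContractError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class TreeProfile:
    """A mother tree: cytotype, genome size, and its pathway distribution."""

    mother_id: str
    maternal_level: float
    maternal_2c_pg: float
    scenarios: tuple[tuple[PathwayExplanation, float], ...]
    measurement: MeasurementModel = field(default_factory=MeasurementModel)

    def __post_init__(self) -> None:
        total = sum(p for _, p in self.scenarios)
        if not self.scenarios or abs(total - 1.0) > 1e-6:
            raise ContractError(f"scenario probabilities must sum to 1, got {total}")


def _weighted(specs: list[tuple[PathwayExplanation, float]]) -> tuple:
    total = sum(p for _, p in specs)
    return tuple((s, p / total) for s, p in specs)


def sexual_diploid_scenarios() -> tuple:
    """Canonical sexual diploid: 1x egg + 1x sperm, 2x central + 1x sperm."""
    s = make_scenario(2.0, Sac.REDUCED, EggFate.FERTILIZED, 1.0, 2, (1.0,))
    return ((s, 1.0),)

def apomictic_triploid_scenarios() -> tuple:
    """Frequency-realistic triploid apomict (pseudogamous, mixed pollen)."""
    P, F = EggFate.PARTHENOGENETIC, EggFate.FERTILIZED
    U = Sac.UNREDUCED
    specs = [
        (make_scenario(3.0, U, P, None, 2, (1.0, 1.0)), 0.39),   # 8x endosperm
        (make_scenario(3.0, U, P, None, 2, (1.5, 1.5)), 0.25),   # 9x
        (make_scenario(3.0, U, P, None, 2, (2.0, 2.0)), 0.12),   # 10x
        (make_scenario(3.0, U, P, None, 2, (1.0,)), 0.07),       # 7x
        (make_scenario(3.0, U, P, None, 2, (1.5,)), 0.05),       # ~7.5x
        (make_scenario(3.0, U, P, None, 2, ()), 0.004),          # autonomous 6x
        (make_scenario(3.0, U, P, None, 2, (), endoreplication=True), 0.05),  # 12x
        (make_scenario(3.0, U, F, 1.0, 2, (1.0,)), 0.027),       # B_III 4x/7x
        (make_scenario(3.0, U, F, 2.0, 2, (2.0,)), 0.004),       # B_III 5x/8x
        (make_scenario(3.0, U, F, 1.0, 3, (1.0,)), 0.023),       # B_III 4x/10x poly
    ]
    return _weighted(specs)

def group1_triploid_scenarios() -> tuple:
    """Euploid-1x-pollen profile (7x/8x endosperm dominate)."""
    P, U = EggFate.PARTHENOGENETIC, Sac.UNREDUCED
    return _weighted([
        (make_scenario(3.0, U, P, None, 2, (1.0, 1.0)), 0.60),
        (make_scenario(3.0, U, P, None, 2, (1.0,)), 0.30),
        (make_scenario(3.0, U, P, None, 2, (2.0, 2.0)), 0.05),
        (make_scenario(3.0, U, P, None, 2, (1.5, 1.5)), 0.05),
    ])

def group2_triploid_scenarios() -> tuple:
    """Aneuploid-~1.5x / 2x-pollen profile (9x-10x endosperm dominate)."""
    P, U = EggFate.PARTHENOGENETIC, Sac.UNREDUCED
    return _weighted([
        (make_scenario(3.0, U, P, None, 2, (1.5, 1.5)), 0.40),
        (make_scenario(3.0, U, P, None, 2, (2.0, 2.0)), 0.30),
        (make_scenario(3.0, U, P, None, 2, (1.5, 2.0)), 0.15),
        (make_scenario(3.0, U, P, None, 2, (1.0, 1.0)), 0.10),
        (make_scenario(3.0, U, P, None, 2, (1.0,)), 0.05),
    ])

def apomictic_tetraploid_scenarios() -> tuple:
    """Facultatively sexual tetraploid apomict (2x pollen, rare meiosis)."""
    P, F = EggFate.PARTHENOGENETIC, EggFate.FERTILIZED
    R, U = Sac.REDUCED, Sac.UNREDUCED
    return _weighted([
        (make_scenario(4.0, U, P, None, 2, (2.0, 2.0)), 0.51),   # 12x
        (make_scenario(4.0, U, P, None, 2, (2.0,)), 0.08),       # 10x
        (make_scenario(4.0, U, P, None, 2, (1.5, 2.0)), 0.15),   # ~11.5x
        (make_scenario(4.0, U, P, None, 2, (), endoreplication=True), 0.13),  # 16x
        (make_scenario(4.0, R, P, None, 2, (2.0, 2.0)), 0.055),  # rP 2x/8x
        (make_scenario(4.0, R, F, 2.0, 2, (2.0,)), 0.04),        # sexual 4x/6x
        (make_scenario(4.0, U, F, 2.0, 2, (2.0,)), 0.02),        # B_III 6x/10x
    ])


DEFAULT_SCENARIOS = {
    2.0: sexual_diploid_scenarios,
    3.0: apomictic_triploid_scenarios,
    4.0: apomictic_tetraploid_scenarios,
}


def _draw_2c(level: float, rng: np.random.Generator) -> float:
    ploidy = int(round(level))
    if ploidy in DEFAULT_CYTOTYPE_RANGES:
        lo, hi = DEFAULT_CYTOTYPE_RANGES[ploidy]
    else:  # extrapolate from the diploid midpoint, +-10%
        per_x = (1.37 + 1.67) / 4.0
        lo, hi = 0.9 * per_x * level, 1.1 * per_x * level
    return float(rng.uniform(lo, hi))


def make_population(
    cytotype_proportions: dict[float, float],
    n_trees: int,
    seed: int,
    *,
    rounding: str = "multinomial",
    measurement: MeasurementModel | None = None,
    scenario_factories: dict | None = None,
) -> list[TreeProfile]:
    """Draw a population of mother trees with the given cytotype percentages.

    ``rounding="deterministic"`` allocates counts by largest remainder
    (exactly reproducible expected counts); ``"multinomial"`` samples.
    """
    props = {float(k): float(v) for k, v in cytotype_proportions.items()}
    if abs(sum(props.values()) - 100.0) > 1e-6:
        raise ContractError("cytotype proportions must sum to 100")
    rng = np.random.default_rng(seed)
    levels = sorted(props)
    weights = np.array([props[lv] / 100.0 for lv in levels])
    if rounding == "deterministic":
        exact = weights * n_trees
        counts = np.floor(exact).astype(int)
        remainder = exact - counts
        for i in np.argsort(-remainder)[: n_trees - counts.sum()]:
            counts[i] += 1
    elif rounding == "multinomial":
        counts = rng.multinomial(n_trees, weights)
    else:
        raise ContractError(f"unknown rounding mode {rounding!r}")
    factories = dict(DEFAULT_SCENARIOS)
    if scenario_factories:
        factories.update(scenario_factories)
    measurement = measurement or MeasurementModel()
    trees = []
    for level, count in zip(levels, counts):
        if count and level not in factories:
            raise ContractError(f"no scenario factory for cytotype {level}x")
        for j in range(count):
            trees.append(
                TreeProfile(
                    mother_id=f"T{int(level)}x_{j + 1:03d}",
                    maternal_level=level,
                    maternal_2c_pg=_draw_2c(level, rng),
                    scenarios=factories[level]() if count else (),
                    measurement=measurement,
                )
            )
    return trees


@dataclass(frozen=True)
class SyntheticSeedFamily:
    """Generated peaks plus hidden ground truth for one mother tree."""

    tree: TreeProfile
    peaks: pd.DataFrame  # sample_id, tissue, peak_mean, cv, n_nuclei
    truth: pd.DataFrame  # per-seed hidden scenario and true levels


def simulate_seed_family(
    tree: TreeProfile,
    n_seeds: int,
    seed: int,
    *,
    standard: ReferenceStandard = PISUM,
    standard_channel: float = 200.0,
    noise: bool = True,
) -> SyntheticSeedFamily:
    """Draw ``n_seeds`` seeds from the tree's pathway distribution and emit
    noisy peak measurements (embryo, endosperm, maternal, standard)."""
    rng = np.random.default_rng(seed)
    mm = tree.measurement
    per_x_pg = tree.maternal_2c_pg / tree.maternal_level
    scen, probs = zip(*tree.scenarios)
    idx = rng.choice(len(scen), size=n_seeds, p=np.asarray(probs))

    def channel(level: float) -> float:
        return standard_channel * (level * per_x_pg) / standard.twoC_pg

    def noisy(mean: float, cv: float, n_nuclei: int) -> float:
        if not noise or cv == 0:
            return mean
        sd_frac = (cv / 100.0) * float(
            np.sqrt(mm.position_drift**2 + 1.0 / n_nuclei)
        )
        return float(mean * (1.0 + rng.normal(0.0, sd_frac)))

    peak_rows, truth_rows = [], []
    for i, which in enumerate(idx):
        scenario: PathwayExplanation = scen[which]
        seed_id = f"{tree.mother_id}_s{i + 1:05d}"
        emb, end = scenario.embryo_level, scenario.endosperm_level
        missing = rng.random() < mm.p_missing_endosperm
        multiple = (not missing) and rng.random() < mm.p_multiple_endosperm
        peak_rows.append((seed_id, "standard", noisy(standard_channel, mm.cv_standard, 2000), mm.cv_standard, 2000))
        peak_rows.append((seed_id, "maternal", noisy(channel(tree.maternal_level), mm.cv_maternal, 1500), mm.cv_maternal, 1500))
        peak_rows.append((seed_id, "embryo", noisy(channel(emb), mm.cv_embryo, 1500), mm.cv_embryo, 1500))
        if not missing:
            peak_rows.append((seed_id, "endosperm", noisy(channel(end), mm.cv_endosperm, 800), mm.cv_endosperm, 800))
            if multiple:  # spurious second endosperm signal
                peak_rows.append((seed_id, "endosperm", noisy(channel(end) * 2.0, mm.cv_endosperm, 300), mm.cv_endosperm, 300))
        truth_rows.append({
            "seed_id": seed_id,
            "mother_id": tree.mother_id,
            "maternal_level": tree.maternal_level,
            "true_embryo_level": emb,
            "true_endosperm_level": end,
            "true_label": scenario.label.value,
            "true_endosperm_mode": scenario.endosperm_mode.value,
            "true_sac": scenario.sac.value,
            "true_egg_fate": scenario.egg_fate.value,
            "true_sperm_to_egg": scenario.sperm_to_egg if scenario.sperm_to_egg is not None else np.nan,
            "true_sperm_to_central": "+".join(f"{s:g}" for s in scenario.sperm_to_central),
            "fail_mode": "missing" if missing else ("multiple" if multiple else ""),
        })
    peaks = pd.DataFrame(
        peak_rows, columns=["sample_id", "tissue", "peak_mean", "cv", "n_nuclei"]
    )
    return SyntheticSeedFamily(tree, peaks, pd.DataFrame(truth_rows))


def fixture_tables():
    """Bundled survey fixtures (re-exported from :mod:`reference_data`)."""
    from . import reference_data

    return reference_data.fixture_tables()


def all_failures(model: MeasurementModel) -> MeasurementModel:
    """Variant of a measurement model in which every seed fails."""
    return replace(model, p_missing_endosperm=1.0)
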