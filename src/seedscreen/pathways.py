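"""Reproduction-pathway inference from (maternal, embryo, endosperm) ploidy.

A seed's reproductive origin is reconstructed by exhaustively enumerating
every combination of embryo-sac reduction, egg fate, sperm contributions,
central-cell nucleus count and endoreplication whose conservation arithmetic
matches the observed embryo and endosperm levels:

    egg      = m/2 (reduced sac) | m (unreduced) | 2m (unreduced, sac
               endoreplicated)
    embryo   = egg + sperm_to_egg            (sperm only when fertilized)
    central  = central_nuclei x egg          (binucleate or trinucleate)
    endosperm = (central + sum(sperm_to_central)) x (2 if endoreplicated)

Matching scenarios are ranked by a lexicographic cost preferring
mechanistically minimal explanations; all co-optimal scenarios are kept as
ties (observed ploidy alone often cannot separate e.g. one 2x sperm from two
1x sperm).  The cost vector, in order:

1. number of unreduced sperm (3x/4x pollen is improbable),
2. number of aneuploid sperm (half-integral levels),
3. number of distinct sperm ploidies outside the cytotype-typical pollen
   pool (diploid mothers receive 1x pollen; triploids accept 1x, ~1.5x, 2x
   and even ~2.5x; tetraploids are fertilized almost exclusively by 2x),
4. deviation from the cytotype-typical sac/egg-fate prior (diploid mothers
   are typically sexual: reduced sac + fertilized egg; polyploid mothers
   typically apomictic: unreduced sac + parthenogenetic egg),
5. number of special endosperm mechanisms used (endosperm endoreplication,
   trinucleate central cell, sac endoreplication),
6. extra pollen tubes: each tube delivers two sperm of one ploidy, so the
   minimum tube count for the scenario's sperm multiset, minus one.

The priors (3, 4) are explicit configuration; they are what lets the same
arithmetic call a 2x/2x/6x seed sexual-with-endopolyploidized-endosperm but
a 4x/4x/12x seed parthenogenetic-pseudogamous.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from typing import Optional

from .errors import ContractError
from .ploidy import PloidyCategory, format_level, is_on_grid


class Sac(str, enum.Enum):
    REDUCED = "reduced"
    UNREDUCED = "unreduced"


class EggFate(str, enum.Enum):
    PARTHENOGENETIC = "parthenogenetic"
    FERTILIZED = "fertilized"


class Label(str, enum.Enum):
    SEXUAL = "sexual"
    PARTHENOGENETIC = "parthenogenetic"
    B_III = "B_III"
    REDUCED_PARTHENOGENESIS = "reduced_parthenogenesis"


class EndospermMode(str, enum.Enum):
    PSEUDOGAMOUS = "pseudogamous"
    AUTONOMOUS = "autonomous"
    AUTONOMOUS_PLUS_ENDOREPLICATION = "autonomous_plus_endoreplication"
    UNRESOLVED = "unresolved"


class SeedStatus(str, enum.Enum):
    OK = "ok"
    EXCLUDED_MISSING_SIGNAL = "excluded_missing_signal"
    EXCLUDED_MULTIPLE_SIGNALS = "excluded_multiple_signals"
    EXCLUDED_QC = "excluded_qc"


@dataclass(frozen=True)
class SpermCandidateSet:
    """Sperm ploidy levels admitted in scenario enumeration.

    ``unreduced`` members are penalized hardest, half-integral (aneuploid)
    members next; the default universe is reduced euploid 1x/2x, aneuploid
    ~1.5x/~2.5x, and unreduced 3x/4x.
    """

    levels: tuple[float, ...] = (1.0, 1.5, 2.0, 2.5, 3.0, 4.0)
    unreduced: tuple[float, ...] = (3.0, 4.0)

    def __post_init__(self) -> None:
        if not self.levels:
            raise ContractError("sperm candidate set must be non-empty")
        for lv in self.levels:
            if not is_on_grid(lv):
                raise ContractError(f"sperm level {lv} is not on the 0.5x grid")

    def n_unreduced(self, sperm: tuple[float, ...]) -> int:
        return sum(1 for s in sperm if s in self.unreduced)

    @staticmethod
    def n_aneuploid(sperm: tuple[float, ...]) -> int:
        return sum(1 for s in sperm if not float(s).is_integer())


@dataclass(frozen=True)
class PathwayPriors:
    """Cytotype-typical expectations used in ranking."""

    sexual_below: float = 3.0  # mothers below this level default to sexuality

    def expected(self, maternal_level: float) -> tuple[Sac, EggFate]:
        if maternal_level < self.sexual_below:
            return (Sac.REDUCED, EggFate.FERTILIZED)
        return (Sac.UNREDUCED, EggFate.PARTHENOGENETIC)

    def typical_sperm(self, maternal_level: float) -> frozenset[float]:
        """Pollen ploidies expected in the maternal cytotype's pollen pool."""
        if maternal_level < 3.0:
            return frozenset({1.0})
        if maternal_level < 4.0:
            return frozenset({1.0, 1.5, 2.0, 2.5})
        return frozenset({2.0})


def _min_pollen_tubes(sperm: tuple[float, ...]) -> int:
    """Minimum number of pollen tubes delivering a sperm multiset (each tube
    carries two sperm of a single ploidy)."""
    if not sperm:
        return 0
    tubes = 0
    for level in set(sperm):
        tubes += -(-sperm.count(level) // 2)  # ceil division
    return tubes


@dataclass(frozen=True)
class PathwayExplanation:
    """One arithmetically consistent reproduction scenario."""

    sac: Sac
    egg_ploidy: float
    egg_fate: EggFate
    sperm_to_egg: Optional[float]
    central_nuclei: int
    central_ploidy: float
    sperm_to_central: tuple[float, ...]
    endoreplication: bool
    sac_endoreplication: bool
    cost: tuple[int, ...] = field(default=(), compare=False)

    @property
    def label(self) -> Label:
        if self.sac is Sac.REDUCED:
            return Label.SEXUAL if self.egg_fate is EggFate.FERTILIZED else Label.REDUCED_PARTHENOGENESIS
        return Label.B_III if self.egg_fate is EggFate.FERTILIZED else Label.PARTHENOGENETIC

    @property
    def endosperm_mode(self) -> EndospermMode:
        if self.sperm_to_central:
            return EndospermMode.PSEUDOGAMOUS
        if self.endoreplication or self.sac_endoreplication:
            return EndospermMode.AUTONOMOUS_PLUS_ENDOREPLICATION
        return EndospermMode.AUTONOMOUS

    @property
    def n_sperm_total(self) -> int:
        return len(self.sperm_to_central) + (1 if self.sperm_to_egg is not None else 0)

    @property
    def polyspermy(self) -> bool:
        return self.n_sperm_total > 2

    @property
    def embryo_level(self) -> float:
        return self.egg_ploidy + (self.sperm_to_egg or 0.0)

    @property
    def endosperm_level(self) -> float:
        base = self.central_ploidy + sum(self.sperm_to_central)
        return base * 2.0 if self.endoreplication else base

    @property
    def mp_ratio(self) -> tuple[float, float]:
        """(maternal, paternal) genome dose in the endosperm."""
        factor = 2.0 if self.endoreplication else 1.0
        return (self.central_ploidy * factor, sum(self.sperm_to_central) * factor)

    @property
    def mp_balanced(self) -> bool:
        """True iff the endosperm carries the canonical 2m:1p dose."""
        m, p = self.mp_ratio
        return p > 0 and abs(m - 2.0 * p) < 1e-9

    def mp_ratio_text(self) -> str:
        m, p = self.mp_ratio
        if p == 0:
            return f"{m:g}m:0p"
        frac = Fraction(m / p).limit_denominator(100)
        return f"{frac.numerator}m:{frac.denominator}p"

    def sort_key(self) -> tuple:
        """Stable deterministic ordering: cost, then fewer sperm, then a
        lexicographic scenario encoding."""
        return (
            self.cost,
            self.n_sperm_total,
            self.sac.value,
            self.egg_fate.value,
            self.sperm_to_egg or 0.0,
            self.central_nuclei,
            self.sperm_to_central,
            self.endoreplication,
            self.sac_endoreplication,
        )


@dataclass(frozen=True)
class SeedScreenRecord:
    """One seed's QC-passed ploidy calls plus maternal context."""

    seed_id: str
    mother_id: str
    maternal_ploidy: PloidyCategory
    embryo: Optional[PloidyCategory]
    endosperm: Optional[PloidyCategory]
    status: SeedStatus = SeedStatus.OK

    def __post_init__(self) -> None:
        if self.status is SeedStatus.OK and (self.embryo is None or self.endosperm is None):
            raise ContractError("status=ok requires both embryo and endosperm calls")


def make_scenario(
    maternal_level: float,
    sac: Sac,
    egg_fate: EggFate,
    sperm_to_egg: Optional[float] = None,
    central_nuclei: int = 2,
    sperm_to_central: tuple[float, ...] = (),
    endoreplication: bool = False,
    sac_endoreplication: bool = False,
) -> PathwayExplanation:
    """Construct a concrete scenario for a given maternal level.

    Shares the conservation arithmetic with the enumerator, so generated
    seeds are classifiable back to their hidden scenario by construction.
    """
    _validate_grid("maternal", maternal_level)
    if sac_endoreplication and sac is not Sac.UNREDUCED:
        raise ContractError("sac endoreplication applies to unreduced sacs only")
    egg = maternal_level / 2.0 if sac is Sac.REDUCED else maternal_level
    if sac_endoreplication:
        egg *= 2.0
    if egg_fate is EggFate.FERTILIZED and sperm_to_egg is None:
        raise ContractError("fertilized egg requires sperm_to_egg")
    if egg_fate is EggFate.PARTHENOGENETIC and sperm_to_egg is not None:
        raise ContractError("parthenogenetic egg admits no sperm")
    if egg_fate is EggFate.FERTILIZED and not sperm_to_central:
        raise ContractError("egg fertilization implies central-cell fertilization")
    if central_nuclei not in (2, 3):
        raise ContractError("central cell has 2 or 3 nuclei")
    return PathwayExplanation(
        sac=sac,
        egg_ploidy=egg,
        egg_fate=egg_fate,
        sperm_to_egg=sperm_to_egg,
        central_nuclei=central_nuclei,
        central_ploidy=central_nuclei * egg,
        sperm_to_central=tuple(sorted(sperm_to_central)),
        endoreplication=endoreplication,
        sac_endoreplication=sac_endoreplication,
    )


def _validate_grid(name: str, level: float) -> None:
    if not is_on_grid(level):
        raise ContractError(f"{name} level {level} is not on the 0.5x grid")


@lru_cache(maxsize=65536)
def _enumerate_cached(
    maternal: float,
    embryo: float,
    endosperm: float,
    levels: tuple[float, ...],
    unreduced: tuple[float, ...],
    tolerance: float,
    sexual_below: float,
    allow_sac_endoreplication: bool,
) -> tuple[PathwayExplanation, ...]:
    sperm_set = SpermCandidateSet(levels, unreduced)
    priors = PathwayPriors(sexual_below)
    expect_sac, expect_fate = priors.expected(maternal)
    typical = priors.typical_sperm(maternal)
    tol = tolerance + 1e-9

    egg_options: list[tuple[Sac, float, bool]] = [
        (Sac.REDUCED, maternal / 2.0, False),
        (Sac.UNREDUCED, maternal, False),
    ]
    if allow_sac_endoreplication:
        egg_options.append((Sac.UNREDUCED, 2.0 * maternal, True))

    central_multisets = [()] + [
        tuple(comb)
        for size in (1, 2)
        for comb in itertools.combinations_with_replacement(sorted(levels), size)
    ]

    found: list[PathwayExplanation] = []
    for sac, egg, sac_ep in egg_options:
        fate_options: list[tuple[EggFate, Optional[float]]] = [(EggFate.PARTHENOGENETIC, None)]
        fate_options += [(EggFate.FERTILIZED, s) for s in levels]
        for fate, sperm_egg in fate_options:
            if abs(egg + (sperm_egg or 0.0) - embryo) > tol:
                continue
            for nuclei in (2, 3):
                central = nuclei * egg
                for sperm_central in central_multisets:
                    # egg fertilization implies central-cell fertilization:
                    # the delivering pollen tube carries two sperm and egg
                    # fertilization without endosperm fertilization is not a
                    # viable seed scenario.
                    if fate is EggFate.FERTILIZED and not sperm_central:
                        continue
                    base = central + sum(sperm_central)
                    for endorep in (False, True):
                        if abs(base * (2.0 if endorep else 1.0) - endosperm) > tol:
                            continue
                        all_sperm = sperm_central + (
                            (sperm_egg,) if sperm_egg is not None else ()
                        )
                        cost = (
                            sperm_set.n_unreduced(all_sperm),
                            SpermCandidateSet.n_aneuploid(all_sperm),
                            len(set(all_sperm) - typical),
                            int(sac is not expect_sac) + int(fate is not expect_fate),
                            int(endorep) + int(nuclei == 3) + int(sac_ep),
                            max(0, _min_pollen_tubes(all_sperm) - 1),
                        )
                        found.append(
                            PathwayExplanation(
                                sac=sac,
                                egg_ploidy=egg,
                                egg_fate=fate,
                                sperm_to_egg=sperm_egg,
                                central_nuclei=nuclei,
                                central_ploidy=central,
                                sperm_to_central=sperm_central,
                                endoreplication=endorep,
                                sac_endoreplication=sac_ep,
                                cost=cost,
                            )
                        )
    found.sort(key=PathwayExplanation.sort_key)
    return tuple(found)


def enumerate_explanations(
    maternal: PloidyCategory | float,
    embryo: PloidyCategory | float,
    endosperm: PloidyCategory | float,
    sperm_set: SpermCandidateSet | None = None,
    tolerance: float = 0.25,
    priors: PathwayPriors | None = None,
    allow_sac_endoreplication: bool = True,
) -> list[PathwayExplanation]:
    """All reproduction scenarios consistent with the observed ploidy triple,
    ranked best-first.  Empty list means the triple is unresolved."""
    m = maternal.level_x if isinstance(maternal, PloidyCategory) else float(maternal)
    e = embryo.level_x if isinstance(embryo, PloidyCategory) else float(embryo)
    n = endosperm.level_x if isinstance(endosperm, PloidyCategory) else float(endosperm)
    for name, level in (("maternal", m), ("embryo", e), ("endosperm", n)):
        _validate_grid(name, level)
    sperm_set = sperm_set or SpermCandidateSet()
    priors = priors or PathwayPriors()
    return list(
        _enumerate_cached(
            m, e, n,
            tuple(sperm_set.levels), tuple(sperm_set.unreduced),
            float(tolerance), priors.sexual_below, allow_sac_endoreplication,
        )
    )


def top_explanations(explanations: list[PathwayExplanation]) -> list[PathwayExplanation]:
    """The co-optimal (tied) prefix of a ranked explanation list."""
    if not explanations:
        return []
    best = explanations[0].cost
    return [x for x in explanations if x.cost == best]


QUESTIONABLE_MEIOSIS = "questionable_meiosis"
QUESTIONABLE_ENDOSPERM_NEAR_2M = "questionable_endosperm_near_2m"
QUESTIONABLE_EMBRYO_HALF_STEP = "questionable_embryo_half_step"
UNCERTAIN_HIGH_ENDOSPERM = "uncertain_high_endosperm"


def flag_questionable(maternal: float, embryo: float, endosperm: float) -> frozenset[str]:
    """Annotate classifications the screen itself cannot firmly support.

    * ``questionable_endosperm_near_2m`` — embryo = m with endosperm at
      2m - 0.5, within measurement error of the unreduced-sac minimum 2m;
      neither meiosis nor central-cell fertilization can be firmly read off.
    * ``questionable_embryo_half_step`` — embryo = m + 0.5 with endosperm
      >= 3m: the embryo call sits half a step above an ordinary apomictic
      seed, so the apparent egg fertilization may be measurement error.
    * ``questionable_meiosis`` — union of the two above; such seeds are kept
      in denominators but excluded from meiosis / egg-fertilization rate
      numerators.
    * ``uncertain_high_endosperm`` — endosperm above 12x, where level
      identification is only putative; excluded from sperm-ploidy
      reconstruction confidence, retained everywhere else.
    """
    flags = set()
    if embryo == maternal and endosperm == 2.0 * maternal - 0.5:
        flags.add(QUESTIONABLE_ENDOSPERM_NEAR_2M)
        flags.add(QUESTIONABLE_MEIOSIS)
    if embryo == maternal + 0.5 and endosperm >= 3.0 * maternal:
        flags.add(QUESTIONABLE_EMBRYO_HALF_STEP)
        flags.add(QUESTIONABLE_MEIOSIS)
    if endosperm > 12.0:
        flags.add(UNCERTAIN_HIGH_ENDOSPERM)
    return frozenset(flags)


@dataclass(frozen=True)
class SeedClassification:
    """Category label plus ranked explanations for one screened seed."""

    record: SeedScreenRecord
    category_label: str = ""
    explanations: tuple[PathwayExplanation, ...] = ()
    flags: frozenset[str] = frozenset()

    @property
    def status(self) -> SeedStatus:
        return self.record.status

    @property
    def resolved(self) -> bool:
        return bool(self.explanations)

    @property
    def top(self) -> Optional[PathwayExplanation]:
        return self.explanations[0] if self.explanations else None

    @property
    def ties(self) -> tuple[PathwayExplanation, ...]:
        return tuple(top_explanations(list(self.explanations)))

    @property
    def tie_count(self) -> int:
        return len(self.ties)

    @property
    def label(self) -> Optional[Label]:
        return self.top.label if self.top else None

    @property
    def endosperm_mode(self) -> EndospermMode:
        return self.top.endosperm_mode if self.top else EndospermMode.UNRESOLVED

    @property
    def polyspermy(self) -> bool:
        """True when any co-optimal explanation requires more than two sperm."""
        return any(x.polyspermy for x in self.ties)


def category_label(embryo: float, endosperm: float) -> str:
    """Table-style seed category name, e.g. "3x_emb/~9.5x_end"."""
    return f"{format_level(embryo)}_emb/{format_level(endosperm)}_end"


def classify_seed(
    record: SeedScreenRecord,
    sperm_set: SpermCandidateSet | None = None,
    tolerance: float = 0.25,
    priors: PathwayPriors | None = None,
) -> SeedClassification:
    """Classify one screened seed: category label, ranked explanations, flags.

    Excluded records pass through untouched (their status is the result).
    Scenario ties that differ only in sperm composition share the single
    category label.
    """
    if record.status is not SeedStatus.OK:
        return SeedClassification(record)
    assert record.embryo is not None and record.endosperm is not None
    m = record.maternal_ploidy.level_x
    e, n = record.embryo.level_x, record.endosperm.level_x
    explanations = enumerate_explanations(
        m, e, n, sperm_set=sperm_set, tolerance=tolerance, priors=priors
    )
    return SeedClassification(
        record=record,
        category_label=category_label(e, n),
        explanations=tuple(explanations),
        flags=flag_questionable(m, e, n),
    )
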