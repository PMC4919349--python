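"""Reaction-graph model of bacterial sterol biosynthesis.

Compounds are encoded as feature states (methylation counts, double bonds,
ring features) and reactions as deterministic state maps gated by enzyme
families. The model starts from squalene, which is assumed available in
every strain (squalene synthesis itself is out of model):

* squalene oxygenation (SE): squalene -> 2,3-oxidosqualene
* oxidosqualene cyclization (LAS -> lanosterol; CAS -> cycloartenol;
  optionally LAS -> parkeol when the product-spectrum flag is on)
* C-14 demethylation (ERG11): removes the C-14 methyl, introducing the
  Δ14 double bond
* C-14 reduction (ERG24): removes Δ14
* C-4 demethylation (ERG25 + ERG26 + ERG27 in canonical mode; any one of
  the three in relaxed mode): removes one C-4 methyl per application
* C-24(28)/Δ24 reduction (ERG4/DHCR24): saturates the Δ24 side chain at
  any cyclized stage
* Δ8 -> Δ7 isomerization: optional, with no known gene family; disabled
  by default and excluded from discrepancy accounting

By default C-4 demethylation applies only after the C-14 methyl is gone,
following the canonical eukaryotic ordering; a configuration flag lifts
that ordering constraint.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping

from .core_io import ENZYME_FAMILIES, GeneComplementRecord, LIPID_COMPOUNDS

MODES = ("canonical", "relaxed")

C4_FAMILIES = frozenset({"ERG25", "ERG26", "ERG27"})


class InvalidStateError(ValueError):
    """A compound state violating the model's structural invariants."""


class InfeasibleTargetError(ValueError):
    """The target compound is unreachable even under the full family set."""


@dataclass(frozen=True)
class CompoundState:
    """A sterol-pathway intermediate encoded by structural features."""

    stage: str = "cyclized"  # linear | epoxide | cyclized
    c4_methyl_count: int = 2
    c14_methyl: bool = True
    delta8: bool = False
    delta14: bool = False
    delta24: bool = False
    cyclopropane_9_19: bool = False
    delta9_11: bool = False

    def __post_init__(self) -> None:
        if self.stage not in ("linear", "epoxide", "cyclized"):
            raise InvalidStateError(f"unknown stage {self.stage!r}")
        if self.stage in ("linear", "epoxide"):
            # precursors carry fixed default features
            if (
                self.c4_methyl_count != 2
                or not self.c14_methyl
                or self.delta8
                or self.delta14
                or self.delta24
                or self.cyclopropane_9_19
                or self.delta9_11
            ):
                raise InvalidStateError(f"{self.stage} stage admits no ring/unsaturation features")
        if self.c4_methyl_count not in (0, 1, 2):
            raise InvalidStateError("c4_methyl_count must be 0, 1, or 2")
        if self.delta14 and self.c14_methyl:
            raise InvalidStateError("Δ14 arises only after C-14 demethylation")
        if self.cyclopropane_9_19 and self.delta8:
            raise InvalidStateError("9,19-cyclopropane and Δ8 are mutually exclusive")


SQUALENE = CompoundState(stage="linear")
OXIDOSQUALENE = CompoundState(stage="epoxide")
LANOSTEROL = CompoundState(stage="cyclized", delta8=True, delta24=True)
CYCLOARTENOL = CompoundState(stage="cyclized", cyclopropane_9_19=True, delta24=True)
PARKEOL = CompoundState(stage="cyclized", delta9_11=True, delta24=True)
ZYMOSTEROL = CompoundState(
    stage="cyclized", c4_methyl_count=0, c14_methyl=False, delta8=True, delta24=True
)


def compound_name(state: CompoundState) -> str:
    """Canonical name for a state: the community (trivial) name where one
    exists, otherwise a systematic sterol descriptor built from the
    features (e.g. ``4,4-dimethylcholesta-8,14-dien-3-ol``)."""
    if state.stage == "linear":
        return "squalene"
    if state.stage == "epoxide":
        return "oxidosqualene"
    methyls = [4] * state.c4_methyl_count + ([14] if state.c14_methyl else [])
    if methyls:
        count = {1: "methyl", 2: "dimethyl", 3: "trimethyl"}[len(methyls)]
        prefix = ",".join(str(m) for m in methyls) + "-" + count
    else:
        prefix = ""
    bonds: list[str] = []
    if state.delta8:
        bonds.append("8")
    if state.delta9_11:
        bonds.append("9(11)")
    if state.delta14:
        bonds.append("14")
    if state.delta24:
        bonds.append("24")
    core = "9,19-cyclocholest" if state.cyclopropane_9_19 else "cholest"
    joiner = "-" if prefix and state.cyclopropane_9_19 else ""
    if not bonds:
        name = f"{prefix}{joiner}{core}an-3-ol"
    else:
        # single double bonds keep the "cholesta-8-en" spelling used in the
        # observable-compound vocabulary
        suffix = {1: "en", 2: "dien", 3: "trien", 4: "tetraen"}[len(bonds)]
        name = f"{prefix}{joiner}{core}a-{','.join(bonds)}-{suffix}-3-ol"
    return _TRIVIAL_NAMES.get(name, name)


_TRIVIAL_NAMES = {
    "4,4,14-trimethylcholesta-8,24-dien-3-ol": "lanosterol",
    "4,4,14-trimethyl-9,19-cyclocholesta-24-en-3-ol": "cycloartenol",
    "4,4,14-trimethylcholesta-9(11),24-dien-3-ol": "parkeol",
    "cholesta-8,24-dien-3-ol": "zymosterol",
}


def enumerate_states() -> list[CompoundState]:
    """Every structurally valid state of the finite model."""
    states = [SQUALENE, OXIDOSQUALENE]
    for c4, c14, d8, d14, d24, cyc, d911 in itertools.product(
        (0, 1, 2), (True, False), (True, False), (True, False), (True, False), (True, False), (True, False)
    ):
        if d14 and c14:
            continue
        if cyc and d8:
            continue
        states.append(
            CompoundState(
                stage="cyclized",
                c4_methyl_count=c4,
                c14_methyl=c14,
                delta8=d8,
                delta14=d14,
                delta24=d24,
                cyclopropane_9_19=cyc,
                delta9_11=d911,
            )
        )
    return states


_NAME_TO_STATE: dict[str, CompoundState] | None = None


def name_to_state(name: str) -> CompoundState:
    """Inverse of :func:`compound_name` over the enumerated state space."""
    global _NAME_TO_STATE
    if _NAME_TO_STATE is None:
        _NAME_TO_STATE = {compound_name(s): s for s in enumerate_states()}
    try:
        return _NAME_TO_STATE[name]
    except KeyError:
        raise LookupError(f"unknown compound name {name!r}") from None


@dataclass(frozen=True)
class PathwayConfig:
    """Optional model behaviors (defaults follow the canonical eukaryotic pathway)."""

    allow_parkeol: bool = False
    allow_delta7_isomerization: bool = False
    allow_c4_before_c14: bool = False


@dataclass(frozen=True)
class Reaction:
    """A family-gated deterministic state transformation."""

    name: str
    required_families: frozenset[str]
    applicable: Callable[[CompoundState], bool]
    transform: Callable[[CompoundState], CompoundState]
    any_one_suffices_when_relaxed: bool = False

    def satisfied_by(self, families: frozenset[str], mode: str) -> bool:
        if mode not in MODES:
            raise ValueError(f"unknown mode {mode!r}")
        if not self.required_families:
            return True  # flag-gated reactions carry no family requirement
        if mode == "relaxed" and self.any_one_suffices_when_relaxed:
            return bool(self.required_families & families)
        return self.required_families <= families


def build_reactions(config: PathwayConfig | None = None) -> list[Reaction]:
    config = config or PathwayConfig()
    reactions = [
        Reaction(
            name="squalene oxygenation",
            required_families=frozenset({"SE"}),
            applicable=lambda s: s.stage == "linear",
            transform=lambda s: OXIDOSQUALENE,
        ),
        Reaction(
            name="oxidosqualene cyclization (lanosterol)",
            required_families=frozenset({"LAS"}),
            applicable=lambda s: s.stage == "epoxide",
            transform=lambda s: LANOSTEROL,
        ),
        Reaction(
            name="oxidosqualene cyclization (cycloartenol)",
            required_families=frozenset({"CAS"}),
            applicable=lambda s: s.stage == "epoxide",
            transform=lambda s: CYCLOARTENOL,
        ),
        Reaction(
            name="C-14 demethylation",
            required_families=frozenset({"ERG11"}),
            applicable=lambda s: s.stage == "cyclized"
            and s.c14_methyl
            and s.delta8
            and not s.cyclopropane_9_19,
            transform=lambda s: replace(s, c14_methyl=False, delta14=True),
        ),
        Reaction(
            name="C-14 reduction",
            required_families=frozenset({"ERG24"}),
            applicable=lambda s: s.stage == "cyclized" and s.delta14,
            transform=lambda s: replace(s, delta14=False),
        ),
        Reaction(
            name="C-4 demethylation",
            required_families=C4_FAMILIES,
            applicable=lambda s: s.stage == "cyclized"
            and s.c4_methyl_count > 0
            and (not s.c14_methyl or config.allow_c4_before_c14),
            transform=lambda s: replace(s, c4_methyl_count=s.c4_methyl_count - 1),
            any_one_suffices_when_relaxed=True,
        ),
        Reaction(
            name="C-24 reduction",
            required_families=frozenset({"ERG4_DHCR24"}),
            applicable=lambda s: s.stage == "cyclized" and s.delta24,
            transform=lambda s: replace(s, delta24=False),
        ),
    ]
    if config.allow_parkeol:
        reactions.insert(
            3,
            Reaction(
                name="oxidosqualene cyclization (parkeol)",
                required_families=frozenset({"LAS"}),
                applicable=lambda s: s.stage == "epoxide",
                transform=lambda s: PARKEOL,
            ),
        )
    if config.allow_delta7_isomerization:
        reactions.append(
            Reaction(
                name="Δ8→Δ7 isomerization",
                required_families=frozenset(),
                applicable=lambda s: s.stage == "cyclized" and s.delta8,
                transform=lambda s: replace(s, delta8=False),
            )
        )
    return reactions


def required_families(reaction_name: str, mode: str = "canonical") -> frozenset[str]:
    """Family requirement of a reaction; in relaxed mode C-4 demethylation is
    satisfied by any non-empty subset of the returned set."""
    for reaction in build_reactions(PathwayConfig(allow_parkeol=True, allow_delta7_isomerization=True)):
        if reaction.name == reaction_name:
            if mode not in MODES:
                raise ValueError(f"unknown mode {mode!r}")
            return reaction.required_families
    raise LookupError(f"unknown reaction {reaction_name!r}")


@dataclass(frozen=True)
class EnzymeComplement:
    """The enzyme families present in one strain."""

    strain_name: str
    families: frozenset[str]

    def __post_init__(self) -> None:
        unknown = self.families - set(ENZYME_FAMILIES)
        if unknown:
            raise ValueError(f"unknown enzyme family(ies) {sorted(unknown)}")
        object.__setattr__(self, "families", frozenset(self.families))

    @classmethod
    def from_record(cls, record: GeneComplementRecord) -> "EnzymeComplement":
        return cls(strain_name=record.strain_name, families=record.families)


@dataclass(frozen=True)
class PredictedProfile:
    """The compound set reachable from squalene under an enzyme complement."""

    strain_name: str
    mode: str
    states: frozenset[CompoundState]
    compounds: tuple[str, ...]
    terminal_compounds: tuple[str, ...]
    # closure edges: (source state, reaction name, required families used, product state)
    edges: tuple[tuple[CompoundState, str, frozenset[str], CompoundState], ...]


def reachable_compounds(
    complement: EnzymeComplement,
    mode: str = "canonical",
    config: PathwayConfig | None = None,
) -> PredictedProfile:
    """Breadth-first closure from squalene over the satisfied reactions.

    Deterministic and order-independent: the result is the unique least
    fixed point of applying every satisfied, applicable reaction.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    reactions = [r for r in build_reactions(config) if r.satisfied_by(complement.families, mode)]
    states: set[CompoundState] = {SQUALENE}
    frontier = [SQUALENE]
    edges: list[tuple[CompoundState, str, frozenset[str], CompoundState]] = []
    while frontier:
        nxt: list[CompoundState] = []
        for state in frontier:
            for reaction in reactions:
                if not reaction.applicable(state):
                    continue
                product = reaction.transform(state)
                used = reaction.required_families & complement.families
                edges.append((state, reaction.name, frozenset(used), product))
                if product not in states:
                    states.add(product)
                    nxt.append(product)
        frontier = nxt
    terminals = {
        s for s in states if not any(r.applicable(s) for r in reactions)
    }
    return PredictedProfile(
        strain_name=complement.strain_name,
        mode=mode,
        states=frozenset(states),
        compounds=tuple(sorted(compound_name(s) for s in states)),
        terminal_compounds=tuple(sorted(compound_name(s) for s in terminals)),
        edges=tuple(edges),
    )


def minimal_missing_families(
    complement: EnzymeComplement,
    target: str,
    mode: str = "canonical",
    config: PathwayConfig | None = None,
) -> frozenset[str]:
    """Smallest set of absent families whose addition makes ``target``
    reachable; exhaustive over subsets, smallest cardinality first with
    lexicographic tie-breaking. Raises :class:`InfeasibleTargetError` if
    the target is unreachable even with every family present."""
    target_state = name_to_state(target)  # raises LookupError for unknown names

    def reaches(families: frozenset[str]) -> bool:
        profile = reachable_compounds(
            EnzymeComplement(strain_name=complement.strain_name, families=families), mode, config
        )
        return target_state in profile.states

    if reaches(complement.families):
        return frozenset()
    if not reaches(frozenset(ENZYME_FAMILIES)):
        raise InfeasibleTargetError(
            f"{target!r} is unreachable under the full family set in {mode} mode"
        )
    absent = sorted(set(ENZYME_FAMILIES) - complement.families)
    for size in range(1, len(absent) + 1):
        for combo in itertools.combinations(absent, size):
            if reaches(complement.families | frozenset(combo)):
                return frozenset(combo)
    raise AssertionError("unreachable: full-set feasibility was checked")
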