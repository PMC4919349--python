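"""Observed-lipid vs genotype-predicted-capability comparison.

For each strain the observed sterols are split into *agreements* (compounds
the enzyme complement can produce in-model) and *orphan modifications*
(observed compounds the complement cannot reach), each orphan annotated
with the smallest set of absent enzyme families that would explain it.
Families present in the genome but unused on any route to any observed
compound are reported as *silent capacities*.

Squalene and oxidosqualene are excluded from agreement/orphan accounting:
squalene is the model root (detected even in non-producers) and carries no
enzymatic information.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .core_io import ObservedLipidRecord
from .pathway import (
    C4_FAMILIES,
    EnzymeComplement,
    InfeasibleTargetError,
    PathwayConfig,
    PredictedProfile,
    compound_name,
    minimal_missing_families,
    name_to_state,
    reachable_compounds,
    required_families,
)

UNINFORMATIVE_COMPOUNDS = frozenset({"squalene", "oxidosqualene"})

#: reaction each family is required for (family granularity of orphan flags)
REACTION_OF_FAMILY = {
    "SE": "squalene oxygenation",
    "LAS": "oxidosqualene cyclization (lanosterol)",
    "CAS": "oxidosqualene cyclization (cycloartenol)",
    "ERG11": "C-14 demethylation",
    "ERG24": "C-14 reduction",
    "ERG25": "C-4 demethylation",
    "ERG26": "C-4 demethylation",
    "ERG27": "C-4 demethylation",
    "ERG4_DHCR24": "C-24 reduction",
}


@dataclass(frozen=True)
class OrphanFlag:
    """An observed compound the genotype cannot explain."""

    compound: str
    feasible: bool
    missing_families: tuple[str, ...]  # smallest explanatory set (empty if infeasible)
    missing_reactions: tuple[str, ...]
    zero_family: bool  # some implicated reaction has zero present family members


@dataclass(frozen=True)
class DiscrepancyReport:
    strain_name: str
    mode: str
    agreements: tuple[str, ...]
    orphans: tuple[OrphanFlag, ...]
    silent_capacities: tuple[str, ...]

    @property
    def zero_family_orphans(self) -> tuple[OrphanFlag, ...]:
        return tuple(o for o in self.orphans if o.zero_family)

    @property
    def full_agreement(self) -> bool:
        return not self.orphans

    def has_orphan_for_reaction(self, reaction_name: str, zero_family: bool | None = None) -> bool:
        for orphan in self.orphans:
            if reaction_name in orphan.missing_reactions:
                if zero_family is None or orphan.zero_family == zero_family:
                    return True
        return False


def _used_families(profile: PredictedProfile, observed_names: set[str]) -> frozenset[str]:
    """Families on some closure route from squalene to an observed compound."""
    targets = {s for s in profile.states if compound_name(s) in observed_names}
    incoming: dict = {}
    for src, rname, used, dst in profile.edges:
        incoming.setdefault(dst, []).append((src, used))
    used_families: set[str] = set()
    seen = set(targets)
    stack = list(targets)
    while stack:
        state = stack.pop()
        for src, used in incoming.get(state, ()):
            used_families.update(used)
            if src not in seen:
                seen.add(src)
                stack.append(src)
    return frozenset(used_families)


def compare(
    observed: ObservedLipidRecord,
    complement: EnzymeComplement,
    mode: str = "canonical",
    config: PathwayConfig | None = None,
) -> DiscrepancyReport:
    """Classify one strain's observed sterols against its genotype."""
    if observed.strain_name != complement.strain_name:
        raise ValueError(
            f"strain mismatch: lipids for {observed.strain_name!r}, "
            f"complement for {complement.strain_name!r}"
        )
    profile = reachable_compounds(complement, mode, config)
    reachable = set(profile.compounds)
    accounted = sorted(set(observed.compounds) - UNINFORMATIVE_COMPOUNDS)

    agreements: list[str] = []
    orphans: list[OrphanFlag] = []
    for compound in accounted:
        if compound in reachable:
            agreements.append(compound)
            continue
        try:
            missing = minimal_missing_families(complement, compound, mode, config)
            feasible = True
        except InfeasibleTargetError:
            missing, feasible = frozenset(), False
        reactions = sorted({REACTION_OF_FAMILY[f] for f in missing})
        zero_family = any(
            not (required_families(r) & complement.families) for r in reactions
        )
        orphans.append(
            OrphanFlag(
                compound=compound,
                feasible=feasible,
                missing_families=tuple(sorted(missing)),
                missing_reactions=tuple(reactions),
                zero_family=zero_family,
            )
        )

    observed_reachable = set(agreements) | (set(observed.compounds) & UNINFORMATIVE_COMPOUNDS)
    used = _used_families(profile, observed_reachable)
    silent = tuple(sorted(complement.families - used))
    return DiscrepancyReport(
        strain_name=observed.strain_name,
        mode=mode,
        agreements=tuple(agreements),
        orphans=tuple(orphans),
        silent_capacities=silent,
    )


@dataclass(frozen=True)
class CohortSummary:
    """Per-taxon-group discrepancy counts over a cohort of strains."""

    group_counts: Mapping[str, Mapping[str, int]]
    compound_prevalence: Mapping[str, int]
    total_strains: int


def cohort_counts(
    reports: Sequence[DiscrepancyReport],
    lipids: Sequence[ObservedLipidRecord],
) -> CohortSummary:
    """Aggregate reports by taxon group.

    Per group: cohort size, strains with >= 1 C-4 demethylation orphan,
    with >= 1 zero-family C-4 orphan, with >= 1 C-14 reduction orphan,
    with >= 1 silent capacity, and with full agreement. Also counts, per
    compound, the strains whose observed set contains it.
    """
    by_strain = {r.strain_name: r for r in lipids}
    groups: dict[str, dict[str, int]] = {}
    prevalence: dict[str, int] = {}
    for report in reports:
        lipid = by_strain.get(report.strain_name)
        if lipid is None:
            raise ValueError(f"no lipid record for report strain {report.strain_name!r}")
        g = groups.setdefault(
            lipid.taxon_group,
            {
                "cohort_size": 0,
                "c4_orphan": 0,
                "zero_family_c4_orphan": 0,
                "c14_reduction_orphan": 0,
                "silent_capacity": 0,
                "full_agreement": 0,
            },
        )
        g["cohort_size"] += 1
        if report.has_orphan_for_reaction("C-4 demethylation"):
            g["c4_orphan"] += 1
        if report.has_orphan_for_reaction("C-4 demethylation", zero_family=True):
            g["zero_family_c4_orphan"] += 1
        if report.has_orphan_for_reaction("C-14 reduction"):
            g["c14_reduction_orphan"] += 1
        if report.silent_capacities:
            g["silent_capacity"] += 1
        if report.full_agreement:
            g["full_agreement"] += 1
        for compound in lipid.compounds:
            prevalence[compound] = prevalence.get(compound, 0) + 1
    return CohortSummary(
        group_counts={k: dict(v) for k, v in sorted(groups.items())},
        compound_prevalence=dict(sorted(prevalence.items())),
        total_strains=len(reports),
    )
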