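"""Synthetic data generation with known ground truth.

Three generators, all pure functions of (config, seed):

* :func:`simulate_family` — a star-phylogeny protein family: a random
  ancestor (default length 650, the typical size of an oxidosqualene
  cyclase) with descendants evolved independently per site at a configured
  divergence, and class-diagnostic residues (reference positions
  381/449/453) pinned per taxon to lanosterol-synthase (LAS) or
  cycloartenol-synthase (CAS) states.
* :func:`fragment_records` — contiguous subsequences emulating truncated
  metagenome-derived proteins (length variation via fragments, not indels).
* :func:`simulate_cohort` — strain cohorts pairing enzyme complements with
  forward-simulated lipid profiles, optionally injecting orphan compounds
  (observed but unreachable) and silent families (present but unused).

The substitution process replaces a residue, with probability equal to the
divergence, by a uniformly random different residue; the expected identity
to the ancestor is therefore ~(1 - divergence) in closed form. An optional
biased mode weights replacements toward positive-scoring partners so that
percent similarity exceeds percent identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .align import SubstitutionMatrix, default_matrix
from .classifier import ReferenceAnnotation
from .core_io import (
    AMINO_ACIDS,
    ENZYME_FAMILIES,
    GeneComplementRecord,
    LIPID_COMPOUNDS,
    ObservedLipidRecord,
    ProteinRecord,
)
from .pathway import EnzymeComplement, reachable_compounds

#: past this divergence pinned diagnostic states are meaningless
MAX_PINNED_DIVERGENCE = 0.6

LAS_STATES = {381: "T", 449: "Q", 453: "V"}
CAS_STATES = {381: "Y", 449: "H", 453: "I"}


class SimulationConfigError(ValueError):
    pass


class ScenarioError(ValueError):
    pass


@dataclass(frozen=True)
class CohortScenario:
    """One strain archetype: an enzyme complement plus optional injections."""

    name: str
    families: frozenset[str]
    orphan_candidates: tuple[str, ...] = ()
    silent_candidates: tuple[str, ...] = ()


#: archetypes mirroring the surveyed strains: basic cycloartenol and
#: lanosterol producers, a methanotroph-like partial pathway, and a full
#: lanosterol-to-zymosterol route
DEFAULT_SCENARIOS = (
    CohortScenario(
        name="cas_basic",
        families=frozenset({"SE", "CAS"}),
        orphan_candidates=("lanosterol", "zymosterol"),
        silent_candidates=("ERG4_DHCR24",),
    ),
    CohortScenario(
        name="las_basic",
        families=frozenset({"SE", "LAS"}),
        orphan_candidates=("cycloartenol", "zymosterol", "4-methylcholesta-8,24-dien-3-ol"),
        silent_candidates=("CAS",),
    ),
    CohortScenario(
        name="methanotroph_like",
        families=frozenset({"SE", "LAS", "ERG11", "ERG24"}),
        orphan_candidates=("4-methylcholesta-8,24-dien-3-ol", "cycloartenol"),
        silent_candidates=("CAS",),
    ),
    CohortScenario(
        name="zymosterol_route",
        families=frozenset({"SE", "LAS", "ERG11", "ERG24", "ERG25", "ERG26", "ERG27"}),
        orphan_candidates=("cycloartenol", "4,4-dimethylcholesta-8-en-3-ol"),
        silent_candidates=("CAS",),
    ),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Shared configuration for the generators; seed-deterministic."""

    seed: int = 0
    # family simulation
    ancestor_length: int = 650
    n_taxa: int = 50
    divergence: float | tuple[float, ...] = 0.2
    class_assignments: str | tuple[str, ...] = "LAS"  # per-taxon LAS/CAS
    diagnostic_positions: tuple[int, int, int] = (381, 449, 453)
    pin_diagnostic_sites: bool = True
    biased_substitutions: bool = False
    # fragment simulation
    fragment_lengths: tuple[int, ...] = (350, 450)
    # cohort simulation
    scenarios: tuple[CohortScenario, ...] = DEFAULT_SCENARIOS
    n_strains: int = 100
    orphan_injection_rate: float = 0.2
    silent_injection_rate: float = 0.1

    def __post_init__(self) -> None:
        divs = self.divergence if isinstance(self.divergence, tuple) else (self.divergence,)
        if any(d < 0 for d in divs):
            raise SimulationConfigError("divergence must be >= 0")
        if self.pin_diagnostic_sites and any(d > MAX_PINNED_DIVERGENCE for d in divs):
            raise SimulationConfigError(
                f"divergence above {MAX_PINNED_DIVERGENCE} makes pinned classes meaningless"
            )
        if self.ancestor_length < max(self.diagnostic_positions):
            raise SimulationConfigError(
                "ancestor must cover the diagnostic positions"
            )
        if not (0 <= self.orphan_injection_rate <= 1 and 0 <= self.silent_injection_rate <= 1):
            raise SimulationConfigError("injection rates must be in [0, 1]")


@dataclass
class TruthTable:
    """Ground truth for every emitted record and strain."""

    per_record: dict[str, dict] = field(default_factory=dict)
    per_strain: dict[str, dict] = field(default_factory=dict)


def _pin(seq: list[str], cls: str, positions: Sequence[int]) -> None:
    states = LAS_STATES if cls == "LAS" else CAS_STATES
    canonical = dict(zip((381, 449, 453), positions))
    for refpos, pos in canonical.items():
        seq[pos - 1] = states[refpos]


def _substitution_weights(matrix: SubstitutionMatrix) -> dict[str, np.ndarray]:
    """Per-source-residue replacement weights favoring positive-scoring partners."""
    weights = {}
    for a in AMINO_ACIDS:
        w = np.array(
            [math.exp(0.5 * matrix.score(a, b)) if b != a else 0.0 for b in AMINO_ACIDS]
        )
        weights[a] = w / w.sum()
    return weights


def simulate_family(config: SimulationConfig) -> tuple[list[ProteinRecord], TruthTable]:
    """Simulate a protein family from a random ancestor.

    Descendant i mutates each non-pinned site independently with its
    divergence probability; pinned diagnostic sites are set to the taxon's
    class states and never mutated (when pinning is enabled).
    """
    rng = np.random.default_rng(config.seed)
    aa = np.array(list(AMINO_ACIDS))
    ancestor = list(rng.choice(aa, size=config.ancestor_length))
    positions = config.diagnostic_positions
    classes = (
        tuple([config.class_assignments] * config.n_taxa)
        if isinstance(config.class_assignments, str)
        else tuple(config.class_assignments)
    )
    if len(classes) != config.n_taxa:
        raise SimulationConfigError("one class assignment per taxon required")
    divs = (
        tuple([config.divergence] * config.n_taxa)
        if not isinstance(config.divergence, tuple)
        else tuple(config.divergence)
    )
    if len(divs) != config.n_taxa:
        raise SimulationConfigError("one divergence per taxon required")
    if config.pin_diagnostic_sites:
        _pin(ancestor, classes[0] if classes else "LAS", positions)

    pinned_idx = {p - 1 for p in positions} if config.pin_diagnostic_sites else set()
    bias = _substitution_weights(default_matrix()) if config.biased_substitutions else None

    records: list[ProteinRecord] = []
    truth = TruthTable()
    anc_seq = "".join(ancestor)
    truth.per_record["ancestor"] = {"class": classes[0] if classes else "LAS", "divergence": 0.0}
    for i, (cls, d) in enumerate(zip(classes, divs)):
        seq = list(anc_seq)
        mutate = rng.random(config.ancestor_length) < d
        for pos in np.nonzero(mutate)[0]:
            if pos in pinned_idx:
                continue
            src = seq[pos]
            if bias is not None and src in bias:
                seq[pos] = str(rng.choice(aa, p=bias[src]))
            else:
                others = [c for c in AMINO_ACIDS if c != src]
                seq[pos] = others[int(rng.integers(len(others)))]
        if config.pin_diagnostic_sites:
            _pin(seq, cls, positions)
        rid = f"sim_{cls.lower()}_{i:03d}"
        records.append(
            ProteinRecord(
                id=rid,
                sequence="".join(seq),
                description=f"simulated {cls} divergence={d}",
            )
        )
        truth.per_record[rid] = {"class": cls, "divergence": d, "source": "ancestor"}
    truth.per_record["__ancestor_sequence__"] = {"sequence": anc_seq}
    return records, truth


def make_reference_annotation(
    seed: int = 0, length: int = 650
) -> tuple[ProteinRecord, ReferenceAnnotation]:
    """A synthetic LAS-annotated reference cyclase plus its annotation.

    A stand-in for a user-supplied annotated reference (e.g. human Osc):
    random sequence with LAS states pinned at 381/449/453, numbered from 1.
    """
    cfg = SimulationConfig(seed=seed, ancestor_length=length, n_taxa=1, divergence=0.0)
    records, truth = simulate_family(cfg)
    ref = ProteinRecord(
        id="ref_osc_synthetic",
        sequence=truth.per_record["__ancestor_sequence__"]["sequence"],
        description="synthetic LAS reference cyclase",
    )
    return ref, ReferenceAnnotation(reference=ref)


def fragment_records(
    records: Sequence[ProteinRecord], config: SimulationConfig
) -> tuple[list[ProteinRecord], TruthTable]:
    """Contiguous substrings at random offsets, emulating metagenomic fragments."""
    rng = np.random.default_rng(config.seed)
    out: list[ProteinRecord] = []
    truth = TruthTable()
    for rec in records:
        length = int(config.fragment_lengths[int(rng.integers(len(config.fragment_lengths)))])
        if length > len(rec.sequence):
            raise SimulationConfigError(
                f"fragment length {length} exceeds source length {len(rec.sequence)}"
            )
        start = int(rng.integers(len(rec.sequence) - length + 1))
        frag_id = f"{rec.id}_frag{start + 1}-{start + length}"
        out.append(
            ProteinRecord(
                id=frag_id,
                sequence=rec.sequence[start : start + length],
                description=rec.description,
                source_class="metagenome",
            )
        )
        truth.per_record[frag_id] = {
            "source": rec.id,
            "offset": start,
            "length": length,
        }
    return out, truth


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[ObservedLipidRecord], list[GeneComplementRecord], TruthTable]:
    """Strain cohorts with forward-simulated lipid profiles.

    Each strain draws a scenario archetype; its observed set is the
    canonical-mode reachable compound set restricted to the observable
    vocabulary. With the configured rates an orphan compound (unreachable
    by construction) is added to the observation and/or a silent family
    (guaranteed unused) is added to the complement. All injections are
    recorded in the truth table.
    """
    rng = np.random.default_rng(config.seed)
    lipids: list[ObservedLipidRecord] = []
    complements: list[GeneComplementRecord] = []
    truth = TruthTable()

    for i in range(config.n_strains):
        scenario = config.scenarios[int(rng.integers(len(config.scenarios)))]
        strain = f"sim_{scenario.name}_{i:03d}"

        base_profile = reachable_compounds(
            EnzymeComplement(strain_name=strain, families=scenario.families)
        )
        observed = set(base_profile.compounds) & set(LIPID_COMPOUNDS)

        injected_silent: tuple[str, ...] = ()
        families = set(scenario.families)
        if scenario.silent_candidates and rng.random() < config.silent_injection_rate:
            fam = scenario.silent_candidates[int(rng.integers(len(scenario.silent_candidates)))]
            if fam in families:
                raise ScenarioError(f"silent candidate {fam!r} already present in {scenario.name}")
            families.add(fam)
            injected_silent = (fam,)

        full_profile = reachable_compounds(
            EnzymeComplement(strain_name=strain, families=frozenset(families))
        )
        injected_orphans: tuple[str, ...] = ()
        if scenario.orphan_candidates and rng.random() < config.orphan_injection_rate:
            viable = [
                c
                for c in scenario.orphan_candidates
                if c in LIPID_COMPOUNDS and c not in full_profile.compounds
            ]
            if viable:
                orphan = viable[int(rng.integers(len(viable)))]
                observed.add(orphan)
                injected_orphans = (orphan,)

        complements.append(
            GeneComplementRecord(
                strain_name=strain,
                family_to_locus={f: f"{strain}_{f}" for f in sorted(families)},
            )
        )
        lipids.append(
            ObservedLipidRecord(
                strain_name=strain,
                study_section="this_study",
                taxon_group=f"synthetic_{scenario.name}",
                compounds=frozenset(observed),
            )
        )
        truth.per_strain[strain] = {
            "scenario": scenario.name,
            "complement": frozenset(families),
            "producible": frozenset(base_profile.compounds) & set(LIPID_COMPOUNDS),
            "injected_orphans": injected_orphans,
            "injected_silent": injected_silent,
        }
    return lipids, complements, truth
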