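"""Oxidosqualene cyclase classification from diagnostic residues.

A query cyclase is mapped onto an annotated reference's numbering by
global alignment, and the residues at the three product-determining
positions (381, 449, 453 in the reference numbering, as for human Osc) are
read through the mapping. The call follows the single-residue rule: valine
at 453 indicates a lanosterol synthase (LAS), isoleucine a cycloartenol
synthase (CAS); anything else (including an unmapped position, as in short
fragments) is indeterminate. Positions 381 and 449 (T/C and Q for LAS;
Y and H for CAS) do not decide the call but are counted as supporting
agreement. A configurable functional-residue audit checks conservation of
additional annotated positions the same way.

Reference numbering is 1-based; internal sequence indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .align import SubstitutionMatrix, global_align
from .core_io import ProteinRecord

GAP = "-"

DIAGNOSTIC_POSITIONS = (381, 449, 453)
DEFAULT_LAS_STATES: dict[int, frozenset[str]] = {
    381: frozenset({"T", "C"}),
    449: frozenset({"Q"}),
    453: frozenset({"V"}),
}
DEFAULT_CAS_STATES: dict[int, frozenset[str]] = {
    381: frozenset({"Y"}),
    449: frozenset({"H"}),
    453: frozenset({"I"}),
}


@dataclass(frozen=True)
class ReferenceAnnotation:
    """An annotated reference cyclase: numbering anchor plus residue expectations."""

    reference: ProteinRecord
    numbering_offset: int = 0  # reference numbering = 0-based index + 1 + offset
    diagnostic_positions: tuple[int, int, int] = DIAGNOSTIC_POSITIONS
    las_states: Mapping[int, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_LAS_STATES)
    )
    cas_states: Mapping[int, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_CAS_STATES)
    )
    #: positions audited for functional conservation: (position, expected residue set)
    functional_positions: tuple[tuple[int, frozenset[str]], ...] = ()

    def __post_init__(self) -> None:
        ref_len = len(self.reference.sequence)
        for pos in self.diagnostic_positions:
            if not (1 <= pos - self.numbering_offset <= ref_len):
                raise ValueError(f"diagnostic position {pos} outside reference length {ref_len}")
        discriminator = self.diagnostic_positions[2]
        las = self.las_states.get(discriminator, frozenset())
        cas = self.cas_states.get(discriminator, frozenset())
        if las & cas:
            raise ValueError("LAS and CAS expectations must not overlap at the discriminator")
        if not self.functional_positions:
            merged = tuple(
                (pos, self.las_states.get(pos, frozenset()) | self.cas_states.get(pos, frozenset()))
                for pos in self.diagnostic_positions
            )
            object.__setattr__(self, "functional_positions", merged)

    def index_of(self, position: int) -> int:
        """0-based reference index of a reference-numbering position."""
        return position - 1 - self.numbering_offset


@dataclass(frozen=True)
class DiagnosticProfile:
    """Residues at the diagnostic triple and the resulting product call."""

    query_id: str
    residue_at_381: str
    residue_at_449: str
    residue_at_453: str
    call: str  # LAS | CAS | indeterminate
    supporting_agreement: int  # 0-2: positions 381/449 agreeing with the call
    mapped: tuple[bool, bool, bool]


@dataclass(frozen=True)
class FunctionalAudit:
    """Conservation check of annotated functional positions."""

    query_id: str
    checks: tuple[tuple[int, frozenset[str], str, bool], ...]
    verdict: str  # all_conserved | divergent
    divergent_positions: tuple[int, ...]


def map_reference_positions(
    query: ProteinRecord,
    annot: ReferenceAnnotation,
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = 11,
    gap_extend: float = 1,
) -> dict[int, int | None]:
    """Map every reference-numbering position to a query index (or None).

    Built from the global alignment of query and reference; the mapping is
    monotone increasing over mapped positions.
    """
    result = global_align(query, annot.reference, matrix, gap_open, gap_extend)
    by_ref_index = {s: q for q, s in result.aligned_pairs}
    mapping: dict[int, int | None] = {}
    for ref_index in range(len(annot.reference.sequence)):
        position = ref_index + 1 + annot.numbering_offset
        mapping[position] = by_ref_index.get(ref_index)
    return mapping


def _residue_at(query: ProteinRecord, mapping: Mapping[int, int | None], position: int) -> str:
    idx = mapping.get(position)
    return query.sequence[idx] if idx is not None else GAP


def classify_osc(
    query: ProteinRecord,
    annot: ReferenceAnnotation,
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = 11,
    gap_extend: float = 1,
) -> DiagnosticProfile:
    """Call LAS vs CAS from the residue at the discriminator position (453)."""
    mapping = map_reference_positions(query, annot, matrix, gap_open, gap_extend)
    p381, p449, p453 = annot.diagnostic_positions
    residues = {pos: _residue_at(query, mapping, pos) for pos in (p381, p449, p453)}
    discriminator = residues[p453]
    if discriminator in annot.las_states[p453]:
        call = "LAS"
        expectations = annot.las_states
    elif discriminator in annot.cas_states[p453]:
        call = "CAS"
        expectations = annot.cas_states
    else:
        call = "indeterminate"
        expectations = None
    agreement = 0
    if expectations is not None:
        agreement = sum(
            1 for pos in (p381, p449) if residues[pos] in expectations.get(pos, frozenset())
        )
    return DiagnosticProfile(
        query_id=query.id,
        residue_at_381=residues[p381],
        residue_at_449=residues[p449],
        residue_at_453=residues[p453],
        call=call,
        supporting_agreement=agreement,
        mapped=tuple(mapping.get(pos) is not None for pos in (p381, p449, p453)),
    )


def audit_functional_residues(
    query: ProteinRecord,
    annot: ReferenceAnnotation,
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = 11,
    gap_extend: float = 1,
) -> FunctionalAudit:
    """Check conservation of every annotated functional position in the query."""
    if not annot.functional_positions:
        raise ValueError("annotation has no functional positions to audit")
    mapping = map_reference_positions(query, annot, matrix, gap_open, gap_extend)
    checks = []
    divergent = []
    for position, expected in annot.functional_positions:
        observed = _residue_at(query, mapping, position)
        conserved = observed in expected
        checks.append((position, frozenset(expected), observed, conserved))
        if not conserved:
            divergent.append(position)
    return FunctionalAudit(
        query_id=query.id,
        checks=tuple(checks),
        verdict="all_conserved" if not divergent else "divergent",
        divergent_positions=tuple(divergent),
    )


def read_annotation(path: str | Path, reference: ProteinRecord) -> ReferenceAnnotation:
    """Load an annotation TSV: columns position, role, las_states, cas_states.

    ``role`` is ``diagnostic`` (the 381/449/453 triple, in that order by
    position) or ``functional`` (audited positions; ``las_states`` column
    doubles as the expected residue set, unioned with ``cas_states``).
    Residue sets are written as plain strings of one-letter codes.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    las: dict[int, frozenset[str]] = {}
    cas: dict[int, frozenset[str]] = {}
    diagnostic: list[int] = []
    functional: list[tuple[int, frozenset[str]]] = []
    for row in df.to_dict(orient="records"):
        pos = int(row["position"])
        las_set = frozenset(row.get("las_states", "").strip())
        cas_set = frozenset(row.get("cas_states", "").strip())
        if row["role"] == "diagnostic":
            diagnostic.append(pos)
            las[pos] = las_set
            cas[pos] = cas_set
        elif row["role"] == "functional":
            functional.append((pos, las_set | cas_set))
        else:
            raise ValueError(f"{path}: unknown annotation role {row['role']!r}")
    if len(diagnostic) != 3:
        raise ValueError(f"{path}: expected exactly 3 diagnostic positions")
    return ReferenceAnnotation(
        reference=reference,
        diagnostic_positions=tuple(sorted(diagnostic)),
        las_states=las,
        cas_states=cas,
        functional_positions=tuple(functional),
    )
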