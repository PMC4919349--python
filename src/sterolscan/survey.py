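"""Thresholded homolog screening, redundancy reduction, and survey summaries.

Mirrors the search logic of the genomic/metagenomic Osc survey: candidates
are aligned locally to a reference protein and filtered by e-value,
identity, similarity, and fragment length. Three named presets encode the
survey's search modes:

``osc_genome``
    e-value <= 1e-100 and similarity strictly > 30% (genome screen).
``osc_metagenome``
    e-value <= 1e-50 and length >= 400 residues (metagenome screen; Osc
    proteins are generally about 600–650 residues, so shorter fragments are
    unreliable for alignment).
``downstream_erg``
    e-value <= 1e-10 and identity >= 20% (downstream pathway genes).

Comparisons are inclusive for e-value ("equal to or lower"), inclusive for
minimum identity, and strict for the similarity gate ("greater than"), as
those thresholds are conventionally phrased. The length filter is
inclusive (>= 400) by default and flag-configurable to strict.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .align import (
    AlignmentResult,
    EvalueParams,
    SubstitutionMatrix,
    estimate_evalue,
    global_align,
    local_align,
)
from .core_io import GenomeHomologRecord, ProteinRecord, classify_environment


@dataclass(frozen=True)
class SearchThresholds:
    """Pass/fail criteria for a homolog screen; at least one must be set."""

    max_evalue: float | None = None
    min_identity: float | None = None
    min_similarity: float | None = None
    min_length: int | None = None
    strict_length: bool = False

    def __post_init__(self) -> None:
        if all(
            v is None
            for v in (self.max_evalue, self.min_identity, self.min_similarity, self.min_length)
        ):
            raise ValueError("at least one criterion must be present")
        for name in ("min_identity", "min_similarity"):
            v = getattr(self, name)
            if v is not None and not (0 <= v <= 100):
                raise ValueError(f"{name} must be in [0, 100]")
        if self.max_evalue is not None and self.max_evalue <= 0:
            raise ValueError("max_evalue must be positive")
        if self.min_length is not None and self.min_length < 1:
            raise ValueError("min_length must be positive")


PRESETS: dict[str, SearchThresholds] = {
    "osc_genome": SearchThresholds(max_evalue=1e-100, min_similarity=30.0),
    "osc_metagenome": SearchThresholds(max_evalue=1e-50, min_length=400),
    "downstream_erg": SearchThresholds(max_evalue=1e-10, min_identity=20.0),
}


@dataclass(frozen=True)
class HomologHit:
    """One screened candidate with its alignment and per-criterion verdicts."""

    query_id: str
    subject_id: str
    alignment: AlignmentResult
    passed: bool
    failed_criteria: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.passed != (len(self.failed_criteria) == 0):
            raise ValueError("passed must hold exactly when no criterion failed")


def evaluate_thresholds(
    alignment: AlignmentResult, candidate_length: int, thresholds: SearchThresholds
) -> tuple[str, ...]:
    """Names of the criteria the candidate fails (empty tuple = pass)."""
    failed: list[str] = []
    if thresholds.max_evalue is not None:
        if alignment.evalue is None or alignment.evalue > thresholds.max_evalue:
            failed.append("max_evalue")
    if thresholds.min_identity is not None and alignment.percent_identity < thresholds.min_identity:
        failed.append("min_identity")
    if (
        thresholds.min_similarity is not None
        and not alignment.percent_similarity > thresholds.min_similarity
    ):
        failed.append("min_similarity")
    if thresholds.min_length is not None:
        ok = (
            candidate_length > thresholds.min_length
            if thresholds.strict_length
            else candidate_length >= thresholds.min_length
        )
        if not ok:
            failed.append("min_length")
    return tuple(failed)


def screen_candidates(
    candidates: Sequence[ProteinRecord],
    reference: ProteinRecord,
    thresholds: SearchThresholds,
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = 11,
    gap_extend: float = 1,
    evalue_params: EvalueParams | None = None,
) -> list[HomologHit]:
    """Align every candidate locally to the reference and apply the thresholds.

    The e-value search space defaults to reference (query) length times the
    summed candidate (database) length. Output order equals input order.
    """
    if not reference.sequence:
        raise ValueError("reference sequence must be non-empty")
    candidates = list(candidates)
    if evalue_params is None:
        db_len = sum(len(c) for c in candidates)
        evalue_params = EvalueParams(search_space=max(1.0, float(len(reference) * db_len)))
    hits: list[HomologHit] = []
    for cand in candidates:
        aln = local_align(cand, reference, matrix, gap_open, gap_extend)
        estimate_evalue(aln, evalue_params)
        failed = evaluate_thresholds(aln, len(cand), thresholds)
        hits.append(
            HomologHit(
                query_id=cand.id,
                subject_id=reference.id,
                alignment=aln,
                passed=not failed,
                failed_criteria=failed,
            )
        )
    return hits


def reduce_redundancy(
    records: Sequence[ProteinRecord],
    identity_threshold: float,
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = 11,
    gap_extend: float = 1,
) -> tuple[list[ProteinRecord], dict[str, str]]:
    """Greedy redundancy reduction.

    Records are scanned in input order; each joins the first cluster whose
    founding representative it matches at >= ``identity_threshold`` percent
    global identity, otherwise it founds a new cluster. Returns the
    representatives (founders, input order) and a member-id -> rep-id map.
    """
    if not (0 < identity_threshold <= 100):
        raise ValueError("identity_threshold must be in (0, 100]")
    representatives: list[ProteinRecord] = []
    membership: dict[str, str] = {}
    for rec in records:
        placed = False
        for rep in representatives:
            ident = global_align(rec, rep, matrix, gap_open, gap_extend).percent_identity
            if ident >= identity_threshold:
                membership[rec.id] = rep.id
                placed = True
                break
        if not placed:
            representatives.append(rec)
            membership[rec.id] = rec.id
    return representatives, membership


def survey_summary(records: Iterable) -> dict:
    """Counts over a homolog inventory.

    For :class:`GenomeHomologRecord` collections: total plus per-phylum,
    per-taxon-group, and per-ecosystem-class counts (keys sorted). For
    :class:`HomologHit` collections: total, passed, and per-criterion
    failure counts.
    """
    records = list(records)
    if records and isinstance(records[0], HomologHit):
        failures: dict[str, int] = {}
        for hit in records:
            for crit in hit.failed_criteria:
                failures[crit] = failures.get(crit, 0) + 1
        return {
            "total": len(records),
            "passed": sum(1 for h in records if h.passed),
            "failed_by_criterion": dict(sorted(failures.items())),
        }
    by_phylum: dict[str, int] = {}
    by_taxon: dict[str, int] = {}
    by_environment: dict[str, int] = {}
    for rec in records:
        by_phylum[rec.phylum] = by_phylum.get(rec.phylum, 0) + 1
        by_taxon[rec.taxon_group] = by_taxon.get(rec.taxon_group, 0) + 1
        env = classify_environment(rec.environment)
        by_environment[env] = by_environment.get(env, 0) + 1
    return {
        "total": len(records),
        "by_phylum": dict(sorted(by_phylum.items())),
        "by_taxon_group": dict(sorted(by_taxon.items())),
        "by_environment": dict(sorted(by_environment.items())),
    }
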