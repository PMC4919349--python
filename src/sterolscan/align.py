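"""Pairwise and multiple protein alignment with affine gap penalties.

Local (Smith–Waterman) and global (Needleman–Wunsch) affine-gap alignment
are executed through Biopython's :class:`Bio.Align.PairwiseAligner`; this
module wraps it with the statistics the survey thresholds need (percent
identity, percent similarity, Karlin–Altschul e-values) plus a center-star
progressive multiple alignment and conserved-block trimming.

Conventions
-----------
* Gap penalties are passed as positive magnitudes and subtracted: a gap of
  length ``L`` costs ``gap_open + L * gap_extend``. Defaults (11, 1) match
  common protein-search practice.
* Percent identity and percent similarity are computed over aligned residue
  pairs only (gap columns excluded); "similar" means a positive
  substitution-matrix score, the usual "positives" convention.
* One optimal traceback is reported (the engine's first), which is
  deterministic for a fixed input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .core_io import ProteinRecord

DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A symmetric residue-pair score table (default BLOSUM62, X included)."""

    name: str
    array: object  # Bio.Align.substitution_matrices.Array

    @classmethod
    def load(cls, name: str = "BLOSUM62") -> "SubstitutionMatrix":
        return cls(name=name, array=substitution_matrices.load(name))

    @classmethod
    def from_file(cls, path: str | Path) -> "SubstitutionMatrix":
        """Read a matrix in standard NCBI format."""
        arr = substitution_matrices.read(str(path))
        return cls(name=Path(path).stem, array=arr)

    @property
    def alphabet(self) -> str:
        return str(self.array.alphabet)

    def score(self, a: str, b: str) -> float:
        return float(self.array[a, b])


_DEFAULT_MATRIX: SubstitutionMatrix | None = None


def default_matrix() -> SubstitutionMatrix:
    global _DEFAULT_MATRIX
    if _DEFAULT_MATRIX is None:
        _DEFAULT_MATRIX = SubstitutionMatrix.load("BLOSUM62")
    return _DEFAULT_MATRIX


@dataclass(frozen=True)
class EvalueParams:
    """Karlin–Altschul parameters: E = K * search_space * exp(-lambda * S).

    Defaults are the published gapped BLOSUM62 (11/1) constants. The search
    space is the product of effective query and database lengths in
    residues squared.
    """

    lam: float = 0.267
    K: float = 0.041
    search_space: float = 1.0

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.K <= 0 or self.search_space < 1:
            raise ValueError("require lambda > 0, K > 0, search_space >= 1")


@dataclass
class AlignmentResult:
    """One optimal pairwise alignment plus its summary statistics."""

    query_id: str
    subject_id: str
    aligned_pairs: tuple[tuple[int, int], ...]
    raw_score: float
    percent_identity: float
    percent_similarity: float
    alignment_length: int
    evalue: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.percent_identity <= self.percent_similarity <= 100):
            raise ValueError("require 0 <= identity <= similarity <= 100")


def _make_aligner(matrix: SubstitutionMatrix, gap_open: float, gap_extend: float, mode: str):
    if gap_open < 0 or gap_extend < 0:
        raise ValueError("gap penalties are positive magnitudes (they are subtracted)")
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = matrix.array
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -float(gap_extend)
    return aligner


def _stats(pairs, qseq, sseq, matrix):
    n = len(pairs)
    if n == 0:
        return 0.0, 0.0
    ident = sum(1 for q, s in pairs if qseq[q] == sseq[s])
    simil = sum(1 for q, s in pairs if matrix.score(qseq[q], sseq[s]) > 0)
    return 100.0 * ident / n, 100.0 * simil / n


def _run(a: ProteinRecord, b: ProteinRecord, matrix, gap_open, gap_extend, mode) -> AlignmentResult:
    if matrix is None:
        matrix = default_matrix()
    if not a.sequence or not b.sequence:
        raise ValueError("cannot align empty sequences")
    aligner = _make_aligner(matrix, gap_open, gap_extend, mode)
    aln = aligner.align(a.sequence, b.sequence)[0]
    qblocks, sblocks = aln.aligned
    pairs: list[tuple[int, int]] = []
    for (qs, qe), (ss, se) in zip(qblocks, sblocks):
        pairs.extend(zip(range(qs, qe), range(ss, se)))
    identity, similarity = _stats(pairs, a.sequence, b.sequence, matrix)
    return AlignmentResult(
        query_id=a.id,
        subject_id=b.id,
        aligned_pairs=tuple(pairs),
        raw_score=float(aln.score),
        percent_identity=identity,
        percent_similarity=similarity,
        alignment_length=int(aln.length),
    )


def local_align(
    a: ProteinRecord,
    b: ProteinRecord,
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> AlignmentResult:
    """Optimal Smith–Waterman affine-gap local alignment of ``a`` (query) vs ``b``."""
    return _run(a, b, matrix, gap_open, gap_extend, "local")


def global_align(
    a: ProteinRecord,
    b: ProteinRecord,
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> AlignmentResult:
    """End-to-end Needleman–Wunsch affine-gap alignment of ``a`` (query) vs ``b``."""
    return _run(a, b, matrix, gap_open, gap_extend, "global")


def estimate_evalue(result: AlignmentResult, params: EvalueParams) -> float:
    """Karlin–Altschul expect value for the alignment score; stored on the result."""
    e = params.K * params.search_space * math.exp(-params.lam * result.raw_score)
    result.evalue = e
    return e


# ---------------------------------------------------------------------------
# multiple alignment

@dataclass(frozen=True)
class MultipleAlignment:
    """Equal-length gapped rows; degapping any row reproduces its input."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must correspond")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("all rows must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("member ids must be unique")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, member_id: str) -> str:
        return self.rows[self.ids.index(member_id)]

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)


def _pair_columns(pairs: Sequence[tuple[int, int]], len_q: int, len_c: int):
    """Expand aligned pairs of a global alignment into explicit columns.

    Yields ``(q, c)`` with ``None`` marking a gap; center(``c``)-consuming
    columns are emitted before query insertions at the same boundary.
    """
    cols: list[tuple[int | None, int | None]] = []
    qi = ci = 0
    for q, c in pairs:
        while ci < c:
            cols.append((None, ci))
            ci += 1
        while qi < q:
            cols.append((qi, None))
            qi += 1
        cols.append((q, c))
        qi, ci = q + 1, c + 1
    while ci < len_c:
        cols.append((None, ci))
        ci += 1
    while qi < len_q:
        cols.append((qi, None))
        qi += 1
    return cols


def progressive_msa(
    records: Sequence[ProteinRecord],
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> MultipleAlignment:
    """Center-star progressive alignment.

    The center is the record maximizing its summed global-alignment score to
    all others (ties favor input order); every other record is merged into
    the growing profile by its global alignment to the ungapped center,
    with "once a gap, always a gap" column insertion.
    """
    records = list(records)
    if len(records) < 2:
        raise ValueError("progressive MSA requires at least 2 records")
    if matrix is None:
        matrix = default_matrix()
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids in MSA input")

    n = len(records)
    sums = [0.0] * n
    for i in range(n):
        for j in range(i + 1, n):
            s = global_align(records[i], records[j], matrix, gap_open, gap_extend).raw_score
            sums[i] += s
            sums[j] += s
    center_idx = max(range(n), key=lambda i: (sums[i], -i))
    center = records[center_idx]

    # master alignment: per-column center index (None = insertion column)
    master_centers: list[int | None] = list(range(len(center.sequence)))
    master_rows: dict[str, list[str]] = {center.id: list(center.sequence)}

    for rec in records[:center_idx] + records[center_idx + 1 :]:
        res = global_align(rec, center, matrix, gap_open, gap_extend)
        new_cols = _pair_columns(res.aligned_pairs, len(rec.sequence), len(center.sequence))
        out_centers: list[int | None] = []
        out_rows: dict[str, list[str]] = {rid: [] for rid in master_rows}
        new_row: list[str] = []
        mi = 0

        def emit_master(k: int, new_char: str) -> None:
            out_centers.append(master_centers[k])
            for rid in out_rows:
                out_rows[rid].append(master_rows[rid][k])
            new_row.append(new_char)

        for q, c in new_cols:
            if c is None:
                out_centers.append(None)
                for rid in out_rows:
                    out_rows[rid].append("-")
                new_row.append(rec.sequence[q])
            else:
                while master_centers[mi] != c:
                    emit_master(mi, "-")
                    mi += 1
                emit_master(mi, rec.sequence[q] if q is not None else "-")
                mi += 1
        while mi < len(master_centers):
            emit_master(mi, "-")
            mi += 1
        out_rows[rec.id] = new_row
        master_centers = out_centers
        master_rows = out_rows

    ordered_ids = tuple(r.id for r in records)
    return MultipleAlignment(
        ids=ordered_ids,
        rows=tuple("".join(master_rows[rid]) for rid in ordered_ids),
    )


def trim_conserved_blocks(
    msa: MultipleAlignment, max_gap_fraction: float, min_block_length: int
) -> MultipleAlignment:
    """Keep columns whose gap fraction is <= ``max_gap_fraction``, then drop
    surviving runs (consecutive surviving columns) shorter than
    ``min_block_length``. Removing every column yields a zero-column
    alignment, not an error.
    """
    if not (0 <= max_gap_fraction <= 1):
        raise ValueError("max_gap_fraction must be in [0, 1]")
    if min_block_length < 1:
        raise ValueError("min_block_length must be >= 1")
    n_rows = len(msa.rows)
    survive = [
        sum(1 for ch in msa.column(j) if ch == "-") / n_rows <= max_gap_fraction
        for j in range(msa.n_columns)
    ]
    keep: list[int] = []
    run: list[int] = []
    for j in range(msa.n_columns + 1):
        if j < msa.n_columns and survive[j]:
            run.append(j)
        else:
            if len(run) >= min_block_length:
                keep.extend(run)
            run = []
    return MultipleAlignment(
        ids=msa.ids,
        rows=tuple("".join(r[j] for j in keep) for r in msa.rows),
    )


def write_msa(msa: MultipleAlignment, path: str | Path, width: int = 60) -> Path:
    """Write an alignment as aligned (gapped) FASTA."""
    path = Path(path)
    with open(path, "w") as fh:
        for rid, row in zip(msa.ids, msa.rows):
            fh.write(f">{rid}\n")
            for i in range(0, len(row), width):
                fh.write(row[i : i + width] + "\n")
    return path


def read_msa(path: str | Path) -> MultipleAlignment:
    """Read an aligned FASTA file back into a :class:`MultipleAlignment`."""
    ids: list[str] = []
    rows: list[str] = []
    current: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if ids:
                    rows.append("".join(current))
                ids.append(line[1:].split()[0])
                current = []
            else:
                current.append(line)
    if ids:
        rows.append("".join(current))
    return MultipleAlignment(ids=tuple(ids), rows=tuple(rows))
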