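"""Readers and writers for FASTA, the bundled survey fixtures, and run config.

The package ships four tab-separated fixture tables describing the surveyed
sterol-producing bacteria:

* ``strains.tsv`` — strains subjected to lipid analysis (growth metadata).
* ``osc_homologs.tsv`` — bacterial genomes carrying an oxidosqualene
  cyclase (Osc) homolog, with locus tags and isolation environments.
* ``observed_sterols.tsv`` — sterols detected per strain (wide format, one
  column per compound of the controlled vocabulary).
* ``gene_complements.tsv`` — sterol-biosynthesis gene homologs (locus tags)
  per strain, one column per enzyme family; ``.`` marks absence.

All vocabularies are closed: loading a table never silently invents a
compound or enzyme-family name.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: the 20 standard residues plus X for ambiguity (scores as mismatch downstream)
PROTEIN_ALPHABET = frozenset(AMINO_ACIDS + "X")

#: enzyme families of the sterol pathway, in pathway order
ENZYME_FAMILIES = (
    "SE",
    "LAS",
    "CAS",
    "ERG11",
    "ERG24",
    "ERG25",
    "ERG26",
    "ERG27",
    "ERG4_DHCR24",
)

#: controlled vocabulary of observable compounds (lipid-table column heads)
LIPID_COMPOUNDS = (
    "squalene",
    "cycloartenol",
    "lanosterol",
    "parkeol",
    "4,4-dimethylcholesta-8,24-dien-3-ol",
    "4,4-dimethylcholesta-8-en-3-ol",
    "4-methylcholesta-8,24-dien-3-ol",
    "4-methylcholesta-8-en-3-ol",
    "zymosterol",
)

STUDY_SECTIONS = ("this_study", "previous_study")


class FastaParseError(ValueError):
    """Structurally malformed FASTA (bad header, empty sequence)."""


class SequenceValidationError(ValueError):
    """A sequence contains characters outside the protein alphabet."""


class VocabularyError(ValueError):
    """A fixture names an unknown compound or enzyme family."""


class ConsistencyError(ValueError):
    """Cross-references between fixture tables do not resolve."""


@dataclass(frozen=True)
class ProteinRecord:
    """An amino-acid sequence with source metadata."""

    id: str
    sequence: str
    description: str = ""
    source_class: str = "genome"
    taxon_group: str | None = None
    phylum: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceValidationError("record id must be non-empty")
        if not self.sequence:
            raise SequenceValidationError(f"empty sequence for record {self.id!r}")
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - PROTEIN_ALPHABET
        if bad:
            raise SequenceValidationError(
                f"illegal residue characters {sorted(bad)} in record {self.id!r}"
            )
        if self.source_class not in ("genome", "metagenome"):
            raise ValueError(f"unknown source_class {self.source_class!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GenomeHomologRecord:
    """One genome carrying an Osc homolog (survey inventory row)."""

    strain_name: str
    locus_tag: str
    taxon_group: str
    phylum: str
    environment: str

    def __post_init__(self) -> None:
        if not self.locus_tag:
            raise ValueError(f"empty locus tag for {self.strain_name!r}")


@dataclass(frozen=True)
class ObservedLipidRecord:
    """Sterols detected in one strain by lipid analysis."""

    strain_name: str
    study_section: str
    taxon_group: str
    compounds: frozenset[str]

    def __post_init__(self) -> None:
        if self.study_section not in STUDY_SECTIONS:
            raise VocabularyError(f"unknown study section {self.study_section!r}")
        unknown = set(self.compounds) - set(LIPID_COMPOUNDS)
        if unknown:
            raise VocabularyError(
                f"unknown compound(s) {sorted(unknown)} for strain {self.strain_name!r}"
            )
        object.__setattr__(self, "compounds", frozenset(self.compounds))


@dataclass(frozen=True)
class GeneComplementRecord:
    """Enzyme family -> locus tag mapping for one strain (at most one locus per family)."""

    strain_name: str
    family_to_locus: Mapping[str, str]
    study_section: str = "this_study"

    def __post_init__(self) -> None:
        unknown = set(self.family_to_locus) - set(ENZYME_FAMILIES)
        if unknown:
            raise VocabularyError(
                f"unknown enzyme family(ies) {sorted(unknown)} for {self.strain_name!r}"
            )
        if self.study_section not in STUDY_SECTIONS:
            raise VocabularyError(f"unknown study section {self.study_section!r}")
        object.__setattr__(self, "family_to_locus", dict(self.family_to_locus))

    @property
    def families(self) -> frozenset[str]:
        return frozenset(self.family_to_locus)


@dataclass
class RunConfig:
    """Run-wide configuration (seed, thresholds, mode, output)."""

    seed: int = 0
    pathway_mode: str = "canonical"
    output_dir: str = "."
    log_level: str = "INFO"
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pathway_mode not in ("canonical", "relaxed"):
            raise ValueError(f"unknown pathway mode {self.pathway_mode!r}")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Parse a (wrapped or unwrapped) protein FASTA file.

    Raises :class:`FastaParseError` naming the offending line for structural
    problems and :class:`SequenceValidationError` naming the record for
    alphabet violations. Sequences are uppercased; order is preserved.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []
    seen: set[str] = set()

    def flush(line_no: int) -> None:
        nonlocal header, chunks
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FastaParseError(f"{path}: empty sequence for header at line {header_line}")
        rid, _, desc = header.partition(" ")
        if rid in seen:
            raise FastaParseError(f"{path}: duplicate record id {rid!r} at line {header_line}")
        seen.add(rid)
        records.append(ProteinRecord(id=rid, sequence=seq, description=desc))
        header, chunks = None, []

    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(i)
                header = line[1:].strip()
                header_line = i
                if not header:
                    raise FastaParseError(f"{path}: empty FASTA header at line {i}")
            else:
                if header is None:
                    raise FastaParseError(f"{path}: sequence before any header at line {i}")
                chunks.append(line)
        flush(-1)
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            desc = f" {rec.description}" if rec.description else ""
            fh.write(f">{rec.id}{desc}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")
    return path


# ---------------------------------------------------------------------------
# fixture tables

FIXTURE_FILES = {
    "strains": "strains.tsv",
    "homologs": "osc_homologs.tsv",
    "lipids": "observed_sterols.tsv",
    "complements": "gene_complements.tsv",
}


def packaged_fixture_dir() -> Path:
    """Location of the fixture tables bundled with the package."""
    return Path(resources.files("sterolscan") / "data")


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def read_strain_table(path: str | Path) -> list[dict]:
    df = _read_tsv(path)
    required = {"strain_name", "taxon_group", "phylum"}
    missing = required - set(df.columns)
    if missing:
        raise ConsistencyError(f"{path}: missing column(s) {sorted(missing)}")
    return df.to_dict(orient="records")


def read_homolog_table(path: str | Path) -> list[GenomeHomologRecord]:
    df = _read_tsv(path)
    return [
        GenomeHomologRecord(
            strain_name=row["strain_name"],
            locus_tag=row["locus_tag"],
            taxon_group=row["taxon_group"],
            phylum=row["phylum"],
            environment=row["environment"],
        )
        for row in df.to_dict(orient="records")
    ]


def read_lipid_table(path: str | Path) -> list[ObservedLipidRecord]:
    df = _read_tsv(path)
    meta = ["strain_name", "study_section", "taxon_group"]
    compound_cols = [c for c in df.columns if c not in meta]
    unknown = set(compound_cols) - set(LIPID_COMPOUNDS)
    if unknown:
        raise VocabularyError(f"{path}: unknown compound column(s) {sorted(unknown)}")
    out = []
    for row in df.to_dict(orient="records"):
        present = frozenset(c for c in compound_cols if row[c].strip() == "+")
        out.append(
            ObservedLipidRecord(
                strain_name=row["strain_name"],
                study_section=row["study_section"],
                taxon_group=row["taxon_group"],
                compounds=present,
            )
        )
    return out


def read_complement_table(path: str | Path) -> list[GeneComplementRecord]:
    df = _read_tsv(path)
    meta = ["strain_name", "study_section"]
    family_cols = [c for c in df.columns if c not in meta]
    unknown = set(family_cols) - set(ENZYME_FAMILIES)
    if unknown:
        raise VocabularyError(f"{path}: unknown enzyme family column(s) {sorted(unknown)}")
    out = []
    for row in df.to_dict(orient="records"):
        loci = {
            fam: row[fam].strip()
            for fam in family_cols
            if row[fam].strip() not in ("", ".")
        }
        out.append(
            GeneComplementRecord(
                strain_name=row["strain_name"],
                family_to_locus=loci,
                study_section=row.get("study_section", "this_study"),
            )
        )
    return out


def load_fixtures(directory: str | Path | None = None) -> dict:
    """Load the four fixture tables and verify cross-references.

    Every strain in the this-study section of the lipid table must appear in
    both the gene-complement table and the strain table.
    """
    directory = Path(directory) if directory is not None else packaged_fixture_dir()
    paths = {k: directory / v for k, v in FIXTURE_FILES.items()}
    missing = [str(p) for p in paths.values() if not p.exists()]
    if missing:
        raise FileNotFoundError(f"missing fixture file(s): {missing}")
    tables = {
        "strains": read_strain_table(paths["strains"]),
        "homologs": read_homolog_table(paths["homologs"]),
        "lipids": read_lipid_table(paths["lipids"]),
        "complements": read_complement_table(paths["complements"]),
    }
    strain_names = {r["strain_name"] for r in tables["strains"]}
    complement_names = {r.strain_name for r in tables["complements"]}
    for rec in tables["lipids"]:
        if rec.study_section != "this_study":
            continue
        if rec.strain_name not in complement_names:
            raise ConsistencyError(
                f"lipid strain {rec.strain_name!r} has no gene-complement record"
            )
        if rec.strain_name not in strain_names:
            raise ConsistencyError(
                f"lipid strain {rec.strain_name!r} has no strain-table record"
            )
    return tables


# ---------------------------------------------------------------------------
# generic writer (round-trips through the matching reader)

def write_table(records: Sequence, path: str | Path) -> Path:
    """Write a homogeneous record collection as TSV.

    Dispatches on the record type; the output round-trips bit-identically
    through the corresponding reader. An empty collection yields a
    header-only homolog-style file only when given an explicit type via a
    non-empty collection, so empty input writes the generic empty header.
    """
    path = Path(path)
    records = list(records)
    if not records:
        path.write_text("strain_name\n")
        return path
    types = {type(r) for r in records}
    if len(types) > 1:
        raise TypeError(f"heterogeneous record collection: {sorted(t.__name__ for t in types)}")
    rec = records[0]
    if isinstance(rec, GenomeHomologRecord):
        df = pd.DataFrame([dataclasses.asdict(r) for r in records])
        df = df[["strain_name", "locus_tag", "taxon_group", "phylum", "environment"]]
    elif isinstance(rec, ObservedLipidRecord):
        rows = []
        for r in records:
            row = {
                "strain_name": r.strain_name,
                "study_section": r.study_section,
                "taxon_group": r.taxon_group,
            }
            row.update({c: ("+" if c in r.compounds else "") for c in LIPID_COMPOUNDS})
            rows.append(row)
        df = pd.DataFrame(rows)
    elif isinstance(rec, GeneComplementRecord):
        rows = []
        for r in records:
            row = {"strain_name": r.strain_name, "study_section": r.study_section}
            row.update({f: r.family_to_locus.get(f, ".") for f in ENZYME_FAMILIES})
            rows.append(row)
        df = pd.DataFrame(rows)
    elif isinstance(rec, dict):
        df = pd.DataFrame(records)
    else:
        raise TypeError(f"cannot serialize records of type {type(rec).__name__}")
    df.to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# environment classification (for survey summaries)

_ENVIRONMENT_RULES = (
    ("symbiont", ("symbiont",)),
    ("sewage", ("sewage", "sewer")),
    ("hot_spring", ("hot spring",)),
    ("soil", ("soil", "terrestrial", "desert")),
    ("marine", ("marine", "sea", "intertidal", "fjord", "coastal")),
    ("freshwater", ("freshwater", "lake", "river", "dam")),
)


def classify_environment(text: str) -> str:
    """Map a free-text isolation source to a coarse ecosystem class."""
    low = text.lower()
    for label, keywords in _ENVIRONMENT_RULES:
        if any(k in low for k in keywords):
            return label
    return "other"


# ---------------------------------------------------------------------------
# run configuration

def load_run_config(path: str | Path) -> RunConfig:
    """Load a YAML (or flat ``key: value``) run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: run configuration must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown configuration key(s) {sorted(unknown)}")
    return RunConfig(**data)
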