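"""Orchestration: fixture-based survey reproduction and synthetic validation.

Every number in a result's summary block is recomputed from the input
tables or simulations at run time; the pipeline layer holds no result
constants.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .classifier import ReferenceAnnotation, classify_osc
from .core_io import (
    LIPID_COMPOUNDS,
    ObservedLipidRecord,
    ProteinRecord,
    load_fixtures,
)
from .discrepancy import cohort_counts, compare
from .pathway import (
    C4_FAMILIES,
    EnzymeComplement,
    reachable_compounds,
    required_families,
)
from .simulate import SimulationConfig, simulate_cohort, simulate_family
from .survey import survey_summary

CYCLIZED_COMPOUNDS = frozenset(LIPID_COMPOUNDS) - {"squalene"}


@dataclass
class PipelineResult:
    """Stage outputs, a reproducibility manifest, and the summary counts."""

    summary: dict
    outputs: dict[str, str] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _manifest(seed: int, config_repr: str) -> dict:
    return {
        "version": __version__,
        "seed": seed,
        "config_hash": hashlib.sha256(config_repr.encode()).hexdigest()[:16],
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }


def run_survey_reproduction(
    fixture_dir: str | Path | None = None,
    mode: str = "canonical",
    out_dir: str | Path | None = None,
    seed: int = 0,
) -> PipelineResult:
    """Recompute the survey's accounting from the bundled fixture tables.

    Emits the homolog-survey summary, per-strain predicted sterol profiles,
    per-strain discrepancy reports, and cohort counts.
    """
    tables = load_fixtures(fixture_dir)
    homologs = tables["homologs"]
    lipids = tables["lipids"]
    complements = {r.strain_name: r for r in tables["complements"]}

    survey = survey_summary(homologs)

    tested = [r for r in lipids if r.study_section == "this_study"]
    no_cyclized = [r for r in tested if not (r.compounds & CYCLIZED_COMPOUNDS)]

    profiles = {}
    reports = []
    for lipid in tested:
        complement = EnzymeComplement.from_record(complements[lipid.strain_name])
        profiles[lipid.strain_name] = reachable_compounds(complement, mode)
        reports.append(compare(lipid, complement, mode))
    cohort = cohort_counts(reports, tested)

    c4_homolog_counts = {
        name: len(EnzymeComplement.from_record(rec).families & C4_FAMILIES)
        for name, rec in complements.items()
    }

    summary = {
        "mode": mode,
        "osc_homolog_total": survey["total"],
        "osc_homologs_by_phylum": survey["by_phylum"],
        "osc_homologs_by_taxon_group": survey["by_taxon_group"],
        "osc_homologs_by_environment": survey["by_environment"],
        "tested_strain_total": len(tested),
        "strains_without_cyclized_sterols": len(no_cyclized),
        "strains_without_cyclized_sterols_names": sorted(r.strain_name for r in no_cyclized),
        "c4_demethylation_required_families": len(required_families("C-4 demethylation")),
        "c4_homolog_counts": c4_homolog_counts,
        "group_counts": cohort.group_counts,
        "compound_prevalence": cohort.compound_prevalence,
        "zymosterol_prevalence": cohort.compound_prevalence.get("zymosterol", 0),
    }
    result = PipelineResult(
        summary=summary,
        manifest=_manifest(seed, f"reproduction:{mode}"),
    )
    result.summary["reports"] = reports
    result.summary["predicted_profiles"] = profiles
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        _write_reproduction_outputs(result, profiles, reports, out_dir)
    return result


def _write_reproduction_outputs(result, profiles, reports, out_dir: Path) -> None:
    rows = [
        {
            "strain_name": name,
            "mode": p.mode,
            "compound": c,
            "terminal": c in p.terminal_compounds,
        }
        for name, p in profiles.items()
        for c in p.compounds
    ]
    pd.DataFrame(rows).to_csv(out_dir / "predicted_profiles.tsv", sep="\t", index=False)

    flag_rows = []
    for rep in reports:
        for compound in rep.agreements:
            flag_rows.append(
                {"strain_name": rep.strain_name, "flag": "agreement", "compound": compound, "detail": ""}
            )
        for orphan in rep.orphans:
            flag_rows.append(
                {
                    "strain_name": rep.strain_name,
                    "flag": "zero_family_orphan" if orphan.zero_family else "orphan",
                    "compound": orphan.compound,
                    "detail": ";".join(orphan.missing_families),
                }
            )
        for fam in rep.silent_capacities:
            flag_rows.append(
                {"strain_name": rep.strain_name, "flag": "silent_capacity", "compound": "", "detail": fam}
            )
    pd.DataFrame(flag_rows).to_csv(out_dir / "discrepancy_report.tsv", sep="\t", index=False)

    summary = {
        k: v
        for k, v in result.summary.items()
        if k not in ("reports", "predicted_profiles")
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    result.outputs = {
        "predicted_profiles": str(out_dir / "predicted_profiles.tsv"),
        "discrepancy_report": str(out_dir / "discrepancy_report.tsv"),
        "summary": str(out_dir / "summary.json"),
    }


def run_synthetic_validation(
    seed: int = 0,
    n_family: int = 50,
    divergence: float = 0.3,
    n_strains: int = 100,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Simulate, re-analyze, and score recovery against the ground truth.

    Classifier stage: a mixed LAS/CAS family at the given divergence is
    classified against its own (LAS-annotated) ancestor; accuracy is the
    fraction of correct calls. Cohort stage: injected orphan compounds and
    silent families must be recovered exactly by the discrepancy analysis.
    """
    classes = tuple("LAS" if i % 2 == 0 else "CAS" for i in range(n_family))
    fam_cfg = SimulationConfig(
        seed=seed, n_taxa=n_family, divergence=divergence, class_assignments=classes
    )
    records, truth = simulate_family(fam_cfg)
    ancestor = ProteinRecord(
        id="sim_ancestor",
        sequence=truth.per_record["__ancestor_sequence__"]["sequence"],
        description="synthetic LAS-annotated ancestor",
    )
    annot = ReferenceAnnotation(reference=ancestor)
    correct = sum(
        1 for rec in records if classify_osc(rec, annot).call == truth.per_record[rec.id]["class"]
    )
    classifier_accuracy = correct / len(records)

    cohort_cfg = SimulationConfig(seed=seed + 1, n_strains=n_strains)
    lipids, complements, cohort_truth = simulate_cohort(cohort_cfg)
    orphan_exact = silent_exact = 0
    for lipid, comp in zip(lipids, complements):
        report = compare(lipid, EnzymeComplement.from_record(comp))
        strain_truth = cohort_truth.per_strain[lipid.strain_name]
        found_orphans = tuple(sorted(o.compound for o in report.orphans))
        found_silent = tuple(sorted(report.silent_capacities))
        orphan_exact += found_orphans == tuple(sorted(strain_truth["injected_orphans"]))
        silent_exact += found_silent == tuple(sorted(strain_truth["injected_silent"]))
    summary = {
        "classifier_accuracy": classifier_accuracy,
        "classifier_n": len(records),
        "classifier_divergence": divergence,
        "cohort_n": n_strains,
        "cohort_orphan_exact_fraction": orphan_exact / n_strains,
        "cohort_silent_exact_fraction": silent_exact / n_strains,
        "injected_orphan_strains": sum(
            1 for t in cohort_truth.per_strain.values() if t["injected_orphans"]
        ),
        "injected_silent_strains": sum(
            1 for t in cohort_truth.per_strain.values() if t["injected_silent"]
        ),
    }
    result = PipelineResult(
        summary=summary,
        manifest=_manifest(seed, f"validation:{n_family}:{divergence}:{n_strains}"),
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "validation_summary.json"
        path.write_text(json.dumps(summary, indent=2))
        result.outputs["validation_summary"] = str(path)
    return result
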