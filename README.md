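# sterolscan

Sterols are tetracyclic triterpenoid lipids that almost all eukaryotes make
and require, and whose fossilized derivatives (steranes) are read as
biomarkers for eukaryotes and for oxygenated environments. A handful of
bacteria also make sterols, which complicates that reading. `sterolscan` is
a toolkit for surveying bacterial sterol biosynthesis from sequence data and
for confronting what a genome *should* be able to make with what lipid
analysis actually finds. It is aimed at microbiologists and organic
geochemists who work with protein homolog surveys and lipid profiles.

The package bundles, as machine-readable TSV fixtures, a curated survey of
34 bacterial genomes carrying an oxidosqualene cyclase (Osc) homolog across
myxobacteria, Methylococcales methanotrophs, an alphaproteobacterium,
Bacteroidetes, Cyanobacteria, and Planctomycetes, together with the observed
sterols and sterol-gene complements of 11 lipid-analyzed strains.

## What it computes

* **Homolog screening** (`sterolscan.survey`): Smith–Waterman alignment of
  candidate proteins to a reference cyclase with Karlin–Altschul e-values
  (E = K·mn·e^(−λS)) and threshold presets — genome screens at E ≤ 1e−100
  with similarity > 30%, metagenome screens at E ≤ 1e−50 with length ≥ 400
  aa, downstream pathway genes at E ≤ 1e−10 with identity ≥ 20% — plus
  greedy redundancy reduction and survey summaries.
* **LAS/CAS classification** (`sterolscan.classifier`): queries are mapped
  onto an annotated reference numbering by global alignment and called from
  the diagnostic residue triple 381/449/453: V453 ⇒ lanosterol synthase
  (LAS), I453 ⇒ cycloartenol synthase (CAS), with T/C381 + Q449 (LAS) and
  Y381 + H449 (CAS) counted as supporting agreement.
* **Pathway reachability** (`sterolscan.pathway`): a reaction graph from
  squalene through epoxidation (SE), cyclization (LAS/CAS), C-14
  demethylation (ERG11), C-14 reduction (ERG24), two-step C-4 demethylation
  (ERG25+ERG26+ERG27, or any one of them in *relaxed* mode), and Δ24
  reduction (ERG4/DHCR24). Given an enzyme complement it returns the
  reachable compound set and, for any target sterol, the smallest set of
  absent families that would explain it.
* **Discrepancy analysis** (`sterolscan.discrepancy`): per strain, observed
  sterols are split into agreements and *orphan modifications* (observed
  but unreachable — e.g. C-4-demethylated sterols in methanotrophs that
  have none of the eukaryotic C-4 demethylase genes), and present-but-unused
  families are flagged as *silent capacity*.
* **Phylogenetics** (`sterolscan.phylo`): p/Poisson distances over trimmed
  alignments, in-house Saitou–Nei neighbor joining (exact on additive
  matrices), squalene-hopene-cyclase outgroup rooting, and clade-membership
  queries for metagenomic fragments.
* **Synthetic data** (`sterolscan.simulate`): seed-deterministic protein
  families with pinned diagnostic residues, truncated metagenome-style
  fragments, and strain cohorts with injected orphans/silent families — the
  ground truth every stage is tested against.

## Worked example

```bash
sterolscan reproduce --out out/
```

prints (abridged):

```json
{
  "osc_homolog_total": 34,
  "osc_homologs_by_phylum": {"Bacteroidetes": 5, "Cyanobacteria": 5,
                             "Planctomycetes": 2, "Proteobacteria": 22},
  "tested_strain_total": 11,
  "strains_without_cyclized_sterols": 1,
  "strains_without_cyclized_sterols_names": ["Corallococcus coralloides"],
  "c4_demethylation_required_families": 3,
  "zymosterol_prevalence": 3
}
```

Reading: 34 genomes carry an Osc homolog; of the 11 strains with lipid
data, exactly one (*C. coralloides*) shows no cyclized sterol despite an
intact SE + Osc pair (a silent capacity, possibly unexpressed); full C-4
demethylation needs three enzyme families in the eukaryotic model; and
three myxobacteria (*E. salina*, *P. pacifica*, *S. amylolyticus*) carry
lanosterol all the way to zymosterol. The per-strain flags land in
`out/discrepancy_report.tsv`; all four tested Methylococcales are flagged
with zero-family C-4 orphans (they demethylate C-4 without any of
ERG25/26/27), e.g.:

```
Methylobacter luteus  zero_family_orphan  4-methylcholesta-8-en-3-ol  ERG24;ERG25;ERG26;ERG27
```

The same analysis runs on your own tables via
`sterolscan predict|discrepancy|survey|classify|tree` — see `--help`.

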