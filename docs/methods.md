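# Methods

## The model in brief

`sterolscan` treats bacterial sterol biosynthesis as three linked questions:
(1) which genomes carry the enzymes — answered by thresholded protein
homology screening; (2) which basic sterol a cyclase makes — answered by a
diagnostic-residue classifier; and (3) which downstream sterols a genome
can produce — answered by reachability in a reaction graph, compared
against observed lipid profiles.

## Alignment and search statistics

Pairwise local (Smith–Waterman) and global (Needleman–Wunsch) alignment
uses affine gap costs: a gap of length L costs `gap_open + L * gap_extend`
with defaults 11/1 and BLOSUM62, matching common protein-search practice.
Ambiguity is admitted only as X, which scores as a mismatch. Percent
identity and percent similarity are computed over aligned residue pairs
(gap columns excluded); "similar" means a positive substitution score (the
"positives" convention). Whether the 30% similarity gate in such surveys is
taken over aligned columns or full alignment length is genuinely ambiguous;
the aligned-columns convention used here is documented rather than asserted
as the only reading.

E-values follow Karlin–Altschul, `E = K · mn · exp(−λS)`, with the
published gapped BLOSUM62 constants λ = 0.267 nats and K = 0.041 as
defaults and the search space `mn` defaulting to reference length × summed
candidate length. Exact BLAST internals (composition adjustment, effective
length corrections) are not reproduced; the statistic is parameterized so
thresholds behave correctly (monotone in score, linear in search space).

One optimal traceback is reported — the alignment engine's first — which is
deterministic for fixed inputs. Threshold comparisons mirror their usual
phrasing: e-value and identity cutoffs are inclusive, the similarity gate
is strict, and the 400-residue fragment filter is inclusive (≥ 400) with a
flag for strict (>) behavior.

The progressive multiple alignment is center-star: the center maximizes
summed pairwise global scores, and members merge by global alignment to the
ungapped center under "once a gap, always a gap". It is a deliberately
simple, deterministic stand-in for a full MSA tool, adequate for the
conserved-block workflows here. Conserved-block trimming drops columns
whose gap fraction exceeds a threshold, then surviving runs shorter than a
minimum block length; trimming everything yields a zero-column alignment,
not an error.

## Classifier

Queries are globally aligned to a single annotated reference, giving a
monotone map from reference numbering (1-based) to query indices (0-based).
The product call is decided solely by the residue mapped to reference
position 453: V ⇒ LAS, I ⇒ CAS, anything else (including an unmapped
position, as in short fragments) ⇒ indeterminate. Positions 381 (T or C for
LAS, Y for CAS — "T381/C" is read as "T or C acceptable") and 449 (Q vs H)
contribute only a 0–2 supporting-agreement count. Alignment to the single
reference, rather than an all-query MSA, keeps classification
order-independent and deterministic. The functional-residue audit ships
with only the diagnostic triple by default and is user-extensible via a
TSV; no further residue expectations are fabricated. Parkeol producers are
not distinguishable at these three positions, so parkeol-type cyclases are
outside the classifier's claims.

## Pathway model

Compounds are feature states: stage (linear / epoxide / cyclized), C-4
methyl count (0–2), C-14 methyl flag, Δ8, Δ14, Δ24, the 9,19-cyclopropane
ring (cycloartenol-type, mutually exclusive with Δ8), and Δ9(11)
(parkeol-type). Squalene is the root and assumed present in every strain
(upstream synthesis is out of model, and squalene is detected even in
non-producers). Reactions are deterministic state maps gated by enzyme
families; reachability is the least fixed point of applying every satisfied
applicable reaction from squalene, so it is finite, order-independent, and
monotone in the complement.

Numerical/structural choices:

* C-4 demethylation removes one methyl per application and, by default,
  applies only after C-14 demethylation (the canonical eukaryotic order); a
  flag lifts the ordering to model methanotroph-style early C-4 removal.
* *Canonical* mode requires ERG25+ERG26+ERG27 for C-4 demethylation;
  *relaxed* mode accepts any non-empty subset, exposing the open question
  of how strains lacking part of that machinery fully demethylate C-4
  rather than asserting a mechanism.
* Δ24 reduction (ERG4/DHCR24) applies to any cyclized Δ24 state, producing
  the "-8-en" series at every demethylation stage.
* Parkeol is modeled as an optional alternative LAS product (flag, default
  off) since no distinct enzyme family is known; Δ8→Δ7 isomerization is an
  optional reaction with no family assignment and is excluded from
  discrepancy accounting by default.
* Unnamed intermediates get systematic names ("4,4-dimethylcholesta-
  8,14,24-trien-3-ol"); naming is injective over the state space and uses
  the "cholesta-8-en" spelling of the observable-compound vocabulary.

`minimal_missing_families` searches absent-family subsets exhaustively
(≤ 512), smallest cardinality first, ties broken lexicographically.
"Infeasible" is reserved for targets unreachable even under all nine
families (e.g. parkeol with the product flag off).

## Discrepancy analysis

Squalene and oxidosqualene are excluded from agreement/orphan accounting.
An observed compound outside the reachable set is an orphan, annotated with
its minimal missing family set; an orphan is *zero-family* when some
implicated reaction has no present member of its required family set (the
methanotroph C-4 signature). *Silent capacity* is defined at family
granularity: a present family that lies on no closure route from squalene
to any observed compound. This deliberately reports a genome with enzymes
but no corresponding lipids (including the no-sterol case with intact
SE+Osc) as silent capacity, not as an error — expression state is out of
scope. Consequence to note: for a strain observing a compound that is
*unreachable* (an orphan), the families that would serve that route still
count as silent, since in-model no route exists.

## Neighbor joining and clades

Distances are mismatch fractions over mutually ungapped columns
(p-distance) or Poisson-corrected `−ln(1−p)` capped at 25 as p → 1. NJ is
the classical Saitou–Nei algorithm; pair ties (Q within 1e−12) are broken
by the lexicographically smallest contained taxon labels, and negative limb
estimates are clamped to zero with a warning. On additive matrices NJ
recovers topology and path lengths exactly (checked to 1e−9). Outgroup
rooting bisects the branch separating a monophyletic outgroup, preserving
leaf-to-leaf path lengths; a scattered outgroup is an explicit error naming
the intruders. Maximum-likelihood inference is deliberately not
implemented; all claims are restricted to properties NJ supports (clade
membership, outgroup rooting), and published ML group compositions that
depend on external sequence data are not asserted as reproducible.

## Synthetic data: what it emulates and what it does not

Families are simulated as a star phylogeny: a uniform-random ancestor
(default 650 aa — typical cyclase length) whose descendants mutate each
site independently with probability equal to the divergence, replacing the
residue uniformly among the other 19 (so expected identity ≈ 1 −
divergence in closed form; an optional biased mode weights replacements
toward positive-scoring partners so similarity exceeds identity,
exercising the similarity gate separately from the identity gate).
Diagnostic sites are pinned to the assigned class and never mutated;
divergence above 0.6 with pinning is rejected as meaningless. There is no
indel evolution — length variation is modeled by contiguous fragments, as
in the metagenome screen — and no site-rate heterogeneity, guide-tree
correlation, or compositional bias. Passing recovery tests on this
generator therefore shows the machinery is correct under clean conditions;
it does not bound performance on real, indel-rich, compositionally biased
families.

Cohorts pair scenario complements (cycloartenol-basic, lanosterol-basic,
methanotroph-like, full zymosterol route) with observed sets equal to the
reachable compounds restricted to the observable vocabulary. Orphans are
injected at rate 0.2 and silent families at rate 0.1 (validated at
generation time to be genuinely unreachable/unused), so discrepancy
recovery has precision = recall = 1 by construction at this scale.

## Problem sizes

Default verification sizes, chosen as comfortable desk-scale settings: 200
random pairs (lengths 10–60) for the alignment-oracle comparison; 50-member
families at divergence 0.3 for classifier recovery; 100-strain cohorts for
flag recovery; additive-matrix NJ checks up to 12 taxa. The full test
suite runs in well under a minute on one CPU.

## Known limitations

* The bundled fixture follows the printed genome inventory exactly (34
  rows, four phyla after normalizing the Proteobacteria sections); the
  original survey's abstract-level count of five phyla (including a
  Verrucomicrobium) has no corresponding inventory row and is not invented.
* Metagenome-scale results (hit counts against live databases, tree group
  compositions) depend on database state and are covered by property-based
  checks, not numeric reproduction.
* The pathway model has no stereochemistry, kinetics, flux, or C-24
  alkylation (none was observed in the surveyed strains), and dual-cyclase
  ambiguity (lanosterol + cycloartenol in one strain) is reported as an
  orphan under a single-cyclase complement rather than resolved.
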