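# Methods

This note documents the models, rules and numerical choices behind
`covkin`, and what the synthetic-data generator does and does not
emulate.

## Compound standardization

Cross-database compound identity requires a single canonical
representation per molecule. `standardize_smiles` applies, in order:
parse → keep the largest organic fragment → neutralize → strip
stereochemistry and isotopes → canonicalize.

- *Largest organic fragment*: the fragment with the most heavy atoms
  that contains at least one carbon; ties broken by lexicographically
  smallest canonical SMILES so the choice is independent of atom order.
  Fragments without carbon (pure salts) are rejected as `inorganic`.
- *Neutralization* uses RDKit's uncharger: atoms with a valence-legal
  neutral protonation state are (de)protonated; permanent charges
  (quaternary nitrogen, etc.) are kept.
- *Isotopes* are cleared together with stereochemistry: a compound
  measured as a labeled standard and its unlabeled form must collapse
  to one record.
- Tautomers are **not** merged; tautomer canonicalization is a
  different, lossier operation and is deliberately out of scope.

Standardization is idempotent and permutation-invariant (property
tests cover both on a >1000-molecule generated library).

## Activity curation

Records are filtered through a fixed cascade so every rejection has a
deterministic reason code (the first failed filter): mandatory-field
check, units (must be nM when a units column is present), relation
"=", relationship type "D" (ChEMBL only — BindingDB has no such
field), potency ≤ 10,000 nM, measurement type in {Ki, Kd, IC50},
single-kinase assay, ChEMBL assay-confidence score 9, and a
case-insensitive comment scan ("uncertain", "potential transcription
error", "outside typical range", or contradictory active/inactive
tags).

Aggregation per (standard SMILES, kinase): Ki/Kd records take priority
over IC50; the mean and the sample standard deviation (n−1; 0 for a
single record) are computed on the pPotency (log) scale — the SD limit
is stated in log units, so averaging on the same scale keeps the two
consistent; pairs with SD ≥ 1 log unit are dropped. The 10 µM cut-off
is applied per record before averaging; since every surviving record
has pPotency ≥ 5, the aggregated mean cannot fall below 5.

Conservation (kept records + rejected records = input records) is
asserted in the pipeline and tested against a brute-force
reimplementation of the whole cascade.

## Warhead detection

The 14 SMARTS patterns (12 analyzed warheads + acrylamide and
heterocyclic urea from earlier work) are authored from the depicted
warhead structures; published sources typically do not print their
patterns, so the library is shipped as an editable YAML config and
each default is documented beside its pattern. Choices worth noting:

- *terminal alkyne* is `C#[CX2H1]`; *alkynyl benzoate* is modeled as
  the benzoate ester of a propargylic alcohol (the common depiction);
  one source sentence calls this class "alkynyl benzoxaxine" — the
  library follows the structure list and uses `alkynyl_benzoate`.
- *reactive (activated) ester* covers nitrophenyl, pentafluorophenyl
  and O–N (NHS-type) esters via recursive SMARTS on the leaving-group
  oxygen; plain alkyl/aryl esters do not match.
- *heterocyclic urea* requires a urea nitrogen attached to an aromatic
  carbon with an aromatic N/O/S reachable through aromatic bonds — an
  approximation of "attached to a heteroaromatic ring" that SMARTS can
  express without enumerating ring systems.

**Specificity rule.** An embedding of a less specific pattern (higher
rank) is suppressed when its atom set is contained in an embedding of
a more specific one: cyanoacrylamide < acrylamide, acrylate <
reactive ester, alkynyl benzoate < terminal alkyne. This keeps the
warhead classes disjoint where one is a decorated version of another,
without hiding genuinely independent co-occurring warheads.

Compounds matching only acrylamide/heterocyclic urea are routed to an
`excluded_prior` class — detected, but not part of any analyzed
subset, mirroring the separation from the earlier acrylamide/urea
study.

## Analogue series (compound–core decomposition)

A compound is decomposed by cutting 1..max_cuts acyclic single bonds;
the fragment carrying the most ring atoms is the core, the remaining
fragments are substituents. Rules:

- *Cuttable bonds* (shipped as a config table of SMARTS):
  ring-atom-to-non-ring-atom bonds (substituent detachment), amide C–N
  and ester C(=O)–O bonds. Exhaustive cutting of every acyclic bond
  was rejected: it manufactures chemically meaningless "cores" (e.g.
  splitting an ethyl group) and lets accidental shared sub-cores split
  planted series.
- Substituents must be terminal (exactly one attachment point); a cut
  set that isolates a two-attachment linker piece is discarded.
- The core must have at least twice the heavy atoms of all
  substituents combined — a decomposition where the "substituents"
  dominate is not an analogue relationship.
- max_cuts defaults to 3 (substituents at one or multiple sites);
  the recovery guarantee needs max_cuts ≥ number of substitution
  sites.

Series formation: compounds sharing a byte-identical canonical core
(attachment points written as unlabeled `*`, so positions are encoded
structurally) form a series. Each compound joins at most one series by
the largest-core rule — among its decompositions whose core is shared
with another compound, the one with the most core heavy atoms wins.
Cores left with a single member after assignment are not series; those
compounds stay unassigned rather than being re-assigned to their
next-best core (a simple, deterministic one-pass rule).

Every decomposition is exactly reconstructable (`Chem.molzip` on the
isotope-labeled core and substituents reproduces the parent canonical
SMILES), which is tested as an invariant.

**Pair extraction.** Within one series, every (covalent, warhead-free)
member pair active on a shared kinase yields an analogue pair when
|Δp| ≥ log10(min_fold); min_fold defaults to 100 (2 log units). Δp is
signed (CPKI − PKI) but the threshold uses the absolute value: pairs
where the non-covalent analogue is the stronger binder are admitted
too. A CPKI matching several warheads contributes one pair record per
warhead.

## Statistics

- One-way ANOVA (scipy `f_oneway`; brute-force sum-of-squares oracle
  in the tests) for the global comparison of potency distributions;
  groups need n ≥ 2.
- Tukey–Kramer (scipy `tukey_hsd`) for post-hoc pairwise comparisons —
  the unequal-n variant is required because warhead subsets differ in
  size. The q statistic is reported as |mean diff| / SE with
  SE = sqrt(MSW/2·(1/ni + 1/nj)). Studentized-range p-values are
  numerical; agreement with the two-group ANOVA identity is asserted
  to 1e-4.
- Paired t-test: one-sample t of the pair deltas against zero,
  two-sided. All tests are two-sided. Constant deltas raise
  `zero_variance` rather than returning an infinite statistic.
- Quartiles use the linear-interpolation convention (numpy default).
- Global comparisons use each compound's mean pPotency per kinase,
  averaged over its kinases — one value per compound.

## Promiscuity

PD = number of distinct kinase accessions with curated activity;
bins PD 1, 2–4, 5–9, ≥ 10. Mutant annotations count separately only
when the accession differs. Reported proportions reflect the records
available: most inhibitors are annotated with one or two kinases, and
no correction for incomplete kinome coverage is attempted — the
summaries describe the data, not the (unknown) full activity matrix.

## Structure triage

Resolution must be strictly below 3.5 Å (matching the protocol's
wording "less than"); entries without a recorded resolution fail.
Ligands are non-polymer components excluding water and a configurable
list of ions/buffers/cryo-agents. "Large peptides" are polymer chains
other than the largest one with ≥ 4 residues (configurable; the
protocol gives no size). The keyword scan is a case-insensitive
substring match over title and keyword metadata. Covalent links come
from LINK/struct_conn records of covalent type joining a ligand atom
to a protein residue atom.

Binding-site letters (A–L) and ligand types (III, IV, V, VI,
activator, multi-site) are curated annotations read from the packaged
record tables; geometric site assignment and visual adjudication of
structures are explicitly not automated. gemmi parses both dialects;
for mmCIF files whose resolution gemmi does not surface on the
structure object, the `_refine.ls_d_res_high` /
`_reflns.d_resolution_high` tags are read directly.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
not real chemistry or kinome topology:

- Seven shipped kinase-inhibitor-like scaffolds (26–33 heavy atoms,
  bulked with ring decorations so that even the largest warhead moiety
  respects the core-size rule) with two attachment sites; analogues
  vary an R-group at site 1 and carry either a warhead moiety or a
  varied benign group at site 2. Varying the benign group prevents
  plain analogues from sharing an enlarged common core that would
  split the planted series.
- True pPotency per (series, kinase) ~ Normal(7, 1) truncated to
  [5, 11]; warhead members gain `planted_shift_log` (default 2.0, the
  potency gain the analysis is designed to detect). Per-record noise
  is Normal(0, 0.3) log units; measured values are clipped to the
  assay range (pPotency 5–12), so clean records always pass the 10 µM
  cut-off.
- Each compound is single-kinase with probability 0.725 (the planted
  PD 1 fraction); otherwise its PD is drawn from a small tail
  distribution over 2–12. Analogues of one series share a primary
  kinase so pairs exist.
- Replicate counts are drawn uniformly from 2–4 — typical of public
  activity data, where most compounds have a handful of measurements.
- With configured `violation_rates`, records are corrupted to violate
  one named curation filter, with ground truth recorded;
  `violation_showcase()` is the deterministic one-violator-per-filter
  batch.
- Structure fixtures: six minimal PDB/mmCIF files covering each triage
  filter branch (good entry with covalent LINK; resolution 3.6 Å; no
  ligand; peptide-only; keyword miss; mmCIF dialect pass), plus the
  packaged survey tables. Output is fully deterministic.

What passing tests on this generator shows: the pipeline recovers
planted structure (series, warheads, potency shift, PD fraction) under
realistic noise, and every filter fires exactly when designed to. What
it does not show: behavior on real assay heterogeneity (mixed units,
free-text comments, inconsistent target mapping), real scaffold
diversity, or tautomer/salt corner cases beyond those tested — the
generator's chemistry is deliberately regular.

### Measurement choices

The planted-shift recovery is measured on pairs extracted at a
log-threshold of 1.0 (min_fold = 10, half the planted shift). Selecting
pairs at the planted value itself (2.0) would truncate the noise
distribution at its center and bias the recovered mean upward by about
0.8 of a pair-delta standard deviation; thresholding at half the shift
keeps the pair set essentially complete, so the estimator is unbiased,
while the analysis default (min_fold = 100) is unchanged.

Problem sizes: recovery tests use 5 cores × 8 substituents (series)
and 7 × 10 (pairs, ≥ 50 of them); the single-kinase-fraction check
uses ~1000 distinct compounds (the combinatorial space of the shipped
building blocks), which puts the binomial 95% CI at about ±2.8
percentage points; the ANOVA null calibration uses 1000 replicates of
two n = 30 groups.

## Known limitations

- SMARTS warhead definitions are approximations of depicted
  structures; genuinely ambiguous classes (heterocyclic urea,
  activated ester) are conservative and user-overridable.
- The largest-core rule is greedy and single-pass; pathological
  libraries could leave compounds unassigned that a global optimizer
  would group.
- Structure parsing trusts the file's own metadata (resolution,
  title/keywords); no validation against external databases.
- The curation comment filter is substring-based; it does not parse
  structured ChEMBL validity flags beyond the documented phrases.
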