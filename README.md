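# covkin

Analysis toolkit for **covalent** and **allosteric protein kinase
inhibitors** (CPKIs / APKIs), for computational chemists working with
public bioactivity data (ChEMBL/BindingDB-style activity tables) and
kinase X-ray structures.

Protein kinase inhibitors that carry an electrophilic *warhead*
(acrylamide, vinyl sulfone, cyanoacrylamide, ...) can bond covalently
to nucleophilic residues — mostly free cysteines — and are of growing
interest in kinase drug discovery, as are allosteric inhibitors that
bind outside the ATP pocket. `covkin` implements the full data-analysis
chain needed to characterize such compounds:

- **Standardization** — input SMILES are reduced to a unique canonical
  form (largest organic fragment, neutralized, stereochemistry and
  isotopes stripped) so compounds can be matched across databases.
- **Curation** — activity records are filtered through a fixed
  high-confidence cascade (relation "=", direct binding assays, Ki/Kd/IC50
  ≤ 10,000 nM, single-kinase assays, ChEMBL confidence score 9, flagged
  comments removed) and aggregated per compound–kinase pair as
  pPotency = −log10(molar potency), averaging replicates on the log
  scale with Ki/Kd prioritized over IC50 and a 1-log-unit replicate-SD
  limit.
- **Warhead detection** — a configurable library of 14 SMARTS patterns
  with a specificity rule (e.g. the acrylamide embedded inside a
  cyanoacrylamide is suppressed); compounds carrying only the two
  previously characterized warheads (acrylamide, heterocyclic urea) are
  detected but excluded from the covalent subsets.
- **Analogue series and pairs** — compounds are decomposed into
  core + substituents by retrosynthetic bond cutting; compounds sharing
  a byte-identical canonical core form a series, and covalent/
  non-covalent analogue pairs with ≥ 100-fold potency difference on the
  same kinase are extracted (Δp = pPotency(CPKI) − pPotency(PKI)).
- **Statistics** — one-way ANOVA with Tukey–Kramer post hoc for global
  potency-distribution comparison; paired t-tests for analogue-pair
  deltas; quartile summaries for boxplot-style reporting.
- **Promiscuity** — the promiscuity degree (PD) of each inhibitor is
  its number of distinct kinases with qualifying activity, binned as
  PD 1, 2–4, 5–9, ≥ 10.
- **Structure triage** — kinase X-ray entries (PDB/mmCIF) are screened
  by resolution (< 3.5 Å), presence of a qualifying small-molecule
  ligand, and a keyword scan ("allosteric", "activator", "covalent",
  "inhibit", "noncompetitive", "uncompetitive"); covalent
  ligand–protein links are read from the connectivity records.
  Packaged survey tables (ligand-type counts and the 13 structurally
  characterized covalent allosteric inhibitors) are aggregated into
  summary statistics.
- **Synthetic data** — a seeded generator produces compound libraries
  with planted analogue series, warheads, a planted 2-log-unit potency
  shift, a 72.5% single-kinase fraction, log-normal measurement noise
  and designed filter violations, so the whole pipeline is testable
  without any database download.

The core stages are sklearn-style transformers (`SmilesStandardizer`,
`ActivityCurator`, `WarheadDetector`, `AnalogueSeriesExtractor`,
`PromiscuityProfiler`, `StructureTriage`) and compose with sklearn
pipelines; plain functions wrap them for scripting.

## Worked example

```python
from covkin.synthetic import GeneratorConfig, generate_library, generate_activities
from covkin.pipeline import PipelineConfig, run_pipeline

cfg = GeneratorConfig(n_cores=5, substituents_per_core=8, seed=1)
library = generate_library(cfg)
records, _ = generate_activities(library, cfg)
summary = run_pipeline(records.drop(columns=["corrupted"]),
                       PipelineConfig(max_cuts=2, min_fold=100))
```

With this seed the run prints (via the summary dict):

```
records in: 393, kept: 393, compound-kinase pairs: 127
compounds: 40, covalent subsets: {'acrylate': 3, 'aldehyde': 3, 'cyanamide': 3,
  'cyanoacrylamide': 3, 'reactive_ester': 3, 'terminal_alkyne': 3, 'vinyl_sulfone': 2}
analogue series: 5 (sizes [8, 8, 8, 8, 8]), pairs at >=100-fold: 46
  acrylate: n=4 mean delta=2.11 p=2.83e-06
  aldehyde: n=8 mean delta=2.14 p=8.82e-10
  ...
ANOVA F=10.4 p=9.34e-07
PD1 proportion (non-covalent): 0.800
```

393 simulated measurements curate into 127 compound–kinase potencies
over 40 compounds; the five planted analogue series are recovered
exactly; each warhead subset's analogue pairs show the planted
~2-log-unit potency gain with paired-t p-values far below 1e-5; and the
global ANOVA separates covalent from non-covalent potency
distributions.

The same stages are available from the shell:

```bash
covkin simulate --out-dir sim --seed 1
covkin run-all --input sim/activities.csv --out-dir results \
       --structures-dir sim/structures
```

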