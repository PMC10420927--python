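"""End-to-end analysis pipeline.

Chains the stages standardize -> curate -> warheads -> series -> pairs
-> stats -> promiscuity (plus structure triage when structure files are
given), writing per-stage tables and a JSON summary.  Record counts are
conserved and asserted at every stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import curation, promiscuity, series as series_mod, stats, triage, warheads

log = logging.getLogger("covkin")


@dataclass
class PipelineConfig:
    """All thresholds of the pipeline, at their standard defaults."""

    potency_cutoff_nM: float = 10_000.0
    sd_limit_log: float = 1.0
    required_confidence: int = 9
    warhead_config: str | None = None
    min_fold: float = 100.0
    max_cuts: int = 3
    resolution_max: float = 3.5
    peptide_min_residues: int = 4
    keywords: tuple = triage.DEFAULT_KEYWORDS
    seed: int = 0


def run_pipeline(
    records: pd.DataFrame,
    config: PipelineConfig | None = None,
    structure_paths=None,
    out_dir: str | None = None,
) -> dict:
    """Run the full analysis on a raw activity table.

    Returns the summary dict; when ``out_dir`` is given, per-stage TSVs
    and ``summary.json`` are written there.
    """
    config = config or PipelineConfig()
    out = Path(out_dir) if out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": {}}

    cur_cfg = curation.CurationConfig(
        potency_cutoff_nM=config.potency_cutoff_nM,
        sd_limit_log=config.sd_limit_log,
        required_confidence=config.required_confidence,
    )
    curated, report = curation.curate(records, cur_cfg)
    n_rejected = sum(report.rejected.values())
    assert report.n_kept_records + n_rejected == report.n_input, "record conservation"
    log.info("curation: %d records in, %d kept, %d rejected",
             report.n_input, report.n_kept_records, n_rejected)
    summary["stages"]["curation"] = report.to_dict()

    library = warheads.load_warhead_library(config.warhead_config)
    compounds = sorted(curated["standard_smiles"].unique())
    assignments = [warheads.detect_warheads(s, library) for s in compounds]
    subsets, noncovalent, excluded = warheads.partition_by_warhead(assignments)
    n_in_subsets = len(set().union(*subsets.values())) if subsets else 0
    assert n_in_subsets + len(noncovalent) + len(excluded) == len(compounds), \
        "warhead partition conservation"
    summary["stages"]["warheads"] = {
        "n_compounds": len(compounds),
        "subset_sizes": {k: len(v) for k, v in sorted(subsets.items())},
        "n_noncovalent": len(noncovalent),
        "n_excluded_prior": len(excluded),
    }

    series = series_mod.build_series(compounds, max_cuts=config.max_cuts)
    pairs = series_mod.extract_pairs(series, curated, assignments, min_fold=config.min_fold)
    summary["stages"]["series"] = {
        "n_series": len(series),
        "series_sizes": sorted((len(s.members) for s in series), reverse=True),
        "n_pairs": len(pairs),
    }

    # global potency comparison: non-covalent vs each warhead subset
    potency_by_compound = curated.groupby("standard_smiles")["pPotency"].mean()
    groups, names = [], []
    nc = potency_by_compound.reindex(sorted(noncovalent)).dropna()
    if len(nc) >= 2:
        groups.append(nc.to_numpy())
        names.append("noncovalent")
    for name, members in sorted(subsets.items()):
        vals = potency_by_compound.reindex(sorted(members)).dropna()
        if len(vals) >= 2:
            groups.append(vals.to_numpy())
            names.append(name)
    if len(groups) >= 2:
        comp = stats.compare_groups(groups, names=names)
        summary["stages"]["potency"] = {
            "group_names": comp.group_names,
            "group_sizes": comp.group_sizes,
            "medians": comp.medians,
            "F_statistic": comp.F_statistic,
            "p_value": comp.p_value,
            "tukey": [
                {
                    "pair": [t.group_i, t.group_j],
                    "mean_diff": t.mean_diff,
                    "adjusted_p": t.adjusted_p,
                    "significant": t.significant,
                }
                for t in comp.tukey
            ],
        }

    # local analogue-pair tests per warhead
    pair_tests = {}
    by_warhead: dict[str, list] = {}
    for p in pairs:
        by_warhead.setdefault(p.warhead, []).append(p.delta_p)
    for name, deltas in sorted(by_warhead.items()):
        if len(deltas) >= 2 and np.ptp(deltas) > 0:
            t = stats.paired_t_test(deltas, warhead=name)
            pair_tests[name] = {
                "n_pairs": t.n_pairs,
                "mean_delta": t.mean_delta,
                "t_statistic": t.t_statistic,
                "p_value": t.p_value,
            }
    summary["stages"]["pair_tests"] = pair_tests

    profiles = promiscuity.compute_pd(curated)
    pd_tables = {}
    def _dist(subset, label):
        try:
            dist = promiscuity.pd_distribution(profiles, subset)
        except ValueError:
            return
        pd_tables[label] = {
            "counts": dist["count"].to_dict(),
            "proportions": dist["proportion"].to_dict(),
        }
    _dist(noncovalent, "noncovalent")
    for name, members in sorted(subsets.items()):
        _dist(members, name)
    summary["stages"]["promiscuity"] = pd_tables

    if structure_paths:
        tri = triage.StructureTriage(
            keywords=config.keywords,
            resolution_max=config.resolution_max,
            peptide_min_residues=config.peptide_min_residues,
        )
        frame = tri.transform(sorted(str(p) for p in structure_paths))
        summary["stages"]["triage"] = frame.to_dict("records")
        if out is not None:
            frame.to_csv(out / "triage.tsv", sep="\t", index=False)

    summary["ligand_type_summary"] = triage.summarize_ligand_types(
        triage.load_ligand_type_table()
    )
    summary["covalent_apki_summary"] = triage.summarize_ligand_records(
        triage.load_covalent_records()
    )

    if out is not None:
        curated.to_csv(out / "curated.tsv", sep="\t", index=False)
        series_mod.pairs_to_frame(pairs).to_csv(out / "pairs.tsv", sep="\t", index=False)
        pd.DataFrame(
            {
                "standard_smiles": [p.standard_smiles for p in profiles],
                "pd": [p.pd for p in profiles],
                "bin": [p.bin for p in profiles],
            }
        ).to_csv(out / "promiscuity.tsv", sep="\t", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
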