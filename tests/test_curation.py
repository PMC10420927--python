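import math

import numpy as np
import pandas as pd
import pytest

from covkin.curation import (
    CurationConfig,
    aggregate_measurements,
    curate,
    filter_record,
    to_pPotency,
)
from covkin.standardize import standardize_smiles
from covkin.synthetic import GeneratorConfig, generate_activities, generate_library


@pytest.mark.parametrize("nm,expected", [(10_000, 5.0), (1, 9.0), (100, 7.0), (0.1, 10.0)])
def test_to_ppotency(nm, expected):
    assert to_pPotency(nm) == pytest.approx(expected)


@pytest.mark.parametrize("bad", [0, -1, float("nan")])
def test_to_ppotency_rejects_nonpositive(bad):
    with pytest.raises(ValueError, match="nonpositive_potency"):
        to_pPotency(bad)


BASE = {
    "compound_smiles": "Cc1ccccc1",
    "target_id": "P00533",
    "measurement_type": "IC50",
    "relation": "=",
    "value_nM": 100.0,
    "relationship_type": "D",
    "assay_confidence": 9,
    "assay_kinase_count": 1,
    "activity_comment": "",
    "source": "chembl",
}


@pytest.mark.parametrize(
    "patch,reason",
    [
        ({"relation": ">"}, "relation"),
        ({"value_nM": 20_000.0}, "potency_cutoff"),
        ({"assay_confidence": 8}, "assay_confidence"),
        ({"relationship_type": "B"}, "relationship_type"),
        ({"measurement_type": "EC50"}, "measurement_type"),
        ({"assay_kinase_count": 2}, "assay_kinase_count"),
        ({"activity_comment": "potential transcription error"}, "comment"),
        ({"activity_comment": "Outside Typical Range"}, "comment"),
        ({"activity_comment": "active but also inactive"}, "comment"),
        ({"units": "uM"}, "units"),
        ({"compound_smiles": ""}, "malformed_record"),
    ],
)
def test_single_violation_reason(patch, reason):
    keep, r = filter_record({**BASE, **patch})
    assert not keep and r == reason


def test_clean_record_kept_and_boundary_value():
    assert filter_record(BASE) == (True, "")
    # 10,000 nM is "lower than or equal to": kept
    assert filter_record({**BASE, "value_nM": 10_000.0})[0]


def test_first_failed_filter_names_reason():
    # relation precedes assay_confidence in the cascade
    keep, reason = filter_record({**BASE, "relation": ">", "assay_confidence": 8})
    assert reason == "relation"


def test_bindingdb_skips_chembl_only_filters():
    rec = {**BASE, "source": "bindingdb", "relationship_type": "", "assay_confidence": None}
    assert filter_record(rec) == (True, "")


def _recs(values, mtypes=None):
    mtypes = mtypes or ["IC50"] * len(values)
    return [
        {**BASE, "standard_smiles": "Cc1ccccc1", "value_nM": v, "measurement_type": m}
        for v, m in zip(values, mtypes)
    ]


def test_aggregate_mean_and_sd_in_log_space():
    agg = aggregate_measurements(_recs([100.0, 1000.0]))
    assert agg.pPotency == pytest.approx(6.5)
    assert agg.sd_log == pytest.approx(0.70710678, abs=1e-6)
    assert agg.measurement_class == "IC50"
    assert agg.n_measurements == 2


def test_aggregate_kikd_priority():
    agg = aggregate_measurements(_recs([50.0, 10.0], ["Ki", "IC50"]))
    assert agg.measurement_class == "KiKd"
    assert agg.pPotency == pytest.approx(to_pPotency(50.0))
    assert agg.n_measurements == 1


def test_aggregate_drops_inconsistent_replicates():
    # pPotencies 8.0 and 5.0: sample sd ~2.12 >= 1 log unit
    assert aggregate_measurements(_recs([10.0, 10_000.0])) is None


def test_aggregate_duplicates_and_singletons():
    double = aggregate_measurements(_recs([100.0, 100.0]))
    single = aggregate_measurements(_recs([100.0]))
    assert double.pPotency == single.pPotency
    assert double.sd_log == 0.0 == single.sd_log


def test_aggregate_empty_errors():
    with pytest.raises(ValueError, match="no_records"):
        aggregate_measurements([])


def test_curate_empty_input():
    curated, report = curate([])
    assert curated.empty
    assert report.n_input == 0 and not report.rejected


def test_curate_groups_duplicate_rows():
    curated, report = curate([dict(BASE), dict(BASE)])
    assert len(curated) == 1
    assert curated.n_measurements.iloc[0] == 2
    assert report.n_kept_records == 2


def test_curate_merges_sources_on_standard_smiles():
    """The same molecule as salt (bindingdb) and free base (chembl) is one pair."""
    r1 = {**BASE, "compound_smiles": "Cc1ccccc1"}
    r2 = {
        **BASE,
        "compound_smiles": "Cc1ccccc1.Cl",
        "source": "bindingdb",
        "relationship_type": "",
        "assay_confidence": None,
    }
    curated, _ = curate([r1, r2])
    assert len(curated) == 1
    assert curated.n_measurements.iloc[0] == 2


def _brute_force_curate(records, config=None):
    """Independent reimplementation: plain loops, recomputed from scratch."""
    config = config or CurationConfig()
    kept = []
    for rec in records:
        keep, _ = filter_record(rec, config)
        if not keep:
            continue
        std = standardize_smiles(str(rec["compound_smiles"]))
        if not std.valid:
            continue
        kept.append((std.standard_smiles, str(rec["target_id"]), rec))
    keys = sorted({(s, t) for s, t, _ in kept})
    out = {}
    for s, t in keys:
        grp = [r for (s2, t2, r) in kept if (s2, t2) == (s, t)]
        kikd = [r for r in grp if r["measurement_type"] in ("Ki", "Kd")]
        used = kikd or grp
        ps = [to_pPotency(float(r["value_nM"])) for r in used]
        mean = sum(ps) / len(ps)
        sd = (
            math.sqrt(sum((p - mean) ** 2 for p in ps) / (len(ps) - 1))
            if len(ps) > 1
            else 0.0
        )
        if sd < config.sd_limit_log:
            out[(s, t)] = (mean, "KiKd" if kikd else "IC50", len(used), sd)
    return out


@pytest.mark.parametrize("seed", [0, 1])
def test_curate_matches_brute_force_oracle(seed):
    cfg = GeneratorConfig(
        n_cores=3,
        substituents_per_core=6,
        seed=seed,
        violation_rates={k: 0.1 for k in ("relation", "potency_cutoff", "comment")},
    )
    records, _ = generate_activities(generate_library(cfg), cfg)
    records = records.drop(columns=["corrupted"])
    assert len(records) <= 200
    curated, report = curate(records)
    oracle = _brute_force_curate(records.to_dict("records"))
    got = {
        (r.standard_smiles, r.target_id): (r.pPotency, r.measurement_class, r.n_measurements, r.sd_log)
        for r in curated.itertuples(index=False)
    }
    assert set(got) == set(oracle)
    for key in oracle:
        assert got[key][0] == pytest.approx(oracle[key][0])
        assert got[key][1:3] == oracle[key][1:3]
        assert got[key][3] == pytest.approx(oracle[key][3])


@pytest.mark.parametrize("seed", [2, 3, 4])
def test_conservation_kept_plus_rejected_equals_input(seed):
    cfg = GeneratorConfig(
        n_cores=3,
        substituents_per_core=6,
        seed=seed,
        violation_rates={
            k: 0.08
            for k in (
                "relation",
                "relationship_type",
                "potency_cutoff",
                "measurement_type",
                "assay_kinase_count",
                "assay_confidence",
                "comment",
            )
        },
    )
    records, _ = generate_activities(generate_library(cfg), cfg)
    curated, report = curate(records.drop(columns=["corrupted"]))
    assert report.n_kept_records + sum(report.rejected.values()) == report.n_input
    assert (records["corrupted"] != "").sum() <= sum(report.rejected.values())
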