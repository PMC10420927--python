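import itertools
import math

import pandas as pd
import pytest
from rdkit import Chem

from covkin.series import (
    AnalogueSeriesExtractor,
    build_series,
    extract_pairs,
    fragment_compound,
    pairs_to_frame,
    reconstruct,
)
from covkin.warheads import detect_warheads


def canon(s):
    return Chem.MolToSmiles(Chem.MolFromSmiles(s))


def test_single_substituent_one_decomposition():
    decomps = fragment_compound("Cc1ccccc1", max_cuts=1)
    assert len(decomps) == 1
    assert decomps[0].substituents == ("[1*]C",)


def test_unsubstituted_ring_yields_nothing():
    assert fragment_compound("c1ccccc1", max_cuts=1) == []


def test_disubstituted_enumerates_cut_subsets():
    # cut at site 1, site 2, or both
    assert len(fragment_compound("Cc1ccc(CC)cc1", max_cuts=2)) == 3


def test_acyclic_molecule_yields_nothing():
    assert fragment_compound("CCCCCC", max_cuts=2) == []


def test_reconstruction_exact(small_dataset):
    _, library, _, _ = small_dataset
    for smi in library["standard_smiles"].head(12):
        for d in fragment_compound(smi, max_cuts=2):
            assert reconstruct(d) == canon(smi)


def test_core_dominates_substituents():
    for d in fragment_compound("Cc1ccc(CC)cc1", max_cuts=2):
        sub_heavy = sum(
            sum(1 for a in Chem.MolFromSmiles(s).GetAtoms() if a.GetAtomicNum() > 1)
            for s in d.substituents
        )
        assert d.core_heavy_atoms >= 2 * sub_heavy


def test_planted_single_series_recovered():
    analogues = [canon(f"{r}c1ccc2ncncc2c1") for r in ["C", "CC", "OC", "FC(F)(F)", "N"]]
    series = build_series(analogues, max_cuts=2)
    assert len(series) == 1
    assert len(series[0].members) == 5


def test_two_scaffolds_two_series():
    a = [canon(f"{r}c1ccc2ncncc2c1") for r in ["C", "CC", "OC"]]
    b = [canon(f"{r}c1ccc2[nH]ccc2c1") for r in ["C", "CC", "OC"]]
    series = build_series(a + b, max_cuts=2)
    assert sorted(len(s.members) for s in series) == [3, 3]


def test_all_distinct_scaffolds_no_series():
    compounds = [canon(s) for s in ["Cc1ccccc1", "CC1CCCCC1", "Cc1ccncc1"]]
    assert build_series(compounds, max_cuts=1) == []


def test_full_library_recovery(small_dataset):
    cfg, library, _, _ = small_dataset
    series = build_series(sorted(library["standard_smiles"]), max_cuts=2)
    assert sorted(len(s.members) for s in series) == [8] * 5
    # recovered groups coincide with the generator's ground truth
    truth = {}
    for row in library.itertuples(index=False):
        truth.setdefault(row.series_id, set()).add(row.standard_smiles)
    recovered = {frozenset(s.members) for s in series}
    assert recovered == {frozenset(v) for v in truth.values()}


def _curated_frame(rows):
    return pd.DataFrame(rows, columns=["standard_smiles", "target_id", "pPotency"])


def _series_of(compounds):
    return build_series([canon(c) for c in compounds], max_cuts=2)


def test_pair_extraction_threshold_and_sign(warhead_library):
    cpki = canon("C=CC(=O)Oc1ccc2ncncc2c1")  # acrylate analogue
    pki = canon("Cc1ccc2ncncc2c1")
    series = _series_of([cpki, pki])
    assert len(series) == 1
    assignments = [detect_warheads(s, warhead_library) for s in (cpki, pki)]
    curated = _curated_frame(
        [(cpki, "P1", 8.5), (pki, "P1", 6.0)]
    )
    pairs = extract_pairs(series, curated, assignments, min_fold=100)
    assert len(pairs) == 1
    assert pairs[0].delta_p == pytest.approx(2.5)
    assert pairs[0].warhead == "acrylate"
    # below the 100-fold threshold: no pair
    curated2 = _curated_frame([(cpki, "P1", 8.5), (pki, "P1", 7.0)])
    assert extract_pairs(series, curated2, assignments, min_fold=100) == []
    # threshold equals log10(min_fold)
    assert math.log10(100) == 2.0


def test_pair_requires_shared_target(warhead_library):
    cpki = canon("C=CC(=O)Oc1ccc2ncncc2c1")
    pki = canon("Cc1ccc2ncncc2c1")
    series = _series_of([cpki, pki])
    assignments = [detect_warheads(s, warhead_library) for s in (cpki, pki)]
    curated = _curated_frame([(cpki, "P1", 9.0), (pki, "P2", 5.0)])
    assert extract_pairs(series, curated, assignments, min_fold=100) == []


def _brute_force_pairs(series, curated, assignments, min_fold):
    """Oracle: plain double loop over all compound pairs x targets."""
    threshold = math.log10(min_fold)
    amap = {a.standard_smiles: a for a in assignments}
    pot = {}
    for r in curated.itertuples(index=False):
        pot.setdefault(r.standard_smiles, {})[r.target_id] = r.pPotency
    sid = {}
    for s in series:
        for m in s.members:
            sid[m] = s.series_id
    out = set()
    for c, p in itertools.product(sid, sid):
        if c == p or sid[c] != sid[p]:
            continue
        if not (c in amap and amap[c].is_cpki):
            continue
        if not (p in amap and not amap[p].matched):
            continue
        for t in set(pot.get(c, {})) & set(pot.get(p, {})):
            d = pot[c][t] - pot[p][t]
            if abs(d) >= threshold:
                from covkin.warheads import NEW_WARHEADS

                for wh in amap[c].matched & NEW_WARHEADS:
                    out.add((c, p, t, wh, round(d, 9)))
    return out


@pytest.mark.parametrize("min_fold", [10.0, 100.0])
def test_extract_pairs_equals_brute_force_oracle(small_dataset, warhead_library, min_fold):
    from covkin.curation import curate

    _, library, records, _ = small_dataset
    assert len(library) <= 50
    curated, _ = curate(records.drop(columns=["corrupted"]))
    assignments = [detect_warheads(s, warhead_library) for s in curated["standard_smiles"].unique()]
    series = build_series(sorted(library["standard_smiles"]), max_cuts=2)
    pairs = extract_pairs(series, curated, assignments, min_fold=min_fold)
    got = {(p.cpki_smiles, p.pki_smiles, p.target_id, p.warhead, round(p.delta_p, 9)) for p in pairs}
    assert got == _brute_force_pairs(series, curated, assignments, min_fold)


def test_extractor_transform_labels(small_dataset):
    _, library, _, _ = small_dataset
    ext = AnalogueSeriesExtractor(max_cuts=2)
    frame = ext.fit_transform(library["standard_smiles"])
    assert (frame["series_id"] != "").all()
    assert frame.groupby("series_id").size().tolist() == [8] * 5


def test_min_fold_validation(warhead_library):
    with pytest.raises(ValueError):
        extract_pairs([], _curated_frame([]), [], min_fold=1.0)
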