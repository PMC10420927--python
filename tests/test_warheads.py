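import pytest
import yaml
from rdkit import Chem

from covkin.warheads import (
    NEW_WARHEADS,
    PRIOR_WARHEADS,
    WarheadAssignment,
    WarheadDetector,
    detect_warheads,
    load_warhead_library,
    partition_by_warhead,
)

from golden_warheads import GOLDEN


def test_default_library_has_14_valid_patterns(warhead_library):
    assert len(warhead_library) == 14
    assert {p.name for p in warhead_library} == NEW_WARHEADS | PRIOR_WARHEADS
    assert all(p.mol is not None for p in warhead_library)


def test_config_override_replaces_one_pattern(tmp_path, warhead_library):
    cfg = tmp_path / "wh.yaml"
    cfg.write_text(yaml.safe_dump({"aldehyde": {"smarts": "[CX3H1]=O"}}))
    lib = load_warhead_library(str(cfg))
    assert len(lib) == 14
    assert next(p for p in lib if p.name == "aldehyde").smarts == "[CX3H1]=O"


def test_config_with_invalid_pattern_errors(tmp_path):
    cfg = tmp_path / "wh.yaml"
    cfg.write_text(yaml.safe_dump({"aldehyde": {"smarts": "C((("}}))
    with pytest.raises(ValueError, match="aldehyde"):
        load_warhead_library(str(cfg))


@pytest.mark.parametrize("warhead", sorted(GOLDEN))
def test_golden_positives_and_near_miss_negatives(warhead, warhead_library):
    positives, negatives = GOLDEN[warhead]
    assert len(positives) >= 2 and len(negatives) >= 2
    for smi in positives:
        assert warhead in detect_warheads(smi, warhead_library).matched, smi
    for smi in negatives:
        assert warhead not in detect_warheads(smi, warhead_library).matched, smi


@pytest.mark.parametrize(
    "smiles,expected",
    [
        ("N#CC(=CC)C(N)=O", {"cyanoacrylamide"}),  # nested acrylamide suppressed
        ("C=CC(=O)Oc1ccc([N+](=O)[O-])cc1", {"acrylate"}),  # nested activated ester
        ("C#CCOC(=O)c1ccccc1", {"alkynyl_benzoate"}),  # nested terminal alkyne
        ("C=CS(=O)(=O)c1ccccc1", {"vinyl_sulfone"}),
        ("CCO", set()),
    ],
)
def test_specificity_suppression(smiles, expected, warhead_library):
    assert set(detect_warheads(smiles, warhead_library).matched) == expected


def test_prior_warheads_routed_to_excluded(warhead_library):
    a = detect_warheads("C=CC(=O)Nc1ccccc1", warhead_library)
    assert a.matched == {"acrylamide"}
    assert a.excluded_prior and not a.is_cpki
    # a prior warhead alongside an analyzed one does not exclude
    b = detect_warheads("C=CC(=O)Nc1ccc(C=O)cc1", warhead_library)
    assert {"acrylamide", "aldehyde"} <= set(b.matched)
    assert b.is_cpki and not b.excluded_prior


def test_detection_invariant_to_atom_numbering(warhead_library):
    smi = "C=CS(=O)(=O)c1ccc(C#C)cc1"
    mol = Chem.MolFromSmiles(smi)
    order = list(range(mol.GetNumAtoms()))[::-1]
    permuted = Chem.MolToSmiles(Chem.RenumberAtoms(mol, order), canonical=False)
    assert (
        detect_warheads(permuted, warhead_library).matched
        == detect_warheads(smi, warhead_library).matched
    )


def test_invalid_smiles_errors(warhead_library):
    with pytest.raises(ValueError, match="parse_error"):
        detect_warheads("((((", warhead_library)


def _assignment(smi, matched):
    matched = frozenset(matched)
    excl = bool(matched) and matched <= PRIOR_WARHEADS
    return WarheadAssignment(smi, matched, bool(matched & NEW_WARHEADS) and not excl, excl)


def test_partition_overlap_and_exclusion():
    assignments = [
        _assignment("A", {"aldehyde", "vinyl_sulfone"}),
        _assignment("B", set()),
        _assignment("C", {"acrylamide"}),
    ]
    subsets, noncovalent, excluded = partition_by_warhead(assignments)
    assert subsets["aldehyde"] == {"A"} and subsets["vinyl_sulfone"] == {"A"}
    assert noncovalent == {"B"}
    assert excluded == {"C"}


def test_partition_empty():
    assert partition_by_warhead([]) == ({}, set(), set())


def test_partition_subset_discipline_fixture():
    """7 single-warhead compounds + 3 clean: 7 subsets of 1, 3 non-covalent."""
    warheads = sorted(NEW_WARHEADS)[:7]
    assignments = [_assignment(f"W{i}", {w}) for i, w in enumerate(warheads)]
    assignments += [_assignment(f"N{i}", set()) for i in range(3)]
    subsets, noncovalent, excluded = partition_by_warhead(assignments)
    assert len(subsets) == 7 and all(len(v) == 1 for v in subsets.values())
    assert len(noncovalent) == 3 and not excluded
    covered = set().union(*subsets.values()) | noncovalent | excluded
    assert len(covered) == len(assignments)


def test_detector_transform_matches_ground_truth(small_dataset, warhead_library):
    _, library, _, _ = small_dataset
    frame = WarheadDetector().fit_transform(library["standard_smiles"])
    for got, row in zip(frame.itertuples(index=False), library.itertuples(index=False)):
        expected = row.warhead if row.warhead else ""
        assert got.matched == expected
        assert got.is_cpki == bool(expected)
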