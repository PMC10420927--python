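"""Synthetic activity tables and structure fixtures.

Generates a compound library with planted analogue series and warheads,
multi-source activity records with log-normal measurement noise, and
tiny structure files exercising every triage filter branch, so the full
pipeline is testable without any database download.  The generator's
defaults emulate the statistical features the analysis assumes: a
potency gain of two log units planted on warhead-bearing analogues, a
72.5% single-kinase fraction, replicate noise of 0.3 log units, and
optional records corrupted to violate each curation filter.

All randomness flows from one integer seed; same seed, same output.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

#: Kinase-inhibitor-like scaffold cores with two attachment points.
#: Site 1 carries the varying R-group, site 2 the warhead (or a benign
#: group).  Ring decorations (morpholine, pyridine, piperazine) bulk the
#: cores up to realistic inhibitor size without adding cuttable bonds.
CORE_SMILES = (
    "[*:1]c1ccc(Nc2ncnc3cc(N4CCOCC4)c([*:2])cc23)cc1-c1ccc2ncccc2c1",
    "[*:1]c1cc2[nH]c(-c3ccc(-c4ccc5ncccc5c4)c([*:2])c3)nc2cc1N1CCN(C)CC1",
    "[*:1]c1ccc(-c2nc3ccc(N4CCN(c5ccncc5)CC4)cc3o2)c(N2CCN(C)CC2)c1[*:2]",
    "[*:1]c1cnc(Nc2ccc([*:2])c(-c3ccc4ncccc4c3)n2)nc1-c1ccc(N2CCOCC2)cc1",
    "[*:1]c1ccc(S(=O)(=O)Nc2ccc([*:2])c(N3CCNCC3)c2)cc1-c1ccc2ncccc2c1",
    "[*:1]c1ccc(Oc2ncnc3[nH]cc(-c4ccc(N5CCN(c6ccncc6)CC5)cc4)c23)cc1[*:2]",
    "[*:1]c1ccc(-c2csc(Nc3ccc([*:2])c(N4CCOCC4)c3)n2)cc1-c1ccc2ncccc2c1",
)

#: R-groups for site 1 (distinct per analogue within a series; the
#: small ones come first so warhead-bearing members stay within the
#: core-size rule even with bulky warheads).
R_GROUPS = (
    "[*:1]C",
    "[*:1]F",
    "[*:1]Cl",
    "[*:1]N",
    "[*:1]O",
    "[*:1]OC",
    "[*:1]CC",
    "[*:1]CO",
    "[*:1]C(C)C",
    "[*:1]N(C)C",
    "[*:1]OCC",
    "[*:1]CF",
)

#: Warhead moieties attachable at site 2.
WARHEAD_MOIETIES = {
    "aldehyde": "[*:2]C=O",
    "terminal_alkyne": "[*:2]C#C",
    "acrylate": "[*:2]OC(=O)C=C",
    "cyanamide": "[*:2]N(C)C#N",
    "cyanoacrylamide": "[*:2]NC(=O)C(=C)C#N",
    "vinyl_sulfone": "[*:2]S(=O)(=O)C=C",
    "reactive_ester": "[*:2]C(=O)Oc1ccc([N+](=O)[O-])cc1",
}

#: Benign site-2 moieties for non-covalent analogues.  Varied so that
#: plain members do not share an enlarged common core that would split
#: the planted series under the largest-core rule.
PLAIN_SITE2_GROUPS = (
    "[*:2]C",
    "[*:2]CC",
    "[*:2]OC",
    "[*:2]N",
    "[*:2]F",
    "[*:2]Cl",
    "[*:2]O",
    "[*:2]CO",
    "[*:2]N(C)C",
    "[*:2]OCC",
    "[*:2]C(C)C",
    "[*:2]CF",
)


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic generator."""

    n_cores: int = 5
    substituents_per_core: int = 8
    warhead_fraction: float = 0.5
    warhead_names: tuple = tuple(sorted(WARHEAD_MOIETIES))
    planted_shift_log: float = 2.0
    noise_sd_log: float = 0.3
    single_target_fraction: float = 0.725
    pd_tail: tuple = (2, 3, 4, 5, 6, 7, 9, 10, 12)
    n_targets: int = 40
    n_replicates_range: tuple = (2, 4)
    violation_rates: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        for f in (self.warhead_fraction, self.single_target_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.planted_shift_log < 0:
            raise ValueError("planted_shift_log must be >= 0")


def _attach(core: str, r1: str, r2: str) -> str | None:
    mol = Chem.MolFromSmiles(core)
    for frag in (r1, r2):
        mol = Chem.CombineMols(mol, Chem.MolFromSmiles(frag))
    try:
        out = Chem.molzip(mol)
        Chem.SanitizeMol(out)
        return Chem.MolToSmiles(out)
    except Exception:
        return None


def generate_library(config: GeneratorConfig) -> pd.DataFrame:
    """Build the labeled compound library.

    Returns a frame with columns standard_smiles, series_id, warhead
    ("" for non-covalent members).  Analogues of one core vary the R
    group at site 1; a ``warhead_fraction`` of members carry a warhead
    moiety at site 2 (cycling through ``warhead_names``), the rest a
    methyl.  Attachment chemistry that fails sanitization is skipped.
    """
    rows = []
    n_warhead = round(config.substituents_per_core * config.warhead_fraction)
    wh_cycle = [w for w in config.warhead_names if w in WARHEAD_MOIETIES]
    if config.warhead_fraction > 0 and not wh_cycle:
        raise ValueError("no usable warhead names")
    wi = 0
    for ci in range(config.n_cores):
        core = CORE_SMILES[ci % len(CORE_SMILES)]
        for si in range(config.substituents_per_core):
            # global analogue index so repeated scaffolds still yield
            # distinct substituent combinations
            idx = ci * config.substituents_per_core + si
            r1 = R_GROUPS[idx % len(R_GROUPS)]
            if si < n_warhead:
                warhead = wh_cycle[wi % len(wh_cycle)]
                wi += 1
                r2 = WARHEAD_MOIETIES[warhead]
            else:
                warhead = ""
                # si keeps plain site-2 groups distinct within a series,
                # ci shifts them across repeated scaffolds
                r2 = PLAIN_SITE2_GROUPS[(si + ci) % len(PLAIN_SITE2_GROUPS)]
            smi = _attach(core, r1, r2)
            if smi is None:
                continue
            rows.append(
                {
                    "standard_smiles": smi,
                    "series_id": f"G{ci:03d}",
                    "warhead": warhead,
                }
            )
    frame = pd.DataFrame(rows)
    # scaffold/substituent collisions across repeated cores would alias
    # two planted compounds; keep the first occurrence only
    return frame.drop_duplicates(subset="standard_smiles", ignore_index=True)


def _truncated_normal(rng, mean, sd, low, high):
    while True:
        x = rng.normal(mean, sd)
        if low <= x <= high:
            return x


_CORRUPTIONS = {
    "relation": lambda r: r.update(relation=">"),
    "relationship_type": lambda r: r.update(relationship_type="B", source="chembl"),
    "potency_cutoff": lambda r: r.update(value_nM=25_000.0),
    "measurement_type": lambda r: r.update(measurement_type="EC50"),
    "assay_kinase_count": lambda r: r.update(assay_kinase_count=3),
    "assay_confidence": lambda r: r.update(assay_confidence=8, source="chembl"),
    "comment": lambda r: r.update(activity_comment="potency uncertain"),
}


def generate_activities(
    library: pd.DataFrame, config: GeneratorConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate activity records for a labeled library.

    Every compound gets one kinase with probability
    ``single_target_fraction`` (else a promiscuity degree drawn from
    ``pd_tail``); its series' primary kinase is always included so that
    analogues share a target.  The true pPotency per (series, kinase) is
    Normal(7, 1) truncated to [5, 11]; warhead members gain
    ``planted_shift_log``.  Each record adds Normal(0, noise_sd_log)
    measurement noise; measured values are clipped to the assay range
    (pPotency 5..12, i.e. at most 10 uM).  With the configured
    ``violation_rates``, records are corrupted to violate a named
    curation filter.

    Returns (records, truth) where ``truth`` holds one row per
    compound-kinase pair with the noise-free potency.
    """
    rng = np.random.default_rng(config.seed)
    base: dict[tuple[str, str], float] = {}
    records, truth = [], []
    lo, hi = config.n_replicates_range
    for row in library.itertuples(index=False):
        series = row.series_id
        primary = f"P{int(series[1:]) % config.n_targets:05d}"
        if rng.random() < config.single_target_fraction:
            targets = [primary]
        else:
            k = int(rng.choice(config.pd_tail))
            extra = rng.choice(config.n_targets, size=k - 1, replace=False)
            targets = sorted({primary} | {f"P{t:05d}" for t in extra})[: k]
            if primary not in targets:
                targets[0] = primary
        for target in targets:
            key = (series, target)
            if key not in base:
                base[key] = _truncated_normal(rng, 7.0, 1.0, 5.0, 11.0)
            p_true = base[key] + (config.planted_shift_log if row.warhead else 0.0)
            truth.append(
                {
                    "standard_smiles": row.standard_smiles,
                    "target_id": target,
                    "series_id": series,
                    "warhead": row.warhead,
                    "p_true": p_true,
                }
            )
            mtype = "IC50" if rng.random() < 0.7 else ("Ki" if rng.random() < 0.5 else "Kd")
            n_rep = int(rng.integers(lo, hi + 1))
            for _ in range(n_rep):
                p_obs = min(max(p_true + rng.normal(0.0, config.noise_sd_log), 5.0), 12.0)
                source = "chembl" if rng.random() < 0.6 else "bindingdb"
                rec = {
                    "compound_smiles": row.standard_smiles,
                    "target_id": target,
                    "measurement_type": mtype,
                    "relation": "=",
                    "value_nM": 10.0 ** (9.0 - p_obs),
                    "relationship_type": "D" if source == "chembl" else "",
                    "assay_confidence": 9 if source == "chembl" else None,
                    "assay_kinase_count": 1,
                    "activity_comment": "",
                    "source": source,
                    "corrupted": "",
                }
                for name, rate in sorted(config.violation_rates.items()):
                    if name in _CORRUPTIONS and rng.random() < rate:
                        _CORRUPTIONS[name](rec)
                        rec["corrupted"] = name
                        break
                records.append(rec)
    return pd.DataFrame(records), pd.DataFrame(truth)


def violation_showcase() -> pd.DataFrame:
    """Deterministic batch with exactly one violator per rejection reason.

    Used to verify that the curation cascade rejects each designed
    violator for the designed reason and nothing else; includes one
    clean record, plus two same-type replicates whose spread trips the
    replicate-consistency (sd) filter.
    """
    clean = {
        "compound_smiles": "Cc1ccc2ncncc2c1",
        "target_id": "P00001",
        "measurement_type": "IC50",
        "relation": "=",
        "value_nM": 100.0,
        "relationship_type": "D",
        "assay_confidence": 9,
        "assay_kinase_count": 1,
        "activity_comment": "",
        "source": "chembl",
    }
    rows = [dict(clean)]
    for reason, corrupt in _CORRUPTIONS.items():
        rec = dict(clean)
        rec["target_id"] = f"T_{reason}"
        corrupt(rec)
        rec["expected_reason"] = reason
        rows.append(rec)
    bad_units = dict(clean, target_id="T_units", units="uM", expected_reason="units")
    rows.append(bad_units)
    rows.append(
        dict(clean, compound_smiles="", target_id="T_malformed", expected_reason="malformed_record")
    )
    rows.append(
        dict(
            clean,
            compound_smiles="not_a_smiles((",
            target_id="T_parse",
            expected_reason="standardize_parse_error",
        )
    )
    for v in (10.0, 10_000.0):  # pPotency 8 and 5: sample sd ~2.12 >= 1
        rows.append(
            dict(clean, target_id="T_sd", value_nM=v, expected_reason="sd_exceeds")
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# structure fixtures


def _pdb_text(pdb_id, title, keywords, resolution, include_ligand=True,
              peptide_chain=False, link=False):
    lines = [
        f"HEADER    TRANSFERASE                             01-JAN-22   {pdb_id}",
        f"TITLE     {title.upper()}",
        f"KEYWDS    {keywords.upper()}",
        "REMARK   2",
        f"REMARK   2 RESOLUTION.    {resolution:.2f} ANGSTROMS.",
    ]

    def atom(serial, name, res, chain, seq, x, y, z, element, het=False):
        rec = "HETATM" if het else "ATOM  "
        return (
            f"{rec}{serial:>5} {name:<4}{res:>4} {chain}{seq:>4}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00 10.00          {element:>2}"
        )

    serial = 1
    bb = [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")]
    protein = [("ALA", bb),
               ("CYS", [("N", "N"), ("CA", "C"), ("CB", "C"), ("SG", "S")]),
               ("GLY", bb), ("ALA", bb), ("GLY", bb), ("ALA", bb), ("GLY", bb)]
    for seq, (res, atoms) in enumerate(protein, start=1):
        for i, (name, el) in enumerate(atoms):
            lines.append(atom(serial, name, res, "A", seq, 10.0 + seq, 6.0 + i, -5.0, el))
            serial += 1
    lines.append(f"TER   {serial:>5}      GLY A   7")
    serial += 1
    if peptide_chain:
        for seq in range(1, 6):
            for i, name in enumerate(("N", "CA", "C", "O")):
                el = name[0]
                lines.append(atom(serial, name, "ALA", "B", seq, 20.0 + seq, 3.0 + i, 2.0, el))
                serial += 1
        lines.append(f"TER   {serial:>5}      ALA B   5")
        serial += 1
    if include_ligand:
        for i, (name, el) in enumerate((("C1", "C"), ("C2", "C"), ("O1", "O"), ("N1", "N"))):
            lines.append(atom(serial, name, "LIG", "A", 201, 9.0 + i, 10.0, -3.0, el, het=True))
            serial += 1
    lines.append(atom(serial, "O", "HOH", "A", 301, 5.0, 5.0, 5.0, "O", het=True))
    if link and include_ligand:
        lines.append(
            "LINK         SG  CYS A   2                 C1  LIG A 201     1555   1555  1.80"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def _cif_text(pdb_id, title, keywords, resolution):
    return f"""\
data_{pdb_id}
_entry.id {pdb_id}
_struct.title '{title}'
_struct_keywords.text '{keywords}'
_refine.ls_d_res_high {resolution:.2f}
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_seq_id
_atom_site.auth_asym_id
_atom_site.auth_seq_id
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.pdbx_PDB_model_num
ATOM 1 N N . ALA A 1 A 1 11.1 6.1 -6.5 1
ATOM 2 C CA . ALA A 1 A 1 11.6 6.0 -5.1 1
ATOM 3 C C . ALA A 1 A 1 12.7 7.1 -4.9 1
ATOM 4 O O . ALA A 1 A 1 13.6 7.3 -5.8 1
ATOM 5 N N . CYS A 2 A 2 12.6 7.9 -3.8 1
ATOM 6 C CA . CYS A 2 A 2 13.6 8.9 -3.5 1
HETATM 7 C C1 . LIG B . A 201 10.0 10.0 -3.0 1
HETATM 8 C C2 . LIG B . A 201 9.0 10.5 -2.5 1
HETATM 9 O O1 . LIG B . A 201 8.5 9.8 -1.8 1
"""


#: (filename, expected triage decision, why)
STRUCTURE_FIXTURE_PLAN = (
    ("good_covalent.pdb", True, "resolution 2.1, ligand, 'covalent' keyword, LINK"),
    ("low_resolution.pdb", False, "resolution 3.6 fails the < 3.5 A filter"),
    ("no_ligand.pdb", False, "no small-molecule ligand"),
    ("peptide_only.pdb", False, "only a 5-residue peptide ligand"),
    ("keyword_miss.pdb", False, "no survey keyword in title/keywords"),
    ("good_noncompetitive.cif", True, "mmCIF, resolution 2.0, 'noncompetitive'"),
)


def generate_structure_fixtures(out_dir, seed: int = 0) -> dict:
    """Write the triage fixture set and the packaged survey tables.

    Emits six tiny structure files covering each filter branch plus the
    ligand-type and covalent-inhibitor tables; returns a manifest
    mapping filename to the designed triage decision.  Output is
    byte-identical for any seed (the files are fully determined).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "good_covalent.pdb").write_text(
        _pdb_text("9CV1", "Kinase with a covalent allosteric inhibitor",
                  "transferase, inhibitor", 2.1, link=True)
    )
    (out / "low_resolution.pdb").write_text(
        _pdb_text("9CV2", "Kinase inhibitor complex", "transferase, inhibitor", 3.6)
    )
    (out / "no_ligand.pdb").write_text(
        _pdb_text("9CV3", "Apo kinase allosteric state", "transferase, allosteric", 2.0,
                  include_ligand=False)
    )
    (out / "peptide_only.pdb").write_text(
        _pdb_text("9CV4", "Kinase with inhibitory peptide", "transferase, inhibitor", 2.0,
                  include_ligand=False, peptide_chain=True)
    )
    (out / "keyword_miss.pdb").write_text(
        _pdb_text("9CV5", "Kinase in complex with a small molecule", "transferase", 2.0)
    )
    (out / "good_noncompetitive.cif").write_text(
        _cif_text("9CV6", "Kinase with a noncompetitive ligand", "transferase", 2.0)
    )
    for name in ("allosteric_ligand_types.tsv", "covalent_apkis.tsv"):
        with resources.files("covkin.data").joinpath(name).open("rb") as src:
            with open(out / name, "wb") as dst:
                shutil.copyfileobj(src, dst)
    return {name: expected for name, expected, _ in STRUCTURE_FIXTURE_PLAN}
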