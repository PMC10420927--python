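"""X-ray structure triage for allosteric-ligand surveys.

Screens kinase structure files (PDB or mmCIF) through the survey
protocol: resolution below 3.5 A, presence of at least one qualifying
small-molecule ligand (water, common ions/buffers/cryo-agents and large
peptide ligands excluded), and a case-insensitive keyword scan of the
title/keyword metadata ("allosteric", "activator", "covalent",
"inhibit", "noncompetitive", "uncompetitive").  Covalent links between
a ligand and a protein residue are read from the connectivity records
(LINK / struct_conn).  Binding-site letters and ligand types are
accepted as curated annotations; geometric site assignment and visual
adjudication are out of scope.

Also aggregates curated allosteric-ligand records: counts per ligand
type against a baseline survey, and the covalent (type VI) sub-summary
per kinase / warhead / modified residue.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import gemmi
import pandas as pd
from sklearn.base import BaseEstimator

DEFAULT_KEYWORDS = (
    "allosteric",
    "activator",
    "covalent",
    "inhibit",
    "noncompetitive",
    "uncompetitive",
)

#: Chemical components never counted as ligands.
DEFAULT_EXCLUDED_COMPONENTS = frozenset(
    {
        "HOH", "DOD",  # water
        "NA", "K", "CL", "MG", "CA", "ZN", "MN", "FE", "NI", "CU", "CO", "BR", "IOD",
        "SO4", "PO4", "NO3", "ACT", "FMT",  # common ions
        "GOL", "EDO", "PEG", "PGE", "MPD", "DMS", "BME", "TRS", "EPE", "MES",  # cryo/buffer
    }
)


@dataclass
class StructureEntry:
    """Parsed content of one structure file, as used by the filters."""

    pdb_id: str
    resolution_A: float | None
    title_and_keywords: str
    ligands: list  # (component_id, heavy_atom_count, is_polymer, residue_count)
    covalent_links: list  # (ligand component_id, "ResnameNum", "atom1-atom2")
    deposition_year: int | None = None


def _cif_resolution(path: str) -> float | None:
    try:
        doc = gemmi.cif.read(str(path))
        block = doc.sole_block()
        for tag in ("_refine.ls_d_res_high", "_reflns.d_resolution_high"):
            val = block.find_value(tag)
            if val and val not in (".", "?"):
                return float(val)
    except Exception:
        return None
    return None


def parse_structure(
    path: str,
    excluded_components=DEFAULT_EXCLUDED_COMPONENTS,
    peptide_min_residues: int = 4,
) -> StructureEntry:
    """Parse one PDB/mmCIF file into a :class:`StructureEntry`.

    Ligands are non-polymer components not on the exclusion list;
    polymer chains other than the largest one with at least
    ``peptide_min_residues`` residues are recorded as peptide ligands.
    Covalent links come from connections of covalent type joining a
    ligand atom to a polymer residue atom.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    if resolution is None and str(path).endswith((".cif", ".mmcif")):
        resolution = _cif_resolution(path)
    info = dict(st.info)
    title = " ".join(
        info.get(tag, "")
        for tag in ("_struct.title", "_struct_keywords.pdbx_keywords", "_struct_keywords.text")
    )
    pdb_id = info.get("_entry.id", "") or st.name

    ligands = []
    het_names = set()
    polymer_sizes = []
    for model in st:
        for chain in model:
            n_poly = sum(1 for r in chain if r.entity_type == gemmi.EntityType.Polymer)
            if n_poly:
                polymer_sizes.append((chain.name, n_poly))
            for res in chain:
                if res.entity_type == gemmi.EntityType.NonPolymer:
                    if res.name.upper() in excluded_components:
                        continue
                    ligands.append((res.name, len(res), False, 0))
                    het_names.add(res.name)
        break  # first model only
    if polymer_sizes:
        polymer_sizes.sort(key=lambda t: -t[1])
        for name, n in polymer_sizes[1:]:
            if n >= peptide_min_residues:
                ligands.append((f"chain {name}", 0, True, n))

    links = []
    for con in st.connections:
        if con.type != gemmi.ConnectionType.Covale:
            continue
        p1, p2 = con.partner1, con.partner2
        lig, prot = None, None
        for p in (p1, p2):
            if p.res_id.name in het_names:
                lig = p
            else:
                prot = p
        if lig is not None and prot is not None:
            links.append(
                (
                    lig.res_id.name,
                    f"{prot.res_id.name}{prot.res_id.seqid.num}",
                    f"{prot.atom_name}-{lig.atom_name}",
                )
            )
    return StructureEntry(
        pdb_id=pdb_id,
        resolution_A=resolution,
        title_and_keywords=title,
        ligands=ligands,
        covalent_links=links,
    )


def passes_filters(
    entry: StructureEntry,
    keywords=DEFAULT_KEYWORDS,
    resolution_max: float = 3.5,
) -> tuple[bool, list[str]]:
    """Survey filter: resolution, small-molecule ligand, keyword scan.

    Returns (decision, matched keywords).  The resolution filter is
    strict (< 3.5 A); the keyword match is a case-insensitive substring
    search over title and keyword metadata.
    """
    if entry.resolution_A is None or entry.resolution_A >= resolution_max:
        return False, []
    has_small_mol = any(not is_poly for (_, _, is_poly, _) in entry.ligands)
    if not has_small_mol:
        return False, []
    text = entry.title_and_keywords.lower()
    matched = [k for k in keywords if k.lower() in text]
    return (bool(matched), matched)


@dataclass(frozen=True)
class AllostericLigandRecord:
    """One curated structurally characterized allosteric ligand."""

    pdb_id: str
    ligand_type: str  # III, IV, V, VI, activator, multi_site
    site_label: str = ""
    kinase: str = ""
    modified_residue: str = ""
    warhead: str = ""

    def __post_init__(self):
        if self.ligand_type == "VI" and not (self.modified_residue and self.warhead):
            raise ValueError("type VI records require modified_residue and warhead")


def load_ligand_type_table() -> pd.DataFrame:
    """Packaged per-type counts of the structural survey (with baseline)."""
    with resources.files("covkin.data").joinpath("allosteric_ligand_types.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_covalent_records() -> list[AllostericLigandRecord]:
    """Packaged curated records of the 13 covalent allosteric inhibitors."""
    with resources.files("covkin.data").joinpath("covalent_apkis.tsv").open() as fh:
        frame = pd.read_csv(fh, sep="\t")
    return [
        AllostericLigandRecord(
            pdb_id=r.pdb_id,
            ligand_type=r.ligand_type,
            site_label=r.site,
            kinase=r.kinase,
            modified_residue=r.modified_residue,
            warhead=r.warhead,
        )
        for r in frame.itertuples(index=False)
    ]


def _residue_amino_acid(modified_residue: str) -> str:
    return "".join(c for c in modified_residue if not c.isdigit())


def summarize_ligand_types(type_counts: pd.DataFrame) -> dict:
    """Aggregate the per-type survey counts against the baseline.

    ``type_counts`` has columns ligand_type, count, baseline_count.
    The inhibitor total ("apki") covers every type except activators.
    """
    counts = dict(zip(type_counts["ligand_type"], type_counts["count"]))
    baseline = dict(zip(type_counts["ligand_type"], type_counts["baseline_count"]))
    total = int(sum(counts.values()))
    baseline_total = int(sum(baseline.values()))
    apki_types = [t for t in counts if t != "activator"]
    apki_total = int(sum(counts[t] for t in apki_types))
    apki_baseline = int(sum(baseline[t] for t in apki_types))
    return {
        "per_type": {t: int(counts[t]) for t in counts},
        "per_type_delta": {t: int(counts[t] - baseline[t]) for t in counts},
        "total": total,
        "total_delta": total - baseline_total,
        "apki_total": apki_total,
        "apki_delta": apki_total - apki_baseline,
    }


def summarize_ligand_records(records: list[AllostericLigandRecord]) -> dict:
    """Covalent-inhibitor sub-summary of curated ligand records.

    Counts per kinase, warhead and modified amino acid over the type VI
    records, plus distinct kinases and distinct binding sites.
    """
    covalent = [r for r in records if r.ligand_type == "VI"]
    per_kinase: dict[str, int] = {}
    per_warhead: dict[str, int] = {}
    per_residue: dict[str, int] = {}
    for r in covalent:
        per_kinase[r.kinase] = per_kinase.get(r.kinase, 0) + 1
        per_warhead[r.warhead] = per_warhead.get(r.warhead, 0) + 1
        aa = _residue_amino_acid(r.modified_residue)
        per_residue[aa] = per_residue.get(aa, 0) + 1
    return {
        "n_covalent": len(covalent),
        "per_kinase": per_kinase,
        "per_warhead": per_warhead,
        "per_modified_residue": per_residue,
        "distinct_kinases": len(per_kinase),
        "distinct_sites": len({r.site_label for r in covalent}),
    }


class StructureTriage(BaseEstimator):
    """Estimator-style wrapper over the structure-screening protocol.

    ``transform`` takes a list of structure file paths and returns a
    DataFrame with pdb_id, resolution_A, n_ligands, n_covalent_links,
    passes, matched_keywords.
    """

    def __init__(
        self,
        keywords=DEFAULT_KEYWORDS,
        resolution_max: float = 3.5,
        peptide_min_residues: int = 4,
        excluded_components=DEFAULT_EXCLUDED_COMPONENTS,
    ):
        self.keywords = keywords
        self.resolution_max = resolution_max
        self.peptide_min_residues = peptide_min_residues
        self.excluded_components = excluded_components

    def fit(self, X=None, y=None):
        return self

    def transform(self, paths) -> pd.DataFrame:
        rows = []
        for path in paths:
            entry = parse_structure(
                path,
                excluded_components=self.excluded_components,
                peptide_min_residues=self.peptide_min_residues,
            )
            ok, matched = passes_filters(entry, self.keywords, self.resolution_max)
            rows.append(
                {
                    "pdb_id": entry.pdb_id,
                    "resolution_A": entry.resolution_A,
                    "n_ligands": len(entry.ligands),
                    "n_covalent_links": len(entry.covalent_links),
                    "passes": ok,
                    "matched_keywords": ";".join(matched),
                }
            )
        return pd.DataFrame(rows)
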