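"""Electrophilic-warhead detection by substructure matching.

Covalent kinase inhibitors engage nucleophilic residues (mostly free
cysteines) through reactive electrophilic groups - warheads - such as
acrylamide, vinyl sulfone, or cyanoacrylamide.  This module detects
warheads in standardized compounds with a configurable SMARTS library
and partitions an inhibitor collection into covalent subsets (one per
warhead, possibly overlapping), the non-covalent set, and compounds
carrying only the two previously characterized warheads (acrylamide,
heterocyclic urea), which are detected but routed to a separate
excluded class.

A specificity rule prevents trivially nested double counting: an
embedding of a less specific pattern is suppressed when it is fully
contained in an embedding of a more specific one (lower
``specificity_rank``), e.g. the acrylamide embedded inside a
cyanoacrylamide, or the activated-ester embedded inside an acrylate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
import yaml
from rdkit import Chem
from sklearn.base import BaseEstimator, TransformerMixin

#: Warheads analyzed here (covalent subsets are formed for these).
NEW_WARHEADS = frozenset(
    {
        "aldehyde",
        "alpha_haloketone",
        "acrylate",
        "alkynyl_benzoate",
        "boronic_acid",
        "cyanoacrylamide",
        "cyanamide",
        "epoxide",
        "reactive_ester",
        "sulfonyl_fluoride",
        "terminal_alkyne",
        "vinyl_sulfone",
    }
)

#: Previously studied warheads: detected, then excluded from analysis.
PRIOR_WARHEADS = frozenset({"acrylamide", "heterocyclic_urea"})


@dataclass
class WarheadPattern:
    """One named warhead substructure pattern."""

    name: str
    smarts: str
    specificity_rank: int = 5
    mol: Chem.Mol = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.mol is None:
            self.mol = Chem.MolFromSmarts(self.smarts)
        if self.mol is None:
            raise ValueError(f"invalid SMARTS for warhead '{self.name}': {self.smarts}")


def load_warhead_library(config_path: str | None = None) -> list[WarheadPattern]:
    """Load the warhead library (14 defaults; config may override/extend).

    ``config_path`` points to a YAML/JSON document mapping warhead name
    to either a SMARTS string or ``{smarts, specificity_rank}``.  An
    unparseable pattern raises ``ValueError`` naming the warhead.
    """
    raw = yaml.safe_load(
        resources.files("covkin.data").joinpath("warheads.yaml").read_text()
    )
    if config_path is not None:
        with open(config_path) as fh:
            user = yaml.safe_load(fh) or {}
        for name, entry in user.items():
            raw[name] = entry
    library = []
    for name, entry in raw.items():
        if isinstance(entry, str):
            entry = {"smarts": entry}
        library.append(
            WarheadPattern(
                name=name,
                smarts=entry["smarts"],
                specificity_rank=int(entry.get("specificity_rank", 5)),
            )
        )
    return library


@dataclass(frozen=True)
class WarheadAssignment:
    """Warheads matched by one standardized compound."""

    standard_smiles: str
    matched: frozenset
    is_cpki: bool
    excluded_prior: bool


def _raw_embeddings(mol: Chem.Mol, library: list[WarheadPattern]) -> dict[str, list[frozenset]]:
    out = {}
    for pat in library:
        matches = mol.GetSubstructMatches(pat.mol, uniquify=True)
        if matches:
            out[pat.name] = [frozenset(m) for m in matches]
    return out


def detect_warheads(
    standard_smiles: str, library: list[WarheadPattern] | None = None
) -> WarheadAssignment:
    """Match all library patterns against one standardized compound.

    A pattern counts as matched when at least one of its embeddings
    survives the specificity rule described in the module docstring.
    """
    if library is None:
        library = load_warhead_library()
    mol = Chem.MolFromSmiles(standard_smiles)
    if mol is None:
        raise ValueError("parse_error")
    rank = {p.name: p.specificity_rank for p in library}
    raw = _raw_embeddings(mol, library)
    matched = set()
    for name, embeddings in raw.items():
        surviving = []
        for emb in embeddings:
            contained = any(
                rank[other] < rank[name] and any(emb <= oe for oe in oembs)
                for other, oembs in raw.items()
                if other != name
            )
            if not contained:
                surviving.append(emb)
        if surviving:
            matched.add(name)
    matched = frozenset(matched)
    excluded_prior = bool(matched) and matched <= PRIOR_WARHEADS
    is_cpki = bool(matched & NEW_WARHEADS) and not excluded_prior
    return WarheadAssignment(
        standard_smiles=standard_smiles,
        matched=matched,
        is_cpki=is_cpki,
        excluded_prior=excluded_prior,
    )


def partition_by_warhead(
    assignments: list[WarheadAssignment],
) -> tuple[dict[str, set], set, set]:
    """Partition assignments into warhead subsets / non-covalent / excluded.

    Returns ``(subsets, noncovalent, excluded)`` where ``subsets`` maps
    each analyzed warhead name to the set of compounds matching it
    (subsets may overlap: a compound with two warheads appears in both).
    Compounds carrying only prior-study warheads appear in neither
    subsets nor the non-covalent set.
    """
    subsets: dict[str, set] = {}
    noncovalent: set = set()
    excluded: set = set()
    for a in assignments:
        if a.excluded_prior:
            excluded.add(a.standard_smiles)
        elif not a.matched:
            noncovalent.add(a.standard_smiles)
        else:
            for name in a.matched & NEW_WARHEADS:
                subsets.setdefault(name, set()).add(a.standard_smiles)
    return subsets, noncovalent, excluded


class WarheadDetector(BaseEstimator, TransformerMixin):
    """Transformer annotating standardized compounds with warhead matches.

    ``transform`` accepts a sequence of canonical SMILES or a DataFrame
    with a ``standard_smiles`` column and returns a DataFrame with
    columns standard_smiles, matched (semicolon-joined sorted names),
    is_cpki, excluded_prior.
    """

    def __init__(self, config_path: str | None = None):
        self.config_path = config_path

    def fit(self, X, y=None):
        self.library_ = load_warhead_library(self.config_path)
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "library_"):
            self.fit(X)
        if isinstance(X, pd.DataFrame):
            smiles = X["standard_smiles"].tolist()
        else:
            smiles = list(X)
        rows = [detect_warheads(s, self.library_) for s in smiles]
        return pd.DataFrame(
            {
                "standard_smiles": [r.standard_smiles for r in rows],
                "matched": [";".join(sorted(r.matched)) for r in rows],
                "is_cpki": [r.is_cpki for r in rows],
                "excluded_prior": [r.excluded_prior for r in rows],
            }
        )


def assignments_from_frame(frame: pd.DataFrame) -> list[WarheadAssignment]:
    """Rebuild :class:`WarheadAssignment` objects from a detector frame."""
    out = []
    for row in frame.itertuples(index=False):
        matched = frozenset(m for m in str(row.matched).split(";") if m)
        out.append(
            WarheadAssignment(
                standard_smiles=row.standard_smiles,
                matched=matched,
                is_cpki=bool(row.is_cpki),
                excluded_prior=bool(row.excluded_prior),
            )
        )
    return out
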