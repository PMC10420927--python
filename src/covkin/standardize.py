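"""Compound standardization for cross-database identity.

Public activity databases represent the same inhibitor in many ways
(salt forms, protonation states, stereoisomers, isotope labels).  For
data integration every input SMILES is reduced to a single canonical
representation: the largest organic fragment, neutralized where a
valence-legal neutral form exists, with stereochemistry and isotopes
removed.
"""

from __future__ import annotations

from dataclasses import dataclass

from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize
from sklearn.base import BaseEstimator, TransformerMixin

import pandas as pd

RDLogger.DisableLog("rdApp.*")

_UNCHARGER = rdMolStandardize.Uncharger()


@dataclass(frozen=True)
class StandardCompound:
    """Result of standardizing one input SMILES.

    ``valid`` is False iff ``rejection_reason`` is non-empty; in that
    case ``standard_smiles`` is empty.
    """

    input_smiles: str
    standard_smiles: str
    valid: bool
    rejection_reason: str = ""


def _largest_organic_fragment(mol: Chem.Mol) -> Chem.Mol | None:
    """Fragment with the most heavy atoms that contains >=1 carbon.

    Ties broken by lexicographically smallest canonical SMILES, so the
    choice is independent of input atom ordering.
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    organic = [f for f in frags if any(a.GetAtomicNum() == 6 for a in f.GetAtoms())]
    if not organic:
        return None
    return min(
        organic,
        key=lambda f: (-f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)),
    )


def standardize_smiles(smiles: str) -> StandardCompound:
    """Standardize one SMILES string.

    Steps, in order: parse; keep the largest organic fragment (salt and
    solvent stripping); neutralize formal charges where a neutral
    protonation state exists (permanent charges such as quaternary
    nitrogen are kept); strip stereochemistry and isotope labels; emit
    the RDKit canonical SMILES.  Two inputs denoting the same desalted,
    neutral, achiral molecule yield byte-identical output.
    """
    if not smiles or not smiles.strip():
        return StandardCompound(smiles, "", False, "parse_error")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return StandardCompound(smiles, "", False, "parse_error")
    frag = _largest_organic_fragment(mol)
    if frag is None:
        return StandardCompound(smiles, "", False, "inorganic")
    try:
        Chem.SanitizeMol(frag)
        frag = _UNCHARGER.uncharge(frag)
        Chem.RemoveStereochemistry(frag)
        for atom in frag.GetAtoms():
            atom.SetIsotope(0)
        # canonicalize through a round trip so aromaticity/H counts settle
        out = Chem.MolToSmiles(frag)
        rt = Chem.MolFromSmiles(out)
        if rt is None:  # pragma: no cover - defensive
            return StandardCompound(smiles, "", False, "parse_error")
        return StandardCompound(smiles, Chem.MolToSmiles(rt), True, "")
    except Exception:  # pragma: no cover - rdkit sanitization corner cases
        return StandardCompound(smiles, "", False, "parse_error")


class SmilesStandardizer(BaseEstimator, TransformerMixin):
    """Transformer mapping raw SMILES to standardized canonical SMILES.

    Stateless (``fit`` is a no-op); provided so standardization can sit
    in an sklearn pipeline ahead of curation.  ``transform`` accepts a
    sequence of SMILES strings or a DataFrame with a ``smiles_column``
    and returns a DataFrame with columns input_smiles, standard_smiles,
    valid, rejection_reason.
    """

    def __init__(self, smiles_column: str = "compound_smiles"):
        self.smiles_column = smiles_column

    def fit(self, X, y=None):
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            smiles = X[self.smiles_column].tolist()
        else:
            smiles = list(X)
        rows = [standardize_smiles(s) for s in smiles]
        return pd.DataFrame(
            {
                "input_smiles": [r.input_smiles for r in rows],
                "standard_smiles": [r.standard_smiles for r in rows],
                "valid": [r.valid for r in rows],
                "rejection_reason": [r.rejection_reason for r in rows],
            }
        )


def standardize_batch(smiles_list) -> pd.DataFrame:
    """Standardize a sequence of SMILES; thin wrapper over the transformer."""
    return SmilesStandardizer().fit_transform(smiles_list)
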