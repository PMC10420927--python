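"""Analogue-series decomposition and covalent/non-covalent pair extraction.

Compounds are systematically partitioned into a core (the fragment
carrying the largest ring assembly, with attachment-point markers) and
terminal substituents by cutting 1..max_cuts acyclic single bonds, in
the spirit of retrosynthetic matched-series analysis.  Compounds that
share a byte-identical canonical core form an analogue series; from each
series, covalent/non-covalent analogue pairs with at least a min_fold
potency difference against the same kinase are extracted.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd
from rdkit import Chem
from sklearn.base import BaseEstimator, TransformerMixin

from .warheads import NEW_WARHEADS, WarheadAssignment

#: Cuttable-bond rule table (RECAP-style retrosynthesis): a bond is
#: cuttable when any pattern matches its two atoms and the bond is an
#: acyclic single bond.  Defaults: detachment of a substituent from a
#: ring atom, amide C-N, and ester C(=O)-O bonds.  Overridable per call.
DEFAULT_CUT_PATTERNS = (
    "[R]-!@[!R;!#1;!#0]",
    "[CX3;$([CX3]=O)]-!@[NX3]",
    "[CX3;$([CX3]=O)]-!@[OX2]",
)


@dataclass(frozen=True)
class Decomposition:
    """One core/substituent partition of a compound.

    ``core_key`` is the canonical SMILES of the core with unlabeled
    attachment points ([*]); byte-identical keys define a series.
    ``core_labeled`` and ``substituents`` keep isotope-labeled dummies
    so the molecule can be rebuilt exactly with ``Chem.molzip``.
    """

    core_key: str
    core_labeled: str
    substituents: tuple
    core_heavy_atoms: int


def _unlabeled_key(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetIsotope(0)
            atom.SetAtomMapNum(0)
    return Chem.MolToSmiles(mol)


def _heavy(mol: Chem.Mol) -> int:
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1 and a.GetAtomicNum() != 0)


def fragment_compound(
    standard_smiles: str, max_cuts: int = 3, cut_patterns=DEFAULT_CUT_PATTERNS
) -> list[Decomposition]:
    """Enumerate core/substituent decompositions of one compound.

    Cuts every subset of 1..max_cuts cuttable bonds (acyclic single
    bonds matching one of ``cut_patterns``).  A decomposition is kept when it
    yields one connected core - the fragment with the most ring atoms -
    and terminal single-attachment substituents, and the core has at
    least twice as many heavy atoms as all substituents combined.
    Acyclic molecules (no ring to anchor a core) yield an empty list.
    """
    mol = Chem.MolFromSmiles(standard_smiles)
    if mol is None:
        raise ValueError("parse_error")
    if max_cuts < 1:
        raise ValueError("max_cuts must be >= 1")
    cuttable = set()
    for smarts in cut_patterns:
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ValueError(f"invalid cut pattern: {smarts}")
        for match in mol.GetSubstructMatches(patt):
            # the cut bond joins the first two atoms of the pattern
            bond = mol.GetBondBetweenAtoms(match[0], match[1])
            if (
                bond is not None
                and not bond.IsInRing()
                and bond.GetBondType() == Chem.BondType.SINGLE
            ):
                cuttable.add(bond.GetIdx())
    cuttable = sorted(cuttable)
    out = []
    seen = set()
    for k in range(1, max_cuts + 1):
        for combo in itertools.combinations(cuttable, k):
            labels = [(i + 1, i + 1) for i in range(k)]
            frag = Chem.FragmentOnBonds(mol, list(combo), addDummies=True, dummyLabels=labels)
            pieces = Chem.GetMolFrags(frag, asMols=True, sanitizeFrags=False)
            pieces = [Chem.MolFromSmiles(Chem.MolToSmiles(p)) for p in pieces]
            if any(p is None for p in pieces):
                continue
            ring_atoms = [sum(a.IsInRing() for a in p.GetAtoms()) for p in pieces]
            if max(ring_atoms) == 0:
                continue
            core_i = max(
                range(len(pieces)),
                key=lambda i: (ring_atoms[i], _heavy(pieces[i])),
            )
            core = pieces[core_i]
            subs = [p for i, p in enumerate(pieces) if i != core_i]
            n_dummies = sum(1 for a in core.GetAtoms() if a.GetAtomicNum() == 0)
            if n_dummies != k:
                continue  # a cut bond did not touch the core (linker piece)
            if any(sum(1 for a in s.GetAtoms() if a.GetAtomicNum() == 0) != 1 for s in subs):
                continue  # substituent must be terminal (single attachment)
            sub_heavy = sum(_heavy(s) for s in subs)
            if _heavy(core) < 2 * sub_heavy:
                continue
            core_labeled = Chem.MolToSmiles(core)
            key = _unlabeled_key(core_labeled)
            sub_smiles = tuple(sorted(Chem.MolToSmiles(s) for s in subs))
            dedup = (key, sub_smiles)
            if dedup in seen:
                continue
            seen.add(dedup)
            out.append(
                Decomposition(
                    core_key=key,
                    core_labeled=core_labeled,
                    substituents=sub_smiles,
                    core_heavy_atoms=_heavy(core),
                )
            )
    return out


def reconstruct(decomposition: Decomposition) -> str:
    """Reassemble core + substituents into the canonical parent SMILES."""
    comb = Chem.MolFromSmiles(decomposition.core_labeled)
    for s in decomposition.substituents:
        comb = Chem.CombineMols(comb, Chem.MolFromSmiles(s))
    params = Chem.MolzipParams()
    params.label = Chem.MolzipLabel.Isotope
    mol = Chem.molzip(comb, params)
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


@dataclass
class AnalogueSeries:
    """Compounds sharing one canonical core with varying substituents."""

    series_id: str
    core: str
    members: dict = field(default_factory=dict)  # smiles -> Decomposition


def build_series(
    compounds: list[str], max_cuts: int = 3, cut_patterns=DEFAULT_CUT_PATTERNS
) -> list[AnalogueSeries]:
    """Group compounds into analogue series by shared canonical core.

    Each compound is assigned to at most one series via the largest-core
    rule: among its decompositions whose core is shared with at least
    one other compound, the one with the most core heavy atoms wins
    (ties broken by lexicographically smallest core key).  Cores left
    with fewer than two members after assignment do not form a series.
    """
    decomps = {smi: fragment_compound(smi, max_cuts, cut_patterns) for smi in compounds}
    core_owners: dict[str, set] = {}
    for smi, ds in decomps.items():
        for d in ds:
            core_owners.setdefault(d.core_key, set()).add(smi)
    chosen: dict[str, Decomposition] = {}
    for smi, ds in decomps.items():
        shared = [d for d in ds if len(core_owners[d.core_key]) >= 2]
        if not shared:
            continue
        chosen[smi] = min(shared, key=lambda d: (-d.core_heavy_atoms, d.core_key))
    groups: dict[str, dict] = {}
    for smi, d in chosen.items():
        groups.setdefault(d.core_key, {})[smi] = d
    series = []
    for i, key in enumerate(sorted(k for k, g in groups.items() if len(g) >= 2)):
        series.append(AnalogueSeries(series_id=f"S{i:04d}", core=key, members=groups[key]))
    return series


@dataclass(frozen=True)
class AnaloguePair:
    """A covalent/non-covalent analogue pair on one kinase."""

    cpki_smiles: str
    pki_smiles: str
    target_id: str
    warhead: str
    delta_p: float  # pPotency(cpki) - pPotency(pki), signed
    series_id: str


def extract_pairs(
    series: list[AnalogueSeries],
    curated: pd.DataFrame,
    assignments: list[WarheadAssignment],
    min_fold: float = 100.0,
) -> list[AnaloguePair]:
    """Extract qualifying covalent/non-covalent analogue pairs.

    For every (cpki, pki) pair within one series - cpki carrying at
    least one analyzed warhead, pki warhead-free - and every kinase for
    which both have curated activity, a pair is emitted when the
    absolute potency difference reaches log10(min_fold) (100-fold = 2
    log units).  ``delta_p`` keeps its sign (cpki - pki); a cpki with
    several warheads contributes one pair record per warhead.
    """
    import math

    if min_fold <= 1:
        raise ValueError("min_fold must be > 1")
    threshold = math.log10(min_fold)
    amap = {a.standard_smiles: a for a in assignments}
    potency: dict[str, dict[str, float]] = {}
    for row in curated.itertuples(index=False):
        potency.setdefault(row.standard_smiles, {})[row.target_id] = row.pPotency
    pairs = []
    for s in series:
        members = sorted(s.members)
        cpkis = [m for m in members if m in amap and amap[m].is_cpki]
        pkis = [m for m in members if m in amap and not amap[m].matched]
        for c in cpkis:
            for p in pkis:
                shared = sorted(
                    set(potency.get(c, {})) & set(potency.get(p, {}))
                )
                for t in shared:
                    delta = potency[c][t] - potency[p][t]
                    if abs(delta) >= threshold:
                        for wh in sorted(amap[c].matched & NEW_WARHEADS):
                            pairs.append(
                                AnaloguePair(
                                    cpki_smiles=c,
                                    pki_smiles=p,
                                    target_id=t,
                                    warhead=wh,
                                    delta_p=delta,
                                    series_id=s.series_id,
                                )
                            )
    return pairs


def pairs_to_frame(pairs: list[AnaloguePair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cpki_smiles": [p.cpki_smiles for p in pairs],
            "pki_smiles": [p.pki_smiles for p in pairs],
            "target_id": [p.target_id for p in pairs],
            "warhead": [p.warhead for p in pairs],
            "delta_p": [p.delta_p for p in pairs],
            "series_id": [p.series_id for p in pairs],
        }
    )


class AnalogueSeriesExtractor(BaseEstimator, TransformerMixin):
    """Transformer grouping standardized compounds into analogue series.

    ``fit`` builds the series from a sequence of canonical SMILES (or a
    DataFrame with ``standard_smiles``); fitted attributes ``series_``
    and ``labels_`` expose the grouping; ``transform`` returns a
    DataFrame (standard_smiles, series_id, core) with empty series_id
    for unassigned compounds.
    """

    def __init__(self, max_cuts: int = 3, cut_patterns=DEFAULT_CUT_PATTERNS):
        self.max_cuts = max_cuts
        self.cut_patterns = cut_patterns

    @staticmethod
    def _smiles(X) -> list[str]:
        if isinstance(X, pd.DataFrame):
            return X["standard_smiles"].tolist()
        return list(X)

    def fit(self, X, y=None):
        compounds = list(dict.fromkeys(self._smiles(X)))
        self.series_ = build_series(compounds, self.max_cuts, self.cut_patterns)
        self.labels_ = {}
        for s in self.series_:
            for m in s.members:
                self.labels_[m] = s.series_id
        return self

    def transform(self, X) -> pd.DataFrame:
        smiles = self._smiles(X)
        cores = {s.series_id: s.core for s in self.series_}
        sid = [self.labels_.get(s, "") for s in smiles]
        return pd.DataFrame(
            {
                "standard_smiles": smiles,
                "series_id": sid,
                "core": [cores.get(i, "") for i in sid],
            }
        )
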