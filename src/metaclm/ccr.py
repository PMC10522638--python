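"""Analogue-series identification via compound-core relationships (CCR).

A compound is decomposed by cutting between one and five acyclic single
bonds between heavy atoms. A cut set is a valid decomposition when
exactly one resulting fragment — the core — carries all attachment
points, every other fragment carries exactly one (a substituent), and
the core has at least twice as many non-hydrogen atoms as the combined
substituents. Attachment points are numbered by the canonical atom rank
of the core so that cores are comparable across compounds; compounds
sharing an identical numbered canonical core form an analogue series.

From each series all analogue pairs are enumerated as triples
(source compound, target compound, potency difference). Pairs with an
absolute potency difference of at least 2.0 pKi units (a 100-fold change
in Ki) are activity-cliff pairs (AC_CCR); the rest are CCR pairs.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import pandas as pd
from rdkit import Chem

from .chem import mol_from_smiles
from .curation import ActivityClass, CompoundRecord

AC_THRESHOLD = 2.0  # |dpKi| >= 2.0 <=> at least 100-fold potency difference


class PairCategory(str, enum.Enum):
    CCR = "CCR"
    AC_CCR = "AC_CCR"


@dataclass(frozen=True)
class Decomposition:
    """A core with numbered attachment points plus one substituent per site.

    ``core`` is a canonical SMILES whose attachment points are dummy
    atoms isotope-labelled 1..n_sites; ``substituents[i]`` carries the
    single matching dummy labelled ``i+1``.
    """

    core: str
    substituents: tuple[str, ...]

    @property
    def n_sites(self) -> int:
        return len(self.substituents)


@dataclass
class AnalogueSeries:
    core: str
    members: list[tuple[CompoundRecord, tuple[str, ...]]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class AnaloguePairTriple:
    source: CompoundRecord
    target: CompoundRecord
    delta_pot: float
    category: PairCategory
    core: str = ""
    class_id: str = ""


def categorize(delta_pot: float) -> PairCategory:
    return PairCategory.AC_CCR if abs(delta_pot) >= AC_THRESHOLD else PairCategory.CCR


# ----------------------------------------------------------------------
# Decomposition
# ----------------------------------------------------------------------

def _cuttable_bonds(mol: Chem.Mol) -> list[int]:
    """Indices of acyclic single bonds between heavy atoms."""
    out = []
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        if bond.GetBeginAtom().GetAtomicNum() <= 1 or bond.GetEndAtom().GetAtomicNum() <= 1:
            continue
        out.append(bond.GetIdx())
    return out


def _heavy(mol: Chem.Mol) -> int:
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


def _dummies(mol: Chem.Mol) -> list[Chem.Atom]:
    return [a for a in mol.GetAtoms() if a.GetAtomicNum() == 0]


def size_filter_counts(core_heavy: int, subst_heavy: int) -> bool:
    """Core-size rule: core must have at least twice the combined
    substituent heavy-atom count."""
    return core_heavy >= 2 * subst_heavy


def size_filter(d: Decomposition) -> bool:
    core_heavy = _heavy(mol_from_smiles(d.core))
    subst_heavy = sum(_heavy(mol_from_smiles(s)) for s in d.substituents)
    return size_filter_counts(core_heavy, subst_heavy)


def _canonical_decomposition(core: Chem.Mol, subs: list[Chem.Mol]
                             ) -> Decomposition | None:
    """Renumber attachment points by canonical core rank and canonicalise.

    The core arrives with dummy atoms isotope-labelled by arbitrary cut
    ids; sites are renumbered 1..k in order of the canonical atom rank of
    the dummy within the unlabelled core, which makes identical cores
    from different compounds directly comparable.
    """
    core = Chem.Mol(core)
    stripped = Chem.Mol(core)
    for a in _dummies(stripped):
        a.SetIsotope(0)
    ranks = list(Chem.CanonicalRankAtoms(stripped, breakTies=True))
    dummies = sorted(_dummies(core), key=lambda a: ranks[a.GetIdx()])
    old_to_site: dict[int, int] = {}
    for site, atom in enumerate(dummies, start=1):
        old_to_site[atom.GetIsotope()] = site
        atom.SetIsotope(site)
    sub_smiles: list[str | None] = [None] * len(dummies)
    for sub in subs:
        sub = Chem.Mol(sub)
        (dummy,) = _dummies(sub)
        site = old_to_site[dummy.GetIsotope()]
        dummy.SetIsotope(site)
        sub_smiles[site - 1] = Chem.MolToSmiles(sub)
    return Decomposition(core=Chem.MolToSmiles(core),
                         substituents=tuple(sub_smiles))


def decompose(structure: str, max_sites: int = 5) -> list[Decomposition]:
    """All size-filtered core/substituent decompositions of a molecule.

    Enumerates every cut set of 1..max_sites acyclic single bonds between
    heavy atoms; keeps those where one fragment (the core) carries all
    attachment points and each remaining fragment exactly one. Returned
    in lexicographic order by (core, substituents).
    """
    if not 1 <= max_sites <= 5:
        raise ValueError("max_sites must be between 1 and 5")
    mol = mol_from_smiles(structure)
    bonds = _cuttable_bonds(mol)
    found: set[Decomposition] = set()
    for k in range(1, min(max_sites, len(bonds)) + 1):
        for combo in combinations(bonds, k):
            labels = [(i + 1, i + 1) for i in range(k)]
            frag = Chem.FragmentOnBonds(mol, list(combo), addDummies=True,
                                        dummyLabels=labels)
            try:
                pieces = Chem.GetMolFrags(frag, asMols=True, sanitizeFrags=True)
            except Chem.rdchem.MolSanitizeException:  # pragma: no cover
                continue
            if len(pieces) != k + 1:
                continue
            counts = [len(_dummies(p)) for p in pieces]
            core_candidates = [i for i, c in enumerate(counts) if c == k]
            if k > 1:
                if len(core_candidates) != 1 or any(
                        c != 1 for i, c in enumerate(counts)
                        if i != core_candidates[0]):
                    continue
            for ci in core_candidates:
                core = pieces[ci]
                subs = [p for i, p in enumerate(pieces) if i != ci]
                if any(len(_dummies(s)) != 1 for s in subs):
                    continue
                if not size_filter_counts(_heavy(core),
                                          sum(_heavy(s) for s in subs)):
                    continue
                d = _canonical_decomposition(core, subs)
                if d is not None:
                    found.add(d)
    return sorted(found, key=lambda d: (d.core, d.substituents))


def reassemble(d: Decomposition) -> str:
    """Reattach substituents to the core; returns the canonical parent SMILES."""
    def with_maps(smiles: str) -> Chem.Mol:
        mol = mol_from_smiles(smiles)
        mol = Chem.Mol(mol)
        for a in _dummies(mol):
            a.SetAtomMapNum(a.GetIsotope())
            a.SetIsotope(0)
        return mol

    combined = with_maps(d.core)
    for sub in d.substituents:
        combined = Chem.CombineMols(combined, with_maps(sub))
    zipped = Chem.molzip(combined)
    Chem.SanitizeMol(zipped)
    return Chem.MolToSmiles(zipped)


# ----------------------------------------------------------------------
# Series and pairs
# ----------------------------------------------------------------------

def group_series(compounds: ActivityClass, max_sites: int = 5
                 ) -> list[AnalogueSeries]:
    """Group an activity class into analogue series by shared canonical core.

    A compound may appear in several series through different
    decompositions; series with fewer than two distinct members are
    dropped. Series are ordered lexicographically by core.
    """
    by_core: dict[str, AnalogueSeries] = {}
    for member in compounds.members:
        seen_cores: set[str] = set()
        for d in decompose(member.structure, max_sites=max_sites):
            if d.core in seen_cores:
                continue  # one decomposition per (compound, core)
            seen_cores.add(d.core)
            series = by_core.setdefault(d.core, AnalogueSeries(core=d.core))
            series.members.append((member, d.substituents))
    return [by_core[c] for c in sorted(by_core) if len(by_core[c]) >= 2]


def enumerate_triples(series: AnalogueSeries, ordered: bool,
                      class_id: str = "") -> list[AnaloguePairTriple]:
    """All analogue pair triples of one series.

    Ordered enumeration yields both directions of every pair, n(n-1)
    triples with signed potency differences; unordered enumeration yields
    n(n-1)/2 triples oriented so the target is the more potent member
    (ties broken by structure string).
    """
    members = [m for m, _subs in series.members]
    out: list[AnaloguePairTriple] = []
    for a, b in combinations(members, 2):
        pairs: list[tuple[CompoundRecord, CompoundRecord]]
        if ordered:
            pairs = [(a, b), (b, a)]
        else:
            lo, hi = sorted((a, b), key=lambda m: (m.pki, m.structure))
            pairs = [(lo, hi)]
        for sc, tc in pairs:
            delta = tc.pki - sc.pki
            out.append(AnaloguePairTriple(
                source=sc, target=tc, delta_pot=delta,
                category=categorize(delta), core=series.core,
                class_id=class_id))
    return out


def pool_triples(series_list: list[AnalogueSeries], ordered: bool,
                 class_id: str = "") -> list[AnaloguePairTriple]:
    """Pool triples from all series of a class, deduplicating identical
    (source, target) pairs that arise from different cores."""
    seen: set[tuple[str, str]] = set()
    out: list[AnaloguePairTriple] = []
    for series in series_list:
        for t in enumerate_triples(series, ordered=ordered, class_id=class_id):
            key = (t.source.structure, t.target.structure)
            if key in seen:
                continue
            seen.add(key)
            out.append(t)
    return out


def class_triples(activity_class: ActivityClass, ordered: bool,
                  max_sites: int = 5) -> list[AnaloguePairTriple]:
    """Convenience: decompose, group and pool triples for one class."""
    series = group_series(activity_class, max_sites=max_sites)
    return pool_triples(series, ordered=ordered, class_id=activity_class.target_id)


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

_TRIPLE_COLS = ["sc_smiles", "tc_smiles", "delta_pki", "category", "core", "class_id"]


def write_triples(triples: list[AnaloguePairTriple], path: str | Path) -> None:
    df = pd.DataFrame({
        "sc_smiles": [t.source.structure for t in triples],
        "tc_smiles": [t.target.structure for t in triples],
        "sc_pki": [t.source.pki for t in triples],
        "tc_pki": [t.target.pki for t in triples],
        "delta_pki": [t.delta_pot for t in triples],
        "category": [t.category.value for t in triples],
        "core": [t.core for t in triples],
        "class_id": [t.class_id for t in triples],
    })
    df.to_csv(path, sep="\t", index=False)


def read_triples(path: str | Path) -> list[AnaloguePairTriple]:
    from .chem import compound_id

    df = pd.read_csv(path, sep="\t")
    missing = set(_TRIPLE_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"triple table {path} missing columns: {sorted(missing)}")
    out = []
    for r in df.itertuples(index=False):
        sc_pki = float(getattr(r, "sc_pki", 0.0))
        tc_pki = float(getattr(r, "tc_pki", sc_pki + r.delta_pki))
        sc = CompoundRecord(compound_id(r.sc_smiles), r.sc_smiles, sc_pki)
        tc = CompoundRecord(compound_id(r.tc_smiles), r.tc_smiles, tc_pki)
        out.append(AnaloguePairTriple(sc, tc, float(r.delta_pki),
                                      PairCategory(r.category),
                                      core=str(r.core), class_id=str(r.class_id)))
    return out
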