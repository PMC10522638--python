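"""Shared RDKit helpers: canonicalisation and compound identity.

One canonical SMILES form (RDKit default canonical ordering, no explicit
H, stereochemistry as given) is used package-wide for compound identity,
deduplication and generated-candidate matching.
"""

from __future__ import annotations

import hashlib

from rdkit import Chem, RDLogger

# RDKit is chatty about every rejected parse; warnings are surfaced through
# the package's own logging instead.
RDLogger.DisableLog("rdApp.*")


class InvalidStructureError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


def mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidStructureError(f"unparsable SMILES: {smiles!r}")
    return mol


def canonical_smiles(smiles: str) -> str:
    """Canonical SMILES of ``smiles``; raises on unparsable input."""
    return Chem.MolToSmiles(mol_from_smiles(smiles))


def try_canonical_smiles(smiles: str) -> str | None:
    """Canonical SMILES, or None when the string is not valid chemistry."""
    mol = Chem.MolFromSmiles(smiles)
    return None if mol is None else Chem.MolToSmiles(mol)


def compound_id(canonical: str) -> str:
    """Stable short identifier derived from a canonical structure string."""
    return "CPD-" + hashlib.sha1(canonical.encode()).hexdigest()[:12]


def heavy_atom_count(smiles: str) -> int:
    """Number of non-hydrogen, non-attachment-point atoms."""
    mol = mol_from_smiles(smiles)
    return sum(1 for a in mol.GetAtoms()
               if a.GetAtomicNum() > 1)
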