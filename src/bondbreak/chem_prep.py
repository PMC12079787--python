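"""Molecule parsing, element/size filtering, and 3D embedding.

Input molecules are SMILES strings.  Hydrogens are always made explicit
before any downstream step: the sampling workflow stretches C–H bonds just
like heavy-atom bonds, so the bond enumeration must see them.  The default
validity policy accepts only neutral closed-shell molecules (no formal
charges, no radical electrons), which matches the stable small organics the
workflow is aimed at; the check can be relaxed per call.

Embedding is a contract, not a fixed tool: any generator of a single
low-energy conformer that is deterministic under a fixed seed satisfies it.
The default implementation uses RDKit's ETKDG distance-geometry embedder.
"""
from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, List, Sequence, Set

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .structures import (
    EmbedError,
    Geometry,
    MoleculeRecord,
    ParseError,
    Provenance,
)

DEFAULT_ALLOWED_ELEMENTS = frozenset({"H", "C", "N", "O"})
DEFAULT_MAX_HEAVY = 7


def parse_molecule(
    smiles: str,
    identifier: str,
    require_neutral_closed_shell: bool = True,
) -> MoleculeRecord:
    """Parse a SMILES string into a :class:`MoleculeRecord`.

    Hydrogens are made explicit so that C–H (and N–H, O–H) bonds appear in
    the bond list.  Bond indices are normalized to ``a < b``.

    Parameters
    ----------
    smiles : str
        Input SMILES.
    identifier : str
        Name carried into error messages and provenance.
    require_neutral_closed_shell : bool
        When true (default), reject molecules carrying formal charges or
        radical electrons.

    Raises
    ------
    ParseError
        If the SMILES cannot be parsed/sanitized, or fails the neutrality
        check.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"could not parse SMILES for molecule {identifier!r}: {smiles!r}")
    mol = Chem.AddHs(mol)
    if require_neutral_closed_shell:
        if any(a.GetFormalCharge() != 0 for a in mol.GetAtoms()):
            raise ParseError(
                f"molecule {identifier!r} carries formal charges; pass "
                f"require_neutral_closed_shell=False to accept it"
            )
        if any(a.GetNumRadicalElectrons() != 0 for a in mol.GetAtoms()):
            raise ParseError(
                f"molecule {identifier!r} has radical electrons; pass "
                f"require_neutral_closed_shell=False to accept it"
            )
    return _record_from_rdkit(mol, smiles, identifier)


def _record_from_rdkit(mol: Chem.Mol, smiles: str, identifier: str) -> MoleculeRecord:
    elements = tuple(a.GetSymbol() for a in mol.GetAtoms())
    bonds = []
    for b in mol.GetBonds():
        a, c = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        a, c = (a, c) if a < c else (c, a)
        bonds.append((a, c, float(b.GetBondTypeAsDouble()), bool(b.GetIsAromatic())))
    bonds.sort()
    h_counts = tuple(
        sum(1 for nb in a.GetNeighbors() if nb.GetSymbol() == "H") for a in mol.GetAtoms()
    )
    valences = tuple(a.GetTotalValence() for a in mol.GetAtoms())
    charges = tuple(a.GetFormalCharge() for a in mol.GetAtoms())
    return MoleculeRecord(
        identifier=identifier,
        smiles=smiles,
        elements=elements,
        bonds=tuple(bonds),
        explicit_h_counts=h_counts,
        valences=valences,
        formal_charges=charges,
    )


def passes_filter(
    record: MoleculeRecord,
    allowed_elements: Set[str] = DEFAULT_ALLOWED_ELEMENTS,
    max_heavy: int = DEFAULT_MAX_HEAVY,
) -> bool:
    """Element/size admission filter.

    True iff every element is in ``allowed_elements`` and the number of
    non-hydrogen atoms is at most ``max_heavy``.  Defaults restrict to
    H/C/N/O molecules with at most seven heavy atoms.
    """
    if any(e not in allowed_elements for e in record.elements):
        return False
    return record.heavy_atom_count() <= max_heavy


def embed_geometry(record: MoleculeRecord, seed: int = 0) -> Geometry:
    """Embed one low-energy 3D conformer for ``record``.

    Deterministic for a fixed seed (ETKDG with ``randomSeed`` set and a
    single thread).  The conformer is relaxed with a few hundred steps of
    MMFF/UFF cleanup so bonded distances land in a physical range.

    Raises
    ------
    EmbedError
        If distance-geometry embedding fails.
    """
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        raise EmbedError(f"cannot rebuild molecule {record.identifier!r} for embedding")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) & 0x7FFFFFFF
    params.numThreads = 1
    conf_id = AllChem.EmbedMolecule(mol, params)
    if conf_id < 0:
        raise EmbedError(f"3D embedding failed for molecule {record.identifier!r}")
    try:
        if AllChem.MMFFHasAllMoleculeParams(mol):
            AllChem.MMFFOptimizeMolecule(mol, confId=conf_id, maxIters=500)
        else:
            AllChem.UFFOptimizeMolecule(mol, confId=conf_id, maxIters=500)
    except Exception:
        pass  # embedding alone is acceptable; cleanup is best-effort
    coords = np.array(mol.GetConformer(conf_id).GetPositions(), dtype=float)
    prov = Provenance(
        molecule_id=record.identifier, bond_id="", step_index=-1, origin="embed"
    )
    return Geometry(tuple(a.GetSymbol() for a in mol.GetAtoms()), coords, prov)


def load_molecule_table(path: str | Path) -> List[MoleculeRecord]:
    """Read a CSV/whitespace table with columns ``identifier, smiles``.

    A header row is detected and skipped.  Parse failures propagate with the
    offending identifier in the message.
    """
    path = Path(path)
    records: List[MoleculeRecord] = []
    with open(path, newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delimiter = "," if "," in sample else None
        if delimiter:
            rows: Iterable[Sequence[str]] = csv.reader(fh)
        else:
            rows = (line.split() for line in fh if line.strip())
        for i, row in enumerate(rows):
            if len(row) < 2:
                continue
            ident, smi = row[0].strip(), row[1].strip()
            if i == 0 and ident.lower() in ("identifier", "id", "name"):
                continue
            records.append(parse_molecule(smi, ident))
    return records
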