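"""Oligonucleotide SMILES assembly and molecular-graph extraction.

An assembled oligomer is a chain of nucleoside units joined 3'->5' by
phosphate linkages. Conventions (documented, since vendors differ):

* 5'-OH and 3'-OH termini; no terminal phosphate.
* Neutral, protonated phosphates: ``P(=O)(OH)`` for PO, ``P(=S)(OH)``
  for PS, with no stereo descriptor on phosphorus (Rp/Sp unresolved).
* Sugar stereocenters carry the natural beta-D configuration.
* MOE-modified T is built as the MOE-uridine; MOE-modified C as
  MOE-5-methylcytidine; LNA and DNA keep the plain DNA base.

Building blocks come from a YAML fragment library shipped with the
package (``data/fragments.yaml``); new 2'-chemistries can be registered
by loading an extended library file.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import yaml
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors

from .errors import AssemblyFailure, MissingFragment, ParseError
from .patterns import ModificationPattern
from .sequences import AsoSequence


@dataclass(frozen=True)
class NucleotideBlock:
    """One entry of the fragment library: a (base, sugar) nucleoside."""

    base: str
    sugar: str
    smiles_fragment: str

    def capped_smiles(self) -> str:
        """The free nucleoside: fragment with a 5'-OH cap (3'-OH is implicit)."""
        return "O" + self.smiles_fragment

    def heavy_atom_count(self) -> int:
        mol = Chem.MolFromSmiles(self.capped_smiles())
        if mol is None:
            raise AssemblyFailure(f"fragment for {self.sugar} {self.base} is invalid")
        return mol.GetNumHeavyAtoms() - 1  # minus the 5'-OH cap oxygen

    def formula(self) -> str:
        mol = Chem.MolFromSmiles(self.capped_smiles())
        if mol is None:
            raise AssemblyFailure(f"fragment for {self.sugar} {self.base} is invalid")
        return rdMolDescriptors.CalcMolFormula(mol)


class FragmentLibrary:
    """Registry of sugar templates, base substituents and linkages."""

    def __init__(self, spec: dict):
        self.sugars = {k: v["template"] for k, v in spec["sugars"].items()}
        self.bases = {k: v["smiles"] for k, v in spec["bases"].items()}
        self.linkages = {k: v["smiles"] for k, v in spec["linkages"].items()}
        self.base_for_sugar = spec["base_for_sugar"]

    @classmethod
    def default(cls) -> "FragmentLibrary":
        text = (
            importlib.resources.files("asoforge")
            .joinpath("data/fragments.yaml")
            .read_text(encoding="utf-8")
        )
        return cls(yaml.safe_load(text))

    @classmethod
    def from_file(cls, path) -> "FragmentLibrary":
        with open(path, encoding="utf-8") as fh:
            return cls(yaml.safe_load(fh))

    def block(self, base_letter: str, sugar: str) -> NucleotideBlock:
        """Resolve a sequence letter + sugar chemistry to a building block.

        Raises
        ------
        MissingFragment
            If the library has no entry for the combination.
        """
        try:
            template = self.sugars[sugar]
            ring = self.base_for_sugar[sugar][base_letter]
            base_smiles = self.bases[ring]
        except KeyError as exc:
            raise MissingFragment(
                f"no fragment for base {base_letter!r} with sugar {sugar!r}"
            ) from exc
        return NucleotideBlock(
            base=ring, sugar=sugar, smiles_fragment=template.format(b=base_smiles)
        )


_DEFAULT_LIBRARY: FragmentLibrary | None = None


def default_library() -> FragmentLibrary:
    global _DEFAULT_LIBRARY
    if _DEFAULT_LIBRARY is None:
        _DEFAULT_LIBRARY = FragmentLibrary.default()
    return _DEFAULT_LIBRARY


def build_oligo_smiles(
    seq: AsoSequence,
    pattern: ModificationPattern,
    library: FragmentLibrary | None = None,
) -> str:
    """Assemble the full oligomer and return its canonical SMILES.

    Residues are concatenated 5'->3'; each internucleotide linkage
    contributes a phosphate bridging the previous residue's 3'-O and the
    next residue's 5'-C.

    Raises
    ------
    MissingFragment
        If a (base, sugar) pair has no library entry.
    AssemblyFailure
        If the joined molecule fails RDKit sanitization.
    """
    if pattern.length != seq.length:
        raise ValueError(
            f"pattern length {pattern.length} != sequence length {seq.length}"
        )
    lib = library or default_library()
    parts = ["O"]  # 5'-OH terminus
    for i, (base, sugar) in enumerate(zip(seq.bases, pattern.sugar)):
        if i > 0:
            try:
                parts.append(lib.linkages[pattern.linkage[i - 1]])
            except KeyError as exc:
                raise MissingFragment(
                    f"no linkage fragment for {pattern.linkage[i - 1]!r}"
                ) from exc
        parts.append(lib.block(base, sugar).smiles_fragment)
    raw = "".join(parts)
    mol = Chem.MolFromSmiles(raw)
    if mol is None:
        raise AssemblyFailure(f"assembled SMILES failed sanitization: {raw}")
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class AtomRecord:
    element: str
    formal_charge: int
    aromatic: bool
    degree: int
    in_ring: bool


@dataclass(frozen=True)
class BondRecord:
    i: int
    j: int
    order: float  # 1.0, 2.0, 3.0, or 1.5 for aromatic
    aromatic: bool
    in_ring: bool


@dataclass(frozen=True)
class MolecularGraph:
    """Heavy-atom graph of a molecule with its binary adjacency matrix.

    ``adjacency[i, j] == 1`` iff a bond joins atoms ``i`` and ``j``; the
    matrix is symmetric with a zero diagonal. Hydrogens are implicit.
    """

    atoms: tuple[AtomRecord, ...]
    bonds: tuple[BondRecord, ...]
    adjacency: np.ndarray = field(repr=False)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def is_connected(self) -> bool:
        n = self.n_atoms
        if n == 0:
            return False
        seen = {0}
        stack = [0]
        neigh: dict[int, list[int]] = {i: [] for i in range(n)}
        for b in self.bonds:
            neigh[b.i].append(b.j)
            neigh[b.j].append(b.i)
        while stack:
            for j in neigh[stack.pop()]:
                if j not in seen:
                    seen.add(j)
                    stack.append(j)
        return len(seen) == n


def smiles_to_graph(smiles: str) -> MolecularGraph:
    """Parse SMILES into a heavy-atom :class:`MolecularGraph`.

    Atom order is the canonical atom order of the parsed molecule.

    Raises
    ------
    ParseError
        If the SMILES does not parse.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"invalid SMILES: {smiles}")
    return mol_to_graph(mol)


def mol_to_graph(mol: Chem.Mol) -> MolecularGraph:
    atoms = tuple(
        AtomRecord(
            element=a.GetSymbol(),
            formal_charge=a.GetFormalCharge(),
            aromatic=a.GetIsAromatic(),
            degree=a.GetDegree(),
            in_ring=a.IsInRing(),
        )
        for a in mol.GetAtoms()
    )
    bonds = tuple(
        BondRecord(
            i=b.GetBeginAtomIdx(),
            j=b.GetEndAtomIdx(),
            order=b.GetBondTypeAsDouble(),
            aromatic=b.GetIsAromatic(),
            in_ring=b.IsInRing(),
        )
        for b in mol.GetBonds()
    )
    adjacency = Chem.GetAdjacencyMatrix(mol).astype(np.int8)
    return MolecularGraph(atoms=atoms, bonds=bonds, adjacency=adjacency)


def element_counts(smiles: str) -> dict[str, int]:
    """Heavy-atom element tally of a SMILES string."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"invalid SMILES: {smiles}")
    counts: dict[str, int] = {}
    for a in mol.GetAtoms():
        counts[a.GetSymbol()] = counts.get(a.GetSymbol(), 0) + 1
    return counts
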