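"""Chemistry assembly checks against independent atom-tally oracles.

The oracle counts element symbols directly in the fragment template
strings (simple text scanning), never through the assembly code or a
molecule object, so formula agreement is an independent check of the
SMILES construction.
"""

import itertools
import re

import numpy as np
import pytest
from rdkit import Chem

from asoforge.chemistry import (
    FragmentLibrary,
    build_oligo_smiles,
    element_counts,
    smiles_to_graph,
)
from asoforge.errors import MissingFragment, ParseError
from asoforge.patterns import DNA, PO, PS, ModificationPattern
from asoforge.sequences import AsoSequence, validate_sequence
from tests.conftest import pattern_from_bits

_ELEMENT_RE = re.compile(r"Cl|Br|\[nH\]|[A-Z][a-z]?|[cnos]")


def tally_smiles_text(smiles: str) -> dict:
    """Heavy-atom tally by scanning SMILES text (independent of RDKit)."""
    counts: dict[str, int] = {}
    for tok in _ELEMENT_RE.findall(smiles):
        if tok == "[nH]":
            el = "N"
        elif tok in "cnos":
            el = tok.upper()
        elif tok in ("Cl", "Br") or tok.isalpha() and tok[0].isupper():
            el = tok
        else:
            continue
        if el == "H":
            continue
        counts[el] = counts.get(el, 0) + 1
    return counts


def add_counts(a: dict, b: dict) -> dict:
    out = dict(a)
    for k, v in b.items():
        out[k] = out.get(k, 0) + v
    return out


# literature formulas of the four free deoxyribonucleosides
NUCLEOSIDE_FORMULAS = {
    "T": {"C": 10, "N": 2, "O": 5},
    "A": {"C": 10, "N": 5, "O": 3},
    "C": {"C": 9, "N": 3, "O": 4},
    "G": {"C": 10, "N": 5, "O": 4},
}


@pytest.mark.parametrize("base", "TACG")
def test_dna_nucleoside_formulas_match_literature(library, base):
    block = library.block(base, DNA)
    counts = element_counts(block.capped_smiles())
    assert counts == NUCLEOSIDE_FORMULAS[base]


def test_single_residue_matches_text_tally_oracle(library):
    for base in "TACG":
        for sugar in (DNA, "LNA", "MOE"):
            block = library.block(base, sugar)
            expected = add_counts(tally_smiles_text(block.smiles_fragment), {"O": 1})
            assert element_counts(block.capped_smiles()) == expected


def test_ps_linkage_contributes_one_p_one_s(library):
    seq = AsoSequence(("T", "T"))
    pattern = ModificationPattern(sugar=(DNA, DNA), linkage=(PS,),
                                  modification_type="LNA")
    counts = element_counts(build_oligo_smiles(seq, pattern))
    assert counts["P"] == 1 and counts["S"] == 1


def test_po_linkage_has_no_sulfur(library):
    seq = AsoSequence(("T", "T"))
    pattern = ModificationPattern(sugar=(DNA, DNA), linkage=(PO,),
                                  modification_type="LNA")
    counts = element_counts(build_oligo_smiles(seq, pattern))
    assert counts["P"] == 1 and "S" not in counts


def test_moe_t_is_built_as_uridine_analogue(library):
    seq = AsoSequence(("T",))
    pattern = ModificationPattern(sugar=("MOE",), linkage=(),
                                  modification_type="MOE")
    smiles = build_oligo_smiles(seq, pattern)
    mol = Chem.MolFromSmiles(smiles)
    moe_arm = Chem.MolFromSmarts("OCCOC")
    assert mol.HasSubstructMatch(moe_arm)
    # uracil ring: no methyl on C5 (thymine would add one carbon)
    thymine_methyl = Chem.MolFromSmarts("Cc1cn(*)c(=O)[nH]c1=O")
    assert not mol.HasSubstructMatch(thymine_methyl)


def test_lna_bridge_adds_one_carbon_one_oxygen_everywhere(library):
    seq = validate_sequence("GTAC")
    base_counts = element_counts(
        build_oligo_smiles(seq, pattern_from_bits([0, 0, 0, 0], "LNA"))
    )
    for pos in range(4):
        bits = [0] * 4
        bits[pos] = 1
        counts = element_counts(
            build_oligo_smiles(seq, pattern_from_bits(bits, "LNA"))
        )
        assert counts["C"] == base_counts["C"] + 1
        assert counts["O"] == base_counts["O"] + 1
        assert all(counts[k] == base_counts[k] for k in ("N", "P", "S"))


def test_assembled_heavy_atoms_are_additive(library):
    """l-mer heavy atoms = sum of residue tallies + (l-1) * linkage atoms."""
    seq = validate_sequence("GTTAC")
    pattern = pattern_from_bits([1, 1, 0, 0, 1], "MOE")
    smiles = build_oligo_smiles(seq, pattern)
    total = sum(element_counts(smiles).values())
    residues = 1  # 5'-OH cap oxygen
    for base, sugar in zip(seq.bases, pattern.sugar):
        frag = library.block(base, sugar).smiles_fragment
        residues += sum(tally_smiles_text(frag).values())
    linkage_atoms = sum(tally_smiles_text(library.linkages[PS]).values())
    assert total == residues + 4 * linkage_atoms


def test_exhaustive_smoke_all_short_sequences(library):
    """Every pattern of every sequence of length <= 3 assembles and parses."""
    for l in (1, 2, 3):
        for bases in itertools.product("ATCG", repeat=l):
            seq = AsoSequence(bases)
            for chem in ("LNA", "MOE"):
                for code in range(2**l):
                    bits = [(code >> i) & 1 for i in range(l)]
                    smiles = build_oligo_smiles(
                        seq, pattern_from_bits(bits, chem), library=library
                    )
                    graph = smiles_to_graph(smiles)
                    assert graph.is_connected()


def test_graph_adjacency_contract():
    g = smiles_to_graph("CC")
    assert g.n_atoms == 2 and len(g.bonds) == 1
    assert np.array_equal(g.adjacency, np.array([[0, 1], [1, 0]]))

    benzene = smiles_to_graph("c1ccccc1")
    assert benzene.n_atoms == 6 and len(benzene.bonds) == 6
    assert np.all(benzene.adjacency.sum(axis=1) == 2)
    assert all(a.aromatic for a in benzene.atoms)

    seq = AsoSequence(("T", "T"))
    dimer = smiles_to_graph(
        build_oligo_smiles(seq, pattern_from_bits([0, 1], "LNA"))
    )
    adj = dimer.adjacency
    assert np.array_equal(adj, adj.T)
    assert np.all(np.diag(adj) == 0)
    assert dimer.is_connected()
    # adjacency agrees with the bond list
    assert adj.sum() == 2 * len(dimer.bonds)


def test_parse_error_and_missing_fragment(library):
    with pytest.raises(ParseError):
        smiles_to_graph("not-a-molecule(((")
    with pytest.raises(MissingFragment):
        library.block("T", "2F")
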