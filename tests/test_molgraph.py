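"""Structure parsing, exchangeability and proton equivalence."""

import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from micekit.molgraph import StructureError, parse_structure


@pytest.mark.parametrize(
    "smiles, n_C, n_H, n_heavy, mass",
    [
        ("C", 1, 4, 1, 16),  # methane: smallest case
        ("CN", 1, 5, 2, 31),  # methylamine: lightest cohort member
        # para-cresol glucuronide, C13H16O7: heaviest cohort member
        ("Cc1ccc(O[C@@H]2O[C@@H](C(O)=O)[C@H](O)[C@H](O)[C@H]2O)cc1", 13, 16, 20, 284),
    ],
)
def test_elemental_counts_and_nominal_mass(smiles, n_C, n_H, n_heavy, mass):
    t = parse_structure(smiles)
    assert (t.n_C, t.n_H, t.n_heavy, t.nominal_mass) == (n_C, n_H, n_heavy, mass)


@pytest.mark.parametrize(
    "bad",
    ["", "C(", "not-a-smiles", "[CH3]", "[13CH4]"],  # parse fail / radical / isotope
)
def test_parse_rejects_invalid_and_unsupported(bad):
    with pytest.raises(StructureError):
        parse_structure(bad)


@pytest.mark.parametrize(
    "smiles, n_nonexchanging_classes",
    [
        ("CC(O)=O", 1),  # acetic acid: O-H excluded
        ("CC(=O)NCC(O)=O", 3),  # N-acetylglycine: amide N-H counts
        ("NC(=N)NCC(O)=O", 1),  # guanidoacetic: guanidino N-H exchange, CH2 only
        ("OCC(O)=O", 1),  # glycolic
        ("OS(=O)(=O)Oc1c[nH]c2ccccc12", 5),  # indoxyl sulfate: indole N-H exchanges
    ],
)
def test_exchangeability_rule(smiles, n_nonexchanging_classes):
    t = parse_structure(smiles)
    assert len(t.nonexchanging_classes) == n_nonexchanging_classes


@pytest.mark.parametrize(
    "smiles, class_sizes",
    [
        ("OC(=O)CCC(O)=O", [4]),  # succinic: one singlet of 4H
        ("OC[C@@H](C)C(O)=O", [1, 1, 1, 3]),  # 3-HIBA: diastereotopic CH2 split
        ("CC(C)(O)C(O)=O", [6]),  # 2-HIBA: equivalent methyls merge
        ("C[C@@H](O)[C@H](C)O", [2, 6]),  # meso-diol: enantiotopic CH merge
        ("CC(C)[C@](O)(CC(O)=O)C(O)=O", [1, 1, 1, 3, 3]),  # isopropyl methyls split
    ],
)
def test_equivalence_classes(smiles, class_sizes):
    t = parse_structure(smiles)
    assert sorted(c.size for c in t.nonexchanging_classes) == sorted(class_sizes)


def test_classes_partition_all_hydrogens(records):
    for r in records:
        t = r.topology
        members = [h for c in t.proton_classes for h in c.member_h_ids]
        assert len(members) == len(set(members)) == t.n_H, r.id


@pytest.mark.parametrize(
    "smiles, n_centers",
    [
        ("OC(=O)CC(O)(CC(O)=O)C(O)=O", 0),  # citric acid: prochiral only
        ("CCO", 0),
        ("C[C@H](O)C(O)=O", 1),  # lactic
        ("C[C@H]1O[C@H](O)[C@H](O)[C@@H](O)[C@H]1O", 5),  # fucopyranose anomer
        ("NC(=O)NC1NC(=O)NC1=O", 1),  # allantoin: unassigned centre counts
    ],
)
def test_stereocenter_count(smiles, n_centers):
    assert parse_structure(smiles).n_stereocenters == n_centers


def test_chiral_split_of_cohort(records):
    chiral = [r.id for r in records if r.topology.n_stereocenters >= 1]
    assert len(chiral) == 24
    assert len(records) - len(chiral) == 51


# ---------------------------------------------------------------------------
# brute-force substitution-test oracle


def _oracle_classes(smiles: str) -> list[frozenset]:
    """Independent brute-force oracle: embed, label every single hydrogen,
    compare every pair of labelled canonical forms (direct or mirrored)."""
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = 7  # deliberately different seed from the implementation
    assert AllChem.EmbedMolecule(mol, params) == 0

    def label(h_idx):
        m = Chem.Mol(mol)
        m.GetAtomWithIdx(h_idx).SetIsotope(2)  # deuterium label (impl uses tritium)
        Chem.AssignStereochemistryFrom3D(m)
        direct = Chem.MolToSmiles(m)
        flipped = Chem.Mol(m)
        for atom in flipped.GetAtoms():
            tag = atom.GetChiralTag()
            if tag == Chem.ChiralType.CHI_TETRAHEDRAL_CW:
                atom.SetChiralTag(Chem.ChiralType.CHI_TETRAHEDRAL_CCW)
            elif tag == Chem.ChiralType.CHI_TETRAHEDRAL_CCW:
                atom.SetChiralTag(Chem.ChiralType.CHI_TETRAHEDRAL_CW)
        return direct, Chem.MolToSmiles(flipped)

    h_ids = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 1]
    forms = {h: label(h) for h in h_ids}

    parent = {h: h for h in h_ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(h_ids):
        for b in h_ids[i + 1 :]:
            sa, sa_m = forms[a]
            sb, _ = forms[b]
            if sb == sa or sb == sa_m:
                parent[find(a)] = find(b)
    groups = {}
    for h in h_ids:
        groups.setdefault(find(h), set()).add(h)
    return [frozenset(g) for g in groups.values()]


def test_equivalence_agrees_with_substitution_oracle(records):
    """On every cohort molecule of <= 14 heavy atoms, the rank-pruned
    implementation and the all-pairs oracle give identical partitions of
    the hydrogen set (compared as multisets of class sizes per heavy-atom
    anchor, which is invariant to atom renumbering across embeddings)."""
    checked = 0
    for r in records:
        for form in r.forms:
            t = parse_structure(form)
            if t.n_heavy > 14:
                continue
            impl = sorted(
                (len(c.member_h_ids), tuple(sorted(c.heavy_ids))) for c in t.proton_classes
            )
            mol = t.mol
            oracle = sorted(
                (
                    len(g),
                    tuple(sorted({mol.GetAtomWithIdx(h).GetNeighbors()[0].GetIdx() for h in g})),
                )
                for g in _oracle_classes(form)
            )
            assert impl == oracle, r.id
            checked += 1
    assert checked >= 70
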