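"""Topicity of hydrogens on a molecular graph.

Two hydrogens belong to the same NMR equivalence class when they are
homotopic or enantiotopic; diastereotopic hydrogens (e.g. the CH2 protons
next to a stereocentre) resonate at distinct chemical shifts and are split
into separate classes.  The decision procedure is the classical
substitution test: replace each hydrogen in turn by a test label and
compare the resulting labelled structures — two hydrogens are equivalent
iff their labelled structures are identical or enantiomeric.

The labelled structure produced by substituting a hydrogen is a specific
stereoisomer determined by the spatial arrangement of the parent molecule,
which a connection table alone does not encode (labelling one CH2 proton of
citric acid configures two new stereocentres at once).  The test is
therefore run on a single embedded 3D conformer: the label is applied in
place and the configuration of every centre is read back from the
coordinates.  Tetrahedral configurations are conformation-independent, so
any successfully embedded conformer gives the same answer.  Embedding is
deterministic (fixed seed).
"""

from __future__ import annotations

from rdkit import Chem
from rdkit.Chem import AllChem

_EMBED_SEED = 20150127  # fixed: embedding must be reproducible
_LABEL_ISOTOPE = 3  # tritium label keeps valence and is CIP-visible


class EmbeddingError(RuntimeError):
    """Raised when no 3D conformer could be generated for a molecule."""


def embed_3d(mol: Chem.Mol) -> Chem.Mol:
    """Return a copy of ``mol`` (explicit Hs) with one 3D conformer.

    Uses ETKDG with a fixed seed; falls back to random coordinates for the
    rare pathological case.  Assigned stereo in the input is respected;
    unassigned centres are resolved arbitrarily but deterministically.
    """
    m = Chem.AddHs(Chem.Mol(mol))
    params = AllChem.ETKDGv3()
    params.randomSeed = _EMBED_SEED
    if AllChem.EmbedMolecule(m, params) == 0:
        return m
    params.useRandomCoords = True
    for bump in range(1, 6):
        params.randomSeed = _EMBED_SEED + bump
        if AllChem.EmbedMolecule(m, params) == 0:
            return m
    raise EmbeddingError(
        f"could not embed molecule {Chem.MolToSmiles(Chem.RemoveHs(mol))!r}"
    )


def _mirror(mol: Chem.Mol) -> Chem.Mol:
    """Invert every tetrahedral centre (reflection); cis/trans is unchanged."""
    m = Chem.Mol(mol)
    for atom in m.GetAtoms():
        tag = atom.GetChiralTag()
        if tag == Chem.ChiralType.CHI_TETRAHEDRAL_CW:
            atom.SetChiralTag(Chem.ChiralType.CHI_TETRAHEDRAL_CCW)
        elif tag == Chem.ChiralType.CHI_TETRAHEDRAL_CCW:
            atom.SetChiralTag(Chem.ChiralType.CHI_TETRAHEDRAL_CW)
    return m


def labelled_canonical(mol3d: Chem.Mol, h_idx: int) -> tuple[str, str]:
    """Canonical SMILES of the molecule with hydrogen ``h_idx`` labelled,
    and of its mirror image.

    ``mol3d`` must carry explicit hydrogens and a conformer (``embed_3d``).
    """
    m = Chem.Mol(mol3d)
    atom = m.GetAtomWithIdx(h_idx)
    if atom.GetAtomicNum() != 1:
        raise ValueError(f"atom {h_idx} is not a hydrogen")
    atom.SetIsotope(_LABEL_ISOTOPE)
    Chem.AssignStereochemistryFrom3D(m)
    smi = Chem.MolToSmiles(m)
    smi_mirror = Chem.MolToSmiles(_mirror(m))
    return smi, smi_mirror


def same_class(mol3d: Chem.Mol, h_a: int, h_b: int) -> bool:
    """Substitution test for one hydrogen pair on a shared conformer."""
    sa, sa_mirror = labelled_canonical(mol3d, h_a)
    sb, _ = labelled_canonical(mol3d, h_b)
    return sb == sa or sb == sa_mirror


def hydrogen_classes(mol: Chem.Mol) -> list[tuple[int, ...]]:
    """Partition all hydrogens of ``mol`` into NMR equivalence classes.

    ``mol`` must carry explicit hydrogens.  Constitutional symmetry classes
    (canonical ranks, stereo-agnostic) are computed first; only hydrogens
    sharing a constitutional class can be topicity-equivalent, so the
    substitution test is run within those classes only.  Classes are
    returned sorted by the minimum canonical rank of their members, which
    fixes the ordering deterministically.
    """
    mol3d = embed_3d(mol)
    ranks = list(Chem.CanonicalRankAtoms(mol3d, breakTies=False, includeChirality=False))
    tie_ranks = list(Chem.CanonicalRankAtoms(mol3d, breakTies=True, includeChirality=False))

    by_const: dict[int, list[int]] = {}
    for atom in mol3d.GetAtoms():
        if atom.GetAtomicNum() == 1:
            by_const.setdefault(ranks[atom.GetIdx()], []).append(atom.GetIdx())

    classes: list[list[int]] = []
    for members in by_const.values():
        members = sorted(members, key=lambda i: tie_ranks[i])
        if len(members) == 1:
            classes.append(members)
            continue
        # union-find by pairwise substitution test against class representatives
        subclasses: list[tuple[str, str, list[int]]] = []
        for h in members:
            smi, smi_mirror = labelled_canonical(mol3d, h)
            for rep_smi, rep_mirror, made in subclasses:
                if smi == rep_smi or smi == rep_mirror:
                    made.append(h)
                    break
            else:
                subclasses.append((smi, smi_mirror, [h]))
        classes.extend(made for _, _, made in subclasses)

    classes.sort(key=lambda c: min(tie_ranks[i] for i in c))
    return [tuple(c) for c in classes]
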