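"""Molecular topology for NMR information counting.

Parses metabolite structures (SMILES or InChI) and derives everything the
counting rules need: elemental composition and nominal mass, tetrahedral
stereocentres, hydrogen exchangeability, and proton equivalence classes
(homotopic/enantiotopic merged, diastereotopic split).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import cached_property

from rdkit import Chem

from .topicity import hydrogen_classes

# integer mass of the most abundant isotope, for the elements of this cohort
_NOMINAL_MASS = {"H": 1, "C": 12, "N": 14, "O": 16, "S": 32}


class StructureError(ValueError):
    """Raised for unparsable or unsupported structure input."""


@dataclass(frozen=True)
class ProtonClass:
    """A set of symmetry-equivalent hydrogens (one NMR resonance)."""

    member_h_ids: tuple[int, ...]
    exchangeable: bool
    bound_element: str
    heavy_ids: tuple[int, ...]  # heavy atoms the members attach to
    diastereotopic_partner: int | None = None  # index of the sibling class

    @property
    def size(self) -> int:
        return len(self.member_h_ids)


@dataclass
class MolecularTopology:
    """Parsed structure plus the proton topology used by every rule."""

    mol: Chem.Mol  # explicit hydrogens
    source: str  # the input line notation
    proton_classes: list[ProtonClass] = field(default_factory=list)

    # -- elemental composition -------------------------------------------
    def _count(self, symbol: str) -> int:
        return sum(1 for a in self.mol.GetAtoms() if a.GetSymbol() == symbol)

    @cached_property
    def n_H(self) -> int:
        return self._count("H")

    @cached_property
    def n_C(self) -> int:
        return self._count("C")

    @cached_property
    def n_N(self) -> int:
        return self._count("N")

    @cached_property
    def n_O(self) -> int:
        return self._count("O")

    @cached_property
    def n_S(self) -> int:
        return self._count("S")

    @cached_property
    def n_heavy(self) -> int:
        return sum(1 for a in self.mol.GetAtoms() if a.GetAtomicNum() > 1)

    @cached_property
    def nominal_mass(self) -> int:
        try:
            return sum(_NOMINAL_MASS[a.GetSymbol()] for a in self.mol.GetAtoms())
        except KeyError as exc:  # pragma: no cover - cohort is CHNOS only
            raise StructureError(f"no nominal mass for element {exc}") from exc

    @cached_property
    def n_stereocenters(self) -> int:
        return count_stereocenters(self)

    # -- graph helpers ----------------------------------------------------
    @cached_property
    def distance(self):
        """Topological (bond-count) distance matrix, explicit-H graph."""
        from rdkit.Chem import rdmolops

        return rdmolops.GetDistanceMatrix(self.mol)

    @cached_property
    def carbon_orbits(self) -> list[tuple[int, ...]]:
        """Constitutional symmetry classes of the carbon atoms."""
        ranks = Chem.CanonicalRankAtoms(self.mol, breakTies=False, includeChirality=False)
        orbits: dict[int, list[int]] = {}
        for atom in self.mol.GetAtoms():
            if atom.GetSymbol() == "C":
                orbits.setdefault(ranks[atom.GetIdx()], []).append(atom.GetIdx())
        return [tuple(sorted(v)) for _, v in sorted(orbits.items())]

    @property
    def nonexchanging_classes(self) -> list[ProtonClass]:
        return [c for c in self.proton_classes if not c.exchangeable]


def parse_structure(line_notation: str) -> MolecularTopology:
    """Parse a SMILES (or InChI) string into a :class:`MolecularTopology`.

    Raises :class:`StructureError` on parse failure and for radical or
    isotopically labelled species, which the counting rules do not cover.
    The returned topology has exchangeability classified and proton
    equivalence classes computed.
    """
    text = line_notation.strip()
    if not text:
        raise StructureError("empty structure string")
    if text.startswith("InChI="):
        mol = Chem.MolFromInchi(text)
    else:
        mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise StructureError(f"could not parse structure {text!r}")
    for atom in mol.GetAtoms():
        if atom.GetNumRadicalElectrons():
            raise StructureError(f"radical species unsupported: {text!r}")
        if atom.GetIsotope():
            raise StructureError(f"isotope-labelled species unsupported: {text!r}")
    Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
    molh = Chem.AddHs(mol)
    topo = MolecularTopology(mol=molh, source=text)
    classify_exchangeable(topo)
    topo.proton_classes = proton_equivalence_classes(topo)
    return topo


def _is_amide_nitrogen(atom: Chem.Atom) -> bool:
    """N single-bonded to a carbonyl carbon (C=O)."""
    for bond in atom.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        nbr = bond.GetOtherAtom(atom)
        if nbr.GetSymbol() != "C":
            continue
        for b2 in nbr.GetBonds():
            if (
                b2.GetBondType() == Chem.BondType.DOUBLE
                and b2.GetOtherAtom(nbr).GetSymbol() == "O"
            ):
                return True
    return False


def classify_exchangeable(
    topo: MolecularTopology, overrides: dict[int, bool] | None = None
) -> MolecularTopology:
    """Mark every hydrogen exchangeable or not (stored as an atom property).

    Structural rule: O-H and S-H always exchange; N-H exchanges unless the
    nitrogen is an amide nitrogen (amide N-H is slow to exchange on the NMR
    timescale and is observable in aqueous biofluids); C-H never exchanges.
    ``overrides`` maps hydrogen atom indices to a forced flag.
    """
    overrides = overrides or {}
    for atom in topo.mol.GetAtoms():
        if atom.GetAtomicNum() != 1:
            continue
        heavy = atom.GetNeighbors()[0]
        sym = heavy.GetSymbol()
        if sym in ("O", "S"):
            exch = True
        elif sym == "N":
            exch = not _is_amide_nitrogen(heavy)
        else:
            exch = False
        if atom.GetIdx() in overrides:
            exch = overrides[atom.GetIdx()]
        atom.SetBoolProp("exchangeable", exch)
    return topo


def proton_equivalence_classes(topo: MolecularTopology) -> list[ProtonClass]:
    """Group hydrogens into NMR equivalence classes via the substitution test.

    Homotopic and enantiotopic hydrogens share a class; diastereotopic
    hydrogens are split.  Every hydrogen lands in exactly one class; class
    order is fixed by canonical atom ranks.
    """
    mol = topo.mol
    raw = hydrogen_classes(mol)
    classes: list[ProtonClass] = []
    for members in raw:
        heavies = tuple(sorted({mol.GetAtomWithIdx(h).GetNeighbors()[0].GetIdx() for h in members}))
        bound = mol.GetAtomWithIdx(heavies[0]).GetSymbol()
        exch_flags = {mol.GetAtomWithIdx(h).GetBoolProp("exchangeable") for h in members}
        if len(exch_flags) != 1:  # pragma: no cover - symmetry implies agreement
            raise StructureError("equivalence class mixes exchangeability flags")
        classes.append(
            ProtonClass(
                member_h_ids=tuple(sorted(members)),
                exchangeable=exch_flags.pop(),
                bound_element=bound,
                heavy_ids=heavies,
            )
        )
    # mark diastereotopic geminal siblings: two singleton classes on one carbon
    by_heavy: dict[tuple[int, ...], list[int]] = {}
    for i, cls in enumerate(classes):
        by_heavy.setdefault(cls.heavy_ids, []).append(i)
    for siblings in by_heavy.values():
        if len(siblings) == 2:
            a, b = siblings
            classes[a] = ProtonClass(
                **{**classes[a].__dict__, "diastereotopic_partner": b}
            )
            classes[b] = ProtonClass(
                **{**classes[b].__dict__, "diastereotopic_partner": a}
            )
    return classes


def count_stereocenters(topo: MolecularTopology) -> int:
    """Number of tetrahedral carbon stereocentres (assigned or not).

    Anomeric carbons count; double-bond stereo and stereogenic S/N do not
    (the chiral/non-chiral partition of the cohort is defined on carbon
    centres only).
    """
    centers = Chem.FindMolChiralCenters(
        topo.mol, includeUnassigned=True, useLegacyImplementation=False
    )
    return sum(1 for idx, _ in centers if topo.mol.GetAtomWithIdx(idx).GetSymbol() == "C")


# ---------------------------------------------------------------------------
# metabolite records


@dataclass
class MetaboliteRecord:
    """One metabolite of the cohort table."""

    id: str
    common_name: str
    iupac_name: str = ""
    hmdb_accession: str = ""
    class_label: str = ""
    forms: tuple[str, ...] = ()
    fragment_annotations: dict[str, tuple[str, ...]] | None = None
    overrides: dict | None = None

    def __post_init__(self):
        if not self.forms:
            raise ValueError(f"record {self.id}: at least one structure form required")

    @cached_property
    def topologies(self) -> list[MolecularTopology]:
        topos = [parse_structure(f) for f in self.forms]
        formulas = {(t.n_C, t.n_H, t.n_N, t.n_O, t.n_S) for t in topos}
        if len(formulas) != 1:
            raise StructureError(
                f"record {self.id}: forms disagree on molecular formula"
            )
        return topos

    @property
    def topology(self) -> MolecularTopology:
        """Primary form; elemental denominators always come from one form."""
        return self.topologies[0]


def read_metabolite_table(path) -> list[MetaboliteRecord]:
    """Read the metabolite table TSV.

    Columns: id, common_name, iupac_name, hmdb_accession, class_label,
    smiles (semicolon-separated for multiple forms), and optional
    overrides_json / fragments_json.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    required = {"id", "common_name", "class_label", "smiles"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metabolite table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        overrides = json.loads(row.overrides_json) if getattr(row, "overrides_json", "") else None
        fragments = None
        if getattr(row, "fragments_json", ""):
            fragments = {
                k: tuple(v) for k, v in json.loads(row.fragments_json).items()
            }
        records.append(
            MetaboliteRecord(
                id=row.id,
                common_name=row.common_name,
                iupac_name=getattr(row, "iupac_name", ""),
                hmdb_accession=getattr(row, "hmdb_accession", ""),
                class_label=row.class_label,
                forms=tuple(s.strip() for s in row.smiles.split(";") if s.strip()),
                fragment_annotations=fragments,
                overrides=overrides,
            )
        )
    return records
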