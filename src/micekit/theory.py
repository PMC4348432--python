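"""Theoretical spectroscopic feature counting.

From a molecule's proton topology, counts the seven spectroscopic features
that carry metabolite identification information in ¹H-detected NMR:
chemical shifts, multiplicities, 2-/3-bond H,H coupling constants, a
second-order flag, and COSY/HSQC/HMBC cross-peaks.  The counts roll up
into cumulative bit totals for the four evidence levels (1D ¹H alone, plus
COSY, plus HSQC, plus HMBC).

Counting conventions:

* Only non-exchanging protons are counted (amide N-H counts; O-H, S-H and
  amine/guanidine-type N-H do not).
* One multiplicity per resonance, however complex the multiplet.
* A coupling is a pair of distinct proton classes separated by a 2- or
  3-bond path; longer-range couplings never count theoretically.
* Each theoretical COSY cross-peak corresponds to exactly one counted
  coupling, so the two counts are identical by construction.
* HSQC: one cross-peak per (proton class, carbon orbit) pair —
  diastereotopic CH2 protons give two peaks, symmetry-equivalent carbons
  give one.
* HMBC: one cross-peak per (carbon orbit, proton class) pair with a 2- or
  3-bond C→H path.  Cross-peaks between pseudo-equivalent groups (e.g.
  methyl carbon to the other methyls' protons in trimethylamine) are real
  and count; pairs whose only relationship is the one-bond HSQC pairing do
  not.
* The second-order flag is topological: it is set when some proton class
  contains hydrogens that are chemically equivalent yet magnetically
  inequivalent, i.e. at unequal coupling distance from a proton outside
  the class (AA'BB'-type systems).
* For sugars present as an anomeric mixture, feature counts are summed
  over both anomers.
"""

from __future__ import annotations

from dataclasses import dataclass

from .molgraph import MetaboliteRecord, MolecularTopology, ProtonClass

COUPLING_PATH_LENGTHS = (2, 3)

#: the four NMR evidence levels, in cumulative order
LEVELS = ("1d", "cosy", "hsqc", "hmbc")
LEVEL_TITLES = {
    "1d": "1D 1H NMR",
    "cosy": "1D 1H plus COSY",
    "hsqc": "1D 1H plus COSY and HSQC",
    "hmbc": "1D 1H plus COSY, HSQC and HMBC",
}


@dataclass(frozen=True)
class SpectralFeatureCounts:
    """The seven counted spectroscopic features for one metabolite."""

    n_shifts: int
    n_multiplicities: int
    n_couplings: int
    second_order_flag: int
    n_cosy: int
    n_hsqc: int
    n_hmbc: int
    provenance: str = "theoretical"  # or "observed"
    nmr_invisible: bool = False  # no non-exchanging protons at all

    FEATURE_FIELDS = (
        "n_shifts",
        "n_multiplicities",
        "n_couplings",
        "second_order_flag",
        "n_cosy",
        "n_hsqc",
        "n_hmbc",
    )

    def __post_init__(self):
        for name in self.FEATURE_FIELDS:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.second_order_flag not in (0, 1):
            raise ValueError("second_order_flag must be 0 or 1")

    def __add__(self, other: "SpectralFeatureCounts") -> "SpectralFeatureCounts":
        if self.provenance != other.provenance:
            raise ValueError("cannot sum counts of different provenance")
        return SpectralFeatureCounts(
            n_shifts=self.n_shifts + other.n_shifts,
            n_multiplicities=self.n_multiplicities + other.n_multiplicities,
            n_couplings=self.n_couplings + other.n_couplings,
            second_order_flag=max(self.second_order_flag, other.second_order_flag),
            n_cosy=self.n_cosy + other.n_cosy,
            n_hsqc=self.n_hsqc + other.n_hsqc,
            n_hmbc=self.n_hmbc + other.n_hmbc,
            provenance=self.provenance,
            nmr_invisible=self.nmr_invisible and other.nmr_invisible,
        )


@dataclass(frozen=True)
class LevelBits:
    """Cumulative identification-information bit totals per evidence level."""

    bits_1d: int
    bits_cosy: int
    bits_hsqc: int
    bits_hmbc: int

    def __post_init__(self):
        if not (self.bits_1d <= self.bits_cosy <= self.bits_hsqc <= self.bits_hmbc):
            raise ValueError("level bits must be cumulative (non-decreasing)")

    def at(self, level: str) -> int:
        return getattr(self, f"bits_{level}")

    def as_dict(self) -> dict[str, int]:
        return {level: self.at(level) for level in LEVELS}


def level_bits(counts: SpectralFeatureCounts) -> LevelBits:
    """Roll the seven feature counts up into the four cumulative levels."""
    b = (
        counts.n_shifts
        + counts.n_multiplicities
        + counts.n_couplings
        + counts.second_order_flag
    )
    c = b + counts.n_cosy
    d = c + counts.n_hsqc
    e = d + counts.n_hmbc
    return LevelBits(bits_1d=b, bits_cosy=c, bits_hsqc=d, bits_hmbc=e)


# ---------------------------------------------------------------------------
# per-form counting


def count_shifts_and_multiplicities(topo: MolecularTopology) -> tuple[int, int]:
    """Number of resonances and of multiplet labels (equal by convention)."""
    n = len(topo.nonexchanging_classes)
    return n, n


def _class_pair_min_distance(topo: MolecularTopology, a: ProtonClass, b: ProtonClass) -> int:
    d = topo.distance
    return int(min(d[i][j] for i in a.member_h_ids for j in b.member_h_ids))


def count_couplings(topo: MolecularTopology) -> int:
    """Pairs of distinct non-exchanging proton classes 2 or 3 bonds apart."""
    classes = topo.nonexchanging_classes
    n = 0
    for i in range(len(classes)):
        for j in range(i + 1, len(classes)):
            if _class_pair_min_distance(topo, classes[i], classes[j]) in COUPLING_PATH_LENGTHS:
                n += 1
    return n


def second_order_flag(topo: MolecularTopology) -> int:
    """1 iff some class is chemically equivalent but magnetically inequivalent.

    Detected topologically: hydrogens a, a' share a class while a proton b
    outside the class sits at a coupling distance (2-3 bonds) from a but
    not from a'.
    """
    d = topo.distance
    classes = topo.nonexchanging_classes
    for cls in classes:
        if cls.size < 2:
            continue
        others = [h for c in classes if c is not cls for h in c.member_h_ids]
        for b in others:
            dists = {d[a][b] in COUPLING_PATH_LENGTHS for a in cls.member_h_ids}
            if len(dists) == 2:
                return 1
    return 0


def count_hsqc(topo: MolecularTopology) -> int:
    """Distinct (non-exchanging proton class, attached carbon orbit) pairs."""
    orbit_of = {}
    for k, orbit in enumerate(topo.carbon_orbits):
        for idx in orbit:
            orbit_of[idx] = k
    pairs = set()
    for i, cls in enumerate(topo.nonexchanging_classes):
        if cls.bound_element != "C":
            continue
        for heavy in cls.heavy_ids:
            pairs.add((i, orbit_of[heavy]))
    return len(pairs)


def count_hmbc(topo: MolecularTopology) -> int:
    """Distinct (carbon orbit, proton class) pairs with a 2-/3-bond path."""
    d = topo.distance
    n = 0
    for orbit in topo.carbon_orbits:
        for cls in topo.nonexchanging_classes:
            if any(
                d[c][h] in COUPLING_PATH_LENGTHS
                for c in orbit
                for h in cls.member_h_ids
            ):
                n += 1
    return n


def form_counts(topo: MolecularTopology) -> SpectralFeatureCounts:
    """The seven theoretical feature counts for a single structural form."""
    n_shifts, n_mult = count_shifts_and_multiplicities(topo)
    n_j = count_couplings(topo)
    return SpectralFeatureCounts(
        n_shifts=n_shifts,
        n_multiplicities=n_mult,
        n_couplings=n_j,
        second_order_flag=second_order_flag(topo),
        n_cosy=n_j,  # one theoretical COSY cross-peak per counted coupling
        n_hsqc=count_hsqc(topo),
        n_hmbc=count_hmbc(topo),
        provenance="theoretical",
        nmr_invisible=n_shifts == 0,
    )


def theoretical_profile(record: MetaboliteRecord) -> SpectralFeatureCounts:
    """Feature counts for a metabolite, summed over its structural forms.

    Sugars observed as an anomeric mixture carry both anomers' features.
    A curated override on the record replaces the algorithmic counts
    wholesale (all seven features must be present).
    """
    if record.overrides is not None:
        missing = [f for f in SpectralFeatureCounts.FEATURE_FIELDS if f not in record.overrides]
        if missing:
            raise ValueError(f"record {record.id}: override missing {missing}")
        return SpectralFeatureCounts(
            **{f: int(record.overrides[f]) for f in SpectralFeatureCounts.FEATURE_FIELDS},
            provenance="theoretical",
        )
    total = None
    for topo in record.topologies:
        counts = form_counts(topo)
        total = counts if total is None else total + counts
    return total


def theoretical_level_bits(record: MetaboliteRecord) -> LevelBits:
    return level_bits(theoretical_profile(record))
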