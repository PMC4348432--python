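"""Matching observed values to reference (database/literature) data.

Pairing is by assignment label, not by nearest value: in crowded spectral
regions nearest-value pairing happily cross-assigns peaks from different
metabolites, so the assigned-label route is the default and a nearest-match
mode is offered only for unassigned peak lists, documented as a heuristic.
Values exactly on a tolerance boundary pass ("within ±"); the comparison
carries a relative epsilon so that values equal at the printed precision
are not failed by binary floating point (0.03 must not lose to 4.57-4.54).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .molgraph import MetaboliteRecord
from .observed import ObservedFeatureSet

_REL_EPS = 1e-9


def _within(delta: float, tolerance: float) -> bool:
    return delta <= tolerance * (1.0 + _REL_EPS) + 1e-12


@dataclass(frozen=True)
class MatchTolerances:
    """Published fit tolerances for database comparison."""

    d_h: float = 0.03  # 1H shift, ppm
    d_c: float = 0.5  # 13C shift, ppm
    d_j: float = 0.2  # proton coupling, Hz

    def __post_init__(self):
        if min(self.d_h, self.d_c, self.d_j) <= 0:
            raise ValueError("tolerances must be positive")


@dataclass(frozen=True)
class ReferenceEntry:
    """Literature/database values for one metabolite, by assignment label."""

    metabolite_id: str
    source: str = ""
    h_shifts: dict[str, float] = field(default_factory=dict)
    c_shifts: dict[str, float] = field(default_factory=dict)
    couplings: dict[frozenset, float] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: dict) -> "ReferenceEntry":
        return cls(
            metabolite_id=data["metabolite_id"],
            source=data.get("source", ""),
            h_shifts={e["assignment"]: float(e["ppm"]) for e in data.get("h_shifts", [])},
            c_shifts={e["assignment"]: float(e["ppm"]) for e in data.get("c_shifts", [])},
            couplings={
                frozenset(e["assignment"]): float(e["hz"])
                for e in data.get("couplings", [])
            },
        )


@dataclass(frozen=True)
class MatchRecord:
    kind: str  # "1H" | "13C" | "J"
    assignment: str
    observed: float
    reference: float
    delta: float
    within: bool


@dataclass
class MatchReport:
    records: list[MatchRecord]
    unpaired: list[str]

    @property
    def n_matched(self) -> int:
        return sum(r.within for r in self.records)

    @property
    def n_failed(self) -> int:
        return sum(not r.within for r in self.records)

    @property
    def match_ok(self) -> bool:
        return self.n_failed == 0


def match_features(
    observed: ObservedFeatureSet,
    reference: ReferenceEntry,
    tol: MatchTolerances = MatchTolerances(),
) -> MatchReport:
    """Compare every labelled observed value with its reference counterpart.

    ¹H shifts, ¹³C shifts (from HSQC peaks) and couplings each use their
    own tolerance.  Observations without a reference counterpart are listed
    as unpaired, not failed.  Raises when no assignment is shared at all.
    """
    records: list[MatchRecord] = []
    unpaired: list[str] = []

    for s in observed.shifts:
        ref = reference.h_shifts.get(s.assignment)
        if ref is None:
            unpaired.append(f"1H {s.assignment}")
            continue
        d = abs(s.ppm - ref)
        records.append(MatchRecord("1H", s.assignment, s.ppm, ref, d, _within(d, tol.d_h)))
    for p in observed.hsqc:
        ref = reference.c_shifts.get(p.assignment)
        if ref is None:
            unpaired.append(f"13C {p.assignment}")
            continue
        d = abs(p.c_ppm - ref)
        records.append(MatchRecord("13C", p.assignment, p.c_ppm, ref, d, _within(d, tol.d_c)))
    for c in observed.couplings:
        key = frozenset(c.assignment)
        ref = reference.couplings.get(key)
        if ref is None:
            unpaired.append(f"J {'-'.join(sorted(c.assignment))}")
            continue
        d = abs(c.hz - ref)
        records.append(
            MatchRecord("J", "-".join(sorted(c.assignment)), c.hz, ref, d, _within(d, tol.d_j))
        )

    if not records and (observed.shifts or observed.hsqc or observed.couplings):
        raise ValueError(
            f"no shared assignments between observation and reference "
            f"{reference.source or reference.metabolite_id!r}"
        )
    return MatchReport(records=records, unpaired=unpaired)


def nearest_match(
    observed_values: list[float], reference_values: list[float], tolerance: float
) -> list[tuple[float, float, bool]]:
    """Heuristic pairing for unassigned peak lists: each observed value is
    paired with the nearest reference value.  Prone to mis-pairing in
    crowded regions; prefer assigned-label matching."""
    out = []
    for v in observed_values:
        ref = min(reference_values, key=lambda r: abs(r - v))
        out.append((v, ref, _within(abs(v - ref), tolerance)))
    return out


def assess_coverage(
    observed: ObservedFeatureSet, record: MetaboliteRecord
) -> tuple[float, bool]:
    """Fraction of annotated molecular fragments touched by observed data.

    Fragments are named sets of assignment labels (default: the whole
    molecule as a single fragment, covered by any observation at all).
    Coverage is complete only when every fragment carries at least one
    observed bit.
    """
    observed_labels = (
        {s.assignment for s in observed.shifts}
        | {m.assignment for m in observed.multiplicities}
        | {a for c in observed.couplings for a in c.assignment}
        | {a for pair in observed.cosy for a in pair}
        | {p.assignment for p in observed.hsqc}
        | {p.h_assignment for p in observed.hmbc}
    )
    fragments = record.fragment_annotations
    if not fragments:
        frac = 1.0 if observed_labels else 0.0
        return frac, bool(observed_labels)
    covered = sum(
        1 for labels in fragments.values() if observed_labels & set(labels)
    )
    frac = covered / len(fragments)
    return frac, frac == 1.0
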