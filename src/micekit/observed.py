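"""Experimentally observed spectroscopic features.

Schema-validated containers for the features actually read off 1D and 2D
spectra of a biofluid: shifts (ppm), multiplicity labels, coupling
constants (Hz), COSY/HSQC/HMBC cross-peak lists, and free-form evidence
annotations (long-range couplings, heteronuclear couplings) that support
an identification without contributing countable bits.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, ConfigDict, field_validator

from .theory import SpectralFeatureCounts

EVIDENCE_KINDS = (
    "long_range_cosy",
    "long_range_coupling",
    "heteronuclear_coupling",
    "literature_note",
)


class EvidenceItem(BaseModel):
    """Supporting observation that carries no identification bit."""

    model_config = ConfigDict(extra="forbid")

    kind: Literal[EVIDENCE_KINDS]
    description: str = ""
    value_hz: float | None = None


class ObservedShift(BaseModel):
    model_config = ConfigDict(extra="forbid")
    ppm: float
    assignment: str

    @field_validator("ppm")
    @classmethod
    def _finite(cls, v):
        if not math.isfinite(v):
            raise ValueError("ppm must be finite")
        return v


class ObservedMultiplicity(BaseModel):
    model_config = ConfigDict(extra="forbid")
    assignment: str
    label: str  # s, d, t, q, dd, m, ...


class ObservedCoupling(BaseModel):
    model_config = ConfigDict(extra="forbid")
    assignment: tuple[str, str]
    hz: float

    @field_validator("hz")
    @classmethod
    def _nonneg(cls, v):
        if not math.isfinite(v) or v < 0:
            raise ValueError("coupling must be finite and >= 0 Hz")
        return v


class HsqcPeak(BaseModel):
    model_config = ConfigDict(extra="forbid")
    h_ppm: float
    c_ppm: float
    assignment: str


class HmbcPeak(BaseModel):
    model_config = ConfigDict(extra="forbid")
    c_ppm: float
    h_assignment: str


class ObservedFeatureSet(BaseModel):
    """Everything observed for one metabolite in one study."""

    model_config = ConfigDict(extra="forbid")

    metabolite_id: str
    shifts: list[ObservedShift] = []
    multiplicities: list[ObservedMultiplicity] = []
    couplings: list[ObservedCoupling] = []
    cosy: list[tuple[str, str]] = []
    hsqc: list[HsqcPeak] = []
    hmbc: list[HmbcPeak] = []
    second_order: bool = False
    evidence: list[EvidenceItem] = []
    note: str = ""

    def _cosy_dedup(self) -> set[frozenset]:
        return {frozenset(pair) for pair in self.cosy}

    def _hsqc_dedup(self) -> set[tuple]:
        return {(p.assignment, p.c_ppm) for p in self.hsqc}

    def _hmbc_dedup(self) -> set[tuple]:
        return {(p.c_ppm, p.h_assignment) for p in self.hmbc}


class ObservationFile(BaseModel):
    model_config = ConfigDict(extra="allow")  # tolerate a comment/provenance key
    schema_version: int = 1
    observations: list[ObservedFeatureSet] = []


def read_observations(path, known_ids: list[str] | None = None) -> list[ObservedFeatureSet]:
    """Read and validate an observation JSON file.

    When ``known_ids`` is given, any observation referencing an unknown
    metabolite id raises, listing the known ids.
    """
    data = json.loads(Path(path).read_text())
    parsed = ObservationFile.model_validate(data)
    if known_ids is not None:
        known = set(known_ids)
        for obs in parsed.observations:
            if obs.metabolite_id not in known:
                raise KeyError(
                    f"unknown metabolite_id {obs.metabolite_id!r}; known ids: "
                    f"{sorted(known)}"
                )
    return parsed.observations


def tally_observed(obs: ObservedFeatureSet) -> SpectralFeatureCounts:
    """Primed feature counts from an observed feature set.

    Distinct resonances, labelled multiplets and measured couplings are
    counted; cross-peak lists are deduplicated first.  Long-range COSY
    peaks, long-range couplings and heteronuclear couplings live in
    ``evidence`` and never contribute bits.
    """
    distinct_shifts = {s.assignment for s in obs.shifts}
    labelled = {m.assignment for m in obs.multiplicities if m.label}
    return SpectralFeatureCounts(
        n_shifts=len(distinct_shifts),
        n_multiplicities=len(labelled),
        n_couplings=len({(frozenset(c.assignment), c.hz) for c in obs.couplings}),
        second_order_flag=int(obs.second_order),
        n_cosy=len(obs._cosy_dedup()),
        n_hsqc=len(obs._hsqc_dedup()),
        n_hmbc=len(obs._hmbc_dedup()),
        provenance="observed",
        nmr_invisible=not obs.shifts,
    )


def validate_vs_theory(
    observed: SpectralFeatureCounts, theoretical: SpectralFeatureCounts
) -> list[str]:
    """Warnings for every feature observed in excess of theory."""
    warnings = []
    for name in SpectralFeatureCounts.FEATURE_FIELDS:
        o, t = getattr(observed, name), getattr(theoretical, name)
        if o > t:
            warnings.append(
                f"{name}: observed {o} exceeds theoretical {t} (over-observation)"
            )
    return warnings
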