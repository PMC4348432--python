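"""Identification-efficiency metrics and the confidence call.

MIE  = identification information bits / heavy atoms
MICE = identification information bits / carbon atoms
MIHF = observed bits / theoretically available bits

All three are computed per evidence level.  The confidence guideline is
anchored at the 1D ¹H + COSY + HSQC level, the routine operating point of
urinary metabolomics: an identification is *confident* when the reference
match is precise, the observed data cover the whole molecule, and either
the efficiency clears the guideline thresholds (MICE >= 1 or MIE > 0.5)
or orthogonal ¹³C-carrying data (HSQC/HMBC cross-peaks) or a diagnostic
piece of evidence (a long-range or heteronuclear coupling) backs it up.
Otherwise the metabolite is only *putatively annotated*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .observed import EvidenceItem
from .theory import LEVELS, LevelBits, SpectralFeatureCounts

REFERENCE_LEVEL = "hsqc"  # 1D 1H + COSY + HSQC

CONFIDENT = "confidently_identified"
PUTATIVE = "putatively_annotated"

#: evidence kinds that can rescue a low-efficiency identification
DIAGNOSTIC_EVIDENCE = ("long_range_cosy", "long_range_coupling", "heteronuclear_coupling")


def round_reported(x: float, ndigits: int = 1) -> float:
    """Round half away from zero, the convention of the printed tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def mie(bits: int, n_heavy: int) -> float:
    """Metabolite identification efficiency: bits per heavy atom."""
    if n_heavy < 1:
        raise ZeroDivisionError("MIE undefined: heavy-atom count must be >= 1")
    return bits / n_heavy


def mice(bits: int, n_c: int) -> float:
    """Metabolite identification carbon efficiency: bits per carbon."""
    if n_c < 1:
        raise ZeroDivisionError("MICE undefined: carbon count must be >= 1")
    return bits / n_c


def mihf(nmii_o: int, nmii_t: int) -> float:
    """Metabolite identification hydrogen fraction: observed/theoretical bits."""
    if nmii_t < 1:
        raise ZeroDivisionError("MIHF undefined: theoretical bits must be >= 1")
    return nmii_o / nmii_t


@dataclass(frozen=True)
class EfficiencyScores:
    """MIE/MICE (and optionally MIHF) at one evidence level."""

    level: str
    bits: int
    mie: float
    mice: float
    mihf: float | None = None
    provenance: str = "theoretical"

    def __post_init__(self):
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")


def efficiency_scores(
    bits: LevelBits,
    n_heavy: int,
    n_c: int,
    theoretical_bits: LevelBits | None = None,
    provenance: str = "theoretical",
) -> dict[str, EfficiencyScores]:
    """Scores at all four levels; MIHF when theoretical totals are supplied."""
    out = {}
    for level in LEVELS:
        b = bits.at(level)
        frac = None
        if theoretical_bits is not None and theoretical_bits.at(level) >= 1:
            frac = mihf(b, theoretical_bits.at(level))
        out[level] = EfficiencyScores(
            level=level,
            bits=b,
            mie=mie(b, n_heavy),
            mice=mice(b, n_c),
            mihf=frac,
            provenance=provenance,
        )
    return out


@dataclass(frozen=True)
class Thresholds:
    """Guideline cut-offs, configurable but defaulting to the published ones."""

    mice_min: float = 1.0  # confident when MICE >= this ...
    mie_min: float = 0.5  # ... or MIE strictly above this


@dataclass
class ConfidenceCall:
    label: str
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.reasons:
            raise ValueError("a confidence call must carry its reasons")


def classify_confidence(
    scores: EfficiencyScores,
    counts: SpectralFeatureCounts,
    evidence: list[EvidenceItem] | None = None,
    coverage_ok: bool = True,
    match_ok: bool = True,
    thresholds: Thresholds = Thresholds(),
) -> ConfidenceCall:
    """Confident vs putatively-annotated call at the reference level.

    ``scores`` must be the observed scores at the 1D+COSY+HSQC level;
    ``counts`` the observed feature counts; ``evidence`` the supporting
    annotations.  Reasons record every clause that fired, pass or fail.
    """
    if scores.level != REFERENCE_LEVEL:
        raise ValueError(
            f"confidence is judged at the {REFERENCE_LEVEL!r} level, got {scores.level!r}"
        )
    evidence = evidence or []
    reasons: list[str] = []
    gate_ok = True
    if not match_ok:
        gate_ok = False
        reasons.append("reference match failed (values outside tolerance)")
    else:
        reasons.append("reference match within tolerance")
    if not coverage_ok:
        gate_ok = False
        reasons.append("molecular coverage incomplete")
    else:
        reasons.append("molecular coverage complete")

    mice_ok = scores.mice >= thresholds.mice_min
    mie_ok = scores.mie > thresholds.mie_min
    reasons.append(
        f"MICE {round_reported(scores.mice)} {'>=' if mice_ok else '<'} {thresholds.mice_min}"
    )
    reasons.append(
        f"MIE {round_reported(scores.mie)} {'>' if mie_ok else '<='} {thresholds.mie_min}"
    )
    orthogonal = counts.n_hsqc >= 1 or counts.n_hmbc >= 1
    reasons.append(
        "orthogonal 13C data (HSQC/HMBC) present"
        if orthogonal
        else "no orthogonal 13C data"
    )
    diagnostic = [e for e in evidence if e.kind in DIAGNOSTIC_EVIDENCE]
    if diagnostic:
        reasons.append(
            "diagnostic evidence: " + "; ".join(e.kind for e in diagnostic)
        )
    else:
        reasons.append("no diagnostic evidence")

    if gate_ok and (mice_ok or mie_ok or orthogonal or bool(diagnostic)):
        return ConfidenceCall(label=CONFIDENT, reasons=reasons)
    return ConfidenceCall(label=PUTATIVE, reasons=reasons)
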