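"""Map raw predictor scores to named category bands and binary calls.

Each external tool reports on its own scale; the bands below partition each
scale into the categories used for reporting, while the binary deleterious
call uses the tool's published cutoff:

* SIFT tolerance index in [0, 1] — deleterious below 0.05. The reporting
  bands leave (0.040, 0.050) unassigned in their two-decimal labelling; it is
  folded into Intolerant so the category agrees with the 0.05 cutoff.
* PolyPhen PSIC score difference >= 0 — damaging at 1.5 and above. Band edges
  are half-open so two-decimal labels like 0.99/1.00 are unambiguous.
* I-Mutant DDG (kcal/mol) — neutral within [-0.5, 0.5]; a large predicted
  stability decrease (DDG < -0.5) is the deleterious call.
* ConSurf grade 1..9 — 1-4 variable, 5-6 intermediate, 7-9 conserved.

Missing scores yield missing calls; nothing is imputed.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .errors import DomainError
from .model import ToolScores


class Tool(str, enum.Enum):
    SIFT = "sift"
    POLYPHEN = "polyphen"
    IMUTANT = "imutant"


class SIFTCategory(str, enum.Enum):
    # Declaration order is severity order (benign first).
    TOLERATED = "Tolerated"
    BORDERLINE = "Borderline"
    POTENTIALLY_INTOLERANT = "PotentiallyIntolerant"
    INTOLERANT = "Intolerant"


class PolyPhenCategory(str, enum.Enum):
    BENIGN = "Benign"
    BORDERLINE = "Borderline"
    POTENTIALLY_DAMAGING = "PotentiallyDamaging"
    POSSIBLY_DAMAGING = "PossiblyDamaging"
    PROBABLY_DAMAGING = "ProbablyDamaging"


class IMutantClass(str, enum.Enum):
    LARGE_DECREASE = "LargeDecrease"
    NEUTRAL = "Neutral"
    LARGE_INCREASE = "LargeIncrease"


class ConSurfClass(str, enum.Enum):
    VARIABLE = "Variable"
    INTERMEDIATE = "Intermediate"
    CONSERVED = "Conserved"


SIFT_CUTOFF = 0.05
POLYPHEN_CUTOFF = 1.5
IMUTANT_DESTABILIZING = -0.5


def sift_category(score: float) -> SIFTCategory:
    """Band a SIFT tolerance index: Intolerant [0, 0.05), PotentiallyIntolerant
    [0.05, 0.100], Borderline (0.100, 0.20], Tolerated (0.20, 1.0]."""
    if not (isinstance(score, (int, float)) and math.isfinite(score)) or not 0.0 <= score <= 1.0:
        raise DomainError(f"SIFT tolerance index must be in [0, 1], got {score!r}")
    if score < SIFT_CUTOFF:
        return SIFTCategory.INTOLERANT
    if score <= 0.100:
        return SIFTCategory.POTENTIALLY_INTOLERANT
    if score <= 0.20:
        return SIFTCategory.BORDERLINE
    return SIFTCategory.TOLERATED


def sift_deleterious(score: float) -> bool:
    """True iff the substitution is predicted intolerant (score < 0.05)."""
    return sift_category(score) is SIFTCategory.INTOLERANT


def polyphen_category(psic: float) -> PolyPhenCategory:
    """Band a PSIC score difference: Benign [0, 1.00), Borderline [1.00, 1.25),
    PotentiallyDamaging [1.25, 1.50), PossiblyDamaging [1.50, 2.00),
    ProbablyDamaging [2.00, inf)."""
    if not (isinstance(psic, (int, float)) and math.isfinite(psic)) or psic < 0.0:
        raise DomainError(f"PSIC score difference must be >= 0, got {psic!r}")
    if psic < 1.00:
        return PolyPhenCategory.BENIGN
    if psic < 1.25:
        return PolyPhenCategory.BORDERLINE
    if psic < POLYPHEN_CUTOFF:
        return PolyPhenCategory.POTENTIALLY_DAMAGING
    if psic < 2.00:
        return PolyPhenCategory.POSSIBLY_DAMAGING
    return PolyPhenCategory.PROBABLY_DAMAGING


def polyphen_deleterious(psic: float) -> bool:
    """True iff the PSIC score difference is damaging (>= 1.5)."""
    return polyphen_category(psic) in (
        PolyPhenCategory.POSSIBLY_DAMAGING,
        PolyPhenCategory.PROBABLY_DAMAGING,
    )


def imutant_class(ddg: float) -> IMutantClass:
    """Classify a predicted DDG (kcal/mol): LargeDecrease < -0.5, Neutral in
    [-0.5, 0.5], LargeIncrease > 0.5."""
    if not (isinstance(ddg, (int, float)) and math.isfinite(ddg)):
        raise DomainError(f"DDG must be a finite number, got {ddg!r}")
    if ddg < IMUTANT_DESTABILIZING:
        return IMutantClass.LARGE_DECREASE
    if ddg <= 0.5:
        return IMutantClass.NEUTRAL
    return IMutantClass.LARGE_INCREASE


def imutant_deleterious(ddg: float) -> bool:
    """True iff the mutation largely destabilizes the protein (DDG < -0.5)."""
    return imutant_class(ddg) is IMutantClass.LARGE_DECREASE


def consurf_class(score: int) -> ConSurfClass:
    """Classify a ConSurf grade: 1-4 Variable, 5-6 Intermediate, 7-9 Conserved."""
    if not isinstance(score, int) or isinstance(score, bool) or not 1 <= score <= 9:
        raise DomainError(f"ConSurf score must be an integer in 1..9, got {score!r}")
    if score <= 4:
        return ConSurfClass.VARIABLE
    if score <= 6:
        return ConSurfClass.INTERMEDIATE
    return ConSurfClass.CONSERVED


@dataclass(frozen=True)
class CategoryCall:
    """One tool's banded category plus its binary deleterious call."""

    tool: Tool
    category: str | None
    deleterious: bool | None


def categorize_scores(scores: ToolScores | None) -> dict[Tool, CategoryCall]:
    """Band all available scores of one variant; missing stays missing."""
    if scores is None:
        scores = ToolScores()
    calls: dict[Tool, CategoryCall] = {}
    if scores.sift_score is None:
        calls[Tool.SIFT] = CategoryCall(Tool.SIFT, None, None)
    else:
        calls[Tool.SIFT] = CategoryCall(
            Tool.SIFT,
            sift_category(scores.sift_score).value,
            sift_deleterious(scores.sift_score),
        )
    if scores.polyphen_psic is None:
        calls[Tool.POLYPHEN] = CategoryCall(Tool.POLYPHEN, None, None)
    else:
        calls[Tool.POLYPHEN] = CategoryCall(
            Tool.POLYPHEN,
            polyphen_category(scores.polyphen_psic).value,
            polyphen_deleterious(scores.polyphen_psic),
        )
    if scores.imutant_ddg is None:
        calls[Tool.IMUTANT] = CategoryCall(Tool.IMUTANT, None, None)
    else:
        calls[Tool.IMUTANT] = CategoryCall(
            Tool.IMUTANT,
            imutant_class(scores.imutant_ddg).value,
            imutant_deleterious(scores.imutant_ddg),
        )
    return calls


def deleterious_calls(scores: ToolScores | None) -> tuple[bool | None, bool | None, bool | None]:
    """Binary (SIFT, PolyPhen, I-Mutant) calls, ``None`` where unscored."""
    calls = categorize_scores(scores)
    return (
        calls[Tool.SIFT].deleterious,
        calls[Tool.POLYPHEN].deleterious,
        calls[Tool.IMUTANT].deleterious,
    )
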