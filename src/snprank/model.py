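"""Domain types for protein-level SNP annotation.

The analysis operates on non-synonymous SNPs (nsSNPs) and regulatory-region
SNPs of a single gene, each carrying precomputed outputs from external effect
predictors: a SIFT tolerance index in [0, 1] (low = intolerant substitution),
a PolyPhen PSIC score difference (high = damaging), an I-Mutant predicted
unfolding free-energy change DDG in kcal/mol (negative = destabilizing), a
ConSurf conservation grade 1-9, splicing-element and UTR-motif annotations,
and a FastSNP risk rank 0-5. Predicted and experimental post-translational
modification (PTM) sites are modelled separately.

Coordinates are 1-based protein residue positions throughout; amino acids use
upper-case one-letter codes. Missing values are represented as ``None`` and
are never conflated with zero.
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass, field

from .errors import DomainError

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

_SUBSTITUTION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


def parse_substitution(label: str) -> tuple[str, int, str]:
    """Parse an ``X<pos>Y`` substitution label such as ``"Y2677C"``.

    Returns ``(wild_aa, protein_position, mutant_aa)``.
    """
    m = _SUBSTITUTION_RE.match(label.strip())
    if m is None:
        raise DomainError(f"cannot parse substitution label {label!r}")
    wild, pos, mut = m.group(1), int(m.group(2)), m.group(3)
    if wild not in AMINO_ACIDS or mut not in AMINO_ACIDS:
        raise DomainError(f"non-amino-acid code in substitution label {label!r}")
    if pos < 1:
        raise DomainError(f"protein position must be >= 1 in {label!r}")
    return wild, pos, mut


class Region(str, enum.Enum):
    """Genomic region class of a SNP."""

    CODING_NONSYN = "coding_nonsyn"
    CODING_SYN = "coding_syn"
    MRNA = "mrna"
    UTR5 = "utr5"
    UTR3 = "utr3"
    INTRON = "intron"


class ValidationStatus(str, enum.Enum):
    VALIDATED = "validated"
    UNVALIDATED = "unvalidated"
    UNKNOWN = "unknown"


class Exposure(str, enum.Enum):
    BURIED = "buried"
    EXPOSED = "exposed"


class PupaElement(str, enum.Enum):
    """Splicing-element disruption call (exonic splicing enhancer/silencer)."""

    ESE = "ESE"
    ESS = "ESS"
    NONE = "none"


class UTRPattern(str, enum.Enum):
    """UTR functional-motif classes; the vocabulary is open (-> OTHER)."""

    IRES = "IRES"
    K_BOX = "K-BOX"
    LOX_DICE_15 = "15-LOX-DICE"
    OTHER = "other"


_UTR_ALIASES = {
    "IRES": UTRPattern.IRES,
    "K-BOX": UTRPattern.K_BOX,
    "KBOX": UTRPattern.K_BOX,
    "K_BOX": UTRPattern.K_BOX,
    "15-LOX-DICE": UTRPattern.LOX_DICE_15,
    "15LOXDICE": UTRPattern.LOX_DICE_15,
    "LOX-DICE": UTRPattern.LOX_DICE_15,
}


def parse_utr_pattern(token: str) -> UTRPattern:
    """Map a motif label to its pattern class; unknown labels become OTHER."""
    key = token.strip().upper().replace(" ", "")
    if key in _UTR_ALIASES:
        return _UTR_ALIASES[key]
    key2 = key.replace("_", "-")
    return _UTR_ALIASES.get(key2, UTRPattern.OTHER)


class Modification(str, enum.Enum):
    PHOSPHO = "phospho"
    N_GLYC = "n_glyc"
    O_GLYC = "o_glyc"
    METHYL = "methyl"
    ACETYL = "acetyl"
    SUMO = "sumo"


class SumoType(str, enum.Enum):
    TYPE_I = "typeI"
    TYPE_II = "typeII"
    NONE = "none"


@dataclass(frozen=True)
class VariantRecord:
    """One SNP with its identity, protein-level substitution and region."""

    variant_id: str
    gene: str
    region: Region
    protein_position: int | None = None
    wild_aa: str | None = None
    mutant_aa: str | None = None
    validation_status: ValidationStatus = ValidationStatus.UNKNOWN

    def __post_init__(self) -> None:
        if not self.variant_id:
            raise DomainError("variant_id must be non-empty")
        if self.protein_position is not None and self.protein_position < 1:
            raise DomainError(
                f"{self.variant_id}: protein_position must be >= 1 (1-based)"
            )
        for aa in (self.wild_aa, self.mutant_aa):
            if aa is not None and aa not in AMINO_ACIDS:
                raise DomainError(f"{self.variant_id}: invalid amino acid {aa!r}")
        if self.region is Region.CODING_NONSYN:
            if self.protein_position is None:
                raise DomainError(
                    f"{self.variant_id}: coding nsSNP requires a protein position"
                )
            if self.wild_aa is None or self.mutant_aa is None:
                raise DomainError(
                    f"{self.variant_id}: coding nsSNP requires wild and mutant residues"
                )
            if self.wild_aa == self.mutant_aa:
                raise DomainError(
                    f"{self.variant_id}: wild and mutant residues must differ"
                )

    @property
    def substitution(self) -> str | None:
        if self.wild_aa and self.mutant_aa and self.protein_position:
            return f"{self.wild_aa}{self.protein_position}{self.mutant_aa}"
        return None


@dataclass(frozen=True)
class ToolScores:
    """Raw per-variant outputs of the three coding-region predictors.

    ``None`` means the tool produced no score for this variant.
    """

    sift_score: float | None = None
    polyphen_psic: float | None = None
    imutant_ddg: float | None = None

    def __post_init__(self) -> None:
        if self.sift_score is not None and not 0.0 <= self.sift_score <= 1.0:
            raise DomainError(f"SIFT tolerance index {self.sift_score} not in [0, 1]")
        if self.polyphen_psic is not None and self.polyphen_psic < 0.0:
            raise DomainError(f"PSIC score difference {self.polyphen_psic} is negative")
        if self.imutant_ddg is not None and not math.isfinite(self.imutant_ddg):
            raise DomainError("I-Mutant DDG must be finite")

    @property
    def any_present(self) -> bool:
        return any(
            v is not None
            for v in (self.sift_score, self.polyphen_psic, self.imutant_ddg)
        )

    @property
    def fully_scored(self) -> bool:
        return all(
            v is not None
            for v in (self.sift_score, self.polyphen_psic, self.imutant_ddg)
        )


@dataclass(frozen=True)
class ConservationAnnotation:
    """ConSurf conservation grade (1 variable .. 9 conserved) and burial."""

    consurf_score: int
    exposure: Exposure

    def __post_init__(self) -> None:
        if not 1 <= self.consurf_score <= 9:
            raise DomainError(f"ConSurf score {self.consurf_score} not in 1..9")


@dataclass(frozen=True)
class RegulatoryAnnotation:
    """Merged regulatory evidence for one SNP."""

    pupasuite_element: PupaElement = PupaElement.NONE
    utrscan_patterns: frozenset[UTRPattern] = frozenset()
    fastsnp_risk: int | None = None
    fastsnp_effect: str = ""

    def __post_init__(self) -> None:
        if self.fastsnp_risk is not None and not 0 <= self.fastsnp_risk <= 5:
            raise DomainError(f"FastSNP risk {self.fastsnp_risk} not in 0..5")
        object.__setattr__(self, "utrscan_patterns", frozenset(self.utrscan_patterns))


@dataclass(frozen=True)
class PTMSite:
    """One predicted or experimentally supported modification site.

    Residue identity is recorded as reported by the source predictor and is
    deliberately not validated against modification chemistry: source tables
    occasionally disagree with the surrounding text about the residue at a
    position, and the registry stores what was printed.
    """

    modification: Modification
    residue: str
    position: int
    source: str
    sumo_type: SumoType = SumoType.NONE
    experimental: bool = False

    def __post_init__(self) -> None:
        if self.position < 1:
            raise DomainError(f"PTM position {self.position} must be >= 1")
        if self.residue not in AMINO_ACIDS:
            raise DomainError(f"invalid PTM residue {self.residue!r}")


@dataclass
class AnnotatedVariant:
    """A variant together with whichever annotations are available."""

    variant: VariantRecord
    scores: ToolScores | None = None
    conservation: ConservationAnnotation | None = None
    regulatory: RegulatoryAnnotation | None = None
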