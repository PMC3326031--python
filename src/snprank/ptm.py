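"""PTM site registry and ortholog-alignment conservation of modified residues.

The registry indexes predicted and experimentally supported modification
sites by (modification, position) and supports collision queries against
variants and intersection with experimentally determined position sets.

Conservation of a site is read off a multiple alignment of the human protein
with orthologs: a column is *identical* when every sequence carries the same
residue, *gap* when any ortholog has a deletion gap there, and otherwise
*strong*/*weak* per the standard ClustalW strong and weak residue groups
(the ":" and "." consensus symbols), or *none*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment

from .errors import DomainError, FormatError
from .model import Modification, PTMSite, VariantRecord

GAP_CHARS = "-."

# ClustalW consensus groups: a non-identical column gets ":" when all its
# residues fall in one strong group, "." when in one weak group.
CLUSTAL_STRONG_GROUPS = tuple(
    frozenset(g) for g in ("STA", "NEQK", "NHQK", "NDEQ", "QHRK", "MILV", "MILF", "HY", "FYW")
)
CLUSTAL_WEAK_GROUPS = tuple(
    frozenset(g)
    for g in (
        "CSA", "ATV", "SAG", "STNK", "STPA", "SGND",
        "SNDEQK", "NDEQHK", "NEQHRK", "FVLIM", "HFY",
    )
)


class ConservationSymbol:
    IDENTICAL = "identical"  # "*"
    STRONG = "strong"  # ":"
    WEAK = "weak"  # "."
    NONE = "none"
    GAP = "gap"


@dataclass(frozen=True)
class ColumnStatus:
    """Conservation status of one alignment column for a reference position."""

    reference_position: int
    column_index: int
    symbol: str


@dataclass
class SiteRegistry:
    """PTM sites keyed by (modification, position); duplicates are rejected."""

    _sites: dict[tuple[Modification, int], PTMSite] = field(default_factory=dict)

    @classmethod
    def from_sites(cls, sites: Iterable[PTMSite]) -> "SiteRegistry":
        registry = cls()
        for site in sites:
            registry.add(site)
        return registry

    def add(self, site: PTMSite) -> None:
        key = (site.modification, site.position)
        if key in self._sites:
            raise DomainError(
                f"duplicate PTM site {site.modification.value}@{site.position}"
            )
        self._sites[key] = site

    def __len__(self) -> int:
        return len(self._sites)

    def __iter__(self):
        return iter(self._sites.values())

    def sites(self, modification: Modification | None = None) -> list[PTMSite]:
        if modification is None:
            return list(self._sites.values())
        return [s for s in self._sites.values() if s.modification is modification]

    def positions(self, modification: Modification) -> set[int]:
        return {s.position for s in self.sites(modification)}

    def at_position(self, position: int) -> list[PTMSite]:
        return [s for s in self._sites.values() if s.position == position]


def variant_ptm_collision(variant: VariantRecord, registry: SiteRegistry) -> list[PTMSite]:
    """All registry sites at the variant's protein position."""
    if variant.protein_position is None:
        raise DomainError(f"{variant.variant_id}: variant has no protein position")
    return registry.at_position(variant.protein_position)


def intersect_experimental(
    predicted: SiteRegistry,
    experimental_positions: Iterable[int],
    modification: Modification,
) -> set[int]:
    """Predicted positions of one modification that experiments confirmed."""
    return predicted.positions(modification) & set(experimental_positions)


def read_alignment(path: str | Path, fmt: str | None = None) -> MultipleSeqAlignment:
    """Read a protein multiple alignment in FASTA or Clustal format.

    Format is sniffed from the first line when not given; gap characters are
    normalized to "-".
    """
    path = Path(path)
    if fmt is None:
        with path.open(encoding="utf-8") as fh:
            first = fh.readline()
        fmt = "clustal" if first.upper().startswith(("CLUSTAL", "MUSCLE")) else "fasta"
    try:
        alignment = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise FormatError(f"{path}: not a valid {fmt} alignment: {exc}") from None
    for record in alignment:
        record.seq = record.seq.replace(".", "-")
    return alignment


def _find_reference(alignment: MultipleSeqAlignment, reference_id: str):
    for record in alignment:
        if record.id == reference_id:
            return record
    raise DomainError(f"reference sequence {reference_id!r} not in alignment")


def map_position_to_column(
    alignment: MultipleSeqAlignment, reference_id: str, position: int
) -> int:
    """1-based alignment column holding the reference's position-th residue."""
    if position < 1:
        raise DomainError(f"position {position} must be >= 1 (1-based)")
    reference = _find_reference(alignment, reference_id)
    seen = 0
    for col, char in enumerate(str(reference.seq), start=1):
        if char not in GAP_CHARS:
            seen += 1
            if seen == position:
                return col
    raise DomainError(
        f"position {position} beyond ungapped length {seen} of {reference_id!r}"
    )


def column_to_position(
    alignment: MultipleSeqAlignment, reference_id: str, column_index: int
) -> int:
    """Inverse of :func:`map_position_to_column` for non-gap reference columns."""
    reference = _find_reference(alignment, reference_id)
    seq = str(reference.seq)
    if not 1 <= column_index <= len(seq):
        raise DomainError(f"column {column_index} outside alignment of width {len(seq)}")
    if seq[column_index - 1] in GAP_CHARS:
        raise DomainError(f"reference has a gap in column {column_index}")
    return sum(1 for ch in seq[:column_index] if ch not in GAP_CHARS)


def column_conservation(
    alignment: MultipleSeqAlignment,
    column_index: int,
    reference_position: int | None = None,
) -> ColumnStatus:
    """Classify one alignment column into the Clustal consensus symbols.

    Any gap disqualifies the column (a deletion gap in one ortholog means the
    site is not conserved there), identical residues give ``identical``, and
    otherwise membership in a single strong/weak residue group decides.
    """
    width = alignment.get_alignment_length()
    if not 1 <= column_index <= width:
        raise DomainError(f"column {column_index} outside alignment of width {width}")
    residues = [str(record.seq)[column_index - 1].upper() for record in alignment]
    if any(r in GAP_CHARS for r in residues):
        symbol = ConservationSymbol.GAP
    elif len(set(residues)) == 1:
        symbol = ConservationSymbol.IDENTICAL
    elif any(set(residues) <= group for group in CLUSTAL_STRONG_GROUPS):
        symbol = ConservationSymbol.STRONG
    elif any(set(residues) <= group for group in CLUSTAL_WEAK_GROUPS):
        symbol = ConservationSymbol.WEAK
    else:
        symbol = ConservationSymbol.NONE
    return ColumnStatus(
        reference_position=reference_position if reference_position is not None else -1,
        column_index=column_index,
        symbol=symbol,
    )


def site_conservation(
    alignment: MultipleSeqAlignment,
    reference_id: str,
    sites: Iterable[PTMSite],
) -> list[tuple[PTMSite, ColumnStatus]]:
    """Conservation status of each site's column in the ortholog alignment."""
    out = []
    for site in sites:
        col = map_position_to_column(alignment, reference_id, site.position)
        out.append((site, column_conservation(alignment, col, site.position)))
    return out
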