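"""Integrative consensus ranking of nsSNPs from per-tool deleterious calls.

Three independent predictors (SIFT, PolyPhen, I-Mutant) each give a binary
deleterious call per variant. The consensus tier is the deleterious-vote
count: Rank I (all three deleterious, most likely functional) down to
Rank IV (none deleterious, least likely). Variants with missing calls are
ranked over their available calls via the vote fraction and reported in a
separate partially-scored stratum, excluded from headline rank percentages.

The ``weighted`` scheme applies per-tool weights to the same vote-fraction
rule; with equal weights it coincides with ``vote_count``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .categorize import Tool, categorize_scores, deleterious_calls
from .errors import DomainError, UnrankableError
from .model import AnnotatedVariant
from .stats import percent


class Rank(str, enum.Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"


RANK_ORDER = (Rank.I, Rank.II, Rank.III, Rank.IV)

SCHEMES = ("vote_count", "weighted")


@dataclass(frozen=True)
class ConsensusRank:
    """A consensus tier plus the vote counts it was derived from."""

    rank: Rank
    n_deleterious: int
    n_available: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_deleterious <= self.n_available <= 3:
            raise DomainError(
                f"need 0 <= n_deleterious <= n_available <= 3, got "
                f"{self.n_deleterious}/{self.n_available}"
            )
        if self.n_available < 1:
            raise DomainError("rank defined only when at least one call is available")


def _fraction_rank(weight_deleterious: float, weight_available: float) -> Rank:
    frac = weight_deleterious / weight_available
    if frac == 1.0:
        return Rank.I
    if frac == 0.0:
        return Rank.IV
    if frac >= 0.5:
        return Rank.II
    return Rank.III


def assign_rank(
    calls: Sequence[bool | None],
    scheme: str = "vote_count",
    weights: Sequence[float] = (1.0, 1.0, 1.0),
) -> ConsensusRank:
    """Assign the consensus tier for one variant's (SIFT, PolyPhen, I-Mutant)
    calls; ``None`` marks a missing call.

    With all three calls present the vote-count scheme maps 3/2/1/0
    deleterious votes to Ranks I/II/III/IV.
    """
    if scheme not in SCHEMES:
        raise DomainError(f"unknown rank scheme {scheme!r}; choose from {SCHEMES}")
    if len(calls) != 3:
        raise DomainError(f"expected 3 calls (one per tool), got {len(calls)}")
    if len(weights) != 3 or any(w <= 0 for w in weights):
        raise DomainError("weights must be 3 positive numbers")
    available = [(c, w) for c, w in zip(calls, weights) if c is not None]
    if not available:
        raise UnrankableError("all three calls missing: variant cannot be ranked")
    if scheme == "vote_count":
        w_del = float(sum(1 for c, _ in available if c))
        w_avail = float(len(available))
    else:
        w_del = sum(w for c, w in available if c)
        w_avail = sum(w for _, w in available)
    return ConsensusRank(
        rank=_fraction_rank(w_del, w_avail),
        n_deleterious=sum(1 for c, _ in available if c),
        n_available=len(available),
    )


@dataclass
class CohortSummary:
    """Per-tool and per-rank counts for a cohort; percentages are always
    recomputed from the counts, never stored."""

    n_total: int
    n_fully_scored: int
    n_partially_scored: int
    n_unscored: int
    tool_counts: dict[Tool, dict[str, int]]  # keys: deleterious/tolerated/missing
    rank_counts: dict[Rank, int]  # fully-scored variants only
    partial_rank_counts: dict[Rank, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if sum(self.rank_counts.values()) != self.n_fully_scored:
            raise DomainError("per-rank counts must sum to the fully-scored count")

    def tool_percent(self, tool: Tool) -> tuple[float, float]:
        """(deleterious %, tolerated %) among variants the tool scored."""
        counts = self.tool_counts[tool]
        scored = counts["deleterious"] + counts["tolerated"]
        return percent(counts["deleterious"], scored), percent(counts["tolerated"], scored)

    def rank_percent(self, rank: Rank) -> float:
        """Share of fully-scored variants in the given tier."""
        return percent(self.rank_counts[rank], self.n_fully_scored)


def summarize_cohort(
    cohort: Iterable[AnnotatedVariant],
    scheme: str = "vote_count",
    weights: Sequence[float] = (1.0, 1.0, 1.0),
) -> CohortSummary:
    """Count per-tool deleterious/tolerated calls and per-rank assignments.

    Headline rank counts cover fully-scored variants (all three calls
    present); partially-scored variants are tallied separately.
    """
    cohort = list(cohort)
    if not cohort:
        raise DomainError("cohort is empty")
    tool_counts = {
        tool: {"deleterious": 0, "tolerated": 0, "missing": 0} for tool in Tool
    }
    rank_counts = {rank: 0 for rank in RANK_ORDER}
    partial_rank_counts = {rank: 0 for rank in RANK_ORDER}
    n_full = n_partial = n_unscored = 0
    for av in cohort:
        calls = deleterious_calls(av.scores)
        for tool, call in zip(Tool, calls):
            if call is None:
                tool_counts[tool]["missing"] += 1
            elif call:
                tool_counts[tool]["deleterious"] += 1
            else:
                tool_counts[tool]["tolerated"] += 1
        n_avail = sum(1 for c in calls if c is not None)
        if n_avail == 0:
            n_unscored += 1
            continue
        consensus = assign_rank(calls, scheme=scheme, weights=weights)
        if n_avail == 3:
            n_full += 1
            rank_counts[consensus.rank] += 1
        else:
            n_partial += 1
            partial_rank_counts[consensus.rank] += 1
    return CohortSummary(
        n_total=len(cohort),
        n_fully_scored=n_full,
        n_partially_scored=n_partial,
        n_unscored=n_unscored,
        tool_counts=tool_counts,
        rank_counts=rank_counts,
        partial_rank_counts=partial_rank_counts,
    )


def rank_table(
    cohort: Iterable[AnnotatedVariant],
    scheme: str = "vote_count",
    weights: Sequence[float] = (1.0, 1.0, 1.0),
) -> list[dict[str, object]]:
    """Per-variant rank report rows (variant_id, rank, votes, categories)."""
    rows = []
    for av in cohort:
        calls = categorize_scores(av.scores)
        binary = tuple(calls[t].deleterious for t in Tool)
        row: dict[str, object] = {
            "variant_id": av.variant.variant_id,
            "sift_category": calls[Tool.SIFT].category or ".",
            "polyphen_category": calls[Tool.POLYPHEN].category or ".",
            "imutant_class": calls[Tool.IMUTANT].category or ".",
        }
        try:
            consensus = assign_rank(binary, scheme=scheme, weights=weights)
            row.update(
                rank=consensus.rank.value,
                n_deleterious=consensus.n_deleterious,
                n_available=consensus.n_available,
            )
        except UnrankableError:
            row.update(rank=".", n_deleterious=0, n_available=0)
        rows.append(row)
    return rows
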