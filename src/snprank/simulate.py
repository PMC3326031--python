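"""Seeded generators for synthetic cohorts, validation labels and alignments.

The default generator settings reproduce the study conditions of the source
cohort: 168 nsSNPs with marginal per-tool deleterious rates 0.25 (SIFT),
0.696 (PolyPhen) and 0.678 (I-Mutant), and validated fractions among
tool-deleterious variants of 26/42 (SIFT) and 79/117 (PolyPhen).

Per-tool binary deleterious indicators are drawn with the configured
marginals, either independently or with a shared-latent dependence; the raw
score for each tool is then drawn uniformly within the score band implied by
its indicator, so categorization round-trips to the intended call exactly.
One global seed drives everything via deterministic substreams.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConfigError
from .model import (
    AMINO_ACIDS,
    AnnotatedVariant,
    Region,
    ToolScores,
    ValidationStatus,
    VariantRecord,
)
from .rank import Rank

# Uniform sampling bands per (tool, indicator): deleterious scores land
# strictly inside each tool's deleterious region, tolerated strictly outside.
SCORE_BANDS = {
    "sift": {True: (0.0, 0.05), False: (0.05, 1.0)},
    "polyphen": {True: (1.5, 3.5), False: (0.0, 1.5)},
    "imutant": {True: (-3.0, -0.5), False: (-0.5, 1.5)},
}

_AA_LIST = sorted(AMINO_ACIDS)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for cohort simulation."""

    n_variants: int = 168
    p_deleterious: tuple[float, float, float] = (0.25, 0.696, 0.678)
    p_validated_given_deleterious: dict[str, float] = field(
        default_factory=lambda: {"sift": 26 / 42, "polyphen": 79 / 117}
    )
    dependence: str = "independent"
    dependence_strength: float = 0.0
    seed: int = 0
    gene: str = "ATM"
    protein_length: int = 3056

    def __post_init__(self) -> None:
        if self.n_variants <= 0:
            raise ConfigError("n_variants must be positive")
        if len(self.p_deleterious) != 3 or not all(
            0.0 <= p <= 1.0 for p in self.p_deleterious
        ):
            raise ConfigError("p_deleterious must be three probabilities in [0, 1]")
        if not all(0.0 <= p <= 1.0 for p in self.p_validated_given_deleterious.values()):
            raise ConfigError("validation probabilities must be in [0, 1]")
        if self.dependence not in ("independent", "latent_shared"):
            raise ConfigError(f"unknown dependence model {self.dependence!r}")
        if not 0.0 <= self.dependence_strength <= 1.0:
            raise ConfigError("dependence_strength must be in [0, 1]")


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _draw_indicators(
    rng: np.random.Generator,
    shape: tuple[int, ...],
    p: Sequence[float],
    dependence: str,
    strength: float,
) -> np.ndarray:
    """Bernoulli indicator array of shape (*shape, 3) with given marginals.

    ``latent_shared`` mixes a shared uniform into each tool's threshold draw
    (a comonotone copula), which preserves the marginals exactly while making
    calls agree more than chance.
    """
    p = np.asarray(p, dtype=float)
    u_ind = rng.uniform(size=(*shape, 3))
    if dependence == "independent" or strength == 0.0:
        u = u_ind
    else:
        u_shared = rng.uniform(size=(*shape, 1))
        use_shared = rng.uniform(size=(*shape, 1)) < strength
        u = np.where(use_shared, u_shared, u_ind)
    return u < p


def _scores_from_indicators(rng: np.random.Generator, indicators: np.ndarray) -> np.ndarray:
    """Draw raw tool scores uniformly within the band each indicator implies."""
    n = indicators.shape[0]
    scores = np.empty((n, 3), dtype=float)
    for j, tool in enumerate(("sift", "polyphen", "imutant")):
        for call in (True, False):
            lo, hi = SCORE_BANDS[tool][call]
            mask = indicators[:, j] == call
            scores[mask, j] = rng.uniform(lo, hi, size=int(mask.sum()))
    return scores


def _build_variants(
    rng: np.random.Generator, config: SimulationConfig, scores: np.ndarray
) -> list[AnnotatedVariant]:
    n = config.n_variants
    if n <= config.protein_length:
        positions = rng.choice(config.protein_length, size=n, replace=False) + 1
    else:
        positions = rng.integers(1, config.protein_length + 1, size=n)
    cohort = []
    for i in range(n):
        wild, mutant = rng.choice(_AA_LIST, size=2, replace=False)
        variant = VariantRecord(
            variant_id=f"sim{i + 1:05d}",
            gene=config.gene,
            region=Region.CODING_NONSYN,
            protein_position=int(positions[i]),
            wild_aa=str(wild),
            mutant_aa=str(mutant),
        )
        cohort.append(
            AnnotatedVariant(
                variant,
                ToolScores(
                    sift_score=float(scores[i, 0]),
                    polyphen_psic=float(scores[i, 1]),
                    imutant_ddg=float(scores[i, 2]),
                ),
            )
        )
    return cohort


def generate_cohort(config: SimulationConfig) -> list[AnnotatedVariant]:
    """Simulate one cohort of scored nsSNPs under the configured conditions."""
    rng_ind, rng_scores, rng_variants = _substreams(config.seed, 3)
    indicators = _draw_indicators(
        rng_ind,
        (config.n_variants,),
        config.p_deleterious,
        config.dependence,
        config.dependence_strength,
    )
    scores = _scores_from_indicators(rng_scores, indicators)
    return _build_variants(rng_variants, config, scores)


def generate_exact_margin_cohort(
    n: int, counts: Sequence[int], seed: int = 0, gene: str = "ATM"
) -> list[AnnotatedVariant]:
    """Deterministic cohort with exactly the requested per-tool deleterious
    counts (calls assigned independently per tool by seeded shuffling)."""
    if n <= 0:
        raise ConfigError("n must be positive")
    if len(counts) != 3:
        raise ConfigError("counts must have one entry per tool")
    if any(not 0 <= c <= n for c in counts):
        raise ConfigError(f"each count must be in 0..{n}, got {tuple(counts)}")
    rng_perm, rng_scores, rng_variants = _substreams(seed, 3)
    indicators = np.zeros((n, 3), dtype=bool)
    for j, count in enumerate(counts):
        column = np.zeros(n, dtype=bool)
        column[:count] = True
        indicators[:, j] = rng_perm.permutation(column)
    scores = _scores_from_indicators(rng_scores, indicators)
    config = SimulationConfig(n_variants=n, seed=seed, gene=gene)
    return _build_variants(rng_variants, config, scores)


def generate_validation_labels(
    cohort: Iterable[AnnotatedVariant],
    config: SimulationConfig,
    tool: str = "sift",
) -> list[AnnotatedVariant]:
    """Label variants validated/unvalidated against one reference tool.

    Each variant the reference tool calls deleterious is labeled validated
    with the configured conditional probability; all others unvalidated. A
    single per-variant label cannot honour every tool's conditional rate at
    once, so the calibrating tool is explicit.
    """
    if tool not in config.p_validated_given_deleterious:
        raise ConfigError(f"no validation probability configured for tool {tool!r}")
    p = config.p_validated_given_deleterious[tool]
    tool_index = {"sift": 0, "polyphen": 1, "imutant": 2}[tool]
    rng = _substreams(config.seed, 4)[3]
    from .categorize import deleterious_calls

    out = []
    for av in cohort:
        call = deleterious_calls(av.scores)[tool_index]
        status = ValidationStatus.UNVALIDATED
        if call and rng.uniform() < p:
            status = ValidationStatus.VALIDATED
        out.append(
            dataclasses.replace(
                av, variant=replace(av.variant, validation_status=status)
            )
        )
    return out


def simulate_rank_count_means(
    config: SimulationConfig, n_cohorts: int
) -> dict[Rank, float]:
    """Mean per-cohort count of each consensus rank over simulated cohorts.

    Vectorized variant of generate_cohort + assign_rank: indicators are drawn
    for all cohorts at once and ranked by deleterious-vote count
    (3/2/1/0 votes -> Ranks I/II/III/IV).
    """
    if n_cohorts <= 0:
        raise ConfigError("n_cohorts must be positive")
    rng = _substreams(config.seed, 3)[0]
    indicators = _draw_indicators(
        rng,
        (n_cohorts, config.n_variants),
        config.p_deleterious,
        config.dependence,
        config.dependence_strength,
    )
    votes = indicators.sum(axis=2)
    return {
        Rank.I: float((votes == 3).sum(axis=1).mean()),
        Rank.II: float((votes == 2).sum(axis=1).mean()),
        Rank.III: float((votes == 1).sum(axis=1).mean()),
        Rank.IV: float((votes == 0).sum(axis=1).mean()),
    }


def generate_alignment_fixture(
    n_species: int,
    length: int,
    conserved_positions: Iterable[int] = (),
    gap_positions: Iterable[int] = (),
    seed: int = 0,
    gap_species_index: int = 1,
    reference_id: str = "human",
) -> MultipleSeqAlignment:
    """Synthetic ortholog alignment, gapless in the reference sequence.

    ``conserved_positions`` become identical columns; at each gap position one
    designated species carries a deletion gap while the others match the
    reference (a conserved site disqualified by the gap); remaining columns
    are randomized per species.
    """
    conserved = set(conserved_positions)
    gaps = set(gap_positions)
    if conserved & gaps:
        raise ConfigError(
            f"positions cannot be both conserved and gapped: {sorted(conserved & gaps)}"
        )
    if n_species < 2:
        raise ConfigError("an alignment needs at least 2 sequences")
    bad = [p for p in conserved | gaps if not 1 <= p <= length]
    if bad:
        raise ConfigError(f"positions outside 1..{length}: {sorted(bad)}")
    if not 1 <= gap_species_index < n_species:
        raise ConfigError("gap_species_index must identify a non-reference species")
    rng = np.random.default_rng(seed)
    columns = []
    for pos in range(1, length + 1):
        if pos in conserved:
            columns.append([str(rng.choice(_AA_LIST))] * n_species)
        elif pos in gaps:
            residue = str(rng.choice(_AA_LIST))
            col = [residue] * n_species
            col[gap_species_index] = "-"
            columns.append(col)
        else:
            columns.append([str(r) for r in rng.choice(_AA_LIST, size=n_species)])
    ids = [reference_id] + [f"ortholog{i}" for i in range(1, n_species)]
    records = [
        SeqRecord(Seq("".join(col[i] for col in columns)), id=ids[i], description="")
        for i in range(n_species)
    ]
    return MultipleSeqAlignment(records)
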