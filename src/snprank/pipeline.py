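"""End-to-end report assembly: categorize, rank, test, merge and overlap.

``run_pipeline`` drives the whole analysis over one variant table (plus
optional PTM table and ortholog alignment) and writes one TSV per report
section plus a JSON summary. Every number is recomputed from counts at emit
time; outputs carry ``#`` provenance comments (tool version, seed, config
hash) and are byte-identical across reruns with the same inputs and seed.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from . import __version__
from .categorize import (
    PolyPhenCategory,
    SIFTCategory,
    Tool,
    polyphen_category,
    sift_category,
)
from .errors import ConfigError, DomainError
from .model import AnnotatedVariant, Region, ValidationStatus
from .ptm import SiteRegistry, read_alignment, site_conservation, variant_ptm_collision
from .rank import RANK_ORDER, CohortSummary, rank_table, summarize_cohort
from .regulatory import (
    count_splicing_disruptors,
    fastsnp_high_risk,
    flag_multi_tool,
    merge_by_variant,
    read_regulatory_table,
)
from .stats import (
    ContingencyTable,
    chi_square,
    crosstab,
    percent,
    spearman_rho,
    validation_concordance,
)
from .tables import read_variant_table

logger = logging.getLogger("snprank")

SIFT_COLUMN_ORDER = [c.value for c in SIFTCategory]
POLYPHEN_ROW_ORDER = [c.value for c in PolyPhenCategory]


@dataclass
class RunConfig:
    """Inputs and knobs for one pipeline run."""

    input: str | Path
    out_dir: str | Path
    ptm: str | Path | None = None
    alignment: str | Path | None = None
    regulatory: str | Path | None = None
    reference_id: str = "human"
    scheme: str = "vote_count"
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self) -> None:
        for path in (self.input, self.ptm, self.alignment, self.regulatory):
            if path is not None and not Path(path).exists():
                raise ConfigError(f"input path does not exist: {path}")

    def digest(self) -> str:
        payload = json.dumps(
            {
                "input": str(self.input),
                "ptm": str(self.ptm),
                "alignment": str(self.alignment),
                "regulatory": str(self.regulatory),
                "reference_id": self.reference_id,
                "scheme": self.scheme,
                "weights": list(self.weights),
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _provenance(config: RunConfig) -> list[str]:
    return [f"snprank {__version__}", f"seed={config.seed}", f"config={config.digest()}"]


def _write_tsv(
    path: Path, header: Sequence[str], rows: Iterable[Sequence], comments: Iterable[str]
) -> None:
    with path.open("w", newline="", encoding="utf-8") as fh:
        for comment in comments:
            fh.write(f"# {comment}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        writer.writerows(rows)


def cohort_summary_rows(summary: CohortSummary) -> list[list]:
    rows = []
    for tool in Tool:
        counts = summary.tool_counts[tool]
        pct_del, pct_tol = summary.tool_percent(tool)
        rows.append(
            [tool.value, counts["deleterious"], pct_del, counts["tolerated"], pct_tol,
             counts["missing"]]
        )
    return rows


def rank_summary_rows(summary: CohortSummary) -> list[list]:
    return [
        [rank.value, summary.rank_counts[rank], summary.rank_percent(rank)]
        for rank in RANK_ORDER
    ]


def score_concordance(
    cohort: Sequence[AnnotatedVariant],
) -> tuple[ContingencyTable, dict[str, float | None]]:
    """Cross-tab of PolyPhen x SIFT categories plus Spearman on raw scores,
    over variants scored by both tools."""
    pairs = [
        (av.scores.sift_score, av.scores.polyphen_psic)
        for av in cohort
        if av.scores and av.scores.sift_score is not None and av.scores.polyphen_psic is not None
    ]
    rows = [polyphen_category(p).value for _, p in pairs]
    cols = [sift_category(s).value for s, _ in pairs]
    table = crosstab(rows, cols, POLYPHEN_ROW_ORDER, SIFT_COLUMN_ORDER)
    stats: dict[str, float | None] = {"n": len(pairs), "spearman_rho": None, "p_value": None}
    try:
        result = spearman_rho(pairs)
        stats["spearman_rho"] = result.statistic
        stats["p_value"] = result.p_value
    except DomainError as exc:
        logger.warning("Spearman not computed: %s", exc)
    return table, stats


def validation_report(cohort: Sequence[AnnotatedVariant]) -> list[dict]:
    """Per-tool validated-fraction concordance with a severity-split
    chi-square where both severity bins are populated."""
    from .categorize import deleterious_calls

    report = []
    splitters = {
        Tool.SIFT: lambda s: s.sift_score == 0.0,
        Tool.POLYPHEN: lambda s: polyphen_category(s.polyphen_psic)
        is PolyPhenCategory.PROBABLY_DAMAGING,
        Tool.IMUTANT: None,
    }
    for index, tool in enumerate(Tool):
        predicted = []
        for av in cohort:
            if av.variant.validation_status is ValidationStatus.UNKNOWN:
                continue
            if deleterious_calls(av.scores)[index]:
                predicted.append(av)
        validated = sum(
            1 for av in predicted
            if av.variant.validation_status is ValidationStatus.VALIDATED
        )
        row = {
            "tool": tool.value,
            "predicted_deleterious": len(predicted),
            "validated": validated,
            "concordance_percent": (
                validation_concordance(len(predicted), validated) if predicted else None
            ),
            "chi2": None,
            "chi2_p": None,
        }
        splitter = splitters[tool]
        if splitter is not None and predicted:
            severe = [splitter(av.scores) for av in predicted]
            valid = [
                av.variant.validation_status is ValidationStatus.VALIDATED
                for av in predicted
            ]
            try:
                result = chi_square(crosstab(severe, valid, [True, False], [True, False]))
                row["chi2"], row["chi2_p"] = result.statistic, result.p_value
            except DomainError:
                pass  # a severity bin is empty; chi-square undefined
        report.append(row)
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Run every analysis stage and write the report bundle.

    Returns the JSON summary as a dict; raises on any stage failure with the
    stage named in the log.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    comments = _provenance(config)
    summary_json: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.digest(),
        "scheme": config.scheme,
    }

    stage = "read input"
    t0 = time.perf_counter()
    try:
        cohort = read_variant_table(config.input)

        stage = "cohort summary"
        summary = summarize_cohort(cohort, scheme=config.scheme, weights=config.weights)
        _write_tsv(
            out_dir / "cohort_summary.tsv",
            ["tool", "deleterious", "deleterious_percent", "tolerated",
             "tolerated_percent", "missing"],
            cohort_summary_rows(summary),
            comments,
        )
        summary_json["cohort"] = {
            "n_total": summary.n_total,
            "n_fully_scored": summary.n_fully_scored,
            "n_partially_scored": summary.n_partially_scored,
            "tools": {
                tool.value: {
                    **summary.tool_counts[tool],
                    "deleterious_percent": summary.tool_percent(tool)[0],
                    "tolerated_percent": summary.tool_percent(tool)[1],
                }
                for tool in Tool
                if summary.tool_counts[tool]["deleterious"]
                + summary.tool_counts[tool]["tolerated"] > 0
            },
        }

        stage = "rank table"
        rows = rank_table(cohort, scheme=config.scheme, weights=config.weights)
        _write_tsv(
            out_dir / "rank_table.tsv",
            ["variant_id", "rank", "n_deleterious", "n_available",
             "sift_category", "polyphen_category", "imutant_class"],
            [[r["variant_id"], r["rank"], r["n_deleterious"], r["n_available"],
              r["sift_category"], r["polyphen_category"], r["imutant_class"]]
             for r in rows],
            comments,
        )
        _write_tsv(
            out_dir / "rank_summary.tsv",
            ["rank", "count", "percent"],
            rank_summary_rows(summary),
            comments,
        )
        summary_json["ranks"] = {
            rank.value: {"count": summary.rank_counts[rank],
                         "percent": summary.rank_percent(rank)}
            for rank in RANK_ORDER
        } if summary.n_fully_scored else {}

        stage = "concordance"
        table, spearman = score_concordance(cohort)
        frame = table.to_frame(margins=True)
        _write_tsv(
            out_dir / "concordance.tsv",
            ["polyphen_category", *frame.columns],
            [[idx, *row] for idx, row in zip(frame.index, frame.values.tolist())],
            comments,
        )
        summary_json["concordance"] = spearman

        stage = "validation"
        validation = validation_report(cohort)
        _write_tsv(
            out_dir / "validation.tsv",
            ["tool", "predicted_deleterious", "validated", "concordance_percent",
             "chi2", "chi2_p"],
            [[r["tool"], r["predicted_deleterious"], r["validated"],
              _fmt_opt(r["concordance_percent"]), _fmt_opt(r["chi2"]),
              _fmt_opt(r["chi2_p"])] for r in validation],
            comments,
        )
        summary_json["validation"] = validation

        stage = "regulatory"
        ese, ess, flagged = count_splicing_disruptors(cohort)
        n_nssnp = sum(1 for av in cohort if av.variant.region is Region.CODING_NONSYN)
        summary_json["splicing"] = {
            "ese": ese, "ess": ess, "flagged": flagged,
            "flagged_percent": percent(flagged, n_nssnp) if n_nssnp else None,
        }
        if config.regulatory is not None:
            reg_rows = read_regulatory_table(config.regulatory)
            merged = merge_by_variant(reg_rows)
            _write_tsv(
                out_dir / "regulatory_flags.tsv",
                ["variant_id", "pupasuite_element", "utrscan_patterns",
                 "multi_tool_significant", "fastsnp_high_risk"],
                [[vid, ann.pupasuite_element.value,
                  ",".join(sorted(p.value for p in ann.utrscan_patterns)) or ".",
                  str(flag_multi_tool(ann)).lower(),
                  _fmt_opt(fastsnp_high_risk(ann))]
                 for vid, ann in merged.items()],
                comments,
            )
            summary_json["regulatory"] = {
                "n_snps": len(merged),
                "multi_tool_significant": sorted(
                    vid for vid, ann in merged.items() if flag_multi_tool(ann)
                ),
            }

        stage = "ptm overlap"
        if config.ptm is not None:
            from .tables import read_ptm_table

            registry = SiteRegistry.from_sites(read_ptm_table(config.ptm))
            overlap_rows = []
            for av in cohort:
                if av.variant.protein_position is None:
                    continue
                for site in variant_ptm_collision(av.variant, registry):
                    overlap_rows.append(
                        [av.variant.variant_id, av.variant.substitution or ".",
                         site.modification.value, site.position, site.source,
                         str(site.experimental).lower()]
                    )
            _write_tsv(
                out_dir / "ptm_overlap.tsv",
                ["variant_id", "substitution", "modification", "position",
                 "source", "experimental"],
                overlap_rows,
                comments,
            )
            summary_json["ptm_overlap"] = {"n_collisions": len(overlap_rows)}

            stage = "conservation"
            if config.alignment is not None:
                alignment = read_alignment(config.alignment)
                ungapped = sum(
                    1 for ch in str(_reference_seq(alignment, config.reference_id))
                    if ch != "-"
                )
                in_range = [s for s in registry if s.position <= ungapped]
                conservation = site_conservation(alignment, config.reference_id, in_range)
                _write_tsv(
                    out_dir / "conservation.tsv",
                    ["position", "modification", "column", "symbol"],
                    [[site.position, site.modification.value,
                      status.column_index, status.symbol]
                     for site, status in conservation],
                    comments,
                )
                summary_json["conservation"] = {
                    "n_sites": len(conservation),
                    "identical": sum(
                        1 for _, st in conservation if st.symbol == "identical"
                    ),
                    "gap": sum(1 for _, st in conservation if st.symbol == "gap"),
                }

        stage = "summary"
        with (out_dir / "summary.json").open("w", encoding="utf-8") as fh:
            json.dump(summary_json, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except Exception:
        logger.error("pipeline failed in stage: %s", stage)
        raise
    logger.info("pipeline finished in %.2f s", time.perf_counter() - t0)
    return summary_json


def _reference_seq(alignment, reference_id: str):
    for record in alignment:
        if record.id == reference_id:
            return record.seq
    raise DomainError(f"reference sequence {reference_id!r} not in alignment")


def _fmt_opt(value) -> str:
    if value is None:
        return "."
    if isinstance(value, bool):
        return str(value).lower()
    return str(value)
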