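"""Regulatory-region SNP evidence: splicing-element disruption, UTR motifs
and FastSNP risk, merged per SNP across table rows.

A SNP can appear under more than one region class (e.g. once with an exonic
splicing enhancer call in mRNA context and once with UTR motif hits), so the
merge step unions evidence by identifier before multi-tool significance is
assessed: a SNP is multi-tool significant when it both disrupts a splicing
element and carries at least one UTR motif hit.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .errors import FormatError
from .model import AnnotatedVariant, PupaElement, Region, RegulatoryAnnotation
from .tables import MISSING, _opt_int, _read_rows, format_patterns, parse_patterns

REGULATORY_COLUMNS = [
    "variant_id",
    "region",
    "pupasuite_element",
    "utrscan_patterns",
    "fastsnp_risk",
    "fastsnp_effect",
    "bold",
]

FASTSNP_HIGH_RISK_MIN = 3  # risk scale 0..5; 3 = medium-high through 5 = very high


@dataclass(frozen=True)
class RegulatoryRow:
    """One row of a regulatory-evidence table (one SNP in one region class)."""

    variant_id: str
    region: Region
    annotation: RegulatoryAnnotation
    bold: bool = False


def read_regulatory_table(path: str | Path) -> list[RegulatoryRow]:
    """Read a regulatory-evidence TSV.

    Unlike the variant table, duplicate identifiers are allowed here: the
    same SNP may be annotated in several region classes and is merged later.
    """
    path = Path(path)
    rows, lines = _read_rows(path, REGULATORY_COLUMNS)
    out: list[RegulatoryRow] = []
    for row, lineno in zip(rows, lines):
        try:
            region = Region(row["region"])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: unknown region {row['region']!r}") from None
        element = (
            PupaElement(row["pupasuite_element"])
            if row["pupasuite_element"] not in (MISSING, "", "-")
            else PupaElement.NONE
        )
        annotation = RegulatoryAnnotation(
            pupasuite_element=element,
            utrscan_patterns=parse_patterns(row["utrscan_patterns"]),
            fastsnp_risk=_opt_int(row["fastsnp_risk"], path, lineno, "fastsnp_risk"),
            fastsnp_effect=""
            if row["fastsnp_effect"] in (MISSING, "-")
            else row["fastsnp_effect"],
        )
        bold = row["bold"].strip().lower()
        if bold not in ("true", "false", "0", "1"):
            raise FormatError(f"{path}:{lineno}: bold must be boolean, got {row['bold']!r}")
        out.append(RegulatoryRow(row["variant_id"], region, annotation, bold in ("true", "1")))
    return out


def write_regulatory_table(
    rows: Iterable[RegulatoryRow], path: str | Path, header_comments: Iterable[str] = ()
) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(REGULATORY_COLUMNS)
        for row in rows:
            a = row.annotation
            writer.writerow(
                [
                    row.variant_id,
                    row.region.value,
                    a.pupasuite_element.value,
                    format_patterns(a.utrscan_patterns),
                    MISSING if a.fastsnp_risk is None else str(a.fastsnp_risk),
                    a.fastsnp_effect or MISSING,
                    "true" if row.bold else "false",
                ]
            )


def merge_annotations(
    first: RegulatoryAnnotation, second: RegulatoryAnnotation
) -> RegulatoryAnnotation:
    """Union two evidence records for the same SNP (element: non-none wins;
    motifs: set union; risk: max; effects: concatenated)."""
    element = first.pupasuite_element
    if element is PupaElement.NONE:
        element = second.pupasuite_element
    risks = [r for r in (first.fastsnp_risk, second.fastsnp_risk) if r is not None]
    effects = [e for e in (first.fastsnp_effect, second.fastsnp_effect) if e]
    return RegulatoryAnnotation(
        pupasuite_element=element,
        utrscan_patterns=first.utrscan_patterns | second.utrscan_patterns,
        fastsnp_risk=max(risks) if risks else None,
        fastsnp_effect="; ".join(dict.fromkeys(effects)),
    )


def merge_by_variant(rows: Iterable[RegulatoryRow]) -> dict[str, RegulatoryAnnotation]:
    """Merge evidence rows by SNP identifier, in input order."""
    merged: dict[str, RegulatoryAnnotation] = {}
    for row in rows:
        if row.variant_id in merged:
            merged[row.variant_id] = merge_annotations(merged[row.variant_id], row.annotation)
        else:
            merged[row.variant_id] = row.annotation
    return merged


def flag_multi_tool(annotation: RegulatoryAnnotation) -> bool:
    """True iff a SNP carries both a splicing-element call and a UTR motif hit."""
    return (
        annotation.pupasuite_element is not PupaElement.NONE
        and len(annotation.utrscan_patterns) > 0
    )


def multi_tool_significant(rows: Iterable[RegulatoryRow]) -> list[str]:
    """Identifiers flagged by both tools after per-SNP evidence merging."""
    merged = merge_by_variant(rows)
    return [vid for vid, ann in merged.items() if flag_multi_tool(ann)]


def fastsnp_high_risk(annotation: RegulatoryAnnotation) -> bool | None:
    """True iff FastSNP risk is in the high band (>= 3 of 0..5); None if unscored."""
    if annotation.fastsnp_risk is None:
        return None
    return annotation.fastsnp_risk >= FASTSNP_HIGH_RISK_MIN


def count_splicing_disruptors(
    cohort: Iterable[AnnotatedVariant],
) -> tuple[int, int, int]:
    """Count nsSNPs disrupting splicing elements: (ESE, ESS, total flagged).

    Only coding non-synonymous variants with regulatory evidence contribute.
    """
    ese = ess = 0
    for av in cohort:
        if av.variant.region is not Region.CODING_NONSYN or av.regulatory is None:
            continue
        if av.regulatory.pupasuite_element is PupaElement.ESE:
            ese += 1
        elif av.regulatory.pupasuite_element is PupaElement.ESS:
            ess += 1
    return ese, ess, ese + ess
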