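"""Tab-separated exchange formats for variant and PTM tables.

The on-disk convention is bioinformatics-standard: UTF-8 TSV with a mandatory
header row, ``.`` for missing values, ``#``-prefixed comment lines ignored.
Round trips are lossless: floats are serialized with ``repr`` so that
``read(write(x)) == x`` field for field, and missingness survives distinctly
from zero.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable

from .errors import FormatError
from .model import (
    AnnotatedVariant,
    ConservationAnnotation,
    Exposure,
    Modification,
    PTMSite,
    PupaElement,
    Region,
    RegulatoryAnnotation,
    SumoType,
    ToolScores,
    UTRPattern,
    ValidationStatus,
    VariantRecord,
    parse_utr_pattern,
)

MISSING = "."

VARIANT_COLUMNS = [
    "variant_id",
    "gene",
    "protein_position",
    "wild_aa",
    "mutant_aa",
    "region",
    "validation_status",
    "sift_score",
    "polyphen_psic",
    "imutant_ddg",
    "consurf_score",
    "exposure",
    "pupasuite_element",
    "utrscan_patterns",
    "fastsnp_risk",
    "fastsnp_effect",
]

PTM_COLUMNS = ["modification", "residue", "position", "source", "sumo_type", "experimental"]


def _read_rows(path: str | Path, required: list[str]) -> tuple[list[dict[str, str]], list[int]]:
    """Read a headered TSV, returning row dicts and their 1-based line numbers."""
    path = Path(path)
    rows: list[dict[str, str]] = []
    lines: list[int] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header: list[str] | None = None
        for lineno, raw in enumerate(reader, start=1):
            if not raw or (raw[0].startswith("#")):
                continue
            if header is None:
                header = [c.strip() for c in raw]
                missing = [c for c in required if c not in header]
                if missing:
                    raise FormatError(
                        f"{path}: header is missing required column(s): {', '.join(missing)}"
                    )
                continue
            if len(raw) != len(header):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, found {len(raw)}"
                )
            rows.append(dict(zip(header, (v.strip() for v in raw))))
            lines.append(lineno)
    if header is None:
        raise FormatError(f"{path}: empty file, header row required")
    return rows, lines


def _opt_float(value: str, path: Path, lineno: int, column: str) -> float | None:
    if value == MISSING or value == "":
        return None
    try:
        return float(value)
    except ValueError:
        raise FormatError(
            f"{path}:{lineno}: non-numeric value {value!r} in column {column}"
        ) from None


def _opt_int(value: str, path: Path, lineno: int, column: str) -> int | None:
    if value == MISSING or value == "":
        return None
    try:
        return int(value)
    except ValueError:
        raise FormatError(
            f"{path}:{lineno}: non-integer value {value!r} in column {column}"
        ) from None


def parse_patterns(cell: str) -> frozenset[UTRPattern]:
    if cell in (MISSING, "", "-"):
        return frozenset()
    return frozenset(parse_utr_pattern(tok) for tok in cell.split(",") if tok.strip())


def format_patterns(patterns: Iterable[UTRPattern]) -> str:
    vals = sorted(p.value for p in patterns)
    return ",".join(vals) if vals else MISSING


def read_variant_table(path: str | Path) -> list[AnnotatedVariant]:
    """Read a variant table TSV into annotated variants.

    Enforces unique ``variant_id`` within the file. Missing scores stay
    missing; a variant with no score at all gets ``scores=None``.
    """
    path = Path(path)
    rows, lines = _read_rows(path, VARIANT_COLUMNS)
    cohort: list[AnnotatedVariant] = []
    seen: set[str] = set()
    for row, lineno in zip(rows, lines):
        vid = row["variant_id"]
        if vid in seen:
            raise FormatError(f"{path}:{lineno}: duplicate variant_id {vid!r}")
        seen.add(vid)
        try:
            region = Region(row["region"])
        except ValueError:
            raise FormatError(
                f"{path}:{lineno}: unknown region {row['region']!r}"
            ) from None
        status = row["validation_status"]
        variant = VariantRecord(
            variant_id=vid,
            gene=row["gene"],
            region=region,
            protein_position=_opt_int(row["protein_position"], path, lineno, "protein_position"),
            wild_aa=None if row["wild_aa"] == MISSING else row["wild_aa"],
            mutant_aa=None if row["mutant_aa"] == MISSING else row["mutant_aa"],
            validation_status=ValidationStatus(status)
            if status != MISSING
            else ValidationStatus.UNKNOWN,
        )
        scores = ToolScores(
            sift_score=_opt_float(row["sift_score"], path, lineno, "sift_score"),
            polyphen_psic=_opt_float(row["polyphen_psic"], path, lineno, "polyphen_psic"),
            imutant_ddg=_opt_float(row["imutant_ddg"], path, lineno, "imutant_ddg"),
        )
        consurf = _opt_int(row["consurf_score"], path, lineno, "consurf_score")
        conservation = None
        if consurf is not None:
            if row["exposure"] == MISSING:
                raise FormatError(
                    f"{path}:{lineno}: consurf_score present but exposure missing"
                )
            conservation = ConservationAnnotation(consurf, Exposure(row["exposure"]))
        reg_cells = (
            row["pupasuite_element"],
            row["utrscan_patterns"],
            row["fastsnp_risk"],
            row["fastsnp_effect"],
        )
        regulatory = None
        if any(c != MISSING and c != "" for c in reg_cells):
            element = (
                PupaElement(row["pupasuite_element"])
                if row["pupasuite_element"] not in (MISSING, "")
                else PupaElement.NONE
            )
            regulatory = RegulatoryAnnotation(
                pupasuite_element=element,
                utrscan_patterns=parse_patterns(row["utrscan_patterns"]),
                fastsnp_risk=_opt_int(row["fastsnp_risk"], path, lineno, "fastsnp_risk"),
                fastsnp_effect="" if row["fastsnp_effect"] == MISSING else row["fastsnp_effect"],
            )
        cohort.append(AnnotatedVariant(variant, scores if scores.any_present else None,
                                       conservation, regulatory))
    return cohort


def _fmt(value) -> str:
    if value is None:
        return MISSING
    if isinstance(value, float):
        return repr(value)
    return str(value)


def variant_row(av: AnnotatedVariant) -> list[str]:
    v, s, c, r = av.variant, av.scores, av.conservation, av.regulatory
    return [
        v.variant_id,
        v.gene,
        _fmt(v.protein_position),
        _fmt(v.wild_aa),
        _fmt(v.mutant_aa),
        v.region.value,
        v.validation_status.value,
        _fmt(s.sift_score) if s else MISSING,
        _fmt(s.polyphen_psic) if s else MISSING,
        _fmt(s.imutant_ddg) if s else MISSING,
        _fmt(c.consurf_score) if c else MISSING,
        c.exposure.value if c else MISSING,
        r.pupasuite_element.value if r else MISSING,
        format_patterns(r.utrscan_patterns) if r else MISSING,
        _fmt(r.fastsnp_risk) if r else MISSING,
        (r.fastsnp_effect or MISSING) if r else MISSING,
    ]


def write_variant_table(
    cohort: Iterable[AnnotatedVariant],
    path: str | Path,
    header_comments: Iterable[str] = (),
) -> None:
    """Write annotated variants as a TSV; inverse of :func:`read_variant_table`."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(VARIANT_COLUMNS)
        for av in cohort:
            writer.writerow(variant_row(av))


def read_ptm_table(path: str | Path) -> list[PTMSite]:
    path = Path(path)
    rows, lines = _read_rows(path, PTM_COLUMNS)
    sites = []
    for row, lineno in zip(rows, lines):
        try:
            modification = Modification(row["modification"])
            sumo_type = SumoType(row["sumo_type"]) if row["sumo_type"] != MISSING else SumoType.NONE
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
        position = _opt_int(row["position"], path, lineno, "position")
        if position is None:
            raise FormatError(f"{path}:{lineno}: position is required")
        exp = row["experimental"].lower()
        if exp not in ("true", "false", "0", "1"):
            raise FormatError(
                f"{path}:{lineno}: experimental must be boolean, got {row['experimental']!r}"
            )
        sites.append(
            PTMSite(
                modification=modification,
                residue=row["residue"],
                position=position,
                source=row["source"],
                sumo_type=sumo_type,
                experimental=exp in ("true", "1"),
            )
        )
    return sites


def write_ptm_table(
    sites: Iterable[PTMSite], path: str | Path, header_comments: Iterable[str] = ()
) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(PTM_COLUMNS)
        for s in sites:
            writer.writerow(
                [
                    s.modification.value,
                    s.residue,
                    str(s.position),
                    s.source,
                    s.sumo_type.value,
                    "true" if s.experimental else "false",
                ]
            )
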