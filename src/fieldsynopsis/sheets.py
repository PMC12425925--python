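"""Readers and writers for extraction sheets, GWAS sheets and synopsis tables.

Extraction sheets are UTF-8 delimited text (CSV or TSV) with a mandatory
header row; missing values are empty fields.  Rows that violate record
invariants are collected into an error report rather than silently
dropped, so the eligible set plus the error log always partition the
input.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Sequence, Union

import pandas as pd

from .records import (
    GwasRecord,
    StudyRecord,
    SynopsisError,
    ValidationError,
    VariantTable,
)

__all__ = [
    "ReadReport",
    "FormatError",
    "read_extraction_sheet",
    "write_extraction_sheet",
    "read_gwas_sheet",
    "write_synopsis_table",
    "read_synopsis_table",
    "write_error_report",
    "SYNOPSIS_COLUMNS",
]


class FormatError(SynopsisError):
    """The sheet itself is malformed (missing columns, bad dialect)."""


MANDATORY_COLUMNS = (
    "study_id", "first_author", "year", "ancestry", "variant_id", "gene",
    "n_cases", "n_controls",
)
COUNT_COLUMNS = ("allele_case_test", "allele_case_ref", "allele_control_test",
                 "allele_control_ref")
OPTIONAL_COLUMNS = COUNT_COLUMNS + (
    "reported_or", "ci_low", "ci_high", "diagnostic_criteria",
    "genotyping_method", "partial_typing",
)

# Fixed synopsis layout (13 columns, stable order) for TSV/JSON output.
SYNOPSIS_COLUMNS = (
    "variant_id", "gene", "stratum", "model", "k", "or", "ci_low", "ci_high",
    "p", "i_squared", "venice", "fprp", "evidence",
)


@dataclass
class ReadReport:
    """Validated table plus the row-level errors found while reading."""

    table: VariantTable
    errors: list[dict[str, Any]] = field(default_factory=list)

    @property
    def n_errors(self) -> int:
        return len(self.errors)


def _sep(dialect: str) -> str:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    raise ValueError(f"dialect must be 'csv' or 'tsv', got {dialect!r}")


def _opt_float(value: Any) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return float(value)


def _opt_int(value: Any) -> Optional[int]:
    f = _opt_float(value)
    if f is None:
        return None
    if not float(f).is_integer():
        raise ValueError(f"expected an integer, got {value!r}")
    return int(f)


def read_extraction_sheet(
    path: Union[str, Path], dialect: str = "tsv"
) -> ReadReport:
    """Read one study-per-row extraction sheet into a validated table."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep(dialect), dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing mandatory column(s) {', '.join(missing)}"
        )
    records: list[StudyRecord] = []
    errors: list[dict[str, Any]] = []
    seen: dict[tuple, int] = {}
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header is line 1
        try:
            counts = tuple(_opt_int(row.get(c, "")) for c in COUNT_COLUMNS)
            if any(c is None for c in counts):
                if any(c is not None for c in counts):
                    raise ValidationError(
                        "allele counts must be given for all four cells or none"
                    )
                counts = None
            partial = str(row.get("partial_typing", "")).strip().lower() in (
                "1", "true", "yes",
            )
            rec = StudyRecord(
                study_id=str(row["study_id"]).strip(),
                first_author=str(row["first_author"]).strip(),
                year=_opt_int(row["year"]),
                ancestry=str(row["ancestry"]).strip(),
                variant_id=str(row["variant_id"]).strip(),
                gene=str(row["gene"]).strip(),
                n_cases=_opt_int(row["n_cases"]),
                n_controls=_opt_int(row["n_controls"]),
                allele_counts=counts,
                reported_or=_opt_float(row.get("reported_or", "")),
                ci_low=_opt_float(row.get("ci_low", "")),
                ci_high=_opt_float(row.get("ci_high", "")),
                diagnostic_criteria=str(row.get("diagnostic_criteria", "")).strip(),
                genotyping_method=str(row.get("genotyping_method", "")).strip(),
                partial_typing=partial,
            )
        except (ValidationError, ValueError, TypeError) as exc:
            errors.append({"line": line, "rule": "record_invariant", "message": str(exc)})
            continue
        key = (rec.study_id, rec.variant_id, rec.ancestry)
        if key in seen:
            errors.append({
                "line": line,
                "rule": "duplicate_key",
                "message": (
                    f"duplicate (study_id, variant_id, ancestry) {key}: "
                    f"lines {seen[key]} and {line}"
                ),
            })
            continue
        seen[key] = line
        records.append(rec)
    return ReadReport(
        table=VariantTable(records=records, provenance=f"{path}:{dialect}"),
        errors=errors,
    )


def write_extraction_sheet(
    table: VariantTable, path: Union[str, Path], dialect: str = "tsv"
) -> None:
    """Write a table back to sheet form (inverse of read_extraction_sheet)."""
    rows = []
    for rec in table.records:
        counts = rec.allele_counts or (None, None, None, None)
        rows.append({
            "study_id": rec.study_id,
            "first_author": rec.first_author,
            "year": rec.year,
            "ancestry": rec.ancestry,
            "variant_id": rec.variant_id,
            "gene": rec.gene,
            "n_cases": rec.n_cases,
            "n_controls": rec.n_controls,
            "allele_case_test": counts[0],
            "allele_case_ref": counts[1],
            "allele_control_test": counts[2],
            "allele_control_ref": counts[3],
            "reported_or": rec.reported_or,
            "ci_low": rec.ci_low,
            "ci_high": rec.ci_high,
            "diagnostic_criteria": rec.diagnostic_criteria,
            "genotyping_method": rec.genotyping_method,
            "partial_typing": int(rec.partial_typing),
        })
    df = pd.DataFrame(rows, columns=MANDATORY_COLUMNS + OPTIONAL_COLUMNS)
    df.to_csv(path, sep=_sep(dialect), index=False)


GWAS_COLUMNS = ("locus", "gene", "ancestry_group", "lead_variant", "n_cases",
                "n_controls", "or", "ci_low", "ci_high", "p", "ld_variants")


def read_gwas_sheet(path: Union[str, Path], dialect: str = "tsv") -> list[GwasRecord]:
    """Read a GWAS-catalogue sheet (one lead variant per row)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep(dialect), dtype=str, keep_default_na=False)
    missing = [c for c in GWAS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {', '.join(missing)}")
    records = []
    for _, row in df.iterrows():
        ld = tuple(v.strip() for v in str(row["ld_variants"]).split(",") if v.strip())
        records.append(GwasRecord(
            locus=row["locus"], gene=row["gene"],
            ancestry_group=row["ancestry_group"],
            lead_variant=row["lead_variant"],
            n_cases=_opt_int(row["n_cases"]), n_controls=_opt_int(row["n_controls"]),
            or_value=_opt_float(row["or"]), ci_low=_opt_float(row["ci_low"]),
            ci_high=_opt_float(row["ci_high"]), p_value=_opt_float(row["p"]),
            ld_variants=ld,
        ))
    return records


def write_gwas_sheet(
    records: Sequence[GwasRecord], path: Union[str, Path], dialect: str = "tsv"
) -> None:
    rows = [{
        "locus": r.locus, "gene": r.gene, "ancestry_group": r.ancestry_group,
        "lead_variant": r.lead_variant, "n_cases": r.n_cases,
        "n_controls": r.n_controls, "or": r.or_value, "ci_low": r.ci_low,
        "ci_high": r.ci_high, "p": r.p_value,
        "ld_variants": ",".join(r.ld_variants),
    } for r in records]
    pd.DataFrame(rows, columns=GWAS_COLUMNS).to_csv(path, sep=_sep(dialect), index=False)


def _fmt(value: Any, kind: str) -> str:
    """Fixed numeric rendering: OR/CI 2 dp, I² 1 dp, P 3 significant digits."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    if kind == "or":
        return f"{value:.2f}"
    if kind == "i2":
        return f"{value:.1f}"
    if kind == "p":
        return f"{value:.2e}"
    return str(value)


def synopsis_row(
    variant_id: str, gene: str, stratum: str, model: str, k: int,
    or_value: float, ci_low: float, ci_high: float, p: float,
    i_squared: float, venice: str = "", fprp: Optional[float] = None,
    evidence: str = "",
) -> dict[str, str]:
    """One formatted synopsis line in the fixed 13-column layout."""
    return {
        "variant_id": variant_id,
        "gene": gene,
        "stratum": stratum,
        "model": model,
        "k": str(k),
        "or": _fmt(or_value, "or"),
        "ci_low": _fmt(ci_low, "or"),
        "ci_high": _fmt(ci_high, "or"),
        "p": _fmt(p, "p"),
        "i_squared": _fmt(i_squared, "i2"),
        "venice": venice,
        "fprp": _fmt(fprp, "p") if fprp is not None else "",
        "evidence": evidence,
    }


def write_synopsis_table(
    rows: Sequence[dict[str, str]], path: Union[str, Path], format: str = "tsv"
) -> None:
    """Bit-stable synopsis output: fixed column order and formatting."""
    path = Path(path)
    for row in rows:
        missing = [c for c in SYNOPSIS_COLUMNS if c not in row]
        if missing:
            raise ValidationError(f"synopsis row missing column(s) {missing}")
    if format == "tsv":
        lines = ["\t".join(SYNOPSIS_COLUMNS)]
        lines += ["\t".join(str(row[c]) for c in SYNOPSIS_COLUMNS) for row in rows]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif format == "json":
        payload = [{c: row[c] for c in SYNOPSIS_COLUMNS} for row in rows]
        path.write_text(
            json.dumps(payload, indent=2, sort_keys=False) + "\n", encoding="utf-8"
        )
    else:
        raise ValueError(f"format must be 'tsv' or 'json', got {format!r}")


def read_synopsis_table(path: Union[str, Path], format: str = "tsv") -> list[dict[str, str]]:
    path = Path(path)
    if format == "json":
        return json.loads(path.read_text(encoding="utf-8"))
    lines = path.read_text(encoding="utf-8").splitlines()
    header = lines[0].split("\t")
    return [dict(zip(header, line.split("\t"))) for line in lines[1:]]


def write_error_report(errors: Sequence[dict[str, Any]], path: Union[str, Path]) -> None:
    """Validation errors as JSON lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for err in errors:
            fh.write(json.dumps(err, sort_keys=True) + "\n")
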