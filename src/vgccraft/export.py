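"""Spreadsheet-style export of query/association results.

The table keeps every original VCF field as text (so a CSV round trip is
lossless at the text level), adds per-sample GT columns, annotation
columns, and — when association output is supplied — per-cell counts and
p-values.  Supported formats: csv (RFC 4180), tsv, xlsx (single sheet
named "variants").  Legacy .xls and .pdf are deliberately unsupported.
"""

from __future__ import annotations

import csv
import datetime
from dataclasses import dataclass, field
from pathlib import Path

from .annotation import gnomad_url
from .association import GENOTYPE_COLUMNS, AssociationEntry
from .errors import UnsupportedAlleleError, UnsupportedFormatError
from .query_engine import QueryResult

__all__ = ["ResultTable", "to_table", "write_table", "read_table"]

FIXED_COLUMNS = ("CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO")
ANNOTATION_COLUMNS = ("CLINVAR_SIGNIFICANCE", "REGION", "GNOMAD_URL")


@dataclass
class ResultTable:
    columns: tuple[str, ...]
    rows: list[list[str]]
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        for row in self.rows:
            if len(row) != len(self.columns):
                raise ValueError(
                    f"row length {len(row)} != column count {len(self.columns)}"
                )


def _fmt_p(p: float | None) -> str:
    return "" if p is None else repr(p)


def to_table(
    result: QueryResult,
    assoc: list[AssociationEntry] | None = None,
) -> ResultTable:
    """Flatten a query result (plus optional association output) to a table."""
    columns: list[str] = list(FIXED_COLUMNS) + list(result.sample_ids) + list(ANNOTATION_COLUMNS)
    assoc_by_line: dict[int, AssociationEntry] = {}
    if assoc:
        group_order = assoc[0].table.group_order
        for entry in assoc:
            assoc_by_line[entry.variant.record.source_line_number] = entry
        for group in group_order:
            for cls in GENOTYPE_COLUMNS:
                columns.append(f"N_{group}_{cls.name}")
        columns += ["N_MISSING", "P_MC", "P_EXACT", "MC_SEED"]
    rows: list[list[str]] = []
    for av in result.variants:
        rec = av.record
        row = [
            rec.chrom, str(rec.pos), rec.id, rec.ref, ",".join(rec.alt_alleles),
            rec.raw_fixed[5], rec.filter, rec.info,
        ]
        row += list(rec.gt_strings)
        sig = av.pathogenicity.significance if av.pathogenicity else None
        row.append(sig or "")
        row.append(av.region.value if av.region else "")
        try:
            row.append(gnomad_url(rec, 0, result.spec.assembly))
        except UnsupportedAlleleError:
            row.append("")
        if assoc:
            entry = assoc_by_line.get(rec.source_line_number)
            if entry is None:
                row += [""] * (len(columns) - len(row))
            else:
                for i in range(len(entry.table.group_order)):
                    for j in range(3):
                        row.append(str(int(entry.table.counts[i, j])))
                row.append(str(entry.table.n_missing_excluded))
                if entry.result is None:
                    row += ["", "", ""]
                else:
                    row.append(_fmt_p(entry.result.p_mc))
                    row.append(_fmt_p(entry.result.p_exact))
                    row.append(
                        "" if entry.result.mc_seed is None else str(entry.result.mc_seed)
                    )
        rows.append(row)
    provenance = {
        "spec": result.spec,
        "n_variants": len(result.variants),
        "created": datetime.datetime.now().isoformat(timespec="seconds"),
    }
    return ResultTable(columns=tuple(columns), rows=rows, provenance=provenance)


def write_table(table: ResultTable, path: str | Path, fmt: str | None = None) -> Path:
    """Write csv/tsv/xlsx; format inferred from the extension when omitted."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt in ("xls", "pdf"):
        raise UnsupportedFormatError(
            f".{fmt} export is not supported (only csv, tsv and xlsx are); "
            "this headless build drops legacy/layout formats"
        )
    if fmt == "csv" or fmt == "tsv":
        delimiter = "," if fmt == "csv" else "\t"
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter=delimiter, quoting=csv.QUOTE_MINIMAL)
            writer.writerow(table.columns)
            writer.writerows(table.rows)
        return path
    if fmt == "xlsx":
        from openpyxl import Workbook

        wb = Workbook()
        ws = wb.active
        ws.title = "variants"
        ws.append(list(table.columns))
        for row in table.rows:
            ws.append(row)
        wb.save(path)
        return path
    raise UnsupportedFormatError(f"unsupported export format {fmt!r}")


def read_table(path: str | Path) -> ResultTable:
    """Read back a csv/tsv written by :func:`write_table` (text-level)."""
    path = Path(path)
    delimiter = "\t" if path.suffix.lower() == ".tsv" else ","
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        rows = list(reader)
    if not rows:
        raise UnsupportedFormatError(f"{path}: empty table file")
    return ResultTable(columns=tuple(rows[0]), rows=[list(r) for r in rows[1:]])
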