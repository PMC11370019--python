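"""Typed model of VCF headers, data lines and genotype calls.

Positions are kept 1-based (as in VCF) everywhere in this model; interval
arithmetic elsewhere converts at its own boundary.  Line numbers are
1-based physical line numbers counting every line of the (decompressed)
file, including meta and header lines.
"""

from __future__ import annotations

import gzip
import io
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator, TextIO

from .errors import (
    MalformedLineError,
    MalformedVcfError,
    NoSamplesError,
    PloidyError,
)

__all__ = [
    "GenotypeClass",
    "GenotypeCall",
    "VcfHeaderInfo",
    "VariantRecord",
    "SortednessReport",
    "open_text",
    "read_header",
    "parse_gt",
    "parse_data_line",
    "iter_records",
    "validate_sorted",
]

_GZIP_MAGIC = b"\x1f\x8b"


def open_text(path: str | Path) -> TextIO:
    """Open ``path`` as text, transparently decompressing gzip/bgzip."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == _GZIP_MAGIC:
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "r", encoding="utf-8")


class GenotypeClass(Enum):
    HOM_REF = 0
    HET = 1
    HOM_ALT = 2
    MISSING = -1


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's GT call: a pair of allele indices (-1 = missing)."""

    allele_indices: tuple[int, int]
    phased: bool = False

    @property
    def genotype_class(self) -> GenotypeClass:
        a, b = self.allele_indices
        if a < 0 or b < 0:
            return GenotypeClass.MISSING
        n_alt = (a > 0) + (b > 0)
        if n_alt == 0:
            return GenotypeClass.HOM_REF
        if n_alt == 1:
            return GenotypeClass.HET
        return GenotypeClass.HOM_ALT


_GT_SPLIT = re.compile(r"[/|]")


def parse_gt(gt: str) -> GenotypeCall:
    """Parse a GT subfield ("0/1", "1|2", ".", "0") into a call.

    Haploid calls are treated as homozygous for their single allele; more
    than two alleles per call is rejected (the three-class genotype model
    assumes diploidy).
    """
    phased = "|" in gt
    tokens = _GT_SPLIT.split(gt)
    if len(tokens) == 1:
        tokens = tokens * 2
    if len(tokens) > 2:
        raise PloidyError(f"genotype {gt!r} has {len(tokens)} alleles; at most 2 supported")
    indices = []
    for tok in tokens:
        if tok == "" or tok == ".":
            indices.append(-1)
        else:
            try:
                indices.append(int(tok))
            except ValueError as exc:
                raise MalformedLineError(f"unparseable GT token {tok!r} in {gt!r}") from exc
    return GenotypeCall(allele_indices=(indices[0], indices[1]), phased=phased)


@dataclass(frozen=True)
class VcfHeaderInfo:
    vcf_version: str
    sample_ids: tuple[str, ...]
    column_header_line: str
    meta_line_count: int

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def read_header(vcf_path: str | Path) -> VcfHeaderInfo:
    """Read the meta lines and the #CHROM column header of a VCF.

    Does not read past the column header line.
    """
    vcf_version = ""
    meta = 0
    with open_text(vcf_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##"):
                meta += 1
                if line.startswith("##fileformat="):
                    vcf_version = line.split("=", 1)[1]
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if len(cols) < 10:
                    raise NoSamplesError(f"{vcf_path}: VCF declares no sample columns")
                samples = tuple(cols[9:])
                if len(set(samples)) != len(samples):
                    raise MalformedVcfError(f"{vcf_path}: duplicate sample IDs in header")
                return VcfHeaderInfo(
                    vcf_version=vcf_version,
                    sample_ids=samples,
                    column_header_line=line,
                    meta_line_count=meta + 1,
                )
            raise MalformedVcfError(
                f"{vcf_path}: expected '#CHROM' header line, found {line[:50]!r}"
            )
    raise MalformedVcfError(f"{vcf_path}: no '#CHROM' header line found")


@dataclass(frozen=True)
class VariantRecord:
    """One parsed VCF data line.

    ``raw_fixed`` keeps the nine original CHROM..FORMAT column strings so
    that serialization is byte-exact; parsed fields are derived views.
    """

    chrom: str
    pos: int
    id: str
    ref: str
    alt_alleles: tuple[str, ...]
    qual: float | None
    filter: str
    info: str
    genotypes: tuple[GenotypeCall, ...]
    gt_strings: tuple[str, ...]
    raw_fixed: tuple[str, ...] = field(repr=False)
    source_line_number: int = 1

    @property
    def is_pass(self) -> bool:
        return self.filter == "PASS"

    def serialize_fixed(self) -> str:
        """The original CHROM..FORMAT columns, tab-joined, byte-for-byte."""
        return "\t".join(self.raw_fixed)

    def genotype_codes(self) -> list[int]:
        return [g.genotype_class.value for g in self.genotypes]


def parse_data_line(line: str, n_samples: int, source_line_number: int = 1) -> VariantRecord:
    """Parse one tab-separated VCF data line (FORMAT must contain GT)."""
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 9 + n_samples:
        raise MalformedLineError(
            f"line {source_line_number}: expected {9 + n_samples} columns, got {len(fields)}"
        )
    fmt = fields[8].split(":")
    try:
        gt_idx = fmt.index("GT")
    except ValueError as exc:
        raise MalformedLineError(
            f"line {source_line_number}: FORMAT {fields[8]!r} lacks GT"
        ) from exc
    calls: list[GenotypeCall] = []
    gt_strings: list[str] = []
    for sample_field in fields[9 : 9 + n_samples]:
        subfields = sample_field.split(":")
        gt = subfields[gt_idx] if gt_idx < len(subfields) else "."
        gt_strings.append(gt)
        calls.append(parse_gt(gt))
    qual_raw = fields[5]
    qual = None if qual_raw == "." else float(qual_raw)
    return VariantRecord(
        chrom=fields[0],
        pos=int(fields[1]),
        id=fields[2],
        ref=fields[3],
        alt_alleles=tuple(fields[4].split(",")),
        qual=qual,
        filter=fields[6],
        info=fields[7],
        genotypes=tuple(calls),
        gt_strings=tuple(gt_strings),
        raw_fixed=tuple(fields[:9]),
        source_line_number=source_line_number,
    )


def iter_records(
    vcf_path: str | Path, header: VcfHeaderInfo | None = None
) -> Iterator[VariantRecord]:
    """Yield every data line as a record with its physical line number."""
    if header is None:
        header = read_header(vcf_path)
    n = header.n_samples
    with open_text(vcf_path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if line_no <= header.meta_line_count or not line.strip():
                continue
            yield parse_data_line(line, n, source_line_number=line_no)


@dataclass(frozen=True)
class SortednessReport:
    chrom_blocks_contiguous: bool
    positions_nondecreasing: bool
    first_offending_line: int | None = None

    @property
    def is_sorted(self) -> bool:
        return self.chrom_blocks_contiguous and self.positions_nondecreasing


def validate_sorted(vcf_path: str | Path) -> SortednessReport:
    """Check chromosome-block contiguity and within-chromosome position order.

    Diagnostic: never raises for unsorted input; reports the first
    offending physical line number.
    """
    header = read_header(vcf_path)
    seen: set[str] = set()
    current: str | None = None
    last_pos = 0
    contiguous = True
    nondecreasing = True
    offending: int | None = None
    with open_text(vcf_path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if line_no <= header.meta_line_count or not line.strip():
                continue
            chrom, pos_s = line.split("\t", 2)[:2]
            pos = int(pos_s)
            if chrom != current:
                if chrom in seen:
                    contiguous = False
                    offending = offending or line_no
                seen.add(chrom)
                current = chrom
                last_pos = pos
            elif pos < last_pos:
                nondecreasing = False
                offending = offending or line_no
            last_pos = max(last_pos, pos)
    return SortednessReport(contiguous, nondecreasing, offending)
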