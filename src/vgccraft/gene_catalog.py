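"""Gene catalogs: symbol -> genomic span + exon structure, per assembly.

Catalog files are TSVs with columns symbol, chrom, start, end, exons
(semicolon-joined "start-end" pairs, possibly empty).  All coordinates are
1-based inclusive; overlapping or adjacent exons are merged on load.
A 6-column BED (0-based half-open) is accepted with ``bed=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from .errors import CatalogValidationError, DuplicateGeneError

__all__ = [
    "Assembly",
    "RegionClass",
    "GeneModel",
    "GeneCatalog",
    "load_catalog",
    "classify_position",
    "merge_intervals",
]


class Assembly(Enum):
    GRCH37 = "GRCh37"
    GRCH38 = "GRCh38"

    @classmethod
    def parse(cls, text: str) -> "Assembly":
        for member in cls:
            if member.value.lower() == text.lower():
                return member
        raise ValueError(f"unknown assembly {text!r}; expected GRCh37 or GRCh38")


class RegionClass(Enum):
    EXONIC = "EXONIC"
    INTRONIC = "INTRONIC"
    OUTSIDE = "OUTSIDE"


def merge_intervals(intervals: list[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Sort and merge overlapping/adjacent 1-based inclusive intervals."""
    if not intervals:
        return ()
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return tuple(merged)


@dataclass(frozen=True)
class GeneModel:
    symbol: str
    assembly: Assembly
    chrom: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if self.start > self.end:
            raise CatalogValidationError(f"{self.symbol}: start {self.start} > end {self.end}")
        for s, e in self.exons:
            if s > e or s < self.start or e > self.end:
                raise CatalogValidationError(
                    f"{self.symbol}: exon {s}-{e} outside gene span {self.start}-{self.end}"
                )


@dataclass
class GeneCatalog:
    assembly: Assembly
    genes: dict[str, GeneModel] = field(default_factory=dict)  # keyed upper-case

    def lookup(self, symbol: str) -> GeneModel | None:
        return self.genes.get(symbol.upper())

    def symbols(self) -> list[str]:
        return [g.symbol for g in self.genes.values()]

    def __len__(self) -> int:
        return len(self.genes)


def _parse_exons(text: str) -> list[tuple[int, int]]:
    if not text.strip():
        return []
    out = []
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        s, e = chunk.split("-")
        out.append((int(s), int(e)))
    return out


def load_catalog(path: str | Path, assembly: Assembly, bed: bool = False) -> GeneCatalog:
    """Load a catalog TSV (or 6-col BED with ``bed=True``) into a GeneCatalog."""
    catalog = GeneCatalog(assembly=assembly)
    with open(path, "r", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if bed:
                # BED: chrom, start(0-based), end(exclusive), name, [score, strand]
                chrom, start0, end_excl, symbol = cols[0], int(cols[1]), int(cols[2]), cols[3]
                gene = GeneModel(
                    symbol=symbol, assembly=assembly, chrom=chrom,
                    start=start0 + 1, end=end_excl, exons=(),
                )
            else:
                if line_no == 1 and cols[0].lower() == "symbol":
                    continue
                symbol, chrom = cols[0], cols[1]
                exons = merge_intervals(_parse_exons(cols[4] if len(cols) > 4 else ""))
                gene = GeneModel(
                    symbol=symbol, assembly=assembly, chrom=chrom,
                    start=int(cols[2]), end=int(cols[3]), exons=exons,
                )
            key = gene.symbol.upper()
            if key in catalog.genes:
                raise DuplicateGeneError(f"{path}:{line_no}: duplicate gene symbol {gene.symbol!r}")
            catalog.genes[key] = gene
    return catalog


def classify_position(gene: GeneModel, pos: int) -> RegionClass:
    """EXONIC inside any exon; INTRONIC inside the span but no exon; else OUTSIDE.

    Boundary positions are inside their interval (inclusive ends).
    """
    if pos < gene.start or pos > gene.end:
        return RegionClass.OUTSIDE
    for s, e in gene.exons:
        if s <= pos <= e:
            return RegionClass.EXONIC
        if pos < s:
            break
    return RegionClass.INTRONIC
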