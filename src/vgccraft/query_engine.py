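"""Gene / range / batch variant retrieval over the sidecar index.

Range endpoints are inclusive on both sides.  Retrieval reads only the
physical line span of the requested chromosome (from the index entry),
extracts positions cheaply, binary-searches the requested sub-range and
fully parses only the matching rows; ``QueryStats`` records how much work
was done so tests can assert the index is actually used.
"""

from __future__ import annotations

import re
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from difflib import get_close_matches
from enum import Enum
from pathlib import Path

from .annotation import ClinVarTable, PathogenicityCall, annotate_pathogenicity, normalize_chrom
from .errors import (
    BatchParseError,
    IndexRequiredError,
    MissingAnnotationError,
    PlanParseError,
    UnknownGeneError,
)
from .gene_catalog import Assembly, GeneCatalog, GeneModel, RegionClass, classify_position
from .indexer import IndexBundle
from .vcf_model import VariantRecord, open_text, parse_data_line, read_header

__all__ = [
    "FilterCategory",
    "QueryMode",
    "GenomicRange",
    "QuerySpec",
    "AnnotatedVariant",
    "QueryStats",
    "QueryResult",
    "query_range",
    "query_gene",
    "query_batch",
    "parse_batch_item",
    "save_plan",
    "load_plan",
]


class FilterCategory(Enum):
    ALL = "ALL"
    PASS = "PASS"
    PATHOGENIC = "PATHOGENIC"

    @classmethod
    def parse(cls, text: str) -> "FilterCategory":
        try:
            return cls[text.upper()]
        except KeyError:
            raise ValueError(f"unknown filter {text!r}; expected all|pass|pathogenic") from None


class QueryMode(Enum):
    GENE = "GENE"
    RANGE = "RANGE"
    BATCH = "BATCH"


@dataclass(frozen=True)
class GenomicRange:
    chrom: str
    start: int  # 1-based inclusive
    end: int    # inclusive

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid range {self.chrom}:{self.start}-{self.end}")

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @classmethod
    def parse(cls, text: str) -> "GenomicRange":
        m = re.fullmatch(r"([^:\s]+):(\d+)-(\d+)", text.strip())
        if not m:
            raise ValueError(f"cannot parse genomic range {text!r} (expected chrom:start-end)")
        return cls(m.group(1), int(m.group(2)), int(m.group(3)))


@dataclass(frozen=True)
class QuerySpec:
    mode: QueryMode
    filter: FilterCategory = FilterCategory.ALL
    assembly: Assembly = Assembly.GRCH38
    gene_symbol: str | None = None
    range: GenomicRange | None = None
    batch_items: tuple[str, ...] | None = None


@dataclass(frozen=True)
class AnnotatedVariant:
    record: VariantRecord
    pathogenicity: PathogenicityCall | None = None
    region: RegionClass | None = None


@dataclass
class QueryStats:
    lines_in_span: int = 0
    lines_parsed: int = 0


@dataclass
class QueryResult:
    spec: QuerySpec
    variants: list[AnnotatedVariant]
    sample_ids: tuple[str, ...]
    per_item_counts: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    stats: QueryStats = field(default_factory=QueryStats)

    def __len__(self) -> int:
        return len(self.variants)


def _filter_predicate(flt: FilterCategory, annot: ClinVarTable | None):
    if flt is FilterCategory.ALL:
        return lambda rec, call: True
    if flt is FilterCategory.PASS:
        return lambda rec, call: rec.is_pass
    if annot is None:
        raise MissingAnnotationError(
            "filter PATHOGENIC requires a ClinVar-style annotation table (--clinvar)"
        )
    return lambda rec, call: call is not None and call.is_pathogenic


def query_range(
    bundle: IndexBundle,
    vcf_path: str | Path,
    rng: GenomicRange,
    flt: FilterCategory = FilterCategory.ALL,
    annot: ClinVarTable | None = None,
    spec: QuerySpec | None = None,
) -> QueryResult:
    """All variants with chrom == rng.chrom and start <= pos <= end, filtered."""
    if bundle is None:
        raise IndexRequiredError("query_range needs an index bundle; build one first")
    predicate = _filter_predicate(flt, annot)
    header = read_header(vcf_path)
    spec = spec or QuerySpec(mode=QueryMode.RANGE, filter=flt, range=rng)
    result = QueryResult(spec=spec, variants=[], sample_ids=header.sample_ids)
    entry = bundle.entry_for(rng.chrom)
    if entry is None:
        return result
    # Collect raw lines of the chromosome's span only.
    span_lines: list[tuple[int, str]] = []
    with open_text(vcf_path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if line_no < entry.start_line:
                continue
            if line_no > entry.end_line:
                break
            span_lines.append((line_no, line))
    result.stats.lines_in_span = len(span_lines)
    positions = [int(line.split("\t", 2)[1]) for _no, line in span_lines]
    lo = bisect_left(positions, rng.start)
    hi = bisect_right(positions, rng.end)
    n = header.n_samples
    for line_no, line in span_lines[lo:hi]:
        rec = parse_data_line(line, n, source_line_number=line_no)
        result.stats.lines_parsed += 1
        call = annotate_pathogenicity(rec, annot) if annot is not None else None
        if predicate(rec, call):
            result.variants.append(AnnotatedVariant(record=rec, pathogenicity=call))
    return result


def query_gene(
    bundle: IndexBundle,
    vcf_path: str | Path,
    catalog: GeneCatalog,
    symbol: str,
    flt: FilterCategory = FilterCategory.ALL,
    annot: ClinVarTable | None = None,
) -> QueryResult:
    """query_range over the gene's span, with exonic/intronic labels."""
    gene = catalog.lookup(symbol)
    if gene is None:
        suggestions = tuple(
            get_close_matches(symbol.upper(), [s.upper() for s in catalog.symbols()], n=3)
        )
        hint = f"; did you mean {', '.join(suggestions)}?" if suggestions else ""
        raise UnknownGeneError(f"unknown gene {symbol!r}{hint}", suggestions=suggestions)
    spec = QuerySpec(
        mode=QueryMode.GENE, filter=flt, assembly=catalog.assembly, gene_symbol=gene.symbol
    )
    rng = GenomicRange(gene.chrom, gene.start, gene.end)
    result = query_range(bundle, vcf_path, rng, flt, annot, spec=spec)
    result.variants = [
        AnnotatedVariant(
            record=av.record,
            pathogenicity=av.pathogenicity,
            region=classify_position(gene, av.record.pos),
        )
        for av in result.variants
    ]
    return result


_RANGE_RE = re.compile(r"^[^:\s]+:\d+-\d+$")


def parse_batch_item(item: str) -> GenomicRange | str:
    """A batch line is either "chrom:start-end" or a gene symbol."""
    item = item.strip()
    if ":" in item:
        if not _RANGE_RE.match(item):
            raise BatchParseError(
                f"cannot parse batch item {item!r} (expected chrom:start-end)"
            )
        return GenomicRange.parse(item)
    if not item or any(ch.isspace() for ch in item):
        raise BatchParseError(f"cannot parse batch item {item!r}")
    return item


def query_batch(
    bundle: IndexBundle,
    vcf_path: str | Path,
    catalog: GeneCatalog | None,
    batch_path: str | Path,
    flt: FilterCategory = FilterCategory.ALL,
    annot: ClinVarTable | None = None,
) -> QueryResult:
    """Union of per-item results, deduplicated; one count per input line.

    Unknown genes are recorded as count 0 with a warning rather than
    failing the whole batch; unparseable lines are fatal and name the
    line number.
    """
    items: list[str] = []
    with open(batch_path, "r", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            try:
                parse_batch_item(text)
            except (BatchParseError, ValueError) as exc:
                raise BatchParseError(f"{batch_path}:{line_no}: {exc}") from exc
            items.append(text)
    spec = QuerySpec(mode=QueryMode.BATCH, filter=flt, batch_items=tuple(items))
    header = read_header(vcf_path)
    merged = QueryResult(spec=spec, variants=[], sample_ids=header.sample_ids)
    seen: set[int] = set()
    for item in items:
        parsed = parse_batch_item(item)
        try:
            if isinstance(parsed, GenomicRange):
                sub = query_range(bundle, vcf_path, parsed, flt, annot)
            else:
                if catalog is None:
                    raise UnknownGeneError(f"no gene catalog supplied for item {item!r}")
                sub = query_gene(bundle, vcf_path, catalog, parsed, flt, annot)
        except UnknownGeneError as exc:
            merged.per_item_counts[item] = 0
            merged.warnings.append(str(exc))
            continue
        merged.per_item_counts[item] = len(sub)
        merged.stats.lines_in_span += sub.stats.lines_in_span
        merged.stats.lines_parsed += sub.stats.lines_parsed
        for av in sub.variants:
            key = av.record.source_line_number
            if key not in seen:
                seen.add(key)
                merged.variants.append(av)
    merged.variants.sort(
        key=lambda av: (bundle.chrom_rank(av.record.chrom), av.record.pos,
                        av.record.source_line_number)
    )
    return merged


_PLAN_KEYS = ("mode", "filter", "assembly", "gene", "range", "batch")


def save_plan(spec: QuerySpec, path: str | Path) -> Path:
    """Canonical key=value serialization; equal specs give identical bytes."""
    lines = [
        f"mode={spec.mode.value}",
        f"filter={spec.filter.value}",
        f"assembly={spec.assembly.value}",
    ]
    if spec.gene_symbol is not None:
        lines.append(f"gene={spec.gene_symbol}")
    if spec.range is not None:
        lines.append(f"range={spec.range}")
    if spec.batch_items is not None:
        lines.append(f"batch={','.join(spec.batch_items)}")
    path = Path(path)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def load_plan(path: str | Path) -> QuerySpec:
    kv: dict[str, str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise PlanParseError(f"{path}: malformed line {line!r}", key=line)
        key, value = line.split("=", 1)
        if key not in _PLAN_KEYS:
            raise PlanParseError(f"{path}: unknown plan key {key!r}", key=key)
        kv[key] = value
    try:
        mode = QueryMode[kv["mode"].upper()]
    except KeyError:
        raise PlanParseError(f"{path}: missing or invalid 'mode'", key="mode") from None
    try:
        flt = FilterCategory[kv.get("filter", "ALL").upper()]
    except KeyError:
        raise PlanParseError(
            f"{path}: invalid filter value {kv.get('filter')!r}", key="filter"
        ) from None
    try:
        assembly = Assembly.parse(kv.get("assembly", "GRCh38"))
    except ValueError:
        raise PlanParseError(
            f"{path}: invalid assembly value {kv.get('assembly')!r}", key="assembly"
        ) from None
    rng = None
    if "range" in kv:
        try:
            rng = GenomicRange.parse(kv["range"])
        except ValueError:
            raise PlanParseError(f"{path}: invalid range {kv['range']!r}", key="range") from None
    batch = tuple(kv["batch"].split(",")) if "batch" in kv else None
    return QuerySpec(
        mode=mode,
        filter=flt,
        assembly=assembly,
        gene_symbol=kv.get("gene"),
        range=rng,
        batch_items=batch,
    )
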