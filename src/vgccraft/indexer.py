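"""Sidecar index construction and persistence.

For each VCF a directory ``<root>/VGCGeneratedFiles/VGC_<stem>/`` holds two
text files:

* ``info_<stem>.txt`` — ``key=value`` lines describing the whole file
  (version, sample/chromosome/variant counts, header line, chromosome
  list, plus source size/mtime for staleness checks);
* ``index_<stem>.txt`` — a TSV with one row per chromosome: physical line
  span, position span, PASS count and pathogenic count.

Line numbers are 1-based and count every physical line of the
(decompressed) file, including meta/header lines.  Writes are atomic
(temp file + rename).
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

from .annotation import ClinVarTable, annotate_pathogenicity
from .errors import CorruptIndexError, EmptyVcfError, SortRequiredError
from .vcf_model import VcfHeaderInfo, open_text, parse_data_line, read_header

__all__ = [
    "FileInfo",
    "ChromosomeIndexEntry",
    "IndexBundle",
    "vcf_stem",
    "build_index",
    "write_index_files",
    "load_index",
    "index_dir_for",
]

INDEX_COLUMNS = (
    "chrom", "start_line", "end_line", "start_pos", "end_pos",
    "pass_count", "pathogenic_count",
)


@dataclass(frozen=True)
class FileInfo:
    vcf_version: str
    sample_count: int
    chromosome_count: int
    variant_count: int
    header_line: str
    chromosome_list: tuple[str, ...]
    source_size: int
    source_mtime_ns: int


@dataclass(frozen=True)
class ChromosomeIndexEntry:
    chrom: str
    start_line: int
    end_line: int
    start_pos: int
    end_pos: int
    pass_count: int
    pathogenic_count: int

    @property
    def n_variants(self) -> int:
        return self.end_line - self.start_line + 1


@dataclass
class IndexBundle:
    info: FileInfo
    entries: tuple[ChromosomeIndexEntry, ...]
    source_path: str
    has_pathogenicity_source: bool
    output_dir: str | None = field(default=None, compare=False)

    def entry_for(self, chrom: str) -> ChromosomeIndexEntry | None:
        from .annotation import normalize_chrom

        want = normalize_chrom(chrom)
        for entry in self.entries:
            if normalize_chrom(entry.chrom) == want:
                return entry
        return None

    def chrom_rank(self, chrom: str) -> int:
        from .annotation import normalize_chrom

        want = normalize_chrom(chrom)
        for i, c in enumerate(self.info.chromosome_list):
            if normalize_chrom(c) == want:
                return i
        return len(self.info.chromosome_list)


def vcf_stem(vcf_path: str | Path) -> str:
    name = Path(vcf_path).name
    for suffix in (".vcf.gz", ".vcf.bgz", ".vcf", ".gz"):
        if name.endswith(suffix):
            return name[: -len(suffix)]
    return name


def index_dir_for(vcf_path: str | Path, root: str | Path) -> Path:
    return Path(root) / "VGCGeneratedFiles" / f"VGC_{vcf_stem(vcf_path)}"


class _ChromAccumulator:
    __slots__ = ("chrom", "start_line", "end_line", "start_pos", "end_pos",
                 "pass_count", "pathogenic_count")

    def __init__(self, chrom: str, line_no: int, pos: int):
        self.chrom = chrom
        self.start_line = line_no
        self.end_line = line_no
        self.start_pos = pos
        self.end_pos = pos
        self.pass_count = 0
        self.pathogenic_count = 0


def build_index(
    vcf_path: str | Path,
    pathogenicity_table: ClinVarTable | None = None,
    header: VcfHeaderInfo | None = None,
) -> IndexBundle:
    """Single pass over the VCF: per-chromosome spans and counts.

    Sortedness (contiguous chromosome blocks, nondecreasing positions) is
    enforced during the scan; violations raise :class:`SortRequiredError`
    naming the offending line.  Without a pathogenicity table all
    pathogenic counts are 0 and the bundle is flagged accordingly.
    """
    vcf_path = Path(vcf_path)
    if header is None:
        header = read_header(vcf_path)
    n = header.n_samples
    accs: dict[str, _ChromAccumulator] = {}
    current: str | None = None
    with open_text(vcf_path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if line_no <= header.meta_line_count or not line.strip():
                continue
            rec = parse_data_line(line, n, source_line_number=line_no)
            if rec.chrom != current:
                if rec.chrom in accs:
                    raise SortRequiredError(
                        f"{vcf_path}: chromosome {rec.chrom} re-appears at line {line_no}; "
                        "sort the VCF and retry",
                        line_number=line_no,
                    )
                accs[rec.chrom] = _ChromAccumulator(rec.chrom, line_no, rec.pos)
                current = rec.chrom
            acc = accs[rec.chrom]
            if rec.pos < acc.end_pos:
                raise SortRequiredError(
                    f"{vcf_path}: position {rec.pos} < {acc.end_pos} on {rec.chrom} "
                    f"at line {line_no}; sort the VCF and retry",
                    line_number=line_no,
                )
            acc.end_line = line_no
            acc.end_pos = rec.pos
            if rec.is_pass:
                acc.pass_count += 1
            if pathogenicity_table is not None:
                if annotate_pathogenicity(rec, pathogenicity_table).is_pathogenic:
                    acc.pathogenic_count += 1
    if not accs:
        raise EmptyVcfError(f"{vcf_path}: no data lines")
    entries = tuple(
        ChromosomeIndexEntry(
            chrom=a.chrom, start_line=a.start_line, end_line=a.end_line,
            start_pos=a.start_pos, end_pos=a.end_pos,
            pass_count=a.pass_count, pathogenic_count=a.pathogenic_count,
        )
        for a in accs.values()
    )
    stat = os.stat(vcf_path)
    info = FileInfo(
        vcf_version=header.vcf_version,
        sample_count=n,
        chromosome_count=len(entries),
        variant_count=sum(e.n_variants for e in entries),
        header_line=header.column_header_line,
        chromosome_list=tuple(e.chrom for e in entries),
        source_size=stat.st_size,
        source_mtime_ns=stat.st_mtime_ns,
    )
    return IndexBundle(
        info=info,
        entries=entries,
        source_path=str(vcf_path),
        has_pathogenicity_source=pathogenicity_table is not None,
    )


def _atomic_write(path: Path, content: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(content)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_index_files(bundle: IndexBundle, root: str | Path) -> tuple[Path, Path]:
    """Persist the bundle under root/VGCGeneratedFiles/VGC_<stem>/."""
    stem = vcf_stem(bundle.source_path)
    out_dir = index_dir_for(bundle.source_path, root)
    out_dir.mkdir(parents=True, exist_ok=True)
    info = bundle.info
    info_lines = [
        f"vcf_version={info.vcf_version}",
        f"sample_count={info.sample_count}",
        f"chromosome_count={info.chromosome_count}",
        f"variant_count={info.variant_count}",
        f"header_line={info.header_line}",
        f"chromosomes={','.join(info.chromosome_list)}",
        f"source_size={info.source_size}",
        f"source_mtime_ns={info.source_mtime_ns}",
        f"has_pathogenicity_source={str(bundle.has_pathogenicity_source).lower()}",
    ]
    index_lines = ["\t".join(INDEX_COLUMNS)]
    for e in bundle.entries:
        index_lines.append(
            f"{e.chrom}\t{e.start_line}\t{e.end_line}\t{e.start_pos}\t{e.end_pos}"
            f"\t{e.pass_count}\t{e.pathogenic_count}"
        )
    info_path = out_dir / f"info_{stem}.txt"
    index_path = out_dir / f"index_{stem}.txt"
    _atomic_write(info_path, "\n".join(info_lines) + "\n")
    _atomic_write(index_path, "\n".join(index_lines) + "\n")
    bundle.output_dir = str(out_dir)
    return info_path, index_path


def load_index(vcf_path: str | Path, root: str | Path) -> IndexBundle | None:
    """Load the sidecar bundle if present and fresh; ``None`` otherwise.

    Freshness is a cheap check: recorded source size and mtime must match
    the file on disk.  A present-but-unparseable sidecar raises
    :class:`CorruptIndexError` advising a rebuild.
    """
    vcf_path = Path(vcf_path)
    stem = vcf_stem(vcf_path)
    out_dir = index_dir_for(vcf_path, root)
    info_path = out_dir / f"info_{stem}.txt"
    index_path = out_dir / f"index_{stem}.txt"
    if not info_path.exists() or not index_path.exists():
        return None
    kv: dict[str, str] = {}
    for line in info_path.read_text(encoding="utf-8").splitlines():
        if "=" in line:
            key, value = line.split("=", 1)
            kv[key] = value
    required = {
        "vcf_version", "sample_count", "chromosome_count", "variant_count",
        "header_line", "chromosomes", "source_size", "source_mtime_ns",
    }
    if not required <= kv.keys():
        raise CorruptIndexError(
            f"{info_path}: missing keys {sorted(required - kv.keys())}; rebuild the index"
        )
    entries: list[ChromosomeIndexEntry] = []
    try:
        info = FileInfo(
            vcf_version=kv["vcf_version"],
            sample_count=int(kv["sample_count"]),
            chromosome_count=int(kv["chromosome_count"]),
            variant_count=int(kv["variant_count"]),
            header_line=kv["header_line"],
            chromosome_list=tuple(c for c in kv["chromosomes"].split(",") if c),
            source_size=int(kv["source_size"]),
            source_mtime_ns=int(kv["source_mtime_ns"]),
        )
        lines = index_path.read_text(encoding="utf-8").splitlines()
        if not lines or tuple(lines[0].split("\t")) != INDEX_COLUMNS:
            raise CorruptIndexError(f"{index_path}: bad or missing header row; rebuild the index")
        for line in lines[1:]:
            cols = line.split("\t")
            if len(cols) != len(INDEX_COLUMNS):
                raise CorruptIndexError(f"{index_path}: malformed row {line!r}; rebuild the index")
            entries.append(
                ChromosomeIndexEntry(
                    chrom=cols[0], start_line=int(cols[1]), end_line=int(cols[2]),
                    start_pos=int(cols[3]), end_pos=int(cols[4]),
                    pass_count=int(cols[5]), pathogenic_count=int(cols[6]),
                )
            )
    except CorruptIndexError:
        raise
    except (ValueError, IndexError) as exc:
        raise CorruptIndexError(f"{out_dir}: corrupt sidecar ({exc}); rebuild the index") from exc
    if len(entries) != info.chromosome_count:
        raise CorruptIndexError(
            f"{index_path}: {len(entries)} entries but chromosome_count="
            f"{info.chromosome_count}; rebuild the index"
        )
    stat = os.stat(vcf_path)
    if stat.st_size != info.source_size or stat.st_mtime_ns != info.source_mtime_ns:
        return None  # stale
    bundle = IndexBundle(
        info=info,
        entries=tuple(entries),
        source_path=str(vcf_path),
        has_pathogenicity_source=kv.get("has_pathogenicity_source", "false") == "true",
        output_dir=str(out_dir),
    )
    return bundle
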