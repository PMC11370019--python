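"""Local pathogenicity annotation, gnomAD link construction, GMT gene sets.

The ClinVar-style table is a plain TSV extract keyed by
(chrom, pos, ref, alt); chromosome names are normalized by stripping an
optional "chr" prefix on both sides of every join.  No network access is
ever performed: the gnomAD integration is URL construction only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from .errors import GmtParseError, UnsupportedAlleleError
from .gene_catalog import Assembly
from .vcf_model import VariantRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ClinVarRecord",
    "ClinVarTable",
    "PathogenicityCall",
    "PATHOGENIC_LABELS",
    "load_clinvar_table",
    "annotate_pathogenicity",
    "gnomad_url",
    "DEFAULT_GNOMAD_DATASETS",
    "GeneSetCollection",
    "load_gene_sets",
    "gene_set_membership",
]

#: ClinVar aggregate significance labels counted as pathogenic
#: (lower-cased; "conflicting interpretations" is deliberately excluded).
PATHOGENIC_LABELS = frozenset(
    {"pathogenic", "likely pathogenic", "pathogenic/likely pathogenic"}
)


def normalize_chrom(chrom: str) -> str:
    """'chr1' and '1' address the same chromosome in all joins."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


@dataclass(frozen=True)
class ClinVarRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    clinical_significance: str
    condition: str | None = None
    review_status: str | None = None

    @property
    def is_pathogenic(self) -> bool:
        return self.clinical_significance.lower() in PATHOGENIC_LABELS


class ClinVarTable:
    """O(1) lookup of ClinVar-style records by (chrom, pos, ref, alt)."""

    def __init__(self, records: dict[tuple[str, int, str, str], ClinVarRecord]):
        self._records = records

    def get(self, chrom: str, pos: int, ref: str, alt: str) -> ClinVarRecord | None:
        return self._records.get((normalize_chrom(chrom), pos, ref, alt))

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records.values())


def load_clinvar_table(path: str | Path) -> ClinVarTable:
    """Load a ClinVar-style TSV (chrom, pos, ref, alt, clinical_significance
    [, condition, review_status]); duplicate keys are last-wins with a
    logged warning."""
    records: dict[tuple[str, int, str, str], ClinVarRecord] = {}
    with open(path, "r", encoding="utf-8") as fh:
        header_cols: list[str] | None = None
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if header_cols is None and cols[0].lower() == "chrom":
                header_cols = cols
                continue
            rec = ClinVarRecord(
                chrom=cols[0],
                pos=int(cols[1]),
                ref=cols[2],
                alt=cols[3],
                clinical_significance=cols[4],
                condition=cols[5] if len(cols) > 5 and cols[5] else None,
                review_status=cols[6] if len(cols) > 6 and cols[6] else None,
            )
            key = (normalize_chrom(rec.chrom), rec.pos, rec.ref, rec.alt)
            if key in records:
                logger.warning("duplicate ClinVar key %s at line %d; last wins", key, line_no)
            records[key] = rec
    return ClinVarTable(records)


@dataclass(frozen=True)
class PathogenicityCall:
    is_pathogenic: bool
    significance: str | None
    matched: bool


def annotate_pathogenicity(variant: VariantRecord, table: ClinVarTable) -> PathogenicityCall:
    """Join a variant against the table by any of its alt alleles.

    If several alts match, a pathogenic match takes precedence.
    """
    matches = [
        rec
        for alt in variant.alt_alleles
        if (rec := table.get(variant.chrom, variant.pos, variant.ref, alt)) is not None
    ]
    if not matches:
        return PathogenicityCall(is_pathogenic=False, significance=None, matched=False)
    best = next((m for m in matches if m.is_pathogenic), matches[0])
    return PathogenicityCall(
        is_pathogenic=best.is_pathogenic,
        significance=best.clinical_significance,
        matched=True,
    )


DEFAULT_GNOMAD_DATASETS: dict[Assembly, str] = {
    Assembly.GRCH37: "gnomad_r2_1",
    Assembly.GRCH38: "gnomad_r4",
}

_ALLELE_CHARS = frozenset("ACGTNacgtn")


def gnomad_url(
    variant: VariantRecord,
    alt_index: int,
    assembly: Assembly,
    dataset_tags: dict[Assembly, str] | None = None,
) -> str:
    """Construct the gnomAD variant-page URL; no I/O is performed."""
    if not 0 <= alt_index < len(variant.alt_alleles):
        raise IndexError(f"alt_index {alt_index} out of range")
    alt = variant.alt_alleles[alt_index]
    for allele in (variant.ref, alt):
        if not allele or not set(allele) <= _ALLELE_CHARS:
            raise UnsupportedAlleleError(
                f"allele {allele!r} is symbolic or non-sequence; no gnomAD URL"
            )
    tags = dataset_tags or DEFAULT_GNOMAD_DATASETS
    chrom = normalize_chrom(variant.chrom)
    return (
        f"https://gnomad.broadinstitute.org/variant/"
        f"{chrom}-{variant.pos}-{variant.ref}-{alt}?dataset={tags[assembly]}"
    )


@dataclass(frozen=True)
class GeneSetCollection:
    name: str
    sets: dict[str, tuple[str, tuple[str, ...]]]  # set name -> (description, members)


def load_gene_sets(gmt_path: str | Path) -> GeneSetCollection:
    """Parse a standard GMT file: name TAB description TAB member..."""
    path = Path(gmt_path)
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise GmtParseError(f"{path}:{line_no}: GMT line has {len(cols)} fields (< 3)")
            name, desc = cols[0], cols[1]
            members: list[str] = []
            seen: set[str] = set()
            for m in cols[2:]:
                if m and m.upper() not in seen:
                    seen.add(m.upper())
                    members.append(m)
            sets[name] = (desc, tuple(members))
    return GeneSetCollection(name=path.stem, sets=sets)


def gene_set_membership(collection: GeneSetCollection, symbol: str) -> list[str]:
    """Every set containing ``symbol`` (case-insensitive), possibly empty."""
    target = symbol.upper()
    return [
        name
        for name, (_desc, members) in collection.sets.items()
        if any(m.upper() == target for m in members)
    ]
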