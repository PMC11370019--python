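"""Data models behind the views: histogram + zoom, node graph, heat map.

No rendering happens here; every structure is plain data that a renderer
(or the JSON serializers at the bottom) can consume.  Zoom splits a range
into 20 equal-width bins (the last bin absorbs the remainder); once a
range is narrower than 20 positions, bins become single positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .annotation import ClinVarTable
from .errors import MissingAnnotationError
from .gene_catalog import GeneModel, RegionClass, classify_position
from .indexer import IndexBundle
from .query_engine import (
    AnnotatedVariant,
    FilterCategory,
    GenomicRange,
    QueryResult,
    query_range,
)
from .association import PhenotypeGroups
from .vcf_model import GenotypeClass

import numpy as np

__all__ = [
    "ZOOM_BINS",
    "HistogramBin",
    "HistogramView",
    "TooltipPayload",
    "NodeGraphModel",
    "chromosome_histogram",
    "zoom",
    "back",
    "hover",
    "build_node_graph",
    "genotype_matrix",
    "histogram_to_json",
    "node_graph_to_json",
]

ZOOM_BINS = 20


@dataclass(frozen=True)
class HistogramBin:
    range: GenomicRange
    count: int
    exonic_count: int | None = None
    pathogenic_count: int | None = None


@dataclass
class _ViewContext:
    vcf_path: str
    bundle: IndexBundle
    annot: ClinVarTable | None = None
    gene: GeneModel | None = None


@dataclass
class HistogramView:
    bins: tuple[HistogramBin, ...]
    level: int
    filter: FilterCategory
    # Navigation history: each element is the range the previous level
    # displayed; None marks the level-0 whole-file per-chromosome view.
    zoom_stack: tuple[GenomicRange | None, ...] = ()
    ctx: _ViewContext | None = field(default=None, compare=False, repr=False)

    @property
    def total(self) -> int:
        return sum(b.count for b in self.bins)


def chromosome_histogram(
    bundle: IndexBundle,
    vcf_path: str | Path,
    flt: FilterCategory = FilterCategory.ALL,
    annot: ClinVarTable | None = None,
) -> HistogramView:
    """Level-0 view: one bin per chromosome, counts straight from the index."""
    if flt is FilterCategory.PATHOGENIC and not bundle.has_pathogenicity_source:
        raise MissingAnnotationError(
            "PATHOGENIC histogram requested but the index was built without a "
            "pathogenicity source; rebuild with --clinvar"
        )
    bins = []
    for entry in bundle.entries:
        if flt is FilterCategory.ALL:
            count = entry.n_variants
        elif flt is FilterCategory.PASS:
            count = entry.pass_count
        else:
            count = entry.pathogenic_count
        bins.append(
            HistogramBin(
                range=GenomicRange(entry.chrom, entry.start_pos, entry.end_pos),
                count=count,
                pathogenic_count=entry.pathogenic_count
                if bundle.has_pathogenicity_source
                else None,
            )
        )
    return HistogramView(
        bins=tuple(bins),
        level=0,
        filter=flt,
        zoom_stack=(),
        ctx=_ViewContext(str(vcf_path), bundle, annot),
    )


def _bin_ranges(parent: GenomicRange) -> list[GenomicRange]:
    width = parent.width
    if width <= ZOOM_BINS:
        return [GenomicRange(parent.chrom, p, p) for p in range(parent.start, parent.end + 1)]
    step = width // ZOOM_BINS
    ranges = []
    for i in range(ZOOM_BINS):
        start = parent.start + i * step
        end = parent.end if i == ZOOM_BINS - 1 else start + step - 1
        ranges.append(GenomicRange(parent.chrom, start, end))
    return ranges


def _binned_view(
    parent: GenomicRange,
    level: int,
    stack: tuple[GenomicRange | None, ...],
    flt: FilterCategory,
    ctx: _ViewContext,
) -> HistogramView:
    bins = []
    for rng in _bin_ranges(parent):
        sub = query_range(ctx.bundle, ctx.vcf_path, rng, flt, ctx.annot)
        pathogenic = None
        if ctx.annot is not None:
            pathogenic = sum(
                1 for av in sub.variants if av.pathogenicity and av.pathogenicity.is_pathogenic
            )
        exonic = None
        if ctx.gene is not None:
            exonic = sum(
                1
                for av in sub.variants
                if classify_position(ctx.gene, av.record.pos) is RegionClass.EXONIC
            )
        bins.append(
            HistogramBin(range=rng, count=len(sub), exonic_count=exonic,
                         pathogenic_count=pathogenic)
        )
    return HistogramView(bins=tuple(bins), level=level, filter=flt, zoom_stack=stack, ctx=ctx)


def zoom(view: HistogramView, bin_index: int) -> HistogramView:
    """Split the selected bin's range into child bins (see module docstring)."""
    if view.ctx is None:
        raise ValueError("view carries no source context; cannot zoom")
    parent_bin = view.bins[bin_index]
    prior: GenomicRange | None
    if view.level == 0:
        prior = None
    else:
        first, last = view.bins[0].range, view.bins[-1].range
        prior = GenomicRange(first.chrom, first.start, last.end)
    return _binned_view(
        parent_bin.range,
        level=view.level + 1,
        stack=view.zoom_stack + (prior,),
        flt=view.filter,
        ctx=view.ctx,
    )


def back(view: HistogramView) -> HistogramView:
    """Pop one zoom level; restores a view equal to the pre-zoom one."""
    if not view.zoom_stack:
        raise ValueError("already at level 0; nothing to go back to")
    if view.ctx is None:
        raise ValueError("view carries no source context; cannot navigate")
    prior = view.zoom_stack[-1]
    rest = view.zoom_stack[:-1]
    if prior is None:
        return chromosome_histogram(
            view.ctx.bundle, view.ctx.vcf_path, view.filter, view.ctx.annot
        )
    return _binned_view(prior, level=view.level - 1, stack=rest, flt=view.filter, ctx=view.ctx)


@dataclass(frozen=True)
class TooltipPayload:
    range: GenomicRange
    variant_count: int
    variants_at_position: tuple[tuple[str, str, str | None], ...] | None = None


def hover(view: HistogramView, bin_index: int) -> TooltipPayload:
    """Range + count; at single-position bins also (ref, alt, significance)."""
    hbin = view.bins[bin_index]
    if hbin.range.width != 1 or view.ctx is None:
        return TooltipPayload(range=hbin.range, variant_count=hbin.count)
    ctx = view.ctx
    sub = query_range(ctx.bundle, ctx.vcf_path, hbin.range, view.filter, ctx.annot)
    details = tuple(
        (
            av.record.ref,
            ",".join(av.record.alt_alleles),
            av.pathogenicity.significance if av.pathogenicity else None,
        )
        for av in sub.variants
    )
    return TooltipPayload(range=hbin.range, variant_count=hbin.count,
                          variants_at_position=details)


def variant_key(av: AnnotatedVariant) -> str:
    rec = av.record
    return f"{rec.chrom}:{rec.pos}:{rec.ref}:{','.join(rec.alt_alleles)}"


@dataclass
class NodeGraphModel:
    variant_nodes: list[tuple[str, bool]]                 # (key, pathogenic flag)
    sample_nodes: list[tuple[str, str]]                   # (sample_id, group)
    edges: list[tuple[str, str, GenotypeClass]]           # only HET / HOM_ALT

    def sample_degree(self, sample_id: str) -> int:
        return sum(1 for _v, s, _c in self.edges if s == sample_id)


def build_node_graph(
    result: QueryResult,
    groups: PhenotypeGroups,
    annot: ClinVarTable | None = None,
) -> NodeGraphModel:
    """Bipartite variant/sample graph; edges carry non-reference genotypes only."""
    from .annotation import annotate_pathogenicity

    variant_nodes = []
    edges = []
    assigned = [s for s in result.sample_ids if s in groups.assignment]
    sample_nodes = [(s, groups.assignment[s]) for s in assigned]
    for av in result.variants:
        call = av.pathogenicity
        if call is None and annot is not None:
            call = annotate_pathogenicity(av.record, annot)
        key = variant_key(av)
        variant_nodes.append((key, bool(call and call.is_pathogenic)))
        for sample, gcall in zip(result.sample_ids, av.record.genotypes):
            if sample not in groups.assignment:
                continue
            cls = gcall.genotype_class
            if cls in (GenotypeClass.HET, GenotypeClass.HOM_ALT):
                edges.append((key, sample, cls))
    return NodeGraphModel(variant_nodes=variant_nodes, sample_nodes=sample_nodes, edges=edges)


def genotype_matrix(result: QueryResult, sample_ids: tuple[str, ...] | None = None) -> np.ndarray:
    """Variants x samples matrix of codes 0/1/2/-1 (heat-map backing)."""
    if sample_ids is None:
        sample_ids = result.sample_ids
    col_of = {s: j for j, s in enumerate(result.sample_ids)}
    matrix = np.full((len(result.variants), len(sample_ids)), -1, dtype=np.int8)
    for i, av in enumerate(result.variants):
        codes = av.record.genotype_codes()
        for j, s in enumerate(sample_ids):
            matrix[i, j] = codes[col_of[s]]
    return matrix


def histogram_to_json(view: HistogramView) -> dict:
    return {
        "level": view.level,
        "filter": view.filter.value,
        "bins": [
            {
                "chrom": b.range.chrom,
                "start": b.range.start,
                "end": b.range.end,
                "count": b.count,
                "exonic_count": b.exonic_count,
                "pathogenic_count": b.pathogenic_count,
            }
            for b in view.bins
        ],
    }


def node_graph_to_json(model: NodeGraphModel) -> dict:
    return {
        "nodes": [
            {"id": key, "kind": "variant", "pathogenic": flag}
            for key, flag in model.variant_nodes
        ]
        + [
            {"id": sample, "kind": "sample", "group": group}
            for sample, group in model.sample_nodes
        ],
        "edges": [
            {"variant": v, "sample": s, "genotype": cls.name} for v, s, cls in model.edges
        ],
    }
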