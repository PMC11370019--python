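"""Exception hierarchy shared across the package.

Every error raised deliberately by vgccraft derives from :class:`VgcError`
so callers (and the CLI) can catch one type and report a one-line
diagnostic.
"""


class VgcError(Exception):
    """Base class for all vgccraft errors."""


class MalformedVcfError(VgcError):
    """The file is not parseable as a VCF (e.g. missing #CHROM line)."""


class NoSamplesError(MalformedVcfError):
    """The VCF declares zero sample columns."""


class MalformedLineError(MalformedVcfError):
    """A data line has too few columns or an unusable FORMAT/GT field."""


class PloidyError(MalformedVcfError):
    """A genotype call carries more than two alleles."""


class SortRequiredError(VgcError):
    """The VCF is not coordinate sorted; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        super().__init__(message)
        self.line_number = line_number


class EmptyVcfError(VgcError):
    """The VCF contains no data lines."""


class CorruptIndexError(VgcError):
    """A sidecar index file exists but cannot be parsed; advise a rebuild."""


class IndexRequiredError(VgcError):
    """An operation needs an index bundle that was not supplied."""


class DuplicateGeneError(VgcError):
    """A gene catalog contains the same symbol twice."""


class CatalogValidationError(VgcError):
    """A gene-catalog row violates its own declared span."""


class UnknownGeneError(VgcError):
    """Queried symbol absent from the catalog; carries suggestions."""

    def __init__(self, message: str, suggestions: tuple[str, ...] = ()):
        super().__init__(message)
        self.suggestions = suggestions


class BatchParseError(VgcError):
    """A batch-query file line could not be interpreted."""


class PlanParseError(VgcError):
    """A saved analysis plan is malformed; carries the offending key."""

    def __init__(self, message: str, key: str | None = None):
        super().__init__(message)
        self.key = key


class MissingAnnotationError(VgcError):
    """A pathogenicity-dependent operation ran without an annotation source."""


class UnsupportedAlleleError(VgcError):
    """Symbolic or breakend alleles cannot be turned into a gnomAD URL."""


class GmtParseError(VgcError):
    """A GMT gene-set line has fewer than three fields."""


class PhenotypeConflictError(VgcError):
    """A sample is assigned to two different groups."""


class PhenotypeOverlapError(VgcError):
    """No phenotype sample overlaps the VCF sample list."""


class InsufficientGroupsError(VgcError):
    """Contingency construction needs at least two groups."""


class DegenerateTableError(VgcError):
    """A contingency table has fewer than two effective rows or columns."""


class BudgetExceededError(VgcError):
    """Exact enumeration refused because the table total exceeds the budget."""


class UnsupportedFormatError(VgcError):
    """Requested export format is outside the supported set (csv/tsv/xlsx)."""


class SimulationConfigError(VgcError):
    """A simulation config references loci outside its chromosomes."""
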