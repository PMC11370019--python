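"""Group-by-genotype contingency tables and Fisher's exact test.

For each variant a g x 3 table is built (rows = phenotype groups, columns
= HOM_REF / HET / HOM_ALT; missing genotypes are excluded and tallied
separately).  The test is the conditional test of independence: both
margins fixed, null = multivariate hypergeometric, two-sided p obtained
by summing the probabilities of all tables no more probable than the
observed one.

Two routes are provided:

* :func:`fisher_exact_enumerate` — full enumeration of tables with the
  observed margins, with probabilities computed via log-factorials.
  P(T) = (prod_i R_i!)(prod_j C_j!) / (N! prod_ij n_ij!).
* :func:`fisher_monte_carlo` — the default: tables drawn from the
  fixed-margin null by sequential multivariate-hypergeometric row fill;
  p = (1 + k) / (B + 1) where k counts sampled tables with
  P(t) <= P(observed) + eps (eps = 1e-12 tie tolerance), so p is never 0
  and is deterministic for a fixed seed.

No multiple-testing correction is applied anywhere; p-values are raw.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from scipy.special import gammaln

from .errors import (
    BudgetExceededError,
    DegenerateTableError,
    InsufficientGroupsError,
    PhenotypeConflictError,
    PhenotypeOverlapError,
)
from .query_engine import AnnotatedVariant, QueryResult
from .vcf_model import GenotypeClass, VariantRecord

__all__ = [
    "PhenotypeGroups",
    "ContingencyTable",
    "FisherResult",
    "AssociationEntry",
    "load_phenotypes",
    "build_contingency",
    "table_log_prob",
    "enumerate_margin_tables",
    "fisher_exact_enumerate",
    "fisher_monte_carlo",
    "per_variant_association",
]

TIE_EPS = 1e-12
DEFAULT_ITERATIONS = 2000
DEFAULT_ENUM_BUDGET = 500

GENOTYPE_COLUMNS = (GenotypeClass.HOM_REF, GenotypeClass.HET, GenotypeClass.HOM_ALT)


@dataclass
class PhenotypeGroups:
    assignment: dict[str, str]           # sample_id -> group label
    group_order: tuple[str, ...]         # first-appearance order
    unassigned: tuple[str, ...] = ()     # VCF samples absent from the file
    n_extra_in_file: int = 0             # file samples absent from the VCF

    @property
    def n_groups(self) -> int:
        return len(self.group_order)

    def group_sizes(self) -> dict[str, int]:
        sizes = {g: 0 for g in self.group_order}
        for group in self.assignment.values():
            sizes[group] += 1
        return sizes


def load_phenotypes(path: str | Path, sample_ids: Sequence[str]) -> PhenotypeGroups:
    """Read a sample_id/group TSV (header optional) restricted to the VCF samples.

    Samples listed twice with the same group are deduplicated; with
    different groups it is a conflict error.  VCF samples missing from the
    file are reported as unassigned; file samples missing from the VCF are
    counted but ignored.
    """
    raw: dict[str, str] = {}
    extra = 0
    vcf_samples = set(sample_ids)
    order: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                cols = line.split()
            if len(cols) < 2:
                raise PhenotypeConflictError(f"{path}:{line_no}: expected sample_id and group")
            sample, group = cols[0].strip(), cols[1].strip()
            if line_no == 1 and sample.lower() in ("sample_id", "sample", "id"):
                continue
            if sample in raw and raw[sample] != group:
                raise PhenotypeConflictError(
                    f"{path}:{line_no}: sample {sample!r} assigned to both "
                    f"{raw[sample]!r} and {group!r}"
                )
            raw[sample] = group
            if sample not in vcf_samples:
                extra += 1
            if group not in order:
                order.append(group)
    assignment = {s: g for s, g in raw.items() if s in vcf_samples}
    if not assignment:
        raise PhenotypeOverlapError(f"{path}: no phenotype sample matches a VCF sample")
    # extra counted once per distinct unknown sample
    extra = len(set(raw) - vcf_samples)
    present_groups = tuple(g for g in order if g in set(assignment.values()))
    unassigned = tuple(s for s in sample_ids if s not in assignment)
    return PhenotypeGroups(
        assignment=assignment,
        group_order=present_groups,
        unassigned=unassigned,
        n_extra_in_file=extra,
    )


@dataclass
class ContingencyTable:
    counts: np.ndarray                 # shape (g, 3), int
    group_order: tuple[str, ...]
    n_missing_excluded: int = 0

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def build_contingency(
    variant: VariantRecord,
    groups: PhenotypeGroups,
    sample_ids: Sequence[str],
) -> ContingencyTable:
    """Tally assigned, non-missing genotypes into a g x 3 table."""
    if groups.n_groups < 2:
        raise InsufficientGroupsError(
            f"association needs >= 2 groups, got {groups.n_groups}"
        )
    row_of = {g: i for i, g in enumerate(groups.group_order)}
    counts = np.zeros((groups.n_groups, 3), dtype=np.int64)
    missing = 0
    for sample, call in zip(sample_ids, variant.genotypes):
        group = groups.assignment.get(sample)
        if group is None:
            continue
        cls = call.genotype_class
        if cls is GenotypeClass.MISSING:
            missing += 1
        else:
            counts[row_of[group], cls.value] += 1
    return ContingencyTable(
        counts=counts, group_order=groups.group_order, n_missing_excluded=missing
    )


def table_log_prob(counts: np.ndarray) -> float:
    """log P(T) under the fixed-margin hypergeometric null."""
    counts = np.asarray(counts)
    R = counts.sum(axis=1)
    C = counts.sum(axis=0)
    N = counts.sum()
    return float(
        gammaln(R + 1).sum() + gammaln(C + 1).sum()
        - gammaln(N + 1) - gammaln(counts + 1).sum()
    )


def _reduce(counts: np.ndarray) -> np.ndarray:
    """Drop all-zero rows and columns; they carry no information."""
    counts = np.asarray(counts, dtype=np.int64)
    counts = counts[counts.sum(axis=1) > 0][:, counts.sum(axis=0) > 0]
    return counts


def _compositions(total: int, caps: tuple[int, ...]) -> Iterator[tuple[int, ...]]:
    """All nonnegative integer vectors summing to total with v[j] <= caps[j]."""
    if len(caps) == 1:
        if total <= caps[0]:
            yield (total,)
        return
    tail_cap = sum(caps[1:])
    lo = max(0, total - tail_cap)
    hi = min(caps[0], total)
    for x in range(lo, hi + 1):
        for rest in _compositions(total - x, caps[1:]):
            yield (x,) + rest


def enumerate_margin_tables(
    row_margins: Sequence[int], col_margins: Sequence[int]
) -> Iterator[np.ndarray]:
    """Yield every nonnegative integer table with the given margins."""
    R = list(row_margins)
    C = tuple(col_margins)

    def rec(i: int, remaining: tuple[int, ...], rows: list[tuple[int, ...]]):
        if i == len(R) - 1:
            yield np.array(rows + [remaining], dtype=np.int64)
            return
        for row in _compositions(R[i], remaining):
            new_remaining = tuple(r - x for r, x in zip(remaining, row))
            yield from rec(i + 1, new_remaining, rows + [row])

    yield from rec(0, C, [])


@dataclass(frozen=True)
class FisherResult:
    observed_table_probability: float
    p_exact: float | None = None
    p_mc: float | None = None
    mc_iterations: int = 0
    mc_seed: int | None = None


def fisher_exact_enumerate(
    table: ContingencyTable | np.ndarray, budget: int = DEFAULT_ENUM_BUDGET
) -> FisherResult:
    """Exact two-sided p by full enumeration of fixed-margin tables.

    Zero rows/columns are removed first; a table with a single effective
    row or column is the unique table with its margins, so p = 1.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    reduced = _reduce(counts)
    if reduced.size == 0 or reduced.shape[0] < 2 or reduced.shape[1] < 2:
        return FisherResult(observed_table_probability=1.0, p_exact=1.0)
    n_total = int(reduced.sum())
    if n_total > budget:
        raise BudgetExceededError(
            f"table total {n_total} exceeds enumeration budget {budget}; "
            "use fisher_monte_carlo"
        )
    logp_obs = table_log_prob(reduced)
    p_obs = float(np.exp(logp_obs))
    threshold = p_obs + TIE_EPS
    p = 0.0
    for candidate in enumerate_margin_tables(reduced.sum(axis=1), reduced.sum(axis=0)):
        p_t = float(np.exp(table_log_prob(candidate)))
        if p_t <= threshold:
            p += p_t
    return FisherResult(observed_table_probability=p_obs, p_exact=min(1.0, p))


def _sample_tables_two_rows(
    rng: np.random.Generator, row_margins: np.ndarray, col_margins: np.ndarray, size: int
) -> np.ndarray:
    """Vectorized sampler for 2-row tables: (size, 2, c)."""
    top = rng.multivariate_hypergeometric(col_margins, int(row_margins[0]), size=size)
    bottom = col_margins[None, :] - top
    return np.stack([top, bottom], axis=1)


def _sample_table_general(
    rng: np.random.Generator, row_margins: np.ndarray, col_margins: np.ndarray
) -> np.ndarray:
    """Sequential multivariate-hypergeometric row fill for g > 2."""
    remaining = col_margins.copy()
    rows = []
    for i in range(len(row_margins) - 1):
        row = rng.multivariate_hypergeometric(remaining, int(row_margins[i]))
        rows.append(row)
        remaining = remaining - row
    rows.append(remaining)
    return np.stack(rows)


def fisher_monte_carlo(
    table: ContingencyTable | np.ndarray,
    iterations: int = DEFAULT_ITERATIONS,
    seed: int = 0,
) -> FisherResult:
    """Monte Carlo two-sided p under the fixed-margin null.

    p = (1 + k) / (iterations + 1) with k = number of sampled tables whose
    probability is <= P(observed) + eps.  Deterministic for a fixed seed.
    """
    if iterations < 1:
        raise ValueError(f"iterations must be >= 1, got {iterations}")
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    reduced = _reduce(counts)
    if reduced.size == 0 or reduced.shape[0] < 2 or reduced.shape[1] < 2:
        raise DegenerateTableError(
            "table has fewer than two effective rows or columns after reduction"
        )
    rng = np.random.default_rng(seed)
    R = reduced.sum(axis=1)
    C = reduced.sum(axis=0)
    N = int(reduced.sum())
    const = float(gammaln(R + 1).sum() + gammaln(C + 1).sum() - gammaln(N + 1))
    logp_obs = const - float(gammaln(reduced + 1).sum())
    p_obs = float(np.exp(logp_obs))
    threshold = p_obs + TIE_EPS
    if reduced.shape[0] == 2:
        tables = _sample_tables_two_rows(rng, R, C, iterations)
        logp = const - gammaln(tables + 1).sum(axis=(1, 2))
        k = int(np.count_nonzero(np.exp(logp) <= threshold))
    else:
        k = 0
        for _ in range(iterations):
            t = _sample_table_general(rng, R, C)
            if np.exp(const - float(gammaln(t + 1).sum())) <= threshold:
                k += 1
    return FisherResult(
        observed_table_probability=p_obs,
        p_mc=(1 + k) / (iterations + 1),
        mc_iterations=iterations,
        mc_seed=seed,
    )


@dataclass
class AssociationEntry:
    variant: AnnotatedVariant
    table: ContingencyTable
    result: FisherResult | None
    reason: str | None = None  # set when no p could be computed


def per_variant_association(
    result: QueryResult,
    groups: PhenotypeGroups,
    iterations: int = DEFAULT_ITERATIONS,
    seed: int = 0,
    exact: bool = False,
    enum_budget: int = DEFAULT_ENUM_BUDGET,
) -> list[AssociationEntry]:
    """One Fisher result per queried variant.

    Per-variant seeds are derived as ``seed + ordinal`` so a run is
    reproducible and individual variants can be recomputed in isolation.
    Degenerate tables (e.g. monomorphic variants) yield no p-value and a
    ``reason`` code instead of an error.
    """
    if groups.n_groups < 2:
        raise InsufficientGroupsError(
            f"association needs >= 2 groups, got {groups.n_groups}"
        )
    entries: list[AssociationEntry] = []
    for ordinal, av in enumerate(result.variants):
        table = build_contingency(av.record, groups, result.sample_ids)
        reduced = _reduce(table.counts)
        if reduced.size == 0 or reduced.shape[0] < 2 or reduced.shape[1] < 2:
            entries.append(AssociationEntry(av, table, None, reason="degenerate"))
            continue
        fisher = fisher_monte_carlo(table, iterations=iterations, seed=seed + ordinal)
        if exact and table.n_total <= enum_budget:
            exact_res = fisher_exact_enumerate(table, budget=enum_budget)
            fisher = FisherResult(
                observed_table_probability=fisher.observed_table_probability,
                p_exact=exact_res.p_exact,
                p_mc=fisher.p_mc,
                mc_iterations=fisher.mc_iterations,
                mc_seed=fisher.mc_seed,
            )
        entries.append(AssociationEntry(av, table, fisher))
    return entries
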