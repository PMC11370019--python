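"""Shared fixtures and independent oracle helpers.

The oracle helpers deliberately avoid vgccraft's own parsing/statistics
code paths: ``scan_vcf`` is a naive line splitter and
``fisher_exact_bruteforce`` enumerates tables with exact rational
arithmetic.  Tests compare package output against these.
"""

from __future__ import annotations

import gzip
import itertools
import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import pytest

from vgccraft import fixtures as fx
from vgccraft.annotation import load_clinvar_table
from vgccraft.indexer import build_index, write_index_files


# --------------------------------------------------------------------------
# naive, index-free VCF scan (oracle)

@dataclass
class ScannedVariant:
    line_number: int  # physical, 1-based
    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    filter: str
    gts: tuple[str, ...]


def scan_vcf(path: str | Path) -> list[ScannedVariant]:
    path = Path(path)
    opener = gzip.open if path.read_bytes()[:2] == b"\x1f\x8b" else open
    out: list[ScannedVariant] = []
    with opener(path, "rt") as fh:
        for line_no, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            out.append(
                ScannedVariant(
                    line_number=line_no,
                    chrom=cols[0],
                    pos=int(cols[1]),
                    ref=cols[3],
                    alts=tuple(cols[4].split(",")),
                    filter=cols[6],
                    gts=tuple(f.split(":")[0] for f in cols[9:]),
                )
            )
    return out


def gt_class(gt: str) -> str:
    """Independent genotype classification for oracle tallies."""
    tokens = gt.replace("|", "/").split("/")
    if len(tokens) == 1:
        tokens = tokens * 2
    if any(t in (".", "") for t in tokens):
        return "MISSING"
    n_alt = sum(1 for t in tokens if int(t) > 0)
    return ("HOM_REF", "HET", "HOM_ALT")[n_alt]


def load_clinvar_keys(path: str | Path) -> dict[tuple[str, int, str, str], str]:
    """(chrom-no-prefix, pos, ref, alt) -> significance, parsed naively."""
    keys = {}
    for line in Path(path).read_text().splitlines():
        cols = line.split("\t")
        if not cols or cols[0].lower() == "chrom":
            continue
        chrom = cols[0][3:] if cols[0].lower().startswith("chr") else cols[0]
        keys[(chrom, int(cols[1]), cols[2], cols[3])] = cols[4]
    return keys


PATHOGENIC = {"pathogenic", "likely pathogenic", "pathogenic/likely pathogenic"}


def is_pathogenic_scan(v: ScannedVariant, clinvar: dict) -> bool:
    chrom = v.chrom[3:] if v.chrom.lower().startswith("chr") else v.chrom
    return any(
        clinvar.get((chrom, v.pos, v.ref, alt), "").lower() in PATHOGENIC
        for alt in v.alts
    )


# --------------------------------------------------------------------------
# exact-rational Fisher oracle

def fisher_exact_bruteforce(table: list[list[int]]) -> float:
    """Two-sided Fisher p on an r x c table by full enumeration with
    Fractions; independent of the package's log-factorial implementation."""
    rows = [r[:] for r in table]
    R = [sum(r) for r in rows]
    C = [sum(rows[i][j] for i in range(len(rows))) for j in range(len(rows[0]))]
    N = sum(R)

    def prob(t: tuple[tuple[int, ...], ...]) -> Fraction:
        num = Fraction(1)
        for r in R:
            num *= math.factorial(r)
        for c in C:
            num *= math.factorial(c)
        den = Fraction(math.factorial(N))
        for row in t:
            for cell in row:
                den *= math.factorial(cell)
        return num / den

    def all_tables():
        ncols = len(C)

        def fill(i, remaining, acc):
            if i == len(R) - 1:
                yield tuple(acc) + (tuple(remaining),)
                return
            cells = [range(0, min(R[i], remaining[j]) + 1) for j in range(ncols)]
            for combo in itertools.product(*cells):
                if sum(combo) != R[i]:
                    continue
                yield from fill(
                    i + 1, [remaining[j] - combo[j] for j in range(ncols)], acc + [combo]
                )

        yield from fill(0, C[:], [])

    p_obs = prob(tuple(tuple(r) for r in rows))
    total = Fraction(0)
    for t in all_tables():
        p_t = prob(t)
        if p_t <= p_obs:  # exact rational comparison: ties are exact
            total += p_t
    return float(total)


# --------------------------------------------------------------------------
# cohort fixtures

@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory) -> fx.SimulatedCohort:
    out = tmp_path_factory.mktemp("cohort")
    return fx.simulate_cohort(fx.small_config(seed=11), out)


@pytest.fixture(scope="session")
def small_bundle(small_cohort):
    table = load_clinvar_table(small_cohort.clinvar_path)
    bundle = build_index(small_cohort.vcf_path, pathogenicity_table=table)
    root = small_cohort.vcf_path.parent
    write_index_files(bundle, root)
    return bundle


@pytest.fixture(scope="session")
def small_clinvar(small_cohort):
    return load_clinvar_table(small_cohort.clinvar_path)
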