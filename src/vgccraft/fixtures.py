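"""Synthetic case-control cohort generator.

Produces a fully self-contained input set: a coordinate-sorted VCF with
per-group Hardy-Weinberg genotypes, a phenotype TSV, a gene-catalog TSV,
a ClinVar-style pathogenicity TSV, a GMT gene-set file, and a JSON truth
manifest recording every planted fact (so tests never re-derive ground
truth from the generated VCF).  Output is byte-identical for identical
configs: one RNG, fixed draw order, no timestamps in any file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import SimulationConfigError

__all__ = [
    "GeneSpec",
    "PlantedSignal",
    "SimulationConfig",
    "SimulatedCohort",
    "simulate_cohort",
    "preeclampsia_shape_config",
    "small_config",
]


@dataclass(frozen=True)
class GeneSpec:
    symbol: str
    chrom: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...] = ()


@dataclass(frozen=True)
class PlantedSignal:
    chrom: str
    pos: int
    case_freq: float
    control_freq: float


@dataclass
class SimulationConfig:
    seed: int = 0
    n_cases: int = 61
    n_controls: int = 82
    chromosomes: tuple[tuple[str, int], ...] = (("1", 1_000_000), ("2", 800_000))
    n_variants: int = 120
    pass_fraction: float = 0.85
    genes: tuple[GeneSpec, ...] = ()
    planted_signals: tuple[PlantedSignal, ...] = ()
    planted_pathogenic: tuple[tuple[str, int], ...] = ()  # (chrom, pos)
    missing_rate: float = 0.02
    group_labels: tuple[str, str] = ("case", "control")
    null_freq_range: tuple[float, float] = (0.02, 0.35)

    def validate(self) -> None:
        lengths = dict(self.chromosomes)
        for sig in self.planted_signals:
            if sig.chrom not in lengths or not 1 <= sig.pos <= lengths[sig.chrom]:
                raise SimulationConfigError(
                    f"planted signal at {sig.chrom}:{sig.pos} outside declared chromosomes"
                )
            for freq in (sig.case_freq, sig.control_freq):
                if not 0.0 <= freq <= 1.0:
                    raise SimulationConfigError(f"planted frequency {freq} outside [0, 1]")
        for chrom, pos in self.planted_pathogenic:
            if chrom not in lengths or not 1 <= pos <= lengths[chrom]:
                raise SimulationConfigError(
                    f"planted pathogenic locus {chrom}:{pos} outside declared chromosomes"
                )


@dataclass
class SimulatedCohort:
    vcf_path: Path
    phenotype_path: Path
    catalog_path: Path
    clinvar_path: Path
    gmt_path: Path
    manifest_path: Path
    manifest: dict = field(default_factory=dict)


_BASES = np.array(list("ACGT"))


def _hw_probs(freq: float) -> np.ndarray:
    q = freq
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])


def simulate_cohort(config: SimulationConfig, out_dir: str | Path) -> SimulatedCohort:
    """Generate the full input set under ``out_dir`` (created if needed)."""
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    case_ids = [f"CASE{i:03d}" for i in range(1, config.n_cases + 1)]
    ctrl_ids = [f"CTRL{i:03d}" for i in range(1, config.n_controls + 1)]
    sample_ids = case_ids + ctrl_ids
    case_label, ctrl_label = config.group_labels

    # --- loci -----------------------------------------------------------
    lengths = dict(config.chromosomes)
    total_len = sum(lengths.values())
    planted_positions: dict[str, set[int]] = {c: set() for c in lengths}
    for sig in config.planted_signals:
        planted_positions[sig.chrom].add(sig.pos)
    for chrom, pos in config.planted_pathogenic:
        planted_positions[chrom].add(pos)

    loci: list[tuple[str, int]] = []
    remaining = config.n_variants
    for i, (chrom, length) in enumerate(config.chromosomes):
        if i == len(config.chromosomes) - 1:
            n_here = remaining
        else:
            n_here = max(0, round(config.n_variants * length / total_len))
            n_here = min(n_here, remaining)
        remaining -= n_here
        wanted = set(planted_positions[chrom])
        n_random = max(0, n_here - len(wanted))
        pool = rng.choice(length, size=min(length, n_random + len(wanted) + 8),
                          replace=False) + 1
        for p in pool:
            if len(wanted) >= n_here:
                break
            wanted.add(int(p))
        for pos in sorted(wanted):
            loci.append((chrom, pos))

    signal_by_locus = {(s.chrom, s.pos): s for s in config.planted_signals}
    pathogenic_set = set(config.planted_pathogenic)

    # --- per-locus attributes (fixed draw order for determinism) --------
    refs, alts, null_freqs, filters, quals, dps = [], [], [], [], [], []
    lo, hi = config.null_freq_range
    for chrom, pos in loci:
        ref, alt = rng.choice(4, size=2, replace=False)
        refs.append(str(_BASES[ref]))
        alts.append(str(_BASES[alt]))
        null_freqs.append(float(rng.uniform(lo, hi)))
        filters.append("PASS" if rng.random() < config.pass_fraction else "q10")
        quals.append(int(rng.integers(20, 100)))
        dps.append(int(rng.integers(10, 200)))

    # --- genotypes ------------------------------------------------------
    gt_rows: list[list[str]] = []
    for k, (chrom, pos) in enumerate(loci):
        sig = signal_by_locus.get((chrom, pos))
        case_freq = sig.case_freq if sig else null_freqs[k]
        ctrl_freq = sig.control_freq if sig else null_freqs[k]
        case_codes = rng.choice(3, size=config.n_cases, p=_hw_probs(case_freq))
        ctrl_codes = rng.choice(3, size=config.n_controls, p=_hw_probs(ctrl_freq))
        codes = np.concatenate([case_codes, ctrl_codes])
        if config.missing_rate > 0:
            missing = rng.random(len(codes)) < config.missing_rate
        else:
            missing = np.zeros(len(codes), dtype=bool)
        gts = []
        for code, miss in zip(codes, missing):
            if miss:
                gts.append("./.")
            else:
                gts.append(("0/0", "0/1", "1/1")[code])
        gt_rows.append(gts)

    # --- VCF ------------------------------------------------------------
    vcf_path = out_dir / "cohort.vcf"
    lines = ["##fileformat=VCFv4.2", "##source=vgccraft-simulate"]
    lines += [f"##contig=<ID={chrom},length={length}>" for chrom, length in config.chromosomes]
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids)
    )
    for k, (chrom, pos) in enumerate(loci):
        lines.append(
            f"{chrom}\t{pos}\t.\t{refs[k]}\t{alts[k]}\t{quals[k]}\t{filters[k]}"
            f"\tDP={dps[k]}\tGT\t" + "\t".join(gt_rows[k])
        )
    vcf_path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    # --- phenotype file -------------------------------------------------
    phenotype_path = out_dir / "phenotypes.tsv"
    pheno_lines = ["sample_id\tgroup"]
    pheno_lines += [f"{s}\t{case_label}" for s in case_ids]
    pheno_lines += [f"{s}\t{ctrl_label}" for s in ctrl_ids]
    phenotype_path.write_text("\n".join(pheno_lines) + "\n", encoding="utf-8")

    # --- gene catalog ---------------------------------------------------
    catalog_path = out_dir / "genes.tsv"
    cat_lines = ["symbol\tchrom\tstart\tend\texons"]
    for gene in config.genes:
        exons = ";".join(f"{s}-{e}" for s, e in gene.exons)
        cat_lines.append(f"{gene.symbol}\t{gene.chrom}\t{gene.start}\t{gene.end}\t{exons}")
    catalog_path.write_text("\n".join(cat_lines) + "\n", encoding="utf-8")

    # --- ClinVar-style table -------------------------------------------
    clinvar_path = out_dir / "clinvar.tsv"
    locus_index = {(c, p): k for k, (c, p) in enumerate(loci)}
    cv_lines = ["chrom\tpos\tref\talt\tclinical_significance\tcondition\treview_status"]
    pathogenic_truth = []
    for chrom, pos in sorted(pathogenic_set):
        k = locus_index[(chrom, pos)]
        cv_lines.append(
            f"{chrom}\t{pos}\t{refs[k]}\t{alts[k]}\tPathogenic\tsimulated condition\t"
            "criteria provided"
        )
        pathogenic_truth.append(
            {"chrom": chrom, "pos": pos, "ref": refs[k], "alt": alts[k]}
        )
    # a handful of benign entries on non-planted loci; one uses a chr prefix
    n_benign = 0
    for k, (chrom, pos) in enumerate(loci):
        if (chrom, pos) in pathogenic_set or n_benign >= 4:
            continue
        name = f"chr{chrom}" if n_benign == 0 else chrom
        cv_lines.append(f"{name}\t{pos}\t{refs[k]}\t{alts[k]}\tBenign\t\t")
        n_benign += 1
    clinvar_path.write_text("\n".join(cv_lines) + "\n", encoding="utf-8")

    # --- GMT ------------------------------------------------------------
    gmt_path = out_dir / "genesets.gmt"
    symbols = [g.symbol for g in config.genes]
    gmt_lines = []
    if symbols:
        gmt_lines.append("PATHWAY_SIM_A\tsimulated set A\t" + "\t".join(symbols))
        gmt_lines.append(f"PATHWAY_SIM_B\tsimulated set B\t{symbols[0]}\tZZZ_UNRELATED")
    else:
        gmt_lines.append("PATHWAY_SIM_A\tsimulated set A\tZZZ_UNRELATED")
    gmt_path.write_text("\n".join(gmt_lines) + "\n", encoding="utf-8")

    # --- truth manifest -------------------------------------------------
    per_chrom: dict[str, dict[str, int]] = {}
    for k, (chrom, pos) in enumerate(loci):
        stats = per_chrom.setdefault(chrom, {"n_variants": 0, "n_pass": 0})
        stats["n_variants"] += 1
        if filters[k] == "PASS":
            stats["n_pass"] += 1
    manifest = {
        "seed": config.seed,
        "n_cases": config.n_cases,
        "n_controls": config.n_controls,
        "group_labels": list(config.group_labels),
        "sample_ids": sample_ids,
        "n_variants": len(loci),
        "per_chromosome": per_chrom,
        "planted_signals": [asdict(s) for s in config.planted_signals],
        "planted_pathogenic": pathogenic_truth,
        "pass_fraction": config.pass_fraction,
        "missing_rate": config.missing_rate,
    }
    manifest_path = out_dir / "truth.json"
    manifest_path.write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return SimulatedCohort(
        vcf_path=vcf_path,
        phenotype_path=phenotype_path,
        catalog_path=catalog_path,
        clinvar_path=clinvar_path,
        gmt_path=gmt_path,
        manifest_path=manifest_path,
        manifest=manifest,
    )


def preeclampsia_shape_config(seed: int = 0, n_variants: int = 300) -> SimulationConfig:
    """Cohort in the shape of a 143-sample case-control exome study
    (61 cases / 82 controls), with one strong planted signal and two
    planted pathogenic loci."""
    return SimulationConfig(
        seed=seed,
        n_cases=61,
        n_controls=82,
        chromosomes=(("1", 2_000_000), ("2", 1_500_000)),
        n_variants=n_variants,
        pass_fraction=0.85,
        genes=(
            GeneSpec("ACTN2", "1", 200_000, 420_000,
                     exons=((210_000, 240_000), (300_000, 340_000))),
            GeneSpec("FLT1", "1", 900_000, 1_100_000,
                     exons=((950_000, 990_000), (1_020_000, 1_060_000))),
            GeneSpec("TTN", "2", 600_000, 900_000,
                     exons=((620_000, 660_000), (700_000, 760_000), (820_000, 860_000))),
        ),
        planted_signals=(PlantedSignal("1", 500_000, case_freq=0.8, control_freq=0.05),),
        planted_pathogenic=(("1", 250_000), ("2", 700_500)),
        missing_rate=0.02,
    )


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Tiny fast cohort for unit tests (10 samples, 2 short chromosomes)."""
    defaults = dict(
        seed=seed,
        n_cases=5,
        n_controls=5,
        chromosomes=(("1", 10_000), ("2", 8_000)),
        n_variants=20,
        pass_fraction=0.7,
        genes=(GeneSpec("GENEA", "1", 1_000, 5_000, exons=((1_500, 2_500), (3_500, 4_200))),),
        planted_pathogenic=(("1", 2_000),),
        missing_rate=0.05,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)
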