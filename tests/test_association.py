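import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chisquare, fisher_exact

from conftest import fisher_exact_bruteforce
from vgccraft.association import (
    ContingencyTable,
    PhenotypeGroups,
    build_contingency,
    enumerate_margin_tables,
    fisher_exact_enumerate,
    fisher_monte_carlo,
    load_phenotypes,
    per_variant_association,
    table_log_prob,
)
from vgccraft.errors import (
    BudgetExceededError,
    DegenerateTableError,
    InsufficientGroupsError,
    PhenotypeConflictError,
    PhenotypeOverlapError,
)
from vgccraft.query_engine import (
    AnnotatedVariant,
    FilterCategory,
    GenomicRange,
    query_range,
)
from vgccraft.vcf_model import parse_data_line


def table(counts):
    counts = np.asarray(counts, dtype=np.int64)
    groups = tuple(f"g{i}" for i in range(counts.shape[0]))
    return ContingencyTable(counts=counts, group_order=groups)


class TestLoadPhenotypes:
    def test_cohort_groups(self, small_cohort):
        m = small_cohort.manifest
        groups = load_phenotypes(small_cohort.phenotype_path, m["sample_ids"])
        sizes = groups.group_sizes()
        assert sizes == {"case": m["n_cases"], "control": m["n_controls"]}
        assert groups.group_order == ("case", "control")

    def test_extra_unknown_sample_warns(self, small_cohort, tmp_path):
        p = tmp_path / "pheno.tsv"
        p.write_text(small_cohort.phenotype_path.read_text() + "GHOST\tcase\n")
        groups = load_phenotypes(p, small_cohort.manifest["sample_ids"])
        assert groups.n_extra_in_file == 1

    def test_duplicate_same_group_ok(self, tmp_path):
        p = tmp_path / "pheno.tsv"
        p.write_text("s1\tA\ns1\tA\ns2\tB\n")
        groups = load_phenotypes(p, ["s1", "s2"])
        assert groups.group_sizes() == {"A": 1, "B": 1}

    def test_conflicting_assignment(self, tmp_path):
        p = tmp_path / "pheno.tsv"
        p.write_text("s1\tA\ns1\tB\n")
        with pytest.raises(PhenotypeConflictError):
            load_phenotypes(p, ["s1"])

    def test_no_overlap(self, tmp_path):
        p = tmp_path / "pheno.tsv"
        p.write_text("x1\tA\nx2\tB\n")
        with pytest.raises(PhenotypeOverlapError):
            load_phenotypes(p, ["s1", "s2"])

    def test_unassigned_vcf_samples_reported(self, tmp_path):
        p = tmp_path / "pheno.tsv"
        p.write_text("s1\tA\ns2\tB\n")
        groups = load_phenotypes(p, ["s1", "s2", "s3"])
        assert groups.unassigned == ("s3",)


class TestBuildContingency:
    def make_groups(self):
        return PhenotypeGroups(
            assignment={"s1": "A", "s2": "A", "s3": "B", "s4": "B"},
            group_order=("A", "B"),
        )

    def variant(self, gts):
        joined = "\t".join(gts)
        return parse_data_line(f"1\t1\t.\tA\tT\t.\tPASS\t.\tGT\t{joined}", len(gts))

    def test_hand_tally(self):
        t = build_contingency(
            self.variant(["0/0", "0/1", "1/1", "./."]), self.make_groups(),
            ["s1", "s2", "s3", "s4"],
        )
        assert t.counts.tolist() == [[1, 1, 0], [0, 0, 1]]
        assert t.n_missing_excluded == 1
        assert t.n_total == 3

    def test_all_missing_zero_table(self):
        t = build_contingency(
            self.variant(["./.", "./.", "./.", "./."]), self.make_groups(),
            ["s1", "s2", "s3", "s4"],
        )
        assert t.counts.sum() == 0 and t.n_missing_excluded == 4
        with pytest.raises(DegenerateTableError):
            fisher_monte_carlo(t, iterations=10, seed=0)

    def test_insufficient_groups(self):
        groups = PhenotypeGroups(assignment={"s1": "A"}, group_order=("A",))
        with pytest.raises(InsufficientGroupsError):
            build_contingency(self.variant(["0/0"]), groups, ["s1"])

    def test_unassigned_samples_excluded(self):
        groups = PhenotypeGroups(assignment={"s1": "A", "s3": "B"}, group_order=("A", "B"))
        t = build_contingency(
            self.variant(["0/1", "0/1", "1/1", "0/0"]), groups, ["s1", "s2", "s3", "s4"]
        )
        assert t.counts.tolist() == [[0, 1, 0], [0, 0, 1]]
        assert t.n_total == 2

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.sampled_from(["0/0", "0/1", "1/1", "./."]), min_size=4, max_size=12))
    def test_recount_oracle(self, gts):
        samples = [f"s{i}" for i in range(len(gts))]
        half = len(gts) // 2
        groups = PhenotypeGroups(
            assignment={s: ("A" if i < half else "B") for i, s in enumerate(samples)},
            group_order=("A", "B"),
        )
        t = build_contingency(self.variant(gts), groups, samples)
        assert t.n_total + t.n_missing_excluded == len(gts)
        assert int(t.counts[0].sum()) == sum(1 for g in gts[:half] if g != "./.")


class TestFisherExact:
    def test_two_table_margins(self):
        assert fisher_exact_enumerate(table([[1, 0, 0], [0, 1, 0]])).p_exact == 1.0

    def test_zero_row_unique_table(self):
        assert fisher_exact_enumerate(table([[0, 0, 0], [3, 2, 1]])).p_exact == 1.0

    def test_monomorphic_single_column(self):
        assert fisher_exact_enumerate(table([[5, 0, 0], [7, 0, 0]])).p_exact == 1.0

    def test_brute_force_oracle_fixed_table(self):
        t = [[8, 2, 0], [1, 5, 4]]
        want = fisher_exact_bruteforce(t)
        got = fisher_exact_enumerate(table(t)).p_exact
        assert got == pytest.approx(want, abs=1e-9)

    def test_matches_scipy_on_2x2(self):
        # independent library route for the 2x2 special case
        t = np.array([[7, 1], [2, 6]])
        padded = table([[7, 1, 0], [2, 6, 0]])
        assert fisher_exact_enumerate(padded).p_exact == pytest.approx(
            fisher_exact(t).pvalue, rel=1e-9
        )

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.integers(0, 4), min_size=6, max_size=6))
    def test_brute_force_oracle_random(self, cells):
        t = [cells[:3], cells[3:]]
        if sum(cells) == 0:
            return
        want = fisher_exact_bruteforce(t)
        got = fisher_exact_enumerate(table(t)).p_exact
        assert got == pytest.approx(want, abs=1e-9)

    def test_probabilities_sum_to_one(self):
        t = np.array([[8, 2, 0], [1, 5, 4]])
        total = sum(
            math.exp(table_log_prob(cand))
            for cand in enumerate_margin_tables(t.sum(axis=1), t.sum(axis=0))
        )
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_invariant_under_permutations(self):
        t = np.array([[4, 1, 2], [0, 5, 3]])
        base = fisher_exact_enumerate(table(t)).p_exact
        assert fisher_exact_enumerate(table(t[::-1])).p_exact == pytest.approx(base, abs=1e-12)
        for perm in ([0, 2, 1], [2, 1, 0], [1, 0, 2]):
            assert fisher_exact_enumerate(table(t[:, perm])).p_exact == pytest.approx(
                base, abs=1e-12
            )

    def test_budget_exceeded(self):
        with pytest.raises(BudgetExceededError):
            fisher_exact_enumerate(table([[400, 10, 10], [200, 10, 10]]), budget=500)

    def test_three_groups(self):
        t = [[3, 1, 0], [0, 2, 2], [1, 1, 1]]
        assert fisher_exact_enumerate(table(t)).p_exact == pytest.approx(
            fisher_exact_bruteforce(t), abs=1e-9
        )


class TestFisherMonteCarlo:
    def test_null_symmetry_close_to_one(self):
        res = fisher_monte_carlo(table([[5, 5, 5], [5, 5, 5]]), iterations=2000, seed=42)
        assert res.p_mc >= 0.9

    def test_deterministic_for_seed(self):
        t = table([[8, 2, 0], [1, 5, 4]])
        a = fisher_monte_carlo(t, iterations=2000, seed=7)
        b = fisher_monte_carlo(t, iterations=2000, seed=7)
        assert a.p_mc == b.p_mc

    def test_p_never_zero(self):
        res = fisher_monte_carlo(table([[20, 0, 0], [0, 20, 0]]), iterations=100, seed=0)
        assert res.p_mc == pytest.approx(1 / 101)

    def test_iterations_validated(self):
        with pytest.raises(ValueError):
            fisher_monte_carlo(table([[1, 1, 0], [0, 1, 1]]), iterations=0, seed=0)

    def test_close_to_exact_small_battery(self):
        # scaled-down version of the acceptance criterion
        rng = np.random.default_rng(5)
        failures = 0
        for i in range(40):
            counts = rng.integers(0, 8, size=(2, 3))
            if counts.sum() == 0 or (counts.sum(axis=1) > 0).sum() < 2 \
                    or (counts.sum(axis=0) > 0).sum() < 2:
                continue
            t = table(counts)
            p_exact = fisher_exact_enumerate(t).p_exact
            res = fisher_monte_carlo(t, iterations=20_000, seed=100 + i)
            se = math.sqrt(p_exact * (1 - p_exact) / 20_000)
            if abs(res.p_mc - p_exact) > 3 * se + 1e-4:
                failures += 1
        assert failures == 0

    def test_three_group_sampler_close_to_exact(self):
        t = table([[4, 2, 1], [1, 3, 2], [2, 1, 4]])
        p_exact = fisher_exact_enumerate(t).p_exact
        res = fisher_monte_carlo(t, iterations=5000, seed=3)
        se = math.sqrt(p_exact * (1 - p_exact) / 5000)
        assert abs(res.p_mc - p_exact) <= 4 * se + 1e-3

    def test_sampled_table_distribution_matches_enumeration(self):
        # chi-square goodness of fit of sampled tables vs enumerated probs
        counts = np.array([[3, 2, 1], [1, 2, 3]])
        R, C = counts.sum(axis=1), counts.sum(axis=0)
        tables = list(enumerate_margin_tables(R, C))
        probs = np.array([math.exp(table_log_prob(t)) for t in tables])
        key_of = {tuple(t[0]): i for i, t in enumerate(tables)}
        rng = np.random.default_rng(12)
        draws = rng.multivariate_hypergeometric(C, int(R[0]), size=100_000)
        observed = np.zeros(len(tables))
        for row in draws:
            observed[key_of[tuple(row)]] += 1
        result = chisquare(observed, probs * len(draws))
        assert result.pvalue > 0.001


class TestPerVariantAssociation:
    def test_entries_align_with_query(self, small_cohort, small_bundle):
        groups = load_phenotypes(
            small_cohort.phenotype_path, small_cohort.manifest["sample_ids"]
        )
        result = query_range(small_bundle, small_cohort.vcf_path,
                             GenomicRange("1", 1, 10**9), FilterCategory.ALL)
        entries = per_variant_association(result, groups, iterations=200, seed=1)
        assert len(entries) == len(result)
        for e in entries:
            assert e.result is not None or e.reason == "degenerate"
            if e.result is not None:
                assert 0 < e.result.p_mc <= 1

    def test_per_variant_seeds_derived(self, small_cohort, small_bundle):
        groups = load_phenotypes(
            small_cohort.phenotype_path, small_cohort.manifest["sample_ids"]
        )
        result = query_range(small_bundle, small_cohort.vcf_path,
                             GenomicRange("1", 1, 10**9))
        entries = per_variant_association(result, groups, iterations=50, seed=10)
        seeds = [e.result.mc_seed for e in entries if e.result]
        assert seeds == [10 + i for i, e in enumerate(entries) if e.result]

    def test_monomorphic_degenerate(self):
        groups = PhenotypeGroups(
            assignment={"s1": "A", "s2": "B"}, group_order=("A", "B")
        )
        rec = parse_data_line("1\t1\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/0", 2)
        from vgccraft.query_engine import QueryMode, QueryResult, QuerySpec

        result = QueryResult(
            spec=QuerySpec(mode=QueryMode.RANGE, range=GenomicRange("1", 1, 1)),
            variants=[AnnotatedVariant(record=rec)],
            sample_ids=("s1", "s2"),
        )
        entries = per_variant_association(result, groups, iterations=10, seed=0)
        assert entries[0].result is None and entries[0].reason == "degenerate"

    def test_planted_signal_ranks_first(self, tmp_path):
        from vgccraft.fixtures import PlantedSignal, simulate_cohort, small_config
        from vgccraft.indexer import build_index

        config = small_config(
            seed=3, n_cases=30, n_controls=30, n_variants=25, missing_rate=0.0,
            planted_pathogenic=(),
            planted_signals=(PlantedSignal("1", 5_000, case_freq=0.8, control_freq=0.05),),
        )
        cohort = simulate_cohort(config, tmp_path)
        bundle = build_index(cohort.vcf_path)
        groups = load_phenotypes(cohort.phenotype_path, cohort.manifest["sample_ids"])
        result = query_range(bundle, cohort.vcf_path, GenomicRange("1", 1, 10**9))
        entries = per_variant_association(result, groups, iterations=2000, seed=9)
        p_by_pos = {e.variant.record.pos: e.result.p_mc for e in entries if e.result}
        assert p_by_pos[5_000] == min(p_by_pos.values())
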