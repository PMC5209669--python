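import itertools
import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

import linkagekit as lk
from linkagekit.multipoint import classify_gamete_counts

ORDER = lk.LocusOrder(("LEM", "V", "S", "RLF"))
TRUE_RS = (0.0379, 0.0047, 0.1058)  # LEM-V, V-S, S-RLF


@pytest.fixture(scope="module")
def mm(config):
    return config.parents["Miss Muffet"].restrict(("LEM", "V", "S", "RLF"))


@pytest.fixture(scope="module")
def candidum(config):
    return config.parents["Candidum"].restrict(("LEM", "V", "S", "RLF"))


@pytest.fixture(scope="module")
def models(config):
    return {l: config.trait_models[l] for l in ("LEM", "V", "S", "RLF")}


@pytest.fixture(scope="module")
def table7_classified(config, counts, mm, candidum, models):
    return classify_gamete_counts(counts["t7-01"], mm, candidum, models, ORDER)


class TestInferGamete:
    @pytest.mark.parametrize(
        "labels, gamete",
        [
            (
                ("lemon", "white", "non-spotted", "non-rugose"),
                ("LEM", "V^w", "s", "rlf"),
            ),
            (("green", "green", "spotted", "rugose"), ("lem", "V^g", "S", "RLF")),
            (("lemon", "white", "non-spotted", "rugose"), ("LEM", "V^w", "s", "RLF")),
        ],
    )
    def test_recessive_tester_reveals_the_gamete(
        self, candidum, models, labels, gamete
    ):
        loci = ("LEM", "V", "S", "RLF")
        assert lk.infer_gamete(labels, loci, candidum, models) == gamete

    def test_non_recessive_tester_rejected(self, config, models):
        aaron = config.parents["Aaron"].restrict(("LEM", "V", "S", "RLF"))
        with pytest.raises(lk.GeneticsDomainError, match="recessive"):
            lk.infer_gamete(
                ("lemon", "white", "non-spotted", "non-rugose"),
                ("LEM", "V", "S", "RLF"),
                aaron,  # V^w V^w: white-veined, not the recessive homozygote
                models,
            )

    def test_phenotype_inconsistent_with_tester_named_in_error(
        self, candidum, models
    ):
        # "green" is a background label, not a spotting label: no gamete
        # allele can produce it at S over an ss tester
        with pytest.raises(lk.GeneticsDomainError, match="green"):
            lk.infer_gamete(
                ("lemon", "white", "green", "non-rugose"),
                ("LEM", "V", "S", "RLF"),
                candidum,
                models,
            )


class TestClassifyCrossovers:
    def test_parental_haplotype_has_no_switches(self, mm):
        xo = lk.classify_crossovers(("LEM", "V^w", "s", "rlf"), mm, ORDER)
        assert xo.is_parental
        assert xo.switch_pattern == (False, False, False)

    def test_single_crossover_between_spotting_and_rugosity(self, mm):
        xo = lk.classify_crossovers(("LEM", "V^w", "s", "RLF"), mm, ORDER)
        assert xo.switch_pattern == (False, False, True)
        assert xo.label == "single crossover (S-RLF)"

    def test_against_brute_force_origin_tracing(self, mm):
        # independent oracle: trace each allele to its homolog and diff
        hap_by_locus = {
            l: (mm.haplotype_a[i], mm.haplotype_b[i]) for i, l in enumerate(mm.loci)
        }
        for origins in itertools.product((0, 1), repeat=4):
            hap = tuple(
                hap_by_locus[l][o] for l, o in zip(ORDER.loci, origins)
            )
            expected = tuple(a != b for a, b in zip(origins, origins[1:]))
            xo = lk.classify_crossovers(hap, mm, ORDER)
            assert xo.switch_pattern == expected

    def test_homozygous_locus_excluded_with_warning(self, config):
        parent = config.parents["Miss Muffet"].restrict(("LEM", "F", "S"))
        with pytest.warns(UserWarning, match="'F'"):
            xo = lk.classify_crossovers(
                ("LEM", "F", "s"), parent, lk.LocusOrder(("LEM", "F", "S"))
            )
        assert xo.intervals == (("LEM", "S"),)


class TestIntervalRfs:
    def test_four_locus_table_reproduces_published_frequencies(
        self, table7_classified
    ):
        res = lk.interval_rfs(table7_classified, ORDER, total=1267)
        by_pair = {e.loci: round(e.r_percent, 2) for e in res.per_interval}
        assert by_pair == {("LEM", "V"): 3.79, ("V", "S"): 0.47, ("S", "RLF"): 10.58}
        assert round(res.end_to_end_percent, 2) == 14.84
        assert res.parental_count == 1091
        assert round(100 * res.parental_fraction, 1) == 86.1
        # the declared population total differs from the class-count sum:
        # flagged, never silently corrected
        assert res.count_sum == 1271
        assert res.warnings

    def test_zero_count_crossover_classes_preserved(self, table7_classified):
        zero_classes = [c for c, n in table7_classified.items() if n == 0]
        assert any(c.n_switches == 2 for c in zero_classes)  # a double
        assert any(c.n_switches == 3 for c in zero_classes)  # the triple

    def test_all_parental_progeny_give_zero_rfs(self):
        parental = lk.CrossoverClass((False, False), (("A", "B"), ("B", "C")))
        res = lk.interval_rfs({parental: 500}, lk.LocusOrder(("A", "B", "C")))
        assert all(e.r_percent == 0.0 for e in res.per_interval)

    def test_zero_total_rejected(self):
        parental = lk.CrossoverClass((False,), (("A", "B"),))
        with pytest.raises(lk.GeneticsDomainError):
            lk.interval_rfs({parental: 0}, lk.LocusOrder(("A", "B")))

    @given(
        counts=st.lists(
            st.integers(0, 200), min_size=8, max_size=8
        ).filter(lambda c: sum(c) > 0)
    )
    def test_interval_sum_dominates_end_to_end_switch_frequency(self, counts):
        # triangle property of recombination frequencies
        order = lk.LocusOrder(("A", "B", "C", "D"))
        classes = {
            lk.CrossoverClass(tuple(map(bool, patt)), order.intervals): n
            for patt, n in zip(itertools.product((0, 1), repeat=3), counts)
        }
        res = lk.interval_rfs(classes, order)
        assert res.end_to_end_percent >= res.end_to_end_direct_percent - 1e-9


class TestSearchOrder:
    def test_four_locus_counts_recover_the_published_order(
        self, config, counts, mm, candidum, models
    ):
        ranked = lk.search_order(counts["t7-01"], mm, candidum, models)
        assert len(ranked) == 12  # 4!/2 distinct orders
        assert ranked[0].order.loci == ("LEM", "V", "S", "RLF")

    def test_simulated_well_separated_loci_recover_generating_order(
        self, four_locus_cross, models
    ):
        spec = lk.SimulationSpec(
            four_locus_cross, 2000, 20260301,
            female_rs=(0.05, 0.10, 0.20), male_rs=(0.05, 0.10, 0.20),
        )
        table = lk.simulate_progeny(spec)
        ranked = lk.search_order(
            table, four_locus_cross.female, four_locus_cross.male, models
        )
        assert ranked[0].order.loci == ("LEM", "V", "S", "RLF")

    def test_two_heterozygous_loci_give_the_trivial_order(
        self, config, counts, models
    ):
        cross = config.cross("t4-04").restrict(("S", "LEM"))
        sub_models = {l: models[l] for l in ("S", "LEM")}
        ranked = lk.search_order(counts["t4-04"], cross.female, cross.male, sub_models)
        assert len(ranked) == 1
        assert set(ranked[0].order.loci) == {"S", "LEM"}


class TestMappingFunctions:
    def test_zero_r_is_zero_distance(self):
        assert lk.map_distance(0.0).cm == 0.0
        assert lk.map_distance(0.0, "haldane").cm == 0.0

    @pytest.mark.parametrize(
        "r, cm", [(0.1484, 15.30), (0.0379, 3.80), (0.0047, 0.47), (0.1058, 10.74)]
    )
    def test_kosambi_formula_values(self, r, cm):
        assert round(lk.map_distance(r, "kosambi").cm, 2) == cm

    def test_unlinked_distance_undefined(self):
        with pytest.raises(lk.GeneticsDomainError):
            lk.map_distance(0.5)

    @given(r=st.floats(0.0, 0.499))
    @pytest.mark.parametrize("function", ["kosambi", "haldane"])
    def test_round_trip_below_1e10(self, function, r):
        cm = lk.map_distance(r, function).cm
        assert lk.inverse_map_distance(cm, function) == pytest.approx(r, abs=1e-10)

    @given(r=st.floats(1e-6, 0.499))
    def test_kosambi_never_exceeds_haldane_and_both_exceed_100r(self, r):
        k = lk.map_distance(r, "kosambi").cm
        h = lk.map_distance(r, "haldane").cm
        assert k <= h + 1e-12
        assert k >= 100 * r - 1e-9 and h >= 100 * r - 1e-9

    def test_first_order_agreement_with_100r_at_small_r(self):
        # m ~ 100r as r -> 0; the error is O(r^2) for Kosambi (its series
        # has no quadratic term) and O(r) for Haldane
        r = 1e-4
        assert abs(lk.map_distance(r, "kosambi").cm - 100 * r) / (100 * r) < 1e-6
        assert abs(lk.map_distance(r, "haldane").cm - 100 * r) / (100 * r) < 2e-4


class TestBuildMap:
    def test_cumulative_positions_from_published_intervals(self):
        positions = lk.build_map(TRUE_RS, ORDER, "kosambi")
        assert [(l, round(p, 2)) for l, p in positions] == [
            ("LEM", 0.0), ("V", 3.80), ("S", 4.27), ("RLF", 15.01),
        ]

    def test_zero_intervals_collapse_to_origin(self):
        positions = lk.build_map((0.0, 0.0, 0.0), ORDER)
        assert all(p == 0.0 for _, p in positions)

    def test_orientation_is_a_mirror_symmetry(self):
        # accumulating the same interval distances from the opposite end
        # gives max - position for every locus
        fwd = lk.build_map(TRUE_RS, ORDER)
        length = fwd[-1][1]
        rev_cumulative = {ORDER.loci[-1]: 0.0}
        pos = 0.0
        for locus, r in zip(reversed(ORDER.loci[:-1]), reversed(TRUE_RS)):
            pos += lk.map_distance(r).cm
            rev_cumulative[locus] = pos
        for locus, p in fwd:
            assert rev_cumulative[locus] == pytest.approx(length - p, abs=1e-9)

    def test_locus_order_identifies_with_its_reverse(self):
        assert lk.LocusOrder(("RLF", "S", "V", "LEM")) == ORDER

    def test_missing_interval_rejected(self):
        with pytest.raises(lk.GeneticsDomainError):
            lk.build_map((0.1, 0.2), ORDER)
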