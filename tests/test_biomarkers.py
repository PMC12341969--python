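"""Interval Jaccard, range classification, connectivity, Venn, carbon assay."""

import itertools

import numpy as np
import pytest

from fluxmark import (
    FvaResult,
    MetabolicModel,
    Metabolite,
    Reaction,
    carbon_limited_assay,
    classify_ranges,
    interval_jaccard,
    metabolite_connectivity,
    subsystem_matrix,
    venn_reactions,
)
from fluxmark.biomarkers import CATEGORIES


def fva_result(ranges):
    return FvaResult(ranges=dict(ranges), objective_id="obj")


class TestIntervalJaccard:
    @pytest.mark.parametrize(
        "r1,r2,expected",
        [
            (((1.0, 3.0)), ((2.0, 4.0)), 1.0 / 3.0),
            (((0.0, 1.0)), ((2.0, 3.0)), 0.0),
            (((-2.5, 7.0)), ((-2.5, 7.0)), 1.0),
            (((0.0, 0.0)), ((0.0, 0.0)), 1.0),  # identical points
            (((0.0, 0.0)), ((5.0, 5.0)), 0.0),  # disjoint points
        ],
    )
    def test_reference_values(self, r1, r2, expected):
        assert interval_jaccard(r1, r2) == pytest.approx(expected)

    def test_sub_tolerance_union_counts_as_equal(self):
        assert interval_jaccard((0.0, 1e-9), (2e-9, 5e-9)) == 1.0

    def test_symmetry_and_bounds(self, rng):
        for _ in range(200):
            a, b = np.sort(rng.uniform(-5, 5, 2))
            c, d = np.sort(rng.uniform(-5, 5, 2))
            j1 = interval_jaccard((a, b), (c, d))
            j2 = interval_jaccard((c, d), (a, b))
            assert j1 == pytest.approx(j2)
            assert 0.0 <= j1 <= 1.0

    def test_one_iff_equal_within_tol(self, rng):
        for _ in range(100):
            a, b = np.sort(rng.uniform(-5, 5, 2))
            assert interval_jaccard((a, b), (a, b)) == 1.0
            shifted = interval_jaccard((a, b), (a + 0.5, b + 1.0))
            assert shifted < 1.0

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            interval_jaccard((2.0, 1.0), (0.0, 1.0))


class TestClassifyRanges:
    def test_reference_categories(self):
        control = fva_result({"a": (0.0, 1.0), "b": (0.0, 1.0), "c": (0.0, 2.0),
                              "only_control": (0.0, 1.0)})
        dose = fva_result({"a": (0.0, 1.0), "b": (2.0, 3.0), "c": (1.0, 3.0),
                           "only_dose": (0.0, 1.0)})
        comparison = classify_ranges(control, dose)
        assert comparison.entries["a"].category == "equivalent"
        assert comparison.entries["a"].jaccard == 1.0
        assert comparison.entries["b"].category == "non_overlapping"
        assert comparison.entries["b"].jaccard == 0.0
        assert comparison.entries["c"].category == "overlapping"
        assert comparison.entries["c"].jaccard == pytest.approx(1.0 / 3.0)
        assert comparison.entries["only_control"].category == "absent"
        assert comparison.entries["only_dose"].category == "absent"

    def test_partition_property(self, rng):
        for _ in range(50):
            ids = [f"r{i}" for i in range(10)]
            control = fva_result(
                {i: tuple(np.sort(rng.uniform(-3, 3, 2))) for i in ids}
            )
            dose = fva_result(
                {i: tuple(np.sort(rng.uniform(-3, 3, 2))) for i in ids}
            )
            comparison = classify_ranges(control, dose)
            for entry in comparison.entries.values():
                assert entry.category in CATEGORIES
                assert sum(entry.category == c for c in CATEGORIES) == 1

    def test_disjoint_reaction_sets_rejected(self):
        with pytest.raises(ValueError, match="share no reactions"):
            classify_ranges(fva_result({"a": (0, 1)}), fva_result({"b": (0, 1)}))


class TestSubsystemMatrix:
    def comparison(self):
        control = fva_result({"r1": (0.0, 1.0), "r2": (0.0, 1.0),
                              "r3": (0.0, 1.0), "r4": (0.0, 2.0)})
        dose = fva_result({"r1": (5.0, 6.0), "r2": (0.0, 1.0),
                           "r3": (0.5, 1.5), "r4": (0.0, 2.0)})
        return classify_ranges(control, dose)

    def test_counts_and_by_category_normalization(self):
        subsystem_of = {"r1": "Shuttle", "r2": "Shuttle", "r3": "Other", "r4": ""}
        matrix = subsystem_matrix(self.comparison(), subsystem_of)
        # columns sum to 1 where non-empty
        sums = matrix.sum(axis=0)
        assert all(s == pytest.approx(1.0) for s in sums)
        assert matrix.loc["Shuttle", "non_overlapping"] == pytest.approx(1.0)
        assert "unassigned" in matrix.index

    def test_single_subsystem_rows_are_ones(self):
        subsystem_of = {f"r{i}": "only" for i in range(1, 5)}
        matrix = subsystem_matrix(self.comparison(), subsystem_of)
        assert matrix.loc["only"].tolist() == [1.0, 1.0, 1.0]

    def test_counts_mode(self):
        subsystem_of = {f"r{i}": "only" for i in range(1, 5)}
        matrix = subsystem_matrix(self.comparison(), subsystem_of,
                                  normalize="counts")
        assert matrix.loc["only"].sum() == 4


class TestConnectivity:
    def model(self):
        mets = [Metabolite(i) for i in (
            "crn[c]", "crn[m]", "chsterol[c]", "h2o[c]", "x[c]"
        )]
        rxns = [
            Reaction("i1", {"crn[c]": -1.0, "h2o[c]": 1.0}, 0, 1),
            Reaction("i2", {"crn[m]": -1.0, "chsterol[c]": 1.0}, 0, 1),
            Reaction("i3", {"crn[c]": 1.0, "chsterol[c]": -1.0}, 0, 1),
            Reaction("calm", {"x[c]": -1.0, "h2o[c]": 1.0}, 0, 1),
        ]
        return MetabolicModel(metabolites=mets, reactions=rxns)

    def comparison(self):
        control = fva_result({"i1": (0, 1), "i2": (0, 1), "i3": (0, 2),
                              "calm": (0, 1)})
        dose = fva_result({"i1": (2, 3), "i2": (2, 3), "i3": (1, 3),
                           "calm": (0, 1)})
        return classify_ranges(control, dose)

    def test_carnitine_outranks_cholesterol(self):
        ranking = metabolite_connectivity(self.comparison(), self.model())
        assert ranking.ranking[0] == ("crn", 3)  # compartments merged
        assert ranking.rank_of("chsterol") == 2

    def test_excluded_metabolite_never_appears(self):
        ranking = metabolite_connectivity(self.comparison(), self.model())
        assert ranking.rank_of("h2o") is None

    def test_counts_match_bruteforce_matrix_scan(self, toy_model):
        from fluxmark import fva

        result = fva(toy_model, "ATPM", 0.9)
        shifted = FvaResult(
            ranges={rid: (lo + 10.0, hi + 10.0) for rid, (lo, hi) in
                    result.ranges.items()},
            objective_id="ATPM",
        )
        comparison = classify_ranges(result, shifted)
        ranking = metabolite_connectivity(comparison, toy_model)
        impacted = set(comparison.impacted())
        S, met_index, rxn_index = toy_model.stoichiometric_matrix()
        from fluxmark.biomarkers import DEFAULT_EXCLUDED_METABOLITES
        from fluxmark.model import split_compartment

        brute: dict[str, set] = {}
        for met_id, i in met_index.items():
            base = split_compartment(met_id)[0]
            if base in DEFAULT_EXCLUDED_METABOLITES:
                continue
            for rid, j in rxn_index.items():
                if rid in impacted and S[i, j] != 0:
                    brute.setdefault(base, set()).add(rid)
        expected = sorted(
            ((met, len(rxns)) for met, rxns in brute.items()),
            key=lambda item: (-item[1], item[0]),
        )
        assert ranking.ranking == expected

    def test_ties_break_lexicographically(self):
        control = fva_result({"i1": (0, 1), "i2": (0, 1)})
        dose = fva_result({"i1": (2, 3), "i2": (2, 3)})
        comparison = classify_ranges(control, dose)
        mets = [Metabolite("b[c]"), Metabolite("a[c]")]
        rxns = [
            Reaction("i1", {"a[c]": -1.0, "b[c]": 1.0}, 0, 1),
            Reaction("i2", {"b[c]": -1.0, "a[c]": 1.0}, 0, 1),
        ]
        model = MetabolicModel(metabolites=mets, reactions=rxns)
        ranking = metabolite_connectivity(comparison, model)
        assert ranking.ranking == [("a", 2), ("b", 2)]


class TestVenn:
    def test_reference_decomposition(self):
        report = venn_reactions({"A": {"a", "b", "c"}, "B": {"b", "c", "d"},
                                 "C": {"c"}})
        assert report.union_size == 4
        assert report.all_shared_size == 1
        assert report.fractions_pct["A+B+C"] == pytest.approx(25.0)
        assert report.region_sizes[frozenset({"A", "B"})] == 1  # b only
        assert report.region_sizes[frozenset({"A"})] == 1  # a only

    def test_identical_sets_are_fully_shared(self):
        report = venn_reactions({"A": {"x", "y"}, "B": {"x", "y"}, "C": {"x", "y"}})
        assert report.fractions_pct["A+B+C"] == 100.0

    def test_partition_identity(self, rng):
        universe = [f"r{i}" for i in range(30)]
        for _ in range(25):
            sets = {
                label: {r for r in universe if rng.random() < p} | {"anchor"}
                for label, p in (("A", 0.5), ("B", 0.4), ("C", 0.6))
            }
            report = venn_reactions(sets)
            assert sum(report.region_sizes.values()) == report.union_size
            # inclusion-exclusion for the triple intersection
            triple = len(sets["A"] & sets["B"] & sets["C"])
            assert report.all_shared_size == triple

    def test_wrong_arity_rejected(self):
        with pytest.raises(ValueError):
            venn_reactions({"A": {"x"}, "B": {"x"}})


class TestCarbonAssay:
    def test_glucose_arm_uses_pdh_not_boxd(self, toy_model):
        fluxes = carbon_limited_assay(
            toy_model, "EX_glc__D_e", amount=1.0, objective_id="ATPM",
            report_ids=["PDH", "BOXD_hdcea", "EX_glc__D_e"],
        )
        assert fluxes["PDH"] == pytest.approx(2.0, abs=1e-6)
        assert fluxes["BOXD_hdcea"] == pytest.approx(0.0, abs=1e-6)
        assert fluxes["EX_glc__D_e"] == pytest.approx(-1.0, abs=1e-6)

    def test_palmitoleate_arm_uses_boxd_not_pdh(self, toy_model):
        fluxes = carbon_limited_assay(
            toy_model, "EX_hdcea_e", amount=1.0, objective_id="ATPM",
            report_ids=["PDH", "BOXD_hdcea"],
        )
        assert fluxes["BOXD_hdcea"] == pytest.approx(1.0, abs=1e-6)
        assert fluxes["PDH"] == pytest.approx(0.0, abs=1e-6)

    def test_zero_amount_zeroes_reported_fluxes(self, toy_model):
        fluxes = carbon_limited_assay(
            toy_model, "EX_glc__D_e", amount=0.0, objective_id="ATPM",
            report_ids=["PDH", "AKGDH", "BOXD_hdcea"],
        )
        assert all(abs(v) <= 1e-6 for v in fluxes.values())

    def test_missing_substrate_rejected(self, toy_model):
        with pytest.raises(KeyError):
            carbon_limited_assay(toy_model, "EX_nope", objective_id="ATPM")
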