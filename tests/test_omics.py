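"""Binarization, GPR evaluation, metabolomics scaling, condition models."""

import itertools

import numpy as np
import pandas as pd
import pytest

from fluxmark import (
    BinarizedExpression,
    ExpressionMatrix,
    GprParseError,
    MetaboliteAvailability,
    availability_to_exchange_bounds,
    basc_a_binarize,
    binarize_matrix,
    build_condition_bundle,
    eval_gpr,
    gene_condition_state,
    log2p1,
    scale_metabolomics,
    silence_unexpressed,
)

from .oracles import basc_bruteforce, random_gpr


class TestLog2p1:
    @pytest.mark.parametrize("value,expected", [(0, 0.0), (1, 1.0), (7, 3.0)])
    def test_reference_points(self, value, expected):
        assert log2p1(np.array([value]))[0] == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log2p1(np.array([-1.0]))

    def test_dataframe_preserves_labels(self):
        frame = pd.DataFrame([[3, 7]], index=["g"], columns=["s1", "s2"])
        out = log2p1(frame)
        assert list(out.columns) == ["s1", "s2"]
        assert out.loc["g", "s1"] == pytest.approx(2.0)


class TestBascA:
    def test_clean_two_level_vector(self):
        binary, threshold = basc_a_binarize([0.0, 0.0, 0.0, 10.0, 10.0])
        assert list(binary) == [0, 0, 0, 1, 1]
        assert threshold == pytest.approx(5.0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            basc_a_binarize([1.0, 2.0])

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            basc_a_binarize([4.0, 4.0, 4.0, 4.0])

    def test_dominant_gap_separates(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 9))
            low = rng.uniform(0.0, 1.0, size=rng.integers(1, n))
            high = rng.uniform(50.0, 51.0, size=n - low.size)
            values = rng.permutation(np.concatenate([low, high]))
            binary, threshold = basc_a_binarize(values)
            assert 1.0 < threshold < 50.0
            np.testing.assert_array_equal(binary, (values > 25.0).astype(int))

    def test_matches_bruteforce_enumeration(self, rng):
        for n in range(3, 9):
            for _ in range(30):
                values = rng.normal(size=n)
                binary, threshold = basc_a_binarize(values)
                expected_binary, expected_threshold = basc_bruteforce(values)
                assert threshold == pytest.approx(expected_threshold, abs=1e-9)
                np.testing.assert_array_equal(binary, expected_binary)

    def test_shift_invariance(self, rng):
        values = rng.normal(size=7)
        binary, threshold = basc_a_binarize(values)
        shifted_binary, shifted_threshold = basc_a_binarize(values + 100.0)
        np.testing.assert_array_equal(binary, shifted_binary)
        assert shifted_threshold == pytest.approx(threshold + 100.0, abs=1e-8)


class TestBinarizeMatrix:
    def matrix(self):
        counts = pd.DataFrame(
            {
                "DMSO_1": [500, 500, 0], "DMSO_2": [500, 500, 0],
                "Dose_1": [500, 7, 0], "Dose_2": [500, 7, 0],
            },
            index=["flat_on", "drops", "flat_off"],
        )
        conditions = {s: s.rsplit("_", 1)[0] for s in counts.columns}
        return ExpressionMatrix(counts=counts, condition_of=conditions)

    def test_constant_genes_keep_flat_state(self):
        binarized = binarize_matrix(self.matrix())
        assert binarized.states.loc["flat_on"].tolist() == [1, 1, 1, 1]
        assert binarized.states.loc["flat_off"].tolist() == [0, 0, 0, 0]

    def test_dropping_gene_splits_on_condition(self):
        binarized = binarize_matrix(self.matrix())
        assert binarized.states.loc["drops"].tolist() == [1, 1, 0, 0]

    def test_condition_aggregation_rules(self):
        binarized = BinarizedExpression(
            states=pd.DataFrame(
                {"c_1": [1, 0, 1], "c_2": [1, 0, 0]}, index=["a", "b", "tie"]
            ),
            thresholds=pd.Series([1.0, 1.0, 1.0], index=["a", "b", "tie"]),
            condition_of={"c_1": "c", "c_2": "c"},
        )
        majority = gene_condition_state(binarized, "c")
        assert majority == {"a": 1, "b": 0, "tie": 1}  # documented tie -> 1
        assert gene_condition_state(binarized, "c", rule="all")["tie"] == 0
        assert gene_condition_state(binarized, "c", rule="any")["tie"] == 1
        with pytest.raises(KeyError):
            gene_condition_state(binarized, "missing")


class TestEvalGpr:
    def test_reference_cases(self):
        assert eval_gpr("g1 and (g2 or g3)", {"g1": 1, "g2": 0, "g3": 1}) == 1
        assert eval_gpr("g1 and g2", {"g1": 1, "g2": 0}) == 0
        assert eval_gpr("", {}) == 1

    def test_missing_gene_defaults_to_expressed(self):
        assert eval_gpr("g1 and mystery", {"g1": 1}) == 1

    def test_parse_error_reports_position(self):
        with pytest.raises(GprParseError, match="position"):
            eval_gpr("g1 and (g2 or", {})
        with pytest.raises(GprParseError):
            eval_gpr("and g1", {})

    def test_matches_truth_table_oracle(self, rng):
        genes = [f"g{i}" for i in range(5)]
        for _ in range(50):
            expr = random_gpr(rng, genes)
            for bits in itertools.product((0, 1), repeat=len(genes)):
                states = dict(zip(genes, bits))
                expected = int(eval(expr, {}, {g: bool(v) for g, v in states.items()}))
                assert eval_gpr(expr, states) == expected


class TestScaleMetabolomics:
    def test_zero_z_is_identity(self):
        out = scale_metabolomics({"a": 100.0}, {"a": 0.0})
        assert out.values["a"] == pytest.approx(100.0)

    def test_exp2_doubles_on_unit_z(self):
        out = scale_metabolomics({"a": 100.0}, {"a": 1.0}, mode="exp2")
        assert out.values["a"] == pytest.approx(200.0)

    def test_multiplicative_floors_at_zero(self):
        out = scale_metabolomics({"a": 100.0}, {"a": -2.0}, mode="multiplicative")
        assert out.values["a"] == 0.0

    def test_unmatched_metabolites_keep_reference(self):
        out = scale_metabolomics({"a": 10.0, "b": 5.0}, {"a": 1.0, "ghost": 3.0})
        assert out.values["b"] == 5.0
        assert "ghost" not in out.values


class TestExchangeBounds:
    def test_bounds_scaled_by_kappa(self, toy_model):
        availability = MetaboliteAvailability("c", {"glc__D": 10.0, "hdcea": 0.0})
        scaled = availability_to_exchange_bounds(toy_model, availability, kappa=0.1)
        assert scaled.reaction("EX_glc__D_e").lower_bound == pytest.approx(-1.0)
        assert scaled.reaction("EX_hdcea_e").lower_bound == 0.0  # no uptake
        # exchange without data untouched
        assert scaled.reaction("EX_hdca_e").lower_bound == pytest.approx(
            toy_model.reaction("EX_hdca_e").lower_bound
        )

    def test_absent_metabolite_is_noop(self, toy_model):
        availability = MetaboliteAvailability("c", {"unobtainium": 5.0})
        scaled = availability_to_exchange_bounds(toy_model, availability)
        for before, after in zip(toy_model.reactions, scaled.reactions):
            assert (before.lower_bound, before.upper_bound) == (
                after.lower_bound, after.upper_bound,
            )


class TestSilenceUnexpressed:
    def test_off_gene_nulls_bounds(self, chain_model):
        silenced = silence_unexpressed(chain_model, {"g1": 0})
        assert silenced.reaction("A2B").lower_bound == 0.0
        assert silenced.reaction("A2B").upper_bound == 0.0

    def test_isozyme_rescues(self, chain_model):
        chain_model.reaction("A2B").gpr = "g1 or g2"
        chain_model.genes = ["g1", "g2"]
        silenced = silence_unexpressed(chain_model, {"g1": 0, "g2": 1})
        assert silenced.reaction("A2B").upper_bound == 1000.0

    def test_empty_gpr_untouched(self, chain_model):
        silenced = silence_unexpressed(chain_model, {"g1": 0})
        assert silenced.reaction("EX_A").lower_bound == -1.0


class TestConditionBundle:
    def _binarized(self, genes, dose_off=()):
        samples = ["DMSO_1", "DMSO_2", "Low_1", "Low_2"]
        states = pd.DataFrame(1, index=list(genes), columns=samples, dtype=int)
        for gene in dose_off:
            states.loc[gene, ["Low_1", "Low_2"]] = 0
        return BinarizedExpression(
            states=states,
            thresholds=pd.Series(1.0, index=list(genes)),
            condition_of={s: s.rsplit("_", 1)[0] for s in samples},
        )

    def test_identical_omics_gives_identical_models(self, toy_model):
        from fluxmark.model import model_to_json

        binarized = self._binarized(toy_model.genes)
        availability = MetaboliteAvailability("DMSO", {"glc__D": 1.0})
        bundle = build_condition_bundle(
            toy_model, binarized, availability,
            MetaboliteAvailability("Low", {"glc__D": 1.0}), "Low",
        )
        assert model_to_json(bundle.control_model) == model_to_json(bundle.dose_model)

    def test_silenced_shuttle_is_pruned_from_dose_arm(self, toy_model):
        binarized = self._binarized(toy_model.genes, dose_off=("cpt1a", "cpt1b"))
        availability = MetaboliteAvailability("DMSO", {})
        bundle = build_condition_bundle(
            toy_model, binarized, availability,
            MetaboliteAvailability("Low", {}), "Low",
        )
        control_ids = set(bundle.control_model.reaction_ids)
        dose_ids = set(bundle.dose_model.reaction_ids)
        assert {"CPT1_hdcea", "CRNt_hdcea", "CPT2_hdcea", "BOXD_hdcea"} <= control_ids
        # CPT-I loss blocks the whole shuttle and beta-oxidation downstream
        assert not any(r.startswith(("CPT", "CRNt", "BOXD")) for r in dose_ids)
        assert control_ids != dose_ids
        assert any("cpt" in line.lower() or "CPT" in line for line in bundle.provenance)

    def test_reaction_sets_differ_iff_constraints_differ(self, toy_model):
        binarized = self._binarized(toy_model.genes)
        bundle = build_condition_bundle(
            toy_model, binarized,
            MetaboliteAvailability("DMSO", {"hdcea": 0.5}),
            MetaboliteAvailability("Low", {"hdcea": 2.0}), "Low",
        )
        # bounds differ but no reaction is lost: sets equal, provenance differs
        assert set(bundle.control_model.reaction_ids) == set(
            bundle.dose_model.reaction_ids
        )
        assert any("EX_hdcea_e" in line for line in bundle.provenance)

    def test_bad_label_rejected(self, toy_model):
        binarized = self._binarized(toy_model.genes)
        with pytest.raises(ValueError, match="label"):
            build_condition_bundle(
                toy_model, binarized,
                MetaboliteAvailability("DMSO", {}),
                MetaboliteAvailability("Low", {}), "Extreme",
            )

    def test_starved_model_reports_infeasibility(self, toy_model):
        from fluxmark import InfeasibleModelError

        binarized = self._binarized(toy_model.genes)
        starved = {met: 0.0 for met in ("glc__D", "hdcea", "hdca", "ocdcea", "ttdca")}
        with pytest.raises(InfeasibleModelError, match="kappa|ATP|demand"):
            build_condition_bundle(
                toy_model, binarized,
                MetaboliteAvailability("DMSO", starved),
                MetaboliteAvailability("Low", starved), "Low",
            )
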