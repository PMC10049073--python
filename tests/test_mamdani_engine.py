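import json

import numpy as np
import pytest

from clusterfis import (
    FIS,
    FuzzyRule,
    RuleBase,
    aggregate,
    assemble_fis,
    classify,
    classify_batch,
    defuzzify,
    make_ground_truth,
    rule_activation,
    sample_records,
)
from clusterfis.mamdani_engine import AggregatedFuzzySet, AssemblyError
from conftest import make_variable, random_toy_fis
from _naive_mamdani import naive_classify


@pytest.fixture
def toy_fis():
    input_vars = {
        "A": make_variable("A", [2, 8], (0.0, 10.0)),
        "B": make_variable("B", [1, 5, 9], (0.0, 10.0)),
    }
    output_var = make_variable("class", [1, 2], (1.0, 2.0))
    rules = [
        FuzzyRule((("A", 0), ("B", 0)), consequent=0),
        FuzzyRule((("A", 1), ("B", 2)), consequent=1),
    ]
    return assemble_fis(
        input_vars, output_var, RuleBase(rules, ["A", "B"])
    )


class TestAssembly:
    def test_round_trips_through_json(self, toy_fis, tmp_path):
        path = tmp_path / "model.json"
        toy_fis.to_json(path)
        back = FIS.from_json(path)
        assert back.to_dict() == toy_fis.to_dict()

    def test_unknown_feature_rejected(self, toy_fis):
        bad = RuleBase(
            [FuzzyRule((("Z", 0),), consequent=0)], ["Z"]
        )
        with pytest.raises(AssemblyError, match="unknown feature 'Z'"):
            assemble_fis(toy_fis.input_vars, toy_fis.output_var, bad)

    def test_out_of_range_mf_index_rejected(self, toy_fis):
        bad = RuleBase(
            [FuzzyRule((("A", 5),), consequent=0)], ["A"]
        )
        with pytest.raises(AssemblyError, match="MF6"):
            assemble_fis(toy_fis.input_vars, toy_fis.output_var, bad)

    def test_generating_fis_classifies_noiseless_samples_perfectly(self):
        gt = make_ground_truth(n_features=5, seed=11)
        table = sample_records(gt, 400, seed=12)
        _, pred = classify_batch(gt.fis, table.features, table.feature_names)
        assert np.array_equal(pred, table.labels)


class TestActivation:
    def test_record_at_all_apexes_fires_at_one(self, toy_fis):
        s = rule_activation(toy_fis, {"A": 2, "B": 1})
        assert s[0] == 1.0

    def test_min_operator(self, toy_fis):
        # A=4 -> left degree 4/6; B=3 -> mf1 degree 0.5: strength = min
        s = rule_activation(toy_fis, {"A": 4, "B": 3})
        assert s[0] == pytest.approx(min(4 / 6, 0.5))

    def test_matches_naive_clause_loop(self, toy_fis, rng):
        for _ in range(10):
            rec = {"A": rng.uniform(0, 10), "B": rng.uniform(0, 10)}
            s = rule_activation(toy_fis, rec)
            for r_idx, rule in enumerate(toy_fis.rule_base.rules):
                expected = min(
                    toy_fis.input_vars[f].mfs[i].degree(rec[f])
                    for f, i in rule.antecedent
                )
                assert s[r_idx] == pytest.approx(float(expected))

    def test_missing_feature_value_rejected(self, toy_fis):
        with pytest.raises(KeyError):
            rule_activation(toy_fis, {"A": 4})


class TestAggregate:
    def test_single_rule_full_strength_equals_consequent_mf(self, toy_fis):
        agg = aggregate(toy_fis, np.array([1.0, 0.0]))
        expected = toy_fis.output_var.mfs[0].degree(agg.grid)
        assert np.allclose(agg.degrees, expected)

    def test_complementary_rules_plateau_at_half(self, toy_fis):
        agg = aggregate(toy_fis, np.array([0.5, 0.5]))
        # both shoulder mfs clipped at 0.5 -> max plateaus at 0.5 everywhere
        assert np.allclose(agg.degrees, 0.5)

    def test_all_zero_strengths_give_empty_set(self, toy_fis):
        agg = aggregate(toy_fis, np.zeros(2))
        assert np.all(agg.degrees == 0)


class TestDefuzzify:
    def test_symmetric_triangle_centroid_at_apex(self):
        grid = np.linspace(1.0, 2.0, 1001)
        tri = np.maximum(0.0, 1.0 - np.abs(grid - 1.5) / 0.25)
        z, fired = defuzzify(AggregatedFuzzySet(grid, tri), "centroid")
        assert fired and z == pytest.approx(1.5, abs=1e-12)

    def test_left_shoulder_matches_closed_form(self):
        # full left shoulder on [1,2]: mu(z) = 2 - z; centroid = 4/3
        grid = np.linspace(1.0, 2.0, 100001)
        z, _ = defuzzify(AggregatedFuzzySet(grid, 2.0 - grid), "centroid")
        assert z == pytest.approx(4.0 / 3.0, abs=1e-5)

    def test_right_shoulder_matches_closed_form(self):
        grid = np.linspace(1.0, 2.0, 100001)
        z, _ = defuzzify(AggregatedFuzzySet(grid, grid - 1.0), "centroid")
        assert z == pytest.approx(5.0 / 3.0, abs=1e-5)

    def test_mom_on_plateau_is_midpoint(self):
        grid = np.linspace(1.0, 2.0, 1001)
        mu = np.where((grid >= 1.2) & (grid <= 1.6), 0.8, 0.1)
        z, _ = defuzzify(AggregatedFuzzySet(grid, mu), "mom")
        assert z == pytest.approx(1.4, abs=1e-9)
        z_som, _ = defuzzify(AggregatedFuzzySet(grid, mu), "som")
        z_lom, _ = defuzzify(AggregatedFuzzySet(grid, mu), "lom")
        assert z_som == pytest.approx(1.2, abs=1e-9)
        assert z_lom == pytest.approx(1.6, abs=1e-9)

    def test_all_zero_set_flags_no_rule_fired(self):
        grid = np.linspace(1.0, 2.0, 101)
        z, fired = defuzzify(AggregatedFuzzySet(grid, np.zeros_like(grid)))
        assert not fired and z == pytest.approx(1.5)

    def test_grid_refinement_stability(self, rng):
        for _ in range(10):
            fis = random_toy_fis(rng)
            rec = {f: rng.uniform(0, 10) for f in fis.features}
            s = rule_activation(fis, rec)
            z_coarse, _ = defuzzify(aggregate(fis, s), "centroid")
            fis.grid_points = 10001
            z_fine, _ = defuzzify(aggregate(fis, s), "centroid")
            fis.grid_points = 1001
            assert abs(z_coarse - z_fine) < 1e-3


class TestClassify:
    def test_left_shoulder_consequent_gives_class_one(self, toy_fis):
        out = classify(toy_fis, {"A": 2, "B": 1})
        assert out.predicted_class == 1
        assert out.z == pytest.approx(4.0 / 3.0, abs=1e-3)

    def test_z_at_or_above_threshold_gives_class_two(self, toy_fis):
        out = classify(toy_fis, {"A": 8, "B": 9})
        assert out.predicted_class == 2
        assert out.z > toy_fis.threshold

    def test_no_rule_fired_falls_back_to_majority_class(self, toy_fis):
        # A=2 selects mf1, B=9 selects mf3: no rule matches strongly enough
        out = classify(toy_fis, {"A": 0, "B": 5})
        if out.fired_rules == 0:
            assert out.no_rule_fired
            assert out.predicted_class == toy_fis.majority_class

    def test_batch_matches_per_record_path(self, rng):
        for _ in range(5):
            fis = random_toy_fis(rng)
            feats = rng.uniform(0, 10, size=(15, len(fis.features)))
            z_batch, pred_batch = classify_batch(fis, feats, fis.features)
            for i in range(feats.shape[0]):
                out = classify(fis, dict(zip(fis.features, feats[i])))
                assert z_batch[i] == pytest.approx(out.z, abs=1e-12)
                assert pred_batch[i] == out.predicted_class

    def test_matches_independent_brute_force_engine(self, rng):
        for _ in range(20):
            fis = random_toy_fis(rng)
            for _ in range(10):
                rec = {f: float(rng.uniform(0, 10)) for f in fis.features}
                out = classify(fis, rec)
                z_naive, cls_naive = naive_classify(fis, rec)
                assert abs(out.z - z_naive) < 1e-6
                assert out.predicted_class == cls_naive or out.no_rule_fired

    def test_centroid_within_grid_and_apex_exact(self, rng):
        fis = random_toy_fis(rng)
        lo, hi = fis.output_var.domain
        for _ in range(10):
            rec = {f: float(rng.uniform(0, 10)) for f in fis.features}
            out = classify(fis, rec)
            assert lo <= out.z <= hi

    def test_monotone_in_rule_strength(self, toy_fis, rng):
        """For the binary complementary-shoulder output, raising the benign
        rule's strength never pushes Z away from the benign apex (and
        symmetrically for the malignant rule)."""
        for _ in range(20):
            s2 = float(rng.uniform(0.0, 1.0))
            z_prev = None
            for s1 in np.linspace(0.05, 1.0, 8):
                z, _ = defuzzify(aggregate(toy_fis, np.array([s1, s2])), "centroid")
                if z_prev is not None:
                    assert z <= z_prev + 1e-12  # monotone toward apex 1
                z_prev = z
            z_prev = None
            s1 = float(rng.uniform(0.0, 1.0))
            for s2 in np.linspace(0.05, 1.0, 8):
                z, _ = defuzzify(aggregate(toy_fis, np.array([s1, s2])), "centroid")
                if z_prev is not None:
                    assert z >= z_prev - 1e-12  # monotone toward apex 2
                z_prev = z
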