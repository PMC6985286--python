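"""Parameter sweeps, slope sign rules, and scenario comparison."""

import numpy as np
import pytest

from miia import (
    ConfigError,
    ParameterAssignment,
    build_binary_set,
    compare_scenarios,
    correlation_rules_report,
    make_fixture,
    membership_key,
    parse_pair,
    predict_community,
    random_dataset,
    sweep_parameter,
)


class TestPairSyntax:
    def test_parse(self):
        assert parse_pair("CT<-CS") == ("CT", "CS")

    @pytest.mark.parametrize("bad", ["CT", "CT<-", "<-CS", "A<-A"])
    def test_invalid(self, bad):
        with pytest.raises(ConfigError):
            parse_pair(bad)

    def test_scenario_from_dict(self):
        sc = ParameterAssignment.from_dict(
            {"label": "case3", "assignments": {"CT<-CS": 2.5, "CS<-CT": -0.5}}
        )
        assert sc.values[("CT", "CS")] == 2.5
        assert sc.label == "case3"

    def test_scenario_unknown_key_rejected(self):
        with pytest.raises(ConfigError):
            ParameterAssignment.from_dict({"label": "x", "extra": 1})


class TestSweep:
    def test_analytic_slopes(self, simple_ternary):
        """Partners (2, 1) for focal A: self-slope 1 - 4/5, cross -2/5."""
        bset = build_binary_set(simple_ternary)
        prof = sweep_parameter(
            bset, simple_ternary, ("A", "B"), grid=np.linspace(-1, 1, 5),
            override=True,
        )
        key = membership_key(("A", "B", "C"))
        assert prof.slopes[(key, "A", "B")] == pytest.approx(0.2)
        assert prof.slopes[(key, "A", "C")] == pytest.approx(-0.4)

    def test_other_rows_are_flat(self, simple_ternary):
        bset = build_binary_set(simple_ternary)
        prof = sweep_parameter(
            bset, simple_ternary, ("A", "B"), grid=np.linspace(-1, 1, 5),
            override=True,
        )
        key = membership_key(("A", "B", "C"))
        for j in ("A", "C"):
            traj = prof.trajectories[(key, "B", j)]
            assert np.ptp(traj) == 0.0

    def test_trajectories_affine(self, kato_obs):
        bset = build_binary_set(kato_obs)
        prof = sweep_parameter(bset, kato_obs, ("CT", "CS"))
        for traj in prof.trajectories.values():
            assert np.all(np.abs(np.diff(traj, n=2)) <= 1e-9 * max(1, np.max(np.abs(traj))))

    def test_single_point_grid_flags_undefined_slopes(self, kato_obs):
        bset = build_binary_set(kato_obs)
        prof = sweep_parameter(bset, kato_obs, ("CT", "CS"), grid=[0.0])
        assert not prof.slopes_defined
        assert all(s is None for s in prof.slopes.values())

    def test_baseline_grid_point_reproduces_prediction(self, kato_obs):
        bset = build_binary_set(kato_obs)
        prof = sweep_parameter(bset, kato_obs, ("CT", "CS"), grid=[0.0])
        for key in kato_obs.contexts(min_size=3):
            cmat = predict_community(bset, kato_obs, key)
            for pair, v in cmat.entries.items():
                assert prof.trajectories[(key, pair[0], pair[1])][0] == v

    def test_sweeping_identified_pair_needs_override(self, wang_obs):
        bset = build_binary_set(wang_obs)
        pair = bset.estimated_pairs()[0]
        with pytest.raises(ConfigError):
            sweep_parameter(bset, wang_obs, pair)

    def test_unstrict_grid_rejected(self, kato_obs):
        bset = build_binary_set(kato_obs)
        with pytest.raises(ConfigError):
            sweep_parameter(bset, kato_obs, ("CT", "CS"), grid=[1.0, 0.5])


class TestCorrelationRules:
    def test_rules_hold_on_random_instances(self):
        """Self-positive / cross-negative slope rules across random datasets."""
        n_checked = 0
        for seed in range(12):
            ds = random_dataset(
                make_fixture("kato4"), seed=seed, abundance_range=(1.0, 10.0)
            )
            bset = build_binary_set(ds.observations)
            profiles = [
                sweep_parameter(bset, ds.observations, pair,
                                grid=np.linspace(-2, 2, 5))
                for pair in bset.unidentifiable_pairs()
            ]
            report = correlation_rules_report(profiles, ds.observations)
            assert report.ok, report.violations
            for slope in report.self_slopes.values():
                assert -1e-9 <= slope <= 1 + 1e-9
            for slope in report.cross_slopes.values():
                assert slope <= 1e-9
            for total in report.weighted_sums.values():
                assert abs(total) <= 1e-9
            n_checked += len(report.self_slopes)
        assert n_checked > 0

    def test_single_partner_row_self_slope_zero(self):
        """With one partner the constraint fixes the coefficient uniquely."""
        from conftest import build_observation_set
        from miia import predict_community

        # focal I has a single partner J in the ternary (K absent: abundance 0)
        oset = build_observation_set(
            {
                ("I",): {"I": 1.0},
                ("J",): {"J": 1.0},
                ("K",): {"K": 0.0},
                ("I", "J"): {"I": 2.0, "J": 3.0},
                ("I", "K"): {"I": 1.0, "K": 0.0},
                ("J", "K"): {"J": 1.0, "K": 0.0},
                ("I", "J", "K"): {"I": 2.0, "J": 4.0, "K": 0.0},
            }
        )
        bset = build_binary_set(oset)
        prof = sweep_parameter(
            bset, oset, ("I", "J"), grid=np.linspace(-1, 1, 5), override=True
        )
        key = membership_key(("I", "J", "K"))
        assert prof.slopes[(key, "I", "J")] == pytest.approx(0.0)


class TestScenarios:
    def scenarios(self):
        case1 = ParameterAssignment({}, "case1")
        case2 = ParameterAssignment({("CT", "CS"): 2.5}, "case2")
        case3 = ParameterAssignment(
            {("CT", "CS"): 2.5, ("CS", "CT"): -0.5, ("PT", "CT"): 0.1,
             ("BA", "CT"): 2.5},
            "case3",
        )
        return [case1, case2, case3]

    def test_identical_scenarios_fully_robust(self, kato_obs):
        bset = build_binary_set(kato_obs)
        sc = ParameterAssignment({("CT", "CS"): 1.0}, "s")
        comparison = compare_scenarios(bset, kato_obs, [sc, sc])
        assert comparison.robust_fraction == 1.0

    def test_three_cases_structure(self, kato_obs):
        bset = build_binary_set(kato_obs)
        comparison = compare_scenarios(bset, kato_obs, self.scenarios())
        # 12 binary + 6*4 ternary + 12 quaternary signed edges
        assert len(comparison.signs) == 48
        assert set(comparison.classification.values()) <= {"robust", "case_dependent"}
        assert 0.0 <= comparison.robust_fraction <= 1.0
        assert set(comparison.by_size) == {2, 3, 4}
        n_ternary = sum(
            1 for (ctx, _, _) in comparison.signs
            if len(ctx.split("+")) == 3
        )
        assert n_ternary == 24

    def test_neutral_tolerance_semantics(self):
        """Values tiny relative to their focal row classify as neutral;
        values at the row scale keep their sign."""
        from miia import CoefficientMatrix
        from miia.sensitivity import _sign_classes

        cmat = CoefficientMatrix(
            "A+B+C", "scaled",
            {("A", "B"): 1.0, ("A", "C"): 1e-9,
             ("B", "A"): -1e-3, ("B", "C"): 2e-3},
        )
        signs = _sign_classes(cmat, tol_factor=1e-6)
        assert signs[("A", "B")] == 1
        assert signs[("A", "C")] == 0  # structural zero buried in noise
        assert signs[("B", "A")] == -1
        assert signs[("B", "C")] == 1

    def test_requires_two_scenarios(self, kato_obs):
        bset = build_binary_set(kato_obs)
        with pytest.raises(ValueError):
            compare_scenarios(bset, kato_obs, [ParameterAssignment({}, "x")])
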