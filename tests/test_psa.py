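"""Probabilistic analysis driver, scenarios and variance decomposition."""

import numpy as np
import pandas as pd
import pytest

from ascea import psa
from ascea.outcomes import ArmResult
from ascea.psa import SCENARIOS, PsaOutput, ScenarioConfig, run_psa


class TestScenarioConfigs:
    def test_suite_covers_base_plus_nine_alternatives(self):
        assert len(SCENARIOS) == 10
        assert "base" in SCENARIOS

    def test_invalid_switch_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(name="x", adverse_events="everything")
        with pytest.raises(ValueError):
            ScenarioConfig(name="x", iterations=0)

    def test_unknown_scenario_name_lists_valid_ones(self, mtc_draws,
                                                    registry):
        with pytest.raises(KeyError, match="base"):
            run_psa("not-a-scenario", mtc_draws, registry, iterations=1)


class TestReproducibility:
    def test_identical_seeds_identical_tables(self, mtc_draws, registry,
                                              life_table):
        a = run_psa("base", mtc_draws, registry, life_table=life_table,
                    iterations=200, seed=7)
        b = run_psa("base", mtc_draws, registry, life_table=life_table,
                    iterations=200, seed=7)
        pd.testing.assert_frame_equal(a.arm_table(), b.arm_table())
        pd.testing.assert_frame_equal(a.incremental_table(),
                                      b.incremental_table())
        pd.testing.assert_frame_equal(a.ce[30].ceac, b.ce[30].ceac)

    def test_single_iteration_point_estimate_is_deterministic(
            self, mtc_draws, registry, life_table):
        a = run_psa("base", mtc_draws, registry, life_table=life_table,
                    iterations=1, seed=1, point_estimate=True)
        b = run_psa("base", mtc_draws, registry, life_table=life_table,
                    iterations=1, seed=999, point_estimate=True)
        pd.testing.assert_frame_equal(a.arm_table(), b.arm_table())

    def test_monte_carlo_stability_of_mean_qalys(self, mtc_draws,
                                                 registry, life_table,
                                                 base_psa):
        bigger = run_psa("base", mtc_draws, registry,
                         life_table=life_table, iterations=4000, seed=43)
        for arm in ("etoricoxib", "celecoxib", "diclofenac", "naproxen"):
            q1 = base_psa.arm_results[30][arm].qalys.mean()
            q2 = bigger.arm_results[30][arm].qalys.mean()
            assert abs(q1 - q2) < 0.05, arm


class TestScenarios:
    def test_no_adverse_events_zeroes_event_costs(self, mtc_draws,
                                                  registry, life_table):
        out = run_psa("no-adverse-events", mtc_draws, registry,
                      life_table=life_table, iterations=50, seed=3)
        for per_arm in out.arm_results.values():
            for res in per_arm.values():
                assert np.all(res.cost_gi == 0.0)
                assert np.all(res.cost_cv == 0.0)
                assert np.all(res.cost_other == 0.0)

    def test_gi_only_keeps_gi_and_drops_cv(self, mtc_draws, registry,
                                           life_table):
        out = run_psa("gi-only", mtc_draws, registry,
                      life_table=life_table, iterations=50, seed=3)
        res = out.arm_results[5]["diclofenac"]
        assert np.all(res.cost_cv == 0.0)
        assert np.all(res.cost_other == 0.0)
        assert res.cost_gi.mean() > 0.0

    def test_cv_only_keeps_cv_and_drops_gi(self, mtc_draws, registry,
                                           life_table):
        out = run_psa("cv-only", mtc_draws, registry,
                      life_table=life_table, iterations=50, seed=3)
        res = out.arm_results[5]["diclofenac"]
        assert np.all(res.cost_gi == 0.0)
        assert res.cost_cv.mean() > 0.0

    def test_discounting_monotonicity_across_scenarios(self, mtc_draws,
                                                       registry,
                                                       life_table):
        kw = dict(life_table=life_table, iterations=100, seed=5)
        undisc = run_psa("discount-0", mtc_draws, registry, **kw)
        steep = run_psa("discount-8", mtc_draws, registry, **kw)
        for arm in ("etoricoxib", "celecoxib", "diclofenac", "naproxen"):
            assert (undisc.arm_results[30][arm].qalys.mean()
                    > steep.arm_results[30][arm].qalys.mean())

    def test_no_antitnf_cost_scenario_removes_biologic_spend(
            self, mtc_draws, registry, life_table):
        out = run_psa("no-antitnf-cost", mtc_draws, registry,
                      life_table=life_table, iterations=100, seed=6)
        base = run_psa("base", mtc_draws, registry,
                       life_table=life_table, iterations=100, seed=6)
        assert (out.arm_results[30]["celecoxib"].cost_treatment.mean()
                < base.arm_results[30]["celecoxib"].cost_treatment.mean())

    def test_stable_basfi_scenario_raises_late_utility(self, mtc_draws,
                                                       registry,
                                                       life_table):
        kw = dict(life_table=life_table, iterations=100, seed=8)
        stable = run_psa("stable-basfi", mtc_draws, registry, **kw)
        base = run_psa("base", mtc_draws, registry, **kw)
        assert (stable.arm_results[30]["etoricoxib"].qalys.mean()
                > base.arm_results[30]["etoricoxib"].qalys.mean())

    def test_suite_runner_covers_all_and_is_seeded(self, mtc_draws,
                                                   registry, life_table):
        suite = psa.run_scenario_suite(
            registry, mtc_draws, life_table=life_table, iterations=20,
            seed=11, names=("base", "age-20"))
        assert set(suite) == {"base", "age-20"}
        assert suite["age-20"].draw.start_age == 20.0


def test_common_random_numbers_reduce_increment_variance(base_psa):
    """Shared draws across arms shrink Var(per-iteration dQALY) well below
    the independent-sampling value."""
    q_ref = base_psa.arm_results[30]["etoricoxib"].qalys
    q_cmp = base_psa.arm_results[30]["celecoxib"].qalys
    paired_var = np.var(q_ref - q_cmp)
    rng = np.random.default_rng(0)
    independent_var = np.var(q_ref - rng.permutation(q_cmp))
    assert paired_var < 0.5 * independent_var


def test_time_on_nsaid_bounded_by_horizon(base_psa):
    t = psa.time_on_nsaid(base_psa.traces["etoricoxib"])
    assert np.all((t > 0) & (t <= 30.0))


class TestExplainedUncertainty:
    def _stub(self, inputs: pd.DataFrame, y: np.ndarray) -> PsaOutput:
        n = len(inputs)
        z = np.zeros(n)
        ref = ArmResult("etoricoxib", 30, 0.04, np.ones(n), y,
                        z, z.copy(), z.copy(), z.copy())
        cmp_ = ArmResult("celecoxib", 30, 0.04, np.ones(n), np.zeros(n),
                         z.copy(), z.copy(), z.copy(), z.copy())
        return PsaOutput(
            scenario=SCENARIOS["base"], draw=type("D", (), {"n": n})(),
            inputs=inputs, traces={},
            arm_results={30: {"etoricoxib": ref, "celecoxib": cmp_}},
            ce={}, metadata={"reference": "etoricoxib"})

    def test_pure_linear_driver_takes_all_share(self):
        rng = np.random.default_rng(4)
        inputs = pd.DataFrame({
            "p_disc.etoricoxib": rng.normal(size=500),
            "cost_cv": rng.normal(size=500),
            "utility_constant": rng.normal(size=500),
        })
        y = 3.0 * inputs["p_disc.etoricoxib"].to_numpy()
        shares = psa.explained_uncertainty(self._stub(inputs, y),
                                           "delta_qaly")
        assert shares["discontinuation"] == pytest.approx(1.0, abs=0.01)
        assert shares.drop("discontinuation").max() < 0.01

    def test_independent_output_has_no_explained_share(self):
        rng = np.random.default_rng(5)
        inputs = pd.DataFrame({
            "p_disc.etoricoxib": rng.normal(size=500),
            "cost_cv": rng.normal(size=500),
        })
        y = rng.normal(size=500)
        shares = psa.explained_uncertainty(self._stub(inputs, y),
                                           "delta_qaly")
        assert shares.sum() < 0.05

    def test_base_case_discontinuation_dominates(self, base_psa):
        shares = psa.explained_uncertainty(base_psa, "delta_nmb",
                                           wtp=400_000.0, horizon=30,
                                           comparator="celecoxib")
        assert shares.idxmax() == "discontinuation"
        assert np.all((shares.to_numpy() >= 0)
                      & (shares.to_numpy() <= 1))

    def test_rank_transform_option_runs(self, base_psa):
        shares = psa.explained_uncertainty(base_psa, "delta_qaly",
                                           rank_transform=True)
        assert "discontinuation" in shares.index[:2]
        assert np.all((shares.to_numpy() >= 0) & (shares.to_numpy() <= 1))
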