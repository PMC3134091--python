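"""Cohort engine: event tree, transitions, conservation, oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ascea import markov
from ascea.markov import EVENTS, HealthState, LifeTable


def zero_event_overrides():
    keys = ("pub_etoricoxib", "pub_celecoxib", "pub_nsnsaid",
            "suspected_pub_coxib", "suspected_pub_nsnsaid",
            "minor_gi_coxib", "minor_gi_nsnsaid",
            "cv_etoricoxib", "cv_celecoxib", "cv_diclofenac", "cv_naproxen",
            "edema_coxib", "edema_nsnsaid", "hypertension_coxib",
            "hypertension_nsnsaid", "chf_coxib", "chf_nsnsaid",
            "hepatic_coxib", "hepatic_nsnsaid", "renal_coxib",
            "renal_nsnsaid")
    return {k: 0.0 for k in keys}


def zero_efficacy_exit(draw):
    for k in draw.p_disc:
        draw.p_disc[k][:] = 1e-9
    draw.disease["p_antitnf_withdraw"][:] = 0.0
    return draw


class TestLifeTable:
    def test_bundled_table_reads_and_is_monotone_in_adulthood(self):
        table = markov.read_life_table()
        assert table.q(45) == pytest.approx(0.0026, abs=0.0005)
        ages = np.arange(30, 100)
        qs = np.array([table.q(a) for a in ages])
        assert np.all(np.diff(qs) > 0)

    def test_uncovered_age_errors(self):
        table = LifeTable(np.array([45, 46]), np.array([0.001, 0.001]))
        with pytest.raises(ValueError, match="age 47"):
            table.q(47)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            LifeTable(np.array([45]), np.array([1.5]))


class TestCycleTransition:
    def test_no_events_no_mortality_stays_put(self, make_draw):
        draw = zero_efficacy_exit(make_draw(safety=zero_event_overrides()))
        vec, ledger = markov.cycle_transition(
            HealthState.INITIAL_NSAID, draw, age=45, arm="etoricoxib",
            q_background=0.0)
        assert vec[HealthState.INITIAL_NSAID] == pytest.approx(1.0,
                                                               abs=1e-8)
        assert all(v == pytest.approx(0.0, abs=1e-8)
                   for k, v in ledger.items()
                   if k != "discontinuation")

    def test_pub_only_branch_arithmetic(self, make_draw):
        # PUB 0.0270 with case fatality 0.036:
        # fatal 0.000972, survivors 0.026028 to the +PPI alternative state
        overrides = zero_event_overrides()
        overrides["pub_nsnsaid"] = 0.0270
        draw = zero_efficacy_exit(make_draw(safety=overrides))
        vec, ledger = markov.cycle_transition(
            HealthState.INITIAL_NSAID, draw, age=45, arm="diclofenac",
            q_background=0.0)
        assert vec[HealthState.DEAD] == pytest.approx(0.000972)
        assert vec[HealthState.ALT_NSNSAID_PPI] == pytest.approx(0.026028)
        assert vec[HealthState.INITIAL_NSAID] == pytest.approx(1 - 0.0270)
        assert ledger["pub"] == pytest.approx(0.0270)
        assert ledger["death_pub"] == pytest.approx(0.000972)

    def test_antitnf_withdrawal_split(self, make_draw):
        draw = make_draw()
        draw.disease["p_antitnf_withdraw"][:] = 0.10
        vec, ledger = markov.cycle_transition(
            HealthState.ANTI_TNF, draw, age=45, arm="etoricoxib",
            q_background=0.0)
        assert vec[HealthState.ANTI_TNF_DISCONTINUED] == pytest.approx(0.1)
        assert vec[HealthState.ANTI_TNF] == pytest.approx(0.9)
        assert ledger["antitnf_withdrawal"] == pytest.approx(0.1)

    def test_dead_state_rejected(self, make_draw):
        with pytest.raises(ValueError):
            markov.cycle_transition(HealthState.DEAD, make_draw(), 45,
                                    "etoricoxib", q_background=0.0)


class TestRunCohort:
    def test_one_year_life_year_for_living_cohort(self, point_draw,
                                                  life_table):
        trace = markov.run_cohort("etoricoxib", point_draw, life_table,
                                  horizon=1)
        alive = 1 - trace.occupancy[:, 0, HealthState.DEAD]
        assert alive[0] == pytest.approx(1.0)

    def test_zero_everything_keeps_cohort_in_initial_state(self,
                                                           make_draw):
        draw = zero_efficacy_exit(make_draw(safety=zero_event_overrides()))
        table = LifeTable(np.arange(40, 90), np.zeros(50))
        trace = markov.run_cohort("etoricoxib", draw, table, horizon=30)
        assert trace.occupancy[0, -1, HealthState.INITIAL_NSAID] == \
            pytest.approx(1.0, abs=1e-7)

    def test_occupancy_conserved_and_death_monotone(self, base_psa):
        occ = base_psa.traces["etoricoxib"].occupancy
        np.testing.assert_allclose(occ.sum(axis=2), 1.0, atol=1e-9)
        assert np.all(occ >= -1e-12)
        dead = occ[:, :, HealthState.DEAD]
        assert np.all(np.diff(dead, axis=1) >= -1e-12)

    def test_horizon_bounds_and_life_table_coverage(self, point_draw):
        short = LifeTable(np.array([45, 46]), np.array([0.001, 0.001]))
        with pytest.raises(ValueError):
            markov.run_cohort("etoricoxib", point_draw, short, horizon=31)
        with pytest.raises(ValueError, match="age"):
            markov.run_cohort("etoricoxib", point_draw, short, horizon=5)

    def test_arm_label_independence(self, make_draw, life_table):
        """With identical parameters the arm label cannot matter."""
        draw = make_draw()
        for grp in (draw.basfi_cfb, draw.basdai_cfb, draw.p_disc):
            for k in grp:
                grp[k] = grp["etoricoxib"].copy()
        for a, b in [("pub_celecoxib", "pub_etoricoxib"),
                     ("pub_nsnsaid", "pub_etoricoxib"),
                     ("suspected_pub_nsnsaid", "suspected_pub_coxib"),
                     ("minor_gi_nsnsaid", "minor_gi_coxib"),
                     ("cv_celecoxib", "cv_etoricoxib"),
                     ("cv_diclofenac", "cv_etoricoxib"),
                     ("cv_naproxen", "cv_etoricoxib"),
                     ("case_fatality_cv_nsnsaid", "case_fatality_cv_coxib"),
                     ("edema_nsnsaid", "edema_coxib"),
                     ("hypertension_nsnsaid", "hypertension_coxib"),
                     ("chf_nsnsaid", "chf_coxib"),
                     ("hepatic_nsnsaid", "hepatic_coxib"),
                     ("renal_nsnsaid", "renal_coxib")]:
            draw.safety[a] = draw.safety[b].copy()
        t1 = markov.run_cohort("etoricoxib", draw, life_table, horizon=30)
        t2 = markov.run_cohort("naproxen", draw, life_table, horizon=30)
        np.testing.assert_allclose(t1.occupancy, t2.occupancy, atol=1e-12)
        np.testing.assert_allclose(t1.events, t2.events, atol=1e-12)

    def test_ppi_risk_reduction_zero_equalises_pub_hazard(self, make_draw):
        draw = make_draw(safety={"ppi_pub_risk_reduction": 0.0})
        _, A, _ = markov.build_event_tree(draw, "etoricoxib")
        pub = list(e for e in EVENTS if e != "death_background").index("pub")
        assert A[0, HealthState.INITIAL_NSAID, pub] == pytest.approx(
            A[0, HealthState.INITIAL_NSAID_PPI, pub])
        assert A[0, HealthState.ALT_NSNSAID, pub] == pytest.approx(
            A[0, HealthState.ALT_NSNSAID_PPI, pub])

    @given(scale=st.floats(0.0, 3.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_probability_conservation_under_scaled_risks(self, scale):
        # built directly to avoid fixture interplay with hypothesis
        import conftest as c
        from ascea import parameters
        registry = parameters.load_registry()
        draw = parameters.sample_parameter_draw(
            registry, c._point_efficacy(), n=1, rng=0,
            point_estimate=True)
        for k in draw.safety:
            if k.startswith(("pub_", "suspected", "minor", "cv_", "edema",
                             "hypertension", "chf", "hepatic", "renal")):
                draw.safety[k] = np.clip(draw.safety[k] * scale, 0, 1)
        M, A, S = markov.build_event_tree(draw, "diclofenac")
        np.testing.assert_allclose(M.sum(axis=2), 1.0, atol=1e-9)
        assert np.all(M >= -1e-12) and np.all(S >= -1e-12)


def test_micro_simulation_oracle_agrees_on_occupancy(point_draw,
                                                     life_table):
    """10^5 sampled individual walks through the same event tree match
    the deterministic cohort propagation within Monte-Carlo error."""
    horizon, n_ind = 30, 100_000
    trace = markov.run_cohort("etoricoxib", point_draw, life_table,
                              horizon=horizon)
    expected = trace.occupancy[0, -1, :]

    M, _, S = markov.build_event_tree(point_draw, "etoricoxib")
    rng = np.random.default_rng(2024)
    counts = np.zeros(markov.N_STATES, dtype=np.int64)
    counts[HealthState.INITIAL_NSAID] = n_ind
    for t in range(horizon - 1):
        q = life_table.q(point_draw.start_age + t)
        nxt = np.zeros_like(counts)
        for s in range(markov.N_STATES):
            if counts[s] == 0:
                continue
            p = M[0, s, :].copy()
            p[s] -= S[0, s] * q
            p[HealthState.DEAD] += S[0, s] * q
            nxt += rng.multinomial(counts[s], p / p.sum())
        counts = nxt
    observed = counts / n_ind

    for s in range(markov.N_STATES):
        se = np.sqrt(max(expected[s] * (1 - expected[s]), 1e-12) / n_ind)
        assert abs(observed[s] - expected[s]) <= max(3 * se, 5e-4), \
            HealthState(s).name


class TestStateScores:
    def test_background_progression_and_cfb(self, make_draw):
        draw = make_draw(disease={"basfi_baseline": 45.0,
                                  "basfi_progression": 0.5})
        basfi, _ = markov.state_scores(draw, "etoricoxib", cycle=1)
        assert basfi[0, HealthState.INITIAL_NSAID] == pytest.approx(
            45.0 - 17.87)
        basfi10, _ = markov.state_scores(draw, "etoricoxib", cycle=10)
        assert basfi10[0, HealthState.INITIAL_NSAID] == pytest.approx(
            45.0 + 0.5 * 9 - 17.87)

    def test_antitnf_scores_fixed(self, point_draw):
        basfi, basdai = markov.state_scores(point_draw, "etoricoxib", 5)
        assert basfi[0, HealthState.ANTI_TNF] == pytest.approx(23.0)
        assert basdai[0, HealthState.ANTI_TNF] == pytest.approx(19.0)
        assert basfi[0, HealthState.ANTI_TNF_DISCONTINUED] == \
            pytest.approx(55.0)
        assert basdai[0, HealthState.ANTI_TNF_DISCONTINUED] == \
            pytest.approx(52.0)

    def test_basdai_background_is_stable(self, point_draw):
        _, b1 = markov.state_scores(point_draw, "etoricoxib", 1)
        _, b30 = markov.state_scores(point_draw, "etoricoxib", 30)
        np.testing.assert_allclose(b1, b30)

    def test_cycles_are_one_based(self, point_draw):
        with pytest.raises(ValueError):
            markov.state_scores(point_draw, "etoricoxib", 0)


def test_state_drug_costs(point_draw):
    costs = markov.state_drug_cost(point_draw, "etoricoxib")[0]
    assert costs[HealthState.INITIAL_NSAID] == pytest.approx(4654)
    assert costs[HealthState.INITIAL_NSAID_PPI] == pytest.approx(4654 + 3050)
    assert costs[HealthState.ALT_NSNSAID] == pytest.approx(1484)
    assert costs[HealthState.ALT_NSNSAID_PPI_ASA] == pytest.approx(
        1484 + 3050 + 383)
    assert costs[HealthState.ANTI_TNF] == pytest.approx(143322)
    assert costs[HealthState.ANTI_TNF_DISCONTINUED] == 0.0
    assert costs[HealthState.DEAD] == 0.0
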