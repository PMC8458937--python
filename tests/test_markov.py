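import numpy as np
import pytest

import densescreen as ds
from densescreen.markov import HealthState, ModelStructure, StateSpace

from conftest import enumerate_paths_expectation

GEOMETRIC_ANNUITY_20Y_3PCT = 15.32380  # sum of 1.03**-t, t = 0..19
BIENNIAL_XM_ANNUITY = 789.33  # 101.52 * sum of 1.03**-2k, k = 0..9


class TestTransitionMatrix:
    @pytest.mark.parametrize("age", [55, 60, 74])
    @pytest.mark.parametrize(
        "event", [None, (ds.Modality.XM, 1), (ds.Modality.MRM, 2)]
    )
    def test_rows_sum_to_one(self, params, rates, age, event):
        M = ds.build_transition_matrix(age, params, rates, screening_event=event)
        np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(M >= 0) and np.all(M <= 1)

    def test_dead_row_is_absorbing(self, params, rates):
        st = ModelStructure()
        space = StateSpace(st)
        M = ds.build_transition_matrix(60, params, rates, structure=st)
        expected = np.zeros(space.size)
        expected[space.DEAD] = 1.0
        np.testing.assert_array_equal(M[space.DEAD], expected)

    def test_incidence_entry_matches_competing_risk_formula(self, params, rates):
        """HEALTHY -> UNDETECTED equals (1 - all-cause) * incidence."""
        incidence, mortality = rates
        st = ModelStructure(p_interval_detection=0.0)
        space = StateSpace(st)
        M = ds.build_transition_matrix(55, params, rates, structure=st)
        expected = (1.0 - mortality.prob(55)) * incidence.prob(55)
        assert M[space.H, space.U0] == pytest.approx(expected, abs=1e-15)

    def test_age_outside_coverage_raises(self, params, rates):
        with pytest.raises(KeyError):
            ds.build_transition_matrix(90, params, rates)


class TestAdvanceCohort:
    def test_identity(self):
        v = np.array([0.2, 0.3, 0.5])
        np.testing.assert_array_equal(ds.advance_cohort(v, np.eye(3)), v)

    def test_all_mass_to_absorbing(self):
        v = np.array([0.25, 0.25, 0.5])
        M = np.zeros((3, 3))
        M[:, 2] = 1.0
        np.testing.assert_allclose(ds.advance_cohort(v, M), [0, 0, 1])

    def test_two_state_toy(self):
        v = np.array([0.5, 0.5])
        M = np.array([[0.9, 0.1], [0.0, 1.0]])
        np.testing.assert_allclose(ds.advance_cohort(v, M), [0.45, 0.55])

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            ds.advance_cohort(np.ones(3) / 3, np.eye(4))


class TestCohortConservation:
    @pytest.mark.parametrize("modality", [ds.Modality.XM, ds.Modality.MRM])
    def test_mass_conserved_every_cycle(self, params, rates, modality):
        traj = ds.run_strategy(modality, params, rates)
        np.testing.assert_allclose(traj.occupancy.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(traj.occupancy >= -1e-15)

    def test_cumulative_totals_non_decreasing(self, params, rates):
        traj = ds.run_strategy(ds.Modality.MRM, params, rates)
        assert np.all(np.diff(traj.cum_cost) >= 0)
        assert np.all(np.diff(traj.cum_qaly) >= 0)

    def test_survival_matches_life_table_product_without_excess(self, params, rates):
        """With every excess risk at zero, deaths are all-cause only."""
        p = params.replace(
            death_risk_undetected_cum=0.0,
            death_small_annual=0.0,
            death_large_annual=0.0,
            death_advanced_annual=0.0,
        )
        traj = ds.run_strategy(ds.Modality.MRM, p, rates)
        _, mortality = rates
        alive = 1.0 - traj.occupancy[:, HealthState.DEAD]
        expected = np.cumprod(
            [1.0] + [1.0 - mortality.prob(55 + t) for t in range(19)]
        )
        np.testing.assert_allclose(alive, expected, atol=1e-12)


class TestClosedFormAnnuities:
    def test_zero_risk_costless_screening_qaly_annuity(self, params, zero_risk_rates):
        """No disease, no deaths, perfect specificity, free tests: the QALY
        total is the plain 20-year discounted annuity."""
        p = params.replace(
            pretest_probability=0.0,
            spec_xm=1.0,
            spec_mrm_round1=1.0,
            spec_mrm_later=1.0,
            cost_xm=0.0,
            cost_mrm=0.0,
        )
        for modality in ds.Modality:
            traj = ds.run_strategy(modality, p, zero_risk_rates)
            assert traj.total_qaly == pytest.approx(
                GEOMETRIC_ANNUITY_20Y_3PCT, abs=1e-5
            )
            assert traj.total_cost == 0.0

    def test_biennial_screening_cost_annuity(self, params, zero_risk_rates):
        """Ten biennial XM examinations at $101.52 discount to $789.33."""
        p = params.replace(pretest_probability=0.0, spec_xm=1.0)
        traj = ds.run_strategy(ds.Modality.XM, p, zero_risk_rates)
        assert traj.total_cost == pytest.approx(BIENNIAL_XM_ANNUITY, abs=0.01)


class TestMonotonicity:
    def test_qaly_total_decreases_with_lower_utility(self, params, rates):
        base = ds.run_strategy(ds.Modality.XM, params, rates).total_qaly
        worse = ds.run_strategy(
            ds.Modality.XM, params.replace(qol_post_intensive=0.80), rates
        ).total_qaly
        assert worse < base

    def test_cost_total_increases_with_higher_unit_cost(self, params, rates):
        base = ds.run_strategy(ds.Modality.MRM, params, rates).total_cost
        pricier = ds.run_strategy(
            ds.Modality.MRM, params.replace(cost_tx_advanced=200_000.0), rates
        ).total_cost
        assert pricier > base

    def test_perfect_specificity_is_never_costlier(self, params, rates):
        lo_spec = ds.run_strategy(ds.Modality.MRM, params, rates).total_cost
        hi_spec = ds.run_strategy(
            ds.Modality.MRM,
            params.replace(spec_mrm_round1=1.0, spec_mrm_later=1.0),
            rates,
        ).total_cost
        assert hi_spec <= lo_spec


class TestPathEnumerationOracle:
    @pytest.mark.parametrize("modality", [ds.Modality.XM, ds.Modality.MRM])
    @pytest.mark.parametrize("p_interval", [0.0, 0.25])
    def test_three_cycle_expectations_match(self, params, rates, modality, p_interval):
        """Brute-force enumeration of every cohort path over a 3-cycle
        horizon reproduces the engine's discounted totals to 1e-9."""
        structure = ModelStructure(
            dwell_small=1,
            dwell_advanced=2,
            p_interval_detection=p_interval,
            excess_years=1,
        )
        cost, qaly = enumerate_paths_expectation(
            modality, params, rates, structure, horizon=3
        )
        traj = ds.run_strategy(modality, params, rates, structure, horizon=3)
        assert traj.total_cost == pytest.approx(cost, abs=1e-9)
        assert traj.total_qaly == pytest.approx(qaly, abs=1e-9)


class TestTrajectoryExport:
    def test_frame_shape_and_columns(self, params, rates):
        df = ds.run_strategy(ds.Modality.MRM, params, rates).to_frame()
        assert len(df) == params.horizon
        assert {"age", "healthy", "dead", "cum_disc_cost", "cum_disc_qaly"} <= set(
            df.columns
        )
        assert df["age"].iloc[0] == params.start_age
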