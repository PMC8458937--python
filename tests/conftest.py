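import numpy as np
import pytest

import densescreen as ds


@pytest.fixture(scope="session")
def params():
    return ds.base_case()


@pytest.fixture(scope="session")
def rates():
    return ds.load_default_rates()


@pytest.fixture(scope="session")
def zero_risk_rates(params):
    """No incidence, no mortality: the cohort stays healthy forever."""
    ages = np.arange(params.start_age, params.start_age + params.horizon + 1)
    zero = np.zeros_like(ages, dtype=float)
    return ds.RateTable(ages, zero, "zero_inc"), ds.RateTable(ages, zero, "zero_mort")


@pytest.fixture(scope="session")
def paper_table2():
    """Published benchmark outputs reproduced by the calibrated model."""
    return {
        "cost_xm": 5810.0,
        "qaly_xm": 15.099,
        "cost_mrm": 6081.0,
        "qaly_mrm": 15.120,
        "icer": 13_493.0,
    }


def enumerate_paths_expectation(modality, params, rates, structure, horizon):
    """Independent brute-force oracle: expected discounted cost and QALYs by
    explicit enumeration of every cohort path through the cycle operators.

    Walks the nonzero transitions of the detection/interval and annual
    operators cycle by cycle, accruing the rewards the model defines:
    screening cost for screened states, expected false-positive workup cost
    and QOL decrement conditional on being healthy at a screen, one-time
    treatment cost on occupancy of a detected state, and the state utility
    at the accrual point.  Exponential in the horizon - only for tiny
    structures and short horizons.
    """
    from densescreen.markov import (
        StateSpace,
        _annual_matrix,
        _detection_matrix,
        _interval_matrix,
        params_to_arrays,
    )
    from densescreen.screening import Modality

    modality = Modality(modality)
    space = StateSpace(structure)
    arr = params_to_arrays(params)
    incidence, mortality = rates
    sens = arr["sens_xm"] if modality is Modality.XM else arr["sens_mrm"]
    E_screen = _detection_matrix(space, arr, sens)[0]
    E_none = (
        _interval_matrix(space, 1)[0]
        if structure.p_interval_detection > 0
        else np.eye(space.size)
    )
    A_by_cycle = [
        _annual_matrix(
            space,
            arr,
            mortality.prob(params.start_age + t),
            incidence.prob(params.start_age + t),
        )[0]
        for t in range(horizon)
    ]
    c_screen = params.cost_xm if modality is Modality.XM else params.cost_mrm
    u = space.utilities(arr)[0]
    detected_cost = {
        space.DS: params.cost_tx_small,
        space.DL: params.cost_tx_large,
        space.DA: params.cost_tx_advanced,
    }
    screened_states = {space.H} | {space.U0 + j for j in range(space.n_undet)}
    interval = params.screening_interval
    fp_dur = structure.fp_decrement_years
    total = {"cost": 0.0, "qaly": 0.0}

    def walk(state, t, prob, fp_carry):
        if t == horizon or prob == 0.0:
            return
        disc = (1.0 + params.discount_rate) ** (-t)
        cost_t = 0.0
        if t % interval == 0:
            r = t // interval + 1
            if state in screened_states:
                cost_t += c_screen
            if state == space.H:
                fp_p = 1.0 - ds.specificity_for_round(modality, r, params)
                cost_t += fp_p * ds.false_positive_workup(modality, r, params)[0]
                fp_carry = fp_carry + ((fp_p, t + fp_dur),)
            E = E_screen
        else:
            E = E_none
        fp_active = sum(p for p, until in fp_carry if t < until)
        for mid in np.nonzero(E[state])[0]:
            p_mid = prob * E[state, mid]
            total["cost"] += p_mid * disc * (cost_t + detected_cost.get(mid, 0.0))
            total["qaly"] += p_mid * disc * (
                u[mid] - fp_active * params.qol_fp_decrement
            )
            A = A_by_cycle[t]
            for nxt in np.nonzero(A[mid])[0]:
                walk(nxt, t + 1, p_mid * A[mid, nxt], fp_carry)

    walk(space.H, 0, 1.0 - params.pretest_probability, ())
    walk(space.U0, 0, params.pretest_probability, ())
    return total["cost"], total["qaly"]
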