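"""Markov cohort engine: health states, transition matrices, propagation.

The cohort moves through eight health states in annual cycles: healthy,
undetected tumor, three detected stages (small < 1 cm, large > 1 cm,
advanced), two post-treatment states (after simple or intensive treatment)
and death.  Screening rounds occur every ``screening_interval`` years and
move undetected tumors into a detected stage determined by how many
attended rounds the tumor has already been missed at (dwell-time staging).
Detected states are occupied for the treatment year - the one-time
treatment cost is charged on entry - and then empty into the post-treatment
states, where disease-specific excess mortality persists for a fixed number
of years after detection before reverting to all-cause mortality alone.

Internally the engine expands the undetected and post-treatment states into
dwell/tunnel sub-states so that staging and the excess-risk clock are exact
Markov dynamics; :class:`StateSpace` maps the expanded space onto the eight
reported states.  All matrix builders are vectorised over a leading batch
axis so that probabilistic sensitivity analysis can propagate thousands of
parameter draws at once through a single code path.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass

import numpy as np

from .params import ParameterSet, validate_parameters
from .rates import RateTable
from .screening import Modality, false_positive_workup, specificity_for_round

__all__ = [
    "HealthState",
    "ModelStructure",
    "StateSpace",
    "CohortTrajectory",
    "build_transition_matrix",
    "advance_cohort",
    "run_strategy",
]

_MASS_TOL = 1e-10


class HealthState(enum.IntEnum):
    """The eight reported health states; DEAD is absorbing."""

    HEALTHY = 0
    UNDETECTED_TUMOR = 1
    DETECTED_SMALL = 2
    DETECTED_LARGE = 3
    DETECTED_ADVANCED = 4
    POST_SIMPLE_TX = 5
    POST_INTENSIVE_TX = 6
    DEAD = 7


@dataclass(frozen=True)
class ModelStructure:
    """Structural quantities of the disease process that the published
    input tables leave implicit; defaults are the calibrated values.

    ``dwell_small``/``dwell_advanced`` stage a tumor by the number of
    attended screening rounds at which it has already been missed: fewer
    than ``dwell_small`` missed rounds -> detected small, fewer than
    ``dwell_advanced`` -> large, otherwise advanced.
    ``p_interval_detection`` is the per-cycle probability that an
    undetected tumor surfaces symptomatically between screens (staged
    advanced).  ``excess_years`` is the number of years from detection
    during which stage-specific excess mortality applies.
    ``fp_decrement_years`` is how many annual cycles the false-positive
    QOL decrement persists (one cycle by default, the minimal persistent
    interpretation).
    """

    dwell_small: int = 3
    dwell_advanced: int = 4
    p_interval_detection: float = 0.25
    excess_years: int = 3
    fp_decrement_years: int = 1

    def __post_init__(self):
        if not 1 <= self.dwell_small < self.dwell_advanced:
            raise ValueError("need 1 <= dwell_small < dwell_advanced")
        if not 0.0 <= self.p_interval_detection <= 1.0:
            raise ValueError("p_interval_detection must be in [0, 1]")
        if self.excess_years < 1:
            raise ValueError("excess_years must be >= 1")
        if self.fp_decrement_years < 1:
            raise ValueError("fp_decrement_years must be >= 1")

    def replace(self, **changes) -> "ModelStructure":
        return dataclasses.replace(self, **changes)


class StateSpace:
    """Index layout of the expanded Markov state space for one structure."""

    def __init__(self, structure: ModelStructure):
        self.structure = structure
        ka = structure.dwell_advanced
        self.n_undet = ka + 1  # dwell classes: missed 0 .. >= ka rounds
        self.n_tunnel = structure.excess_years - 1
        self.H = 0
        self.U0 = 1
        self.DS = self.U0 + self.n_undet
        self.DL = self.DS + 1
        self.DA = self.DL + 1
        self.PS = self.DA + 1  # tunnel years then a rest state
        self.PIL = self.PS + self.n_tunnel + 1
        self.PIA = self.PIL + self.n_tunnel + 1
        self.DEAD = self.PIA + self.n_tunnel + 1
        self.size = self.DEAD + 1
        # map expanded index -> reported HealthState
        agg = np.empty(self.size, dtype=int)
        agg[self.H] = HealthState.HEALTHY
        agg[self.U0 : self.U0 + self.n_undet] = HealthState.UNDETECTED_TUMOR
        agg[self.DS] = HealthState.DETECTED_SMALL
        agg[self.DL] = HealthState.DETECTED_LARGE
        agg[self.DA] = HealthState.DETECTED_ADVANCED
        agg[self.PS : self.PS + self.n_tunnel + 1] = HealthState.POST_SIMPLE_TX
        agg[self.PIL : self.PIA + self.n_tunnel + 1] = HealthState.POST_INTENSIVE_TX
        agg[self.DEAD] = HealthState.DEAD
        self.aggregation = agg

    def aggregate(self, occupancy: np.ndarray) -> np.ndarray:
        """Collapse expanded occupancy (..., size) to the 8 reported states."""
        out = np.zeros(occupancy.shape[:-1] + (len(HealthState),))
        np.add.at(out.T, self.aggregation, np.moveaxis(occupancy, -1, 0))
        return out

    def utilities(self, arr: dict[str, np.ndarray]) -> np.ndarray:
        """Per-state QOL weights, batched (m, size)."""
        u = np.zeros((arr["qol_healthy"].shape[0], self.size))
        u[:, self.H] = arr["qol_healthy"]
        u[:, self.U0 : self.U0 + self.n_undet] = arr["qol_healthy"][:, None]
        u[:, self.DS] = arr["qol_small"]
        u[:, self.DL] = arr["qol_large"]
        u[:, self.DA] = arr["qol_advanced"]
        u[:, self.PS : self.PS + self.n_tunnel + 1] = arr["qol_post_simple"][:, None]
        u[:, self.PIL : self.PIA + self.n_tunnel + 1] = arr["qol_post_intensive"][
            :, None
        ]
        u[:, self.DEAD] = 0.0
        return u


@dataclass(frozen=True)
class CohortTrajectory:
    """Per-cycle cohort occupancy with discounted cost/QALY accumulators.

    Occupancy is recorded at the accrual point of each cycle (after any
    screening event) over the eight reported states.
    """

    modality: Modality
    ages: np.ndarray  # (T,)
    occupancy: np.ndarray  # (T, 8)
    cost_inc: np.ndarray  # discounted cost accrued in each cycle
    qaly_inc: np.ndarray  # discounted QALYs accrued in each cycle
    cum_cost: np.ndarray
    cum_qaly: np.ndarray

    @property
    def total_cost(self) -> float:
        return float(self.cum_cost[-1])

    @property
    def total_qaly(self) -> float:
        return float(self.cum_qaly[-1])

    @property
    def horizon(self) -> int:
        return len(self.ages)

    def to_frame(self):
        """One row per cycle: age, reported-state occupancy, discounted
        increments and cumulative totals."""
        import pandas as pd

        data = {"cycle": np.arange(self.horizon), "age": self.ages}
        for s in HealthState:
            data[s.name.lower()] = self.occupancy[:, s]
        data["disc_cost_inc"] = self.cost_inc
        data["disc_qaly_inc"] = self.qaly_inc
        data["cum_disc_cost"] = self.cum_cost
        data["cum_disc_qaly"] = self.cum_qaly
        return pd.DataFrame(data)


# ----------------------------------------------------------------------
# batched parameter arrays


def params_to_arrays(params: ParameterSet) -> dict[str, np.ndarray]:
    """All float fields of a parameter set as length-1 arrays (batch axis)."""
    out = {}
    for f in dataclasses.fields(ParameterSet):
        v = getattr(params, f.name)
        out[f.name] = np.atleast_1d(np.asarray(v, dtype=float))
    return out


def _excess(arr: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Stage-specific annual excess death probabilities, incl. annualised
    undetected-tumor risk."""
    span = arr["death_risk_undetected_span"]
    e_undet = 1.0 - (1.0 - arr["death_risk_undetected_cum"]) ** (1.0 / span)
    return {
        "undet": e_undet,
        "small": arr["death_small_annual"],
        "large": arr["death_large_annual"],
        "advanced": arr["death_advanced_annual"],
    }


def _combine(q: float, e: np.ndarray) -> np.ndarray:
    """Competing-risk combination of all-cause q and excess e."""
    return 1.0 - (1.0 - q) * (1.0 - e)


def _annual_matrix(
    space: StateSpace, arr: dict[str, np.ndarray], q: float, inc: float
) -> np.ndarray:
    """One-year transition matrix (no detection events), batched (m, S, S)."""
    m = arr["sens_xm"].shape[0]
    S = space.size
    e = _excess(arr)
    A = np.zeros((m, S, S))
    # healthy: incidence and background death
    A[:, space.H, space.DEAD] = q
    A[:, space.H, space.U0] = (1.0 - q) * inc
    A[:, space.H, space.H] = (1.0 - q) * (1.0 - inc)
    # undetected tumor: excess risk, no dwell advance between screens
    du = _combine(q, e["undet"])
    for j in range(space.n_undet):
        A[:, space.U0 + j, space.DEAD] = du
        A[:, space.U0 + j, space.U0 + j] = 1.0 - du
    # detected states empty into post-treatment states after the tx year
    ds = _combine(q, e["small"])
    A[:, space.DS, space.DEAD] = ds
    A[:, space.DS, space.PS] = 1.0 - ds
    dl = _combine(q, e["large"])
    A[:, space.DL, space.DEAD] = dl
    A[:, space.DL, space.PIL] = (1.0 - dl) * arr["p_r0_large"]
    A[:, space.DL, space.DA] = (1.0 - dl) * (1.0 - arr["p_r0_large"])
    da = _combine(q, e["advanced"])
    A[:, space.DA, space.DEAD] = da
    A[:, space.DA, space.PIA] = 1.0 - da
    # post-treatment tunnels: excess risk until the clock runs out
    for base, key in ((space.PS, "small"), (space.PIL, "large"), (space.PIA, "advanced")):
        dp = _combine(q, e[key])
        for j in range(space.n_tunnel):
            A[:, base + j, space.DEAD] = dp
            A[:, base + j, base + j + 1] = 1.0 - dp
        rest = base + space.n_tunnel
        A[:, rest, space.DEAD] = q
        A[:, rest, rest] = 1.0 - q
    A[:, space.DEAD, space.DEAD] = 1.0
    return A


def _detection_matrix(
    space: StateSpace, arr: dict[str, np.ndarray], sens: np.ndarray
) -> np.ndarray:
    """Screening-round detection operator: undetected tumors move to a
    detected stage by dwell class; missed tumors advance one dwell class."""
    m = sens.shape[0]
    S = space.size
    st = space.structure
    E = np.zeros((m, S, S))
    idx = np.arange(S)
    E[:, idx, idx] = 1.0
    p_sw = arr["p_small_if_detected_within_interval"]
    for j in range(space.n_undet):
        src = space.U0 + j
        E[:, src, src] = 0.0
        if j < st.dwell_small:
            E[:, src, space.DS] = sens * p_sw
            E[:, src, space.DL] = sens * (1.0 - p_sw)
        elif j < st.dwell_advanced:
            E[:, src, space.DL] = sens
        else:
            E[:, src, space.DA] = sens
        nxt = space.U0 + min(j + 1, space.n_undet - 1)
        E[:, src, nxt] += 1.0 - sens
    return E


def _interval_matrix(space: StateSpace, m: int) -> np.ndarray:
    """Between-screens symptomatic detection operator (stage advanced)."""
    p = space.structure.p_interval_detection
    S = space.size
    E = np.zeros((m, S, S))
    idx = np.arange(S)
    E[:, idx, idx] = 1.0
    for j in range(space.n_undet):
        src = space.U0 + j
        E[:, src, src] = 1.0 - p
        E[:, src, space.DA] = p
    return E


def build_transition_matrix(
    age: int,
    params: ParameterSet,
    rates: tuple[RateTable, RateTable],
    screening_event: tuple[Modality, int] | None = None,
    structure: ModelStructure | None = None,
) -> np.ndarray:
    """One-cycle transition matrix over the expanded state space at ``age``.

    ``rates`` is the (incidence, mortality) table pair.  If
    ``screening_event = (modality, round_index)`` is given, the cycle opens
    with a screening round and the returned matrix composes detection with
    the annual dynamics; otherwise the between-screens symptomatic-detection
    operator (if enabled in ``structure``) is composed instead.  Rows sum
    to one and the DEAD row is the unit vector on DEAD.
    """
    structure = structure or ModelStructure()
    space = StateSpace(structure)
    incidence, mortality = rates
    q = mortality.prob(age)
    inc = incidence.prob(age)
    arr = params_to_arrays(params)
    A = _annual_matrix(space, arr, q, inc)
    if screening_event is not None:
        modality, round_index = screening_event
        if round_index < 1:
            raise ValueError(f"round_index must be >= 1, got {round_index}")
        sens = (
            arr["sens_xm"] if Modality(modality) is Modality.XM else arr["sens_mrm"]
        )
        E = _detection_matrix(space, arr, sens)
    elif structure.p_interval_detection > 0:
        E = _interval_matrix(space, 1)
    else:
        return A[0]
    return (E @ A)[0]


def advance_cohort(occupancy: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Propagate a state-occupancy vector one cycle: ``occupancy @ matrix``."""
    occupancy = np.asarray(occupancy, dtype=float)
    matrix = np.asarray(matrix, dtype=float)
    if occupancy.shape[-1] != matrix.shape[0] or matrix.ndim != 2:
        raise ValueError(
            f"dimension mismatch: occupancy {occupancy.shape} vs matrix {matrix.shape}"
        )
    out = occupancy @ matrix
    if abs(out.sum() - occupancy.sum()) > _MASS_TOL * max(1.0, occupancy.sum()):
        raise ValueError("transition matrix does not conserve cohort mass")
    return out


# ----------------------------------------------------------------------
# cohort propagation


def _run_batch(
    modality: Modality,
    arr: dict[str, np.ndarray],
    rates: tuple[RateTable, RateTable],
    structure: ModelStructure,
    start_age: int,
    horizon: int,
    interval: int,
    discount_rate: np.ndarray,
    record: bool = False,
):
    """Propagate a batch of cohorts (one per parameter draw) and accrue
    discounted costs and QALYs.

    Returns ``(cost, qaly)`` arrays of shape (m,), plus per-cycle records
    when ``record`` is true.
    """
    modality = Modality(modality)
    space = StateSpace(structure)
    incidence, mortality = rates
    if not (incidence.covers(start_age, start_age + horizon)
            and mortality.covers(start_age, start_age + horizon)):
        raise KeyError(
            f"rate tables must cover ages [{start_age}, {start_age + horizon}]"
        )
    m = arr["sens_xm"].shape[0]
    S = space.size
    sens = arr["sens_xm"] if modality is Modality.XM else arr["sens_mrm"]
    c_screen = arr["cost_xm"] if modality is Modality.XM else arr["cost_mrm"]
    u = space.utilities(arr)
    E_screen = _detection_matrix(space, arr, sens)
    E_interval = (
        _interval_matrix(space, m) if structure.p_interval_detection > 0 else None
    )
    fp_dur = structure.fp_decrement_years

    v = np.zeros((m, S))
    v[:, space.H] = 1.0 - arr["pretest_probability"]
    v[:, space.U0] = arr["pretest_probability"]

    cost = np.zeros(m)
    qaly = np.zeros(m)
    fp_sched = np.zeros((m, horizon + fp_dur))
    if record:
        occ_rec = np.zeros((horizon, m, S))
        cost_rec = np.zeros((horizon, m))
        qaly_rec = np.zeros((horizon, m))

    for t in range(horizon):
        disc = (1.0 + discount_rate) ** (-t)
        cost_t = np.zeros(m)
        if t % interval == 0:
            round_index = t // interval + 1
            if modality is Modality.XM:
                spec = arr["spec_xm"]
                workup = arr["cost_biopsy"]
            else:
                spec = (
                    arr["spec_mrm_round1"]
                    if round_index == 1
                    else arr["spec_mrm_later"]
                )
                b = (
                    arr["biopsy_rate_fp_round1"]
                    if round_index == 1
                    else arr["biopsy_rate_fp_later"]
                )
                workup = b * arr["cost_biopsy"] + (1.0 - b) * arr["cost_mrm"]
            screened = v[:, space.H] + v[:, space.U0 : space.U0 + space.n_undet].sum(
                axis=1
            )
            cost_t += c_screen * screened
            fp = v[:, space.H] * (1.0 - spec)
            cost_t += workup * fp
            fp_sched[:, t : t + fp_dur] += fp[:, None]
            v = np.einsum("ms,msk->mk", v, E_screen)
        elif E_interval is not None:
            v = np.einsum("ms,msk->mk", v, E_interval)
        # one-time treatment costs: detected states hold exactly the
        # entries since the last accrual because they empty every year
        cost_t += (
            v[:, space.DS] * arr["cost_tx_small"]
            + v[:, space.DL] * arr["cost_tx_large"]
            + v[:, space.DA] * arr["cost_tx_advanced"]
        )
        qaly_t = (v * u).sum(axis=1) - fp_sched[:, t] * arr["qol_fp_decrement"]
        cost += disc * cost_t
        qaly += disc * qaly_t
        if record:
            occ_rec[t] = v
            cost_rec[t] = disc * cost_t
            qaly_rec[t] = disc * qaly_t
        age = start_age + t
        A = _annual_matrix(space, arr, mortality.prob(age), incidence.prob(age))
        v = np.einsum("ms,msk->mk", v, A)
        if np.any(np.abs(v.sum(axis=1) - 1.0) > _MASS_TOL):
            raise ArithmeticError(f"cohort mass not conserved at cycle {t}")

    if record:
        return cost, qaly, occ_rec, cost_rec, qaly_rec, space
    return cost, qaly


def run_strategy(
    modality: Modality,
    params: ParameterSet,
    rates: tuple[RateTable, RateTable],
    structure: ModelStructure | None = None,
    horizon: int | None = None,
) -> CohortTrajectory:
    """Run one screening strategy over the model horizon.

    Screening rounds occur at cycles 0, interval, 2*interval, ...; costs
    and QALYs are discounted at the annual rate with cycle 0 undiscounted.
    """
    params = validate_parameters(params)
    structure = structure or ModelStructure()
    horizon = params.horizon if horizon is None else horizon
    if horizon < 1:
        raise ValueError(f"horizon must be a positive number of cycles, got {horizon}")
    arr = params_to_arrays(params)
    cost, qaly, occ, cost_rec, qaly_rec, space = _run_batch(
        modality,
        arr,
        rates,
        structure,
        params.start_age,
        horizon,
        params.screening_interval,
        np.atleast_1d(params.discount_rate),
        record=True,
    )
    occ8 = space.aggregate(occ[:, 0, :])
    ci = cost_rec[:, 0]
    qi = qaly_rec[:, 0]
    return CohortTrajectory(
        modality=Modality(modality),
        ages=params.start_age + np.arange(horizon),
        occupancy=occ8,
        cost_inc=ci,
        qaly_inc=qi,
        cum_cost=np.cumsum(ci),
        cum_qaly=np.cumsum(qi),
    )
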