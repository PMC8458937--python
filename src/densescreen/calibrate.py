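"""Deterministic calibration of the implicit model structure.

The published input tables fix every rate, cost and utility, but three
structural quantities of the disease process are not printed anywhere: how
dwell time maps to stage at detection, whether tumors surface
symptomatically between screens, and for how long stage-specific excess
mortality persists after detection.  This module pins them down by
exhaustive grid search against a small set of benchmark model outputs
(base-case cumulative costs and effects of both strategies plus the
incremental ratio at the two ends of the later-round specificity sweep),
minimising a weighted sum of squared relative errors.  The search is a
plain deterministic enumeration - the space is tiny - with ties broken
toward the lexicographically smallest candidate, and the per-target
residuals are always reported rather than silently accepted.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markov import ModelStructure, run_strategy
from .params import ParameterSet, validate_parameters
from .rates import RateTable
from .screening import Modality

__all__ = [
    "CalibrationTarget",
    "FreeParameterSpace",
    "CalibrationResult",
    "default_targets",
    "default_space",
    "loss",
    "fit_free_parameters",
]

_RatePair = tuple[RateTable, RateTable]


@dataclass(frozen=True)
class CalibrationTarget:
    """One benchmark output the calibrated model should reproduce.

    ``quantity`` is ``cost`` or ``qaly`` (cumulative discounted, for
    ``modality``) or ``icer`` (MRM vs XM).  ``spec_later`` optionally
    overrides the later-round MRM specificity for this target.
    """

    name: str
    quantity: str  # "cost" | "qaly" | "icer"
    value: float
    modality: Modality | None = None
    spec_later: float | None = None
    weight: float = 1.0

    def __post_init__(self):
        if self.quantity not in ("cost", "qaly", "icer"):
            raise ValueError(f"unknown target quantity {self.quantity!r}")
        if self.quantity in ("cost", "qaly") and self.modality is None:
            raise ValueError(f"target {self.name}: cost/qaly targets need a modality")
        if self.weight <= 0:
            raise ValueError(f"target {self.name}: weight must be > 0")
        if self.value == 0:
            raise ValueError(f"target {self.name}: zero target has no relative error")


def default_targets() -> list[CalibrationTarget]:
    """Benchmark outputs of the published base-case evaluation: cumulative
    discounted costs and effects of both strategies, plus the incremental
    ratio at later-round MRM specificities of 92% and 99%."""
    return [
        CalibrationTarget("cost_xm_base", "cost", 5_810.0, Modality.XM),
        CalibrationTarget("qaly_xm_base", "qaly", 15.099, Modality.XM),
        CalibrationTarget("cost_mrm_base", "cost", 6_081.0, Modality.MRM),
        CalibrationTarget("qaly_mrm_base", "qaly", 15.120, Modality.MRM),
        CalibrationTarget("icer_spec92", "icer", 38_849.0, spec_later=0.92),
        CalibrationTarget("icer_spec99", "icer", 5_062.0, spec_later=0.99),
    ]


@dataclass(frozen=True)
class FreeParameterSpace:
    """Grid of structural candidates.

    ``staging`` enumerates (dwell_small, dwell_advanced) threshold pairs,
    ``p_interval`` the per-cycle symptomatic-detection probabilities, and
    ``excess_years`` the post-detection excess-mortality durations.
    """

    staging: tuple[tuple[int, int], ...] = (
        (1, 2), (1, 3), (2, 3), (2, 4), (3, 4), (3, 5),
    )
    p_interval: tuple[float, ...] = (0.0, 0.05, 0.1, 0.15, 0.2, 0.25, 0.3)
    excess_years: tuple[int, ...] = (2, 3, 5, 10, 15, 20)

    def candidates(self) -> list[ModelStructure]:
        """All structures, in deterministic lexicographic order."""
        combos = itertools.product(
            sorted(set(self.staging)),
            sorted(set(self.p_interval)),
            sorted(set(self.excess_years)),
        )
        return [
            ModelStructure(
                dwell_small=ks,
                dwell_advanced=ka,
                p_interval_detection=p,
                excess_years=d,
            )
            for (ks, ka), p, d in combos
        ]


def default_space() -> FreeParameterSpace:
    return FreeParameterSpace()


def _model_outputs(
    structure: ModelStructure,
    targets: list[CalibrationTarget],
    params: ParameterSet,
    rates: _RatePair,
) -> dict[str, float]:
    """Evaluate every target's model output for one candidate structure."""
    run_cache: dict[tuple[Modality, float], tuple[float, float]] = {}

    def outcome(modality: Modality, spec_later: float) -> tuple[float, float]:
        key = (modality, spec_later)
        if key not in run_cache:
            p = params.replace(spec_mrm_later=spec_later)
            t = run_strategy(modality, p, rates, structure)
            run_cache[key] = (t.total_cost, t.total_qaly)
        return run_cache[key]

    out = {}
    for tg in targets:
        spec_later = (
            params.spec_mrm_later if tg.spec_later is None else tg.spec_later
        )
        if tg.quantity == "icer":
            c_ref, e_ref = outcome(Modality.XM, spec_later)
            c_alt, e_alt = outcome(Modality.MRM, spec_later)
            out[tg.name] = (c_alt - c_ref) / (e_alt - e_ref)
        else:
            c, e = outcome(tg.modality, spec_later)
            out[tg.name] = c if tg.quantity == "cost" else e
    return out


def loss(
    structure: ModelStructure,
    targets: list[CalibrationTarget],
    params: ParameterSet,
    rates: _RatePair,
) -> float:
    """Weighted sum of squared relative errors of the candidate's model
    outputs against the targets."""
    if not targets:
        raise ValueError("target set must be non-empty")
    outputs = _model_outputs(structure, targets, params, rates)
    return float(
        sum(
            tg.weight * ((outputs[tg.name] - tg.value) / tg.value) ** 2
            for tg in targets
        )
    )


@dataclass(frozen=True)
class CalibrationResult:
    """Grid-search argmin with its residual report."""

    structure: ModelStructure
    loss: float
    residuals: pd.DataFrame  # per target: target value, model output, rel. error
    n_candidates: int

    def to_dict(self) -> dict:
        return {
            "structure": {
                "dwell_small": self.structure.dwell_small,
                "dwell_advanced": self.structure.dwell_advanced,
                "p_interval_detection": self.structure.p_interval_detection,
                "excess_years": self.structure.excess_years,
            },
            "loss": self.loss,
            "n_candidates": self.n_candidates,
            "residuals": self.residuals.to_dict(orient="records"),
        }


def fit_free_parameters(
    targets: list[CalibrationTarget],
    space: FreeParameterSpace,
    params: ParameterSet,
    rates: _RatePair,
    grid_resolution: int | None = None,
) -> CalibrationResult:
    """Exhaustive deterministic grid search over the structural space.

    ``grid_resolution``, if given, re-grids the continuous
    symptomatic-detection axis to that many evenly spaced points between
    its extremes (must be >= 2).  Ties in the loss break toward the
    lexicographically smallest candidate.
    """
    if not targets:
        raise ValueError("target set must be non-empty")
    validate_parameters(params)
    if grid_resolution is not None:
        if grid_resolution < 2:
            raise ValueError("grid_resolution must be >= 2")
        lo, hi = min(space.p_interval), max(space.p_interval)
        space = FreeParameterSpace(
            staging=space.staging,
            p_interval=tuple(np.linspace(lo, hi, grid_resolution)),
            excess_years=space.excess_years,
        )
    candidates = space.candidates()
    if not candidates:
        raise ValueError("free-parameter space is empty")

    best: ModelStructure | None = None
    best_loss = np.inf
    for cand in candidates:  # lexicographic order: first strict win keeps ties
        val = loss(cand, targets, params, rates)
        if val < best_loss:
            best, best_loss = cand, val

    outputs = _model_outputs(best, targets, params, rates)
    residuals = pd.DataFrame(
        [
            {
                "target": tg.name,
                "target_value": tg.value,
                "model_value": outputs[tg.name],
                "rel_error": (outputs[tg.name] - tg.value) / tg.value,
                "weight": tg.weight,
            }
            for tg in targets
        ]
    )
    return CalibrationResult(
        structure=best,
        loss=best_loss,
        residuals=residuals,
        n_candidates=len(candidates),
    )
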