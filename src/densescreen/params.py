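"""Model parameters, unit conversions and validation.

The parameter set collects every scalar input of the screening model: the
diagnostic performance of the two modalities (x-ray mammography, XM, and
MR-mammography, MRM), unit costs from the US payer perspective, health-state
utilities, and the transition probabilities of the disease process.  The
base case corresponds to biennial screening of women with extremely dense
breast tissue, starting at age 55, over a 20-year horizon, with costs and
effects discounted at 3% per year against a willingness-to-pay threshold of
$100,000 per QALY.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = [
    "ParameterSet",
    "ValidationError",
    "annual_probability_from_cumulative",
    "discount_factor",
    "validate_parameters",
    "base_case",
    "read_config",
    "write_config",
]


class ValidationError(ValueError):
    """Raised when a parameter set violates its domain invariants.

    Carries the full list of violations in :attr:`errors` so a caller sees
    every offending field at once rather than the first one found.
    """

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("invalid parameters: " + "; ".join(self.errors))


@dataclass(frozen=True)
class ParameterSet:
    """All scalar inputs of the cost-effectiveness model.

    Probabilities and utilities are fractions in [0, 1]; costs are US-$;
    ages and durations are years.
    """

    # cohort and program design
    pretest_probability: float  # probability of malignant lesion per screening round
    start_age: int
    screening_interval: int  # years between screening rounds
    horizon: int  # total model runtime, years
    discount_rate: float  # annual, applied to costs and effects alike
    wtp: float  # willingness-to-pay threshold, $ per QALY

    # diagnostic test performance
    sens_xm: float
    spec_xm: float
    sens_mrm: float
    spec_mrm_round1: float
    spec_mrm_later: float  # second and subsequent screening rounds
    biopsy_rate_fp_round1: float  # share of MRM false positives biopsied
    biopsy_rate_fp_later: float

    # unit costs, US-$
    cost_xm: float
    cost_mrm: float
    cost_biopsy: float
    cost_tx_small: float  # treatment, tumor < 1 cm
    cost_tx_large: float  # treatment, tumor > 1 cm
    cost_tx_advanced: float

    # utilities (QOL weights)
    qol_healthy: float
    qol_small: float
    qol_large: float
    qol_advanced: float
    qol_post_simple: float
    qol_post_intensive: float
    qol_fp_decrement: float  # QOL reduction after a false positive finding

    # transition probabilities
    death_risk_undetected_cum: float  # cumulative over death_risk_undetected_span
    death_risk_undetected_span: int  # years
    death_small_annual: float
    death_large_annual: float
    death_advanced_annual: float
    p_r0_small: float  # probability of initial R0 resection, tumor < 1 cm
    p_r0_large: float
    p_nplus_small: float  # nodal involvement by size class
    p_nplus_large: float
    p_small_if_detected_within_interval: float

    def replace(self, **changes) -> "ParameterSet":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    @property
    def death_undetected_annual(self) -> float:
        """Annualised excess death probability with an undetected tumor."""
        return annual_probability_from_cumulative(
            self.death_risk_undetected_cum, self.death_risk_undetected_span
        )


_PROBABILITY_FIELDS = (
    "pretest_probability",
    "sens_xm", "spec_xm", "sens_mrm", "spec_mrm_round1", "spec_mrm_later",
    "biopsy_rate_fp_round1", "biopsy_rate_fp_later",
    "qol_healthy", "qol_small", "qol_large", "qol_advanced",
    "qol_post_simple", "qol_post_intensive", "qol_fp_decrement",
    "death_risk_undetected_cum", "death_small_annual", "death_large_annual",
    "death_advanced_annual",
    "p_r0_small", "p_r0_large", "p_nplus_small", "p_nplus_large",
    "p_small_if_detected_within_interval",
)

_COST_FIELDS = (
    "cost_xm", "cost_mrm", "cost_biopsy",
    "cost_tx_small", "cost_tx_large", "cost_tx_advanced",
)


def annual_probability_from_cumulative(p_cum: float, span: float) -> float:
    """Convert a cumulative event probability over ``span`` years to the
    constant annual probability that compounds to it.

    Solves ``(1 - p_a) ** span = 1 - p_cum`` for ``p_a``, the standard
    actuarial rate conversion; it is exactly invertible.
    """
    if not 0.0 <= p_cum < 1.0:
        raise ValueError(f"cumulative probability must be in [0, 1), got {p_cum}")
    if span <= 0:
        raise ValueError(f"span must be positive, got {span}")
    return 1.0 - (1.0 - p_cum) ** (1.0 / span)


def discount_factor(cycle_index: int, rate: float) -> float:
    """Present-value factor ``(1 + rate) ** -cycle_index`` for an annual
    cycle; cycle 0 is undiscounted."""
    if cycle_index < 0:
        raise ValueError(f"cycle_index must be >= 0, got {cycle_index}")
    if rate < 0:
        raise ValueError(f"discount rate must be >= 0, got {rate}")
    return (1.0 + rate) ** (-cycle_index)


def validate_parameters(params: ParameterSet) -> ParameterSet:
    """Check every domain invariant; return the set unchanged if all hold.

    Raises :class:`ValidationError` listing *all* violated fields.
    """
    errors: list[str] = []
    for name in _PROBABILITY_FIELDS:
        v = getattr(params, name)
        if not (isinstance(v, (int, float)) and math.isfinite(v) and 0.0 <= v <= 1.0):
            errors.append(f"{name}={v!r} outside [0, 1]")
    for name in _COST_FIELDS:
        v = getattr(params, name)
        if not (isinstance(v, (int, float)) and math.isfinite(v) and v >= 0.0):
            errors.append(f"{name}={v!r} must be >= 0")
    if params.discount_rate < 0:
        errors.append(f"discount_rate={params.discount_rate!r} must be >= 0")
    if params.wtp < 0:
        errors.append(f"wtp={params.wtp!r} must be >= 0")
    for name in ("horizon", "screening_interval", "death_risk_undetected_span"):
        v = getattr(params, name)
        if not (isinstance(v, int) and v > 0):
            errors.append(f"{name}={v!r} must be a positive integer")
    if (
        isinstance(params.horizon, int)
        and isinstance(params.screening_interval, int)
        and 0 < params.horizon < params.screening_interval
    ):
        errors.append(
            f"screening_interval={params.screening_interval} exceeds "
            f"horizon={params.horizon}"
        )
    if params.start_age < 0:
        errors.append(f"start_age={params.start_age!r} must be >= 0")
    if errors:
        raise ValidationError(errors)
    return params


def base_case() -> ParameterSet:
    """The base-case parameter set for biennial screening of the
    dense-breast collective (US payer perspective, 2020 tariffs)."""
    return ParameterSet(
        pretest_probability=0.0165,
        start_age=55,
        screening_interval=2,
        horizon=20,
        discount_rate=0.03,
        wtp=100_000.0,
        sens_xm=0.412,
        spec_xm=0.90,
        sens_mrm=0.952,
        spec_mrm_round1=0.92,
        spec_mrm_later=0.97,
        biopsy_rate_fp_round1=0.672,
        biopsy_rate_fp_later=0.802,
        cost_xm=101.52,
        cost_mrm=314.00,
        cost_biopsy=1536.00,
        cost_tx_small=60_637.0,
        cost_tx_large=82_121.0,
        cost_tx_advanced=129_387.0,
        qol_healthy=1.00,
        qol_small=0.87,
        qol_large=0.74,
        qol_advanced=0.62,
        qol_post_simple=0.99,
        qol_post_intensive=0.95,
        qol_fp_decrement=0.01,
        death_risk_undetected_cum=0.10,
        death_risk_undetected_span=10,
        death_small_annual=0.0011,
        death_large_annual=0.0078,
        death_advanced_annual=0.0181,
        p_r0_small=1.00,
        p_r0_large=0.90,
        p_nplus_small=0.00,
        p_nplus_large=0.40,
        p_small_if_detected_within_interval=1.00,
    )


def write_config(params: ParameterSet, path: str | Path) -> None:
    """Write a flat key-value YAML configuration, one key per field."""
    data = dataclasses.asdict(params)
    Path(path).write_text(
        yaml.safe_dump(data, sort_keys=False, default_flow_style=False)
    )


def read_config(path: str | Path) -> ParameterSet:
    """Read a flat key-value configuration written by :func:`write_config`."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValidationError([f"config {path} is not a flat key-value mapping"])
    known = {f.name for f in dataclasses.fields(ParameterSet)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError([f"unknown config key {k!r}" for k in sorted(unknown)])
    missing = known - set(data)
    if missing:
        raise ValidationError([f"missing config key {k!r}" for k in sorted(missing)])
    return validate_parameters(ParameterSet(**data))
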