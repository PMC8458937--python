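"""Deterministic and probabilistic sensitivity analyses.

Deterministic: one-way (tornado) sweeps of single inputs, the two-way
surface over MRM examination cost and later-round MRM specificity, and the
break-even MRM cost at which the two strategies' cumulative discounted
costs are equal.  Probabilistic: Monte Carlo resampling of the input
parameters (beta for probabilities and utilities, gamma for costs) with a
cost-effectiveness acceptability curve over a willingness-to-pay grid.

Throughout, the reference strategy is x-ray mammography and the
alternative is MR-mammography.  Tornado and surface cells store the
*signed* incremental ratio (incremental cost over incremental effect);
when the incremental effect is positive, a negative value therefore means
the alternative dominates (cheaper and more effective).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .markov import ModelStructure, _run_batch, run_strategy
from .params import ParameterSet, validate_parameters
from .rates import RateTable
from .screening import Modality

__all__ = [
    "TornadoEntry",
    "one_way_tornado",
    "default_tornado_ranges",
    "two_way_cost_specificity",
    "break_even_mrm_cost",
    "BracketError",
    "Distribution",
    "default_distributions",
    "PSAResult",
    "probabilistic_sa",
    "CEACCurve",
    "ceac",
]

_RatePair = tuple[RateTable, RateTable]


def _signed_ratio(params: ParameterSet, rates: _RatePair,
                  structure: ModelStructure | None) -> float:
    """Incremental cost over incremental effect, MRM vs XM (signed;
    NaN when the incremental effect is exactly zero)."""
    ref = run_strategy(Modality.XM, params, rates, structure)
    alt = run_strategy(Modality.MRM, params, rates, structure)
    de = alt.total_qaly - ref.total_qaly
    if de == 0.0:
        return float("nan")
    return (alt.total_cost - ref.total_cost) / de


# ----------------------------------------------------------------------
# one-way (tornado)

_DIAGNOSTIC_COSTS = ("cost_xm", "cost_mrm", "cost_biopsy")
_PERFORMANCE = (
    "sens_xm", "spec_xm", "sens_mrm", "spec_mrm_round1", "spec_mrm_later",
    "biopsy_rate_fp_round1", "biopsy_rate_fp_later",
)


@dataclass(frozen=True)
class TornadoEntry:
    """One bar of the tornado: the ICER at the low and high input value."""

    parameter: str
    low: float
    high: float
    icer_low: float
    icer_high: float

    @property
    def span(self) -> float:
        return abs(self.icer_high - self.icer_low)


def default_tornado_ranges(params: ParameterSet) -> dict[str, tuple[float, float]]:
    """Default one-way ranges: diagnostic costs +/- 25%; MRM specificities
    over the observed first-to-second-round window [0.92, 0.97]; other
    performance probabilities +/- 10% relative, truncated to [0, 1].  For
    specificities the relative variation is applied to the false-positive
    rate (1 - specificity), the operative estimated quantity."""
    ranges: dict[str, tuple[float, float]] = {}
    for name in _DIAGNOSTIC_COSTS:
        v = getattr(params, name)
        ranges[name] = (0.75 * v, 1.25 * v)
    for name in _PERFORMANCE:
        v = getattr(params, name)
        if name in ("spec_mrm_round1", "spec_mrm_later"):
            ranges[name] = (0.92, 0.97)
        elif name.startswith("spec"):
            fp = 1.0 - v
            ranges[name] = (max(0.0, 1.0 - 1.1 * fp), min(1.0, 1.0 - 0.9 * fp))
        else:
            ranges[name] = (max(0.0, 0.9 * v), min(1.0, 1.1 * v))
    return ranges


def one_way_tornado(
    base_params: ParameterSet,
    ranges: dict[str, tuple[float, float]],
    rates: _RatePair,
    structure: ModelStructure | None = None,
) -> list[TornadoEntry]:
    """One-way deterministic sensitivity analysis.

    Each parameter is set to its low and high value with everything else
    at base; both strategies are re-run and the incremental ratio
    recorded.  Entries come back sorted by descending span.
    """
    validate_parameters(base_params)
    entries = []
    for name in sorted(ranges):
        lo, hi = ranges[name]
        base = getattr(base_params, name)
        if not lo <= base <= hi:
            raise ValueError(
                f"range for {name} must bracket the base value {base}: ({lo}, {hi})"
            )
        icers = []
        for v in (lo, hi):
            p = validate_parameters(base_params.replace(**{name: v}))
            icers.append(_signed_ratio(p, rates, structure))
        entries.append(
            TornadoEntry(
                parameter=name, low=lo, high=hi, icer_low=icers[0], icer_high=icers[1]
            )
        )
    return sorted(entries, key=lambda e: -e.span)


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "low": e.low,
                "high": e.high,
                "icer_low": e.icer_low,
                "icer_high": e.icer_high,
                "span": e.span,
            }
            for e in entries
        ]
    )


# ----------------------------------------------------------------------
# two-way surface and break-even

def two_way_cost_specificity(
    base_params: ParameterSet,
    cost_grid: np.ndarray,
    spec_grid: np.ndarray,
    rates: _RatePair,
    structure: ModelStructure | None = None,
) -> pd.DataFrame:
    """Signed incremental ratio over a (MRM cost) x (later-round MRM
    specificity) grid; rows indexed by cost, columns by specificity."""
    cost_grid = np.asarray(cost_grid, dtype=float)
    spec_grid = np.asarray(spec_grid, dtype=float)
    if np.any(cost_grid < 0):
        raise ValueError("MRM costs must be >= 0")
    if np.any((spec_grid < 0) | (spec_grid > 1)):
        raise ValueError("specificities must lie in [0, 1]")
    out = np.empty((cost_grid.size, spec_grid.size))
    for i, c in enumerate(cost_grid):
        for j, s in enumerate(spec_grid):
            p = base_params.replace(cost_mrm=float(c), spec_mrm_later=float(s))
            out[i, j] = _signed_ratio(p, rates, structure)
    return pd.DataFrame(out, index=cost_grid, columns=spec_grid)


class BracketError(RuntimeError):
    """Break-even search bracket does not straddle zero incremental cost."""


def break_even_mrm_cost(
    base_params: ParameterSet,
    spec_later: float,
    rates: _RatePair,
    structure: ModelStructure | None = None,
    bracket: tuple[float, float] | None = None,
    tol: float = 0.01,
) -> float:
    """MRM examination cost at which the cumulative discounted costs of
    the MRM and XM strategies are equal, by bisection to ``tol`` dollars.

    Incremental cost is monotone increasing in the examination cost, so a
    sign change over the bracket pins the root; a bracket without a sign
    change raises :class:`BracketError` with the diagnostic bounds.
    """
    if not 0.0 <= spec_later <= 1.0:
        raise ValueError(f"spec_later must be in [0, 1], got {spec_later}")
    lo, hi = bracket if bracket is not None else (0.0, 4.0 * base_params.cost_mrm)
    ref_cost = run_strategy(
        Modality.XM, base_params.replace(spec_mrm_later=spec_later), rates, structure
    ).total_cost

    def incr_cost(c: float) -> float:
        p = base_params.replace(cost_mrm=float(c), spec_mrm_later=spec_later)
        return run_strategy(Modality.MRM, p, rates, structure).total_cost - ref_cost

    f_lo, f_hi = incr_cost(lo), incr_cost(hi)
    if f_lo * f_hi > 0:
        raise BracketError(
            f"no sign change over bracket [{lo}, {hi}]: "
            f"incremental cost {f_lo:.2f} .. {f_hi:.2f}"
        )
    return float(optimize.brentq(incr_cost, lo, hi, xtol=tol))


# ----------------------------------------------------------------------
# probabilistic sensitivity analysis

_PROB_LIKE = (
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
_COST_LIKE = (
    "cost_xm", "cost_mrm", "cost_biopsy",
    "cost_tx_small", "cost_tx_large", "cost_tx_advanced",
)


@dataclass(frozen=True)
class Distribution:
    """Sampling distribution for one parameter, moment-matched to the base
    value: ``beta`` (probabilities/utilities) or ``gamma`` (costs), with
    standard deviation ``cv`` times the base value."""

    family: str  # "beta" | "gamma" | "fixed"
    cv: float = 0.1

    def __post_init__(self):
        if self.family not in ("beta", "gamma", "fixed"):
            raise ValueError(f"unknown distribution family {self.family!r}")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")

    def sample(self, mean: float, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "fixed" or self.cv == 0.0:
            return np.full(n, mean)
        if self.family == "beta":
            if mean <= 0.0 or mean >= 1.0:
                return np.full(n, mean)  # degenerate at the boundary
            sd = self.cv * mean
            # keep the variance inside the feasible beta range
            sd = min(sd, 0.95 * np.sqrt(mean * (1.0 - mean)))
            nu = mean * (1.0 - mean) / sd**2 - 1.0
            a, b = mean * nu, (1.0 - mean) * nu
            return stats.beta.rvs(a, b, size=n, random_state=rng)
        # gamma
        if mean == 0.0:
            return np.zeros(n)
        shape = 1.0 / self.cv**2
        scale = mean * self.cv**2
        return stats.gamma.rvs(shape, scale=scale, size=n, random_state=rng)


def default_distributions(cv_prob: float = 0.1, cv_cost: float = 0.2
                          ) -> dict[str, Distribution]:
    """Beta on every probability/utility, gamma on every cost."""
    spec = {name: Distribution("beta", cv_prob) for name in _PROB_LIKE}
    spec.update({name: Distribution("gamma", cv_cost) for name in _COST_LIKE})
    return spec


@dataclass(frozen=True)
class PSAResult:
    """Monte Carlo samples of the incremental outcomes.

    ``draws`` holds the sampled parameter values (one row per iteration);
    ``nmb_diff`` is the incremental net monetary benefit at ``wtp``.
    """

    draws: pd.DataFrame
    cost_ref: np.ndarray
    effect_ref: np.ndarray
    cost_alt: np.ndarray
    effect_alt: np.ndarray
    wtp: float
    seed: int

    @property
    def n_iter(self) -> int:
        return len(self.draws)

    @property
    def incr_cost(self) -> np.ndarray:
        return self.cost_alt - self.cost_ref

    @property
    def incr_effect(self) -> np.ndarray:
        return self.effect_alt - self.effect_ref

    @property
    def nmb_diff(self) -> np.ndarray:
        return self.wtp * self.incr_effect - self.incr_cost

    def fraction_cost_effective(self, wtp: float | None = None) -> float:
        """Fraction of iterations with positive incremental NMB."""
        w = self.wtp if wtp is None else wtp
        return float(np.mean(w * self.incr_effect - self.incr_cost > 0))

    def fraction_alt_cheaper(self) -> float:
        """Fraction of iterations in which MRM is the cheaper strategy."""
        return float(np.mean(self.incr_cost < 0))

    def to_frame(self) -> pd.DataFrame:
        out = self.draws.copy()
        out["cost_xm"] = self.cost_ref
        out["effect_xm"] = self.effect_ref
        out["cost_mrm"] = self.cost_alt
        out["effect_mrm"] = self.effect_alt
        out["incr_cost"] = self.incr_cost
        out["incr_effect"] = self.incr_effect
        out["nmb_diff"] = self.nmb_diff
        return out


def probabilistic_sa(
    base_params: ParameterSet,
    distribution_spec: dict[str, Distribution] | None,
    n_iter: int,
    seed: int,
    rates: _RatePair,
    structure: ModelStructure | None = None,
    chunk: int = 4000,
) -> PSAResult:
    """Monte Carlo probabilistic sensitivity analysis.

    Each iteration draws a full parameter set from ``distribution_spec``
    (defaults: :func:`default_distributions`), runs both strategies
    through the cohort engine, and records the paired outcomes.
    Reproducible given ``seed``; the batch engine propagates all draws
    through a single vectorised code path in chunks.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    validate_parameters(base_params)
    structure = structure or ModelStructure()
    spec = default_distributions() if distribution_spec is None else distribution_spec
    unknown = set(spec) - set(_PROB_LIKE) - set(_COST_LIKE)
    if unknown:
        raise ValueError(f"distributions given for unknown/fixed fields: {unknown}")

    rng = np.random.default_rng(seed)
    arr: dict[str, np.ndarray] = {}
    for f in dataclasses.fields(ParameterSet):
        base = float(getattr(base_params, f.name))
        if f.name in spec:
            arr[f.name] = spec[f.name].sample(base, n_iter, rng)
        else:
            arr[f.name] = np.full(n_iter, base)

    cost = {m: np.empty(n_iter) for m in Modality}
    qaly = {m: np.empty(n_iter) for m in Modality}
    dr = np.atleast_1d(float(base_params.discount_rate))
    for start in range(0, n_iter, chunk):
        sl = slice(start, min(start + chunk, n_iter))
        sub = {k: v[sl] for k, v in arr.items()}
        for mod in Modality:
            c, q = _run_batch(
                mod,
                sub,
                rates,
                structure,
                base_params.start_age,
                base_params.horizon,
                base_params.screening_interval,
                dr,
            )
            cost[mod][sl] = c
            qaly[mod][sl] = q

    draws = pd.DataFrame({k: arr[k] for k in sorted(spec)})
    return PSAResult(
        draws=draws,
        cost_ref=cost[Modality.XM],
        effect_ref=qaly[Modality.XM],
        cost_alt=cost[Modality.MRM],
        effect_alt=qaly[Modality.MRM],
        wtp=float(base_params.wtp),
        seed=seed,
    )


# ----------------------------------------------------------------------
# cost-effectiveness acceptability curve

@dataclass(frozen=True)
class CEACCurve:
    """Fraction of PSA iterations cost-effective at each WTP level."""

    wtp_grid: np.ndarray
    fractions: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"wtp": self.wtp_grid, "fraction_cost_effective": self.fractions}
        )


def ceac(samples: PSAResult, wtp_grid: np.ndarray | None = None) -> CEACCurve:
    """Cost-effectiveness acceptability curve: at each willingness to pay,
    the fraction of iterations with positive incremental net benefit."""
    if samples.n_iter == 0:
        raise ValueError("empty PSA sample")
    if wtp_grid is None:
        wtp_grid = np.arange(0.0, 200_001.0, 5_000.0)
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size == 0 or np.any(np.diff(wtp_grid) <= 0):
        raise ValueError("wtp_grid must be non-empty and strictly increasing")
    nmb = wtp_grid[:, None] * samples.incr_effect[None, :] - samples.incr_cost[None, :]
    return CEACCurve(wtp_grid=wtp_grid, fractions=(nmb > 0).mean(axis=1))
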