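"""Incremental cost-effectiveness statistics for paired strategies.

The comparison follows the four-quadrant cost-effectiveness-plane
convention: the ICER is reported only when the alternative is costlier and
more effective (or cheaper and less effective); when one strategy wins on
both axes a dominance flag replaces the ratio, and equal effects leave the
ratio undefined.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .markov import CohortTrajectory

__all__ = ["Dominance", "CEAResult", "icer", "net_monetary_benefit", "compare_strategies"]


class Dominance(str, enum.Enum):
    NONE = "none"  # ICER well-defined
    ALT_DOMINANT = "alt_dominant"  # alternative cheaper and more effective
    REF_DOMINANT = "ref_dominant"  # reference cheaper and more effective
    UNDEFINED = "undefined"  # equal effects


def icer(
    cost_ref: float, effect_ref: float, cost_alt: float, effect_alt: float
) -> float | Dominance:
    """Incremental cost-effectiveness ratio of alt vs ref, or a dominance
    flag where the ratio is meaningless."""
    dc = cost_alt - cost_ref
    de = effect_alt - effect_ref
    if de == 0.0:
        return Dominance.UNDEFINED
    if de > 0 and dc <= 0:
        return Dominance.ALT_DOMINANT
    if de < 0 and dc >= 0:
        return Dominance.REF_DOMINANT
    return dc / de


def net_monetary_benefit(cost: float, effect: float, wtp: float) -> float:
    """``wtp * effect - cost``; positive incremental NMB means
    cost-effective at that willingness to pay."""
    if wtp < 0:
        raise ValueError(f"wtp must be >= 0, got {wtp}")
    return wtp * effect - cost


@dataclass(frozen=True)
class CEAResult:
    """Paired strategy outcomes with incrementals, ICER, dominance and NMB."""

    cost_ref: float
    effect_ref: float
    cost_alt: float
    effect_alt: float
    incr_cost: float
    incr_effect: float
    icer: float | None  # None when dominance/undefined
    dominance: Dominance
    nmb_ref: float
    nmb_alt: float
    wtp: float
    cost_effective_at_wtp: bool

    def to_dict(self) -> dict:
        d = {
            "cost_ref": self.cost_ref,
            "effect_ref": self.effect_ref,
            "cost_alt": self.cost_alt,
            "effect_alt": self.effect_alt,
            "incr_cost": self.incr_cost,
            "incr_effect": self.incr_effect,
            "icer": self.icer,
            "dominance": self.dominance.value,
            "nmb_ref": self.nmb_ref,
            "nmb_alt": self.nmb_alt,
            "wtp": self.wtp,
            "cost_effective_at_wtp": self.cost_effective_at_wtp,
        }
        return d


def compare_strategies(
    traj_ref: CohortTrajectory, traj_alt: CohortTrajectory, wtp: float
) -> CEAResult:
    """Full incremental comparison of two cohort trajectories.

    The trajectories must share the horizon.  ``cost_effective_at_wtp`` is
    true when the alternative dominates or its ICER does not exceed the
    willingness-to-pay threshold.
    """
    if traj_ref.horizon != traj_alt.horizon:
        raise ValueError(
            f"mismatched horizons: {traj_ref.horizon} vs {traj_alt.horizon}"
        )
    c_ref, e_ref = traj_ref.total_cost, traj_ref.total_qaly
    c_alt, e_alt = traj_alt.total_cost, traj_alt.total_qaly
    ratio = icer(c_ref, e_ref, c_alt, e_alt)
    if isinstance(ratio, Dominance):
        dom, value = ratio, None
    else:
        dom, value = Dominance.NONE, ratio
    nmb_ref = net_monetary_benefit(c_ref, e_ref, wtp)
    nmb_alt = net_monetary_benefit(c_alt, e_alt, wtp)
    ce = dom is Dominance.ALT_DOMINANT or (value is not None and value <= wtp)
    return CEAResult(
        cost_ref=c_ref,
        effect_ref=e_ref,
        cost_alt=c_alt,
        effect_alt=e_alt,
        incr_cost=c_alt - c_ref,
        incr_effect=e_alt - e_ref,
        icer=value,
        dominance=dom,
        nmb_ref=nmb_ref,
        nmb_alt=nmb_alt,
        wtp=wtp,
        cost_effective_at_wtp=ce,
    )
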