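"""Per-round screening outcomes and false-positive workup.

One screening round splits the screened cohort into true positive, false
negative, true negative and false positive fractions given the prevalence
of (undetected) malignancy.  MRM specificity is round-dependent: prior
examinations are available for comparison from the second attended round
onward, which raises specificity from 92% to 97%; the share of false
positives worked up by biopsy (rather than a follow-up MRM examination)
likewise differs between the first and later rounds.  XM false positives
always proceed to biopsy.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .params import ParameterSet

__all__ = [
    "Modality",
    "RoundOutcome",
    "sensitivity_for",
    "specificity_for_round",
    "false_positive_workup",
    "round_outcome",
]


class Modality(str, enum.Enum):
    XM = "XM"
    MRM = "MRM"


@dataclass(frozen=True)
class RoundOutcome:
    """Probability split and immediate consequences of one screening round."""

    p_tp: float
    p_fp: float
    p_tn: float
    p_fn: float
    expected_screen_cost: float  # per screened woman
    expected_fp_workup_cost: float  # per false-positive woman
    expected_fp_qol_loss: float  # QALY decrement per false positive, per cycle


def _check_round(round_index: int) -> None:
    if round_index < 1:
        raise ValueError(f"round_index must be >= 1, got {round_index}")


def sensitivity_for(modality: Modality, params: ParameterSet) -> float:
    return params.sens_xm if Modality(modality) is Modality.XM else params.sens_mrm


def specificity_for_round(
    modality: Modality, round_index: int, params: ParameterSet
) -> float:
    """Specificity of the modality in the given attended screening round.

    XM is round-independent; MRM uses the first-round value in round 1 and
    the (higher) later-round value from round 2 onward.
    """
    _check_round(round_index)
    if Modality(modality) is Modality.XM:
        return params.spec_xm
    return params.spec_mrm_round1 if round_index == 1 else params.spec_mrm_later


def biopsy_rate_for_round(
    modality: Modality, round_index: int, params: ParameterSet
) -> float:
    """Fraction of false positives that are biopsied."""
    _check_round(round_index)
    if Modality(modality) is Modality.XM:
        return 1.0
    return (
        params.biopsy_rate_fp_round1
        if round_index == 1
        else params.biopsy_rate_fp_later
    )


def false_positive_workup(
    modality: Modality, round_index: int, params: ParameterSet
) -> tuple[float, float]:
    """Expected workup cost and QOL loss of one false-positive finding.

    XM false positives are biopsied with certainty.  MRM false positives
    are biopsied at the round-dependent biopsy rate, otherwise they receive
    a follow-up MRM examination costed at the MRM tariff.  Both carry the
    false-positive QOL decrement.
    """
    _check_round(round_index)
    if Modality(modality) is Modality.XM:
        cost = params.cost_biopsy
    else:
        b = biopsy_rate_for_round(modality, round_index, params)
        cost = b * params.cost_biopsy + (1.0 - b) * params.cost_mrm
    return cost, params.qol_fp_decrement


def round_outcome(
    prevalence: float,
    modality: Modality,
    round_index: int,
    params: ParameterSet,
) -> RoundOutcome:
    """Diagnostic outcome fractions of one screening round.

    ``prevalence`` is the probability that a screened woman carries an
    undetected malignancy going into the round.
    """
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError(f"prevalence must be in [0, 1], got {prevalence}")
    _check_round(round_index)
    sens = sensitivity_for(modality, params)
    spec = specificity_for_round(modality, round_index, params)
    p_tp = prevalence * sens
    p_fn = prevalence * (1.0 - sens)
    p_fp = (1.0 - prevalence) * (1.0 - spec)
    p_tn = 1.0 - p_tp - p_fn - p_fp
    screen_cost = (
        params.cost_xm if Modality(modality) is Modality.XM else params.cost_mrm
    )
    wk_cost, qol_loss = false_positive_workup(modality, round_index, params)
    return RoundOutcome(
        p_tp=p_tp,
        p_fp=p_fp,
        p_tn=p_tn,
        p_fn=p_fn,
        expected_screen_cost=screen_cost,
        expected_fp_workup_cost=wk_cost,
        expected_fp_qol_loss=qol_loss,
    )
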