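"""30-day decision-tree stage preceding the Markov model.

Patients are allocated to MitraClip-plus-OMT or OMT alone. The intervention
arm incurs the eight one-time MitraClip-related costs and the procedure and
complication disutilities during this month; both arms incur one month of
OMT drug cost. At the end of the stage the cohort is distributed over NYHA
classes (optionally depleted by 30-day mortality) and handed to the Markov
model. One-time stage quantities are charged at time zero, undiscounted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import ARMS, ParameterError, ParameterSet


@dataclass(frozen=True)
class StageResult:
    """Outcome of the 30-day stage for one arm."""

    arm: str
    initial_distribution: np.ndarray  # over (NYHA I..IV, dead), sums to 1
    stage_cost: float  # CNY charged at t=0
    stage_utility_decrement: float  # QALY subtracted at t=0
    stage_deaths: float  # probability mass entering dead during the stage


def run_stage(arm: str, params: ParameterSet) -> StageResult:
    """Run the decision-tree stage for ``arm`` and return its hand-off state."""
    if arm not in ARMS:
        raise ParameterError(f"unknown arm {arm!r}; expected one of {ARMS}")
    costs = params.costs
    mortality = params.decision_tree.thirty_day_mortality.get(arm, 0.0)
    nyha = params.decision_tree.distribution(arm)

    if arm == "mitraclip":
        stage_cost = costs.one_time_total + costs.omt_monthly
        decrement = (
            params.utilities.disutility_procedure
            + params.utilities.disutility_complications
        )
    else:
        stage_cost = costs.omt_monthly
        decrement = 0.0

    dist = np.append(nyha * (1.0 - mortality), mortality)
    return StageResult(
        arm=arm,
        initial_distribution=dist,
        stage_cost=stage_cost,
        stage_utility_decrement=decrement,
        stage_deaths=mortality,
    )
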