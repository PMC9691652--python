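"""Individual-level Monte Carlo simulator and config-fixture generator.

The patient simulator is an independent oracle for the cohort engine: each
patient draws a post-30-day state from the decision-tree distribution and
steps through the monthly Markov chain, with Bernoulli HF-hospitalization
events per live cycle (independent of the transition, matching the cohort
engine's independence assumption). Accrual uses the same cost, utility and
discount rules as the deterministic pipeline but deliberately without
half-cycle correction — events are realized at whole-cycle resolution — so
agreement is checked against the cohort model with correction disabled,
isolating the correction as a separately tested term.

The fixture generator emits valid configuration documents: at jitter 0,
exactly the shipped base case; at jitter > 0, parameters perturbed within
their uncertainty ranges while preserving every invariant (simplexes, row
sums, utility ordering).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from .decision_tree import run_stage
from .economics import monthly_discount_factor
from .markov import DEAD
from .parameters import (
    ARMS,
    NYHA_STATES,
    ParameterError,
    ParameterSet,
    default_parameters,
    to_document,
)


@dataclass(frozen=True)
class MicrosimResult:
    """Per-patient means with Monte Carlo standard errors."""

    arm: str
    n: int
    mean_cost: float
    se_cost: float
    mean_qaly: float
    se_qaly: float
    mean_life_years: float
    se_life_years: float
    mean_hospitalizations: float
    se_hospitalizations: float


def simulate_trajectories(
    params: ParameterSet, arm: str, n: int, seed: int, n_cycles: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Raw patient paths: states ``(n, n_cycles+1)`` and event flags ``(n, n_cycles)``."""
    if n < 1:
        raise ParameterError("need at least one patient")
    stage = run_stage(arm, params)
    matrix = params.transitions.matrix(arm)
    h = np.append(params.transitions.hosp_vector(arm), 0.0)  # dead never hospitalized
    cycles = params.model.n_cycles if n_cycles is None else n_cycles
    rng = np.random.default_rng(seed)

    cum = np.cumsum(matrix, axis=1)
    states = np.empty((n, cycles + 1), dtype=np.int8)
    states[:, 0] = rng.choice(len(stage.initial_distribution), size=n,
                              p=stage.initial_distribution)
    events = np.zeros((n, cycles), dtype=bool)
    for t in range(1, cycles + 1):
        u = rng.random(n)
        states[:, t] = (u[:, None] > cum[states[:, t - 1]]).sum(axis=1)
        live = states[:, t] != DEAD
        events[:, t - 1] = live & (rng.random(n) < h[states[:, t]])
    return states, events


def simulate_patients(params: ParameterSet, arm: str, n: int, seed: int) -> MicrosimResult:
    """Mean per-patient cost, QALY, life-years and hospitalizations with SEs."""
    stage = run_stage(arm, params)
    states, events = simulate_trajectories(params, arm, n, seed)
    cycles = states.shape[1] - 1

    u5 = np.append(params.utilities.monthly_vector(), 0.0)
    rm = monthly_discount_factor(params.econ.annual_discount_rate)
    disc = (1.0 + rm) ** (-np.arange(1, cycles + 1, dtype=float))
    live = states[:, 1:] != DEAD

    costs = params.costs
    cost = stage.stage_cost + (
        (costs.omt_monthly * live + costs.hf_hospitalization * events) @ disc
    )
    qaly = -stage.stage_utility_decrement + (
        (u5[states[:, 1:]] - params.utilities.disutility_hf_hospitalization * events) @ disc
    )
    ly = live.sum(axis=1) / 12.0
    hosp = events.sum(axis=1).astype(float)

    def se(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else 0.0

    return MicrosimResult(
        arm=arm, n=n,
        mean_cost=float(cost.mean()), se_cost=se(cost),
        mean_qaly=float(qaly.mean()), se_qaly=se(qaly),
        mean_life_years=float(ly.mean()), se_life_years=se(ly),
        mean_hospitalizations=float(hosp.mean()), se_hospitalizations=se(hosp),
    )


# ---------------------------------------------------------------------------
# fixture generation
# ---------------------------------------------------------------------------

def _jitter_value(rng: np.random.Generator, base: float, low: float, high: float,
                  jitter: float) -> float:
    """Shift ``base`` a random fraction of the way toward one of its bounds."""
    t = rng.uniform(-1.0, 1.0) * min(jitter, 1.0)
    return base + t * ((high - base) if t >= 0 else (base - low))


def generate_fixture(seed: int, jitter: float = 0.0) -> dict:
    """A valid configuration document; ``jitter=0`` reproduces the shipped base case.

    With ``jitter > 0`` every parameter that carries uncertainty bounds is
    perturbed within those bounds (utilities re-sorted to keep the severity
    ordering), transition rows and initial distributions are perturbed and
    renormalized, and hospitalization probabilities are scaled — all
    invariants checked by :func:`load_parameters` still hold.
    """
    if jitter < 0:
        raise ParameterError("jitter must be nonnegative")
    doc = to_document(default_parameters())
    if jitter == 0:
        return doc

    rng = np.random.default_rng(seed)

    for name, spec in doc["uncertainty"].items():
        if spec["family"] == "fixed" or spec["low"] >= spec["high"]:
            continue
        value = _jitter_value(rng, spec["base"], spec["low"], spec["high"], jitter)
        group, field = name.split(".", 1)
        doc[group][field] = value
        spec["base"] = value

    # restore the severity ordering of NYHA utilities after marginal jitter
    u = sorted((doc["utilities"][s] for s in NYHA_STATES), reverse=True)
    for s, v in zip(NYHA_STATES, u):
        doc["utilities"][s] = v

    for arm in ARMS:
        for state in NYHA_STATES:
            row = np.array(doc["transitions"]["matrices"][arm][state], dtype=float)
            nonzero = row > 0
            factors = 1.0 + rng.uniform(-1, 1, size=row.size) * min(jitter, 1.0) * 0.2
            row[nonzero] = np.clip(row[nonzero] * factors[nonzero], 1e-9, 1.0)
            row /= row.sum()
            row[nonzero.argmax()] += 1.0 - row.sum()  # absorb float residue
            doc["transitions"]["matrices"][arm][state] = [float(v) for v in row]

            hkey = doc["transitions"]["hospitalization"][arm]
            hkey[state] = float(np.clip(
                hkey[state] * (1.0 + rng.uniform(-1, 1) * min(jitter, 1.0) * 0.5),
                0.0, 1.0,
            ))

        share = np.array(doc["decision_tree"]["initial_nyha_distribution"][arm], dtype=float)
        share *= np.exp(rng.uniform(-1, 1, size=share.size) * min(jitter, 1.0))
        share /= share.sum()
        share[-1] += 1.0 - share.sum()
        doc["decision_tree"]["initial_nyha_distribution"][arm] = [float(v) for v in share]

    return doc
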