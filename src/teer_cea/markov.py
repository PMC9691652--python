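"""Markov cohort engine: monthly state-transition propagation over NYHA I-IV
plus an absorbing dead state.

The cohort trace records state occupancy at the end of each monthly cycle,
row 0 being the entry distribution. Half-cycle correction replaces each
cycle's end-of-cycle occupancy with the mean of its start and end occupancy
when accruing per-cycle quantities, correcting the discrete-time bias of
counting whole cycles for members who die mid-cycle. The same convention is
applied to state occupancy (life-years, utilities, OMT cost) and to
hospitalization events, for internal consistency.

Death is fed only by the heart-failure death column of the transition rows;
no background all-cause mortality is layered on (the published transition
structure alone reproduces the short life expectancies of this cohort). The
matrices are time-homogeneous over the whole horizon.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .parameters import NYHA_STATES, STATES, ParameterError, TransitionSpec

DEAD = len(STATES) - 1  # index of the absorbing state

_ROW_TOL = 1e-12


def build_transition_matrix(arm: str, spec: TransitionSpec) -> np.ndarray:
    """5x5 monthly transition matrix for ``arm``, dead row absorbing."""
    matrix = spec.matrix(arm)
    sums = matrix.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-9):
        raise ParameterError(f"transition rows for {arm!r} are not stochastic: {sums}")
    return matrix


def run_cohort(initial: np.ndarray, matrix: np.ndarray, n_cycles: int) -> np.ndarray:
    """Propagate an occupancy vector through ``n_cycles`` monthly transitions.

    Returns an ``(n_cycles + 1, 5)`` trace whose row ``t`` is the occupancy
    after ``t`` cycles (row 0 = ``initial``).
    """
    if n_cycles < 1:
        raise ParameterError("n_cycles must be at least 1")
    initial = np.asarray(initial, dtype=float)
    if initial.shape != (len(STATES),):
        raise ParameterError(f"initial occupancy must have length {len(STATES)}")
    if np.any(initial < -_ROW_TOL) or abs(initial.sum() - 1.0) > 1e-9:
        raise ParameterError("initial occupancy must lie on the simplex")
    trace = np.empty((n_cycles + 1, len(STATES)))
    trace[0] = initial
    for t in range(1, n_cycles + 1):
        trace[t] = trace[t - 1] @ matrix
    return trace


def per_cycle_occupancy(trace: np.ndarray, half_cycle: bool) -> np.ndarray:
    """Occupancy attributed to each of the n cycles (shape ``(n, 5)``).

    With half-cycle correction, cycle t gets the mean of the trace rows
    t-1 and t; without, it gets the end-of-cycle row t.
    """
    if half_cycle:
        return 0.5 * (trace[:-1] + trace[1:])
    return trace[1:]


def life_years(trace: np.ndarray, half_cycle: bool = True) -> float:
    """Undiscounted expected life-years implied by a cohort trace."""
    alive = 1.0 - per_cycle_occupancy(trace, half_cycle)[:, DEAD]
    return float(alive.sum() / 12.0)


def expected_hospitalizations(trace: np.ndarray, h: np.ndarray, half_cycle: bool = True) -> float:
    """Expected HF hospitalizations per person over the traced horizon.

    ``h`` holds the monthly hospitalization probability for each live state;
    events accrue as occupancy x probability under the same half-cycle
    convention as life-years.
    """
    h = np.asarray(h, dtype=float)
    if h.shape != (len(NYHA_STATES),):
        raise ParameterError(f"hospitalization probabilities must have length {len(NYHA_STATES)}")
    if np.any((h < 0) | (h > 1)):
        raise ParameterError("hospitalization probabilities must lie in [0,1]")
    occ = per_cycle_occupancy(trace, half_cycle)[:, : len(NYHA_STATES)]
    return float((occ @ h).sum())


def trace_to_frame(trace: np.ndarray) -> pd.DataFrame:
    """Cohort trace as a tidy table: cycle, per-state occupancy, cumulative deaths."""
    df = pd.DataFrame(trace, columns=list(STATES))
    df.insert(0, "cycle", np.arange(trace.shape[0]))
    df["cumulative_deaths"] = df["dead"]
    return df
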