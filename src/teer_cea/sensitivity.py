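"""Deterministic and probabilistic sensitivity analysis.

One-way analysis re-runs the full deterministic pipeline with each uncertain
parameter at its 95%-interval bounds, holding the rest at base, and ranks
parameters by the ICER swing (tornado diagram). The probabilistic analysis
draws every uncertain parameter jointly — costs from gamma, utilities,
disutilities and transition probabilities from beta distributions moment-
matched to their intervals — and re-evaluates the model per draw.

Transition probabilities carry no published intervals; each nonzero
off-diagonal entry (including the HF-death column) is given a beta
distribution whose 95% CI spans +/-20% of the base value, and each perturbed
row is renormalized to remain stochastic. Structural zeros (impossible
transitions, e.g. recovery out of NYHA IV) are never perturbed. Draws use
one substream per parameter derived from the master seed, so adding or
removing a parameter does not shift any other parameter's stream.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .decision_tree import run_stage
from .economics import (
    COMPARATOR,
    INTERVENTION,
    _accrue_from_trace,
    evaluate,
    monthly_discount_factor,
)
from .markov import run_cohort
from .parameters import (
    ARMS,
    NYHA_STATES,
    DistributionSpec,
    ParameterError,
    ParameterSet,
    derive_distribution,
    set_path,
)

#: relative half-width of the assumed 95% CI for transition probabilities
TRANSITION_CI_FRACTION = 0.2

#: default CEAC grid: 0 to 1.5 million CNY/QALY in 10,000-CNY steps
DEFAULT_WTP_GRID = np.arange(0, 1_500_001, 10_000, dtype=float)


@dataclass(frozen=True)
class TornadoEntry:
    """One-way sensitivity result for a single parameter."""

    name: str
    low: float
    high: float
    icer_at_low: float
    icer_at_high: float

    @property
    def swing(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


@dataclass(frozen=True)
class PsaSample:
    """One probabilistic draw with its model evaluation."""

    index: int
    draws: dict[str, float]
    cost: dict[str, float]
    qaly: dict[str, float]
    delta_cost: float
    delta_qaly: float


@dataclass(frozen=True)
class CEACPoint:
    wtp: float
    acceptability: float


# ---------------------------------------------------------------------------
# one-way (tornado)
# ---------------------------------------------------------------------------

def one_way(params: ParameterSet, names: list[str] | None = None) -> list[TornadoEntry]:
    """Tornado entries for ``names`` (default: every uncertainty entry),
    sorted by ICER swing, largest first."""
    if names is None:
        names = list(params.uncertainty)
    entries = []
    for name in names:
        spec = params.uncertainty.get(name)
        if spec is None:
            raise ParameterError(f"no uncertainty bounds for parameter {name!r}")
        icer_lo = evaluate(set_path(params, name, spec.low)).cea.icer
        icer_hi = evaluate(set_path(params, name, spec.high)).cea.icer
        if icer_lo is None or icer_hi is None:
            raise ParameterError(f"ICER undefined at a bound of {name!r}")
        entries.append(
            TornadoEntry(
                name=name, low=spec.low, high=spec.high,
                icer_at_low=icer_lo, icer_at_high=icer_hi,
            )
        )
    return sorted(entries, key=lambda e: e.swing, reverse=True)


# ---------------------------------------------------------------------------
# probabilistic (PSA)
# ---------------------------------------------------------------------------

def transition_distributions(
    params: ParameterSet, ci_fraction: float = TRANSITION_CI_FRACTION
) -> dict[str, DistributionSpec]:
    """Beta specs for every nonzero off-diagonal transition entry per arm."""
    out: dict[str, DistributionSpec] = {}
    states = list(NYHA_STATES) + ["dead"]
    for arm in ARMS:
        for from_state in NYHA_STATES:
            row = params.transitions.matrices[arm][from_state]
            for j, p in enumerate(row):
                if p <= 0 or states[j] == from_state:
                    continue
                name = f"transitions.{arm}.{from_state}.{states[j]}"
                out[name] = derive_distribution(
                    name, "beta", p,
                    max(p * (1 - ci_fraction), 0.0),
                    min(p * (1 + ci_fraction), 1.0),
                )
    return out


def _substream(master_seed: int, name: str) -> np.random.Generator:
    """Independent, name-keyed random stream derived from the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([master_seed & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


def _perturbed_matrix(
    base: np.ndarray, arm: str, draws: dict[str, float]
) -> np.ndarray:
    """Replace drawn off-diagonal entries and renormalize each row."""
    m = base.copy()
    states = list(NYHA_STATES) + ["dead"]
    for i, from_state in enumerate(NYHA_STATES):
        changed = False
        for j, to_state in enumerate(states):
            key = f"transitions.{arm}.{from_state}.{to_state}"
            if key in draws:
                m[i, j] = draws[key]
                changed = True
        if changed:
            m[i] /= m[i].sum()
    return m


def run_psa(
    params: ParameterSet,
    n_iter: int = 10_000,
    seed: int = 0,
    transition_ci_fraction: float = TRANSITION_CI_FRACTION,
) -> list[PsaSample]:
    """Seeded Monte Carlo re-evaluation of the model over joint parameter draws."""
    if n_iter < 1:
        raise ParameterError("n_iter must be at least 1")

    specs: dict[str, DistributionSpec] = {
        name: spec
        for name, spec in params.uncertainty.items()
        if spec.family != "fixed" and spec.low < spec.high
    }
    specs.update(transition_distributions(params, transition_ci_fraction))

    draws = {
        name: np.asarray(spec.sample(_substream(seed, name), n_iter))
        for name, spec in specs.items()
    }

    n_cycles = params.model.n_cycles
    half_cycle = params.model.half_cycle_correction
    rm = monthly_discount_factor(params.econ.annual_discount_rate)
    stages = {arm: run_stage(arm, params) for arm in ARMS}
    base_matrices = {arm: params.transitions.matrix(arm) for arm in ARMS}

    cost_fields = ("device", "procedure", "diagnosis", "medicine",
                   "complications", "ward", "nursing", "others")

    samples: list[PsaSample] = []
    for i in range(n_iter):
        d = {name: float(v[i]) for name, v in draws.items()}

        def drawn(path: str, base: float) -> float:
            return d.get(path, base)

        omt_monthly = drawn("costs.omt_monthly", params.costs.omt_monthly)
        hosp_cost = drawn("costs.hf_hospitalization", params.costs.hf_hospitalization)
        utilities = np.array([drawn(f"utilities.{s}", getattr(params.utilities, s))
                              for s in NYHA_STATES])
        du_hosp = drawn("utilities.disutility_hf_hospitalization",
                        params.utilities.disutility_hf_hospitalization)
        one_time = sum(drawn(f"costs.{f}", getattr(params.costs, f)) for f in cost_fields)
        stage_decrement_mc = (
            drawn("utilities.disutility_procedure", params.utilities.disutility_procedure)
            + drawn("utilities.disutility_complications",
                    params.utilities.disutility_complications)
        )

        cost: dict[str, float] = {}
        qaly: dict[str, float] = {}
        for arm in ARMS:
            matrix = _perturbed_matrix(base_matrices[arm], arm, d)
            trace = run_cohort(stages[arm].initial_distribution, matrix, n_cycles)
            if arm == INTERVENTION:
                stage_cost = one_time + omt_monthly
                stage_decrement = stage_decrement_mc
            else:
                stage_cost = omt_monthly
                stage_decrement = 0.0
            res = _accrue_from_trace(
                arm=arm, trace=trace,
                h=params.transitions.hosp_vector(arm),
                stage_cost=stage_cost, stage_decrement=stage_decrement,
                omt_monthly=omt_monthly, hosp_cost=hosp_cost,
                utilities=utilities, du_hosp=du_hosp,
                monthly_rate=rm, half_cycle=half_cycle,
            )
            cost[arm] = res.lifetime_cost
            qaly[arm] = res.lifetime_qaly

        samples.append(
            PsaSample(
                index=i, draws=d, cost=cost, qaly=qaly,
                delta_cost=cost[INTERVENTION] - cost[COMPARATOR],
                delta_qaly=qaly[INTERVENTION] - qaly[COMPARATOR],
            )
        )
    return samples


# ---------------------------------------------------------------------------
# acceptability
# ---------------------------------------------------------------------------

def acceptability_at(samples: list[PsaSample], wtp: float) -> float:
    """Fraction of draws in which the intervention has positive NMB at ``wtp``."""
    if not samples:
        raise ParameterError("no PSA samples")
    dc = np.array([s.delta_cost for s in samples])
    dq = np.array([s.delta_qaly for s in samples])
    return float(np.mean(wtp * dq - dc > 0))


def ceac(samples: list[PsaSample], wtp_grid=None) -> list[CEACPoint]:
    """Cost-effectiveness acceptability curve over a WTP grid."""
    if wtp_grid is None:
        wtp_grid = DEFAULT_WTP_GRID
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size == 0:
        return []
    if not samples:
        raise ParameterError("no PSA samples")
    dc = np.array([s.delta_cost for s in samples])
    dq = np.array([s.delta_qaly for s in samples])
    accept = (wtp_grid[:, None] * dq[None, :] - dc[None, :] > 0).mean(axis=1)
    return [CEACPoint(wtp=float(w), acceptability=float(a)) for w, a in zip(wtp_grid, accept)]


def ceac_crossover(samples: list[PsaSample], wtp_grid=None) -> float | None:
    """Smallest grid WTP at which intervention acceptability reaches 50%."""
    for point in ceac(samples, wtp_grid):
        if point.acceptability >= 0.5:
            return point.wtp
    return None
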