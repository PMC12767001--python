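"""Therapeutic-intervention simulations.

Scenarios scale individual mechanistic rates (k_a, k_s) or the
vulnerability from a common partially aggregated initial state, and all
run for the amount of simulated time the unaltered (baseline) condition
takes to reach a late-stage endpoint.  Above the switch fraction
f_switch = k_a/k_s the cell-to-cell channel dominates, so halving k_a
barely changes the outcome while halving k_s or the vulnerability slows
progression clearly — the model's central therapeutic prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .fixtures import CellArrangement
from .simulator import (
    AggregationState,
    Engine,
    ModelParams,
    Trajectory,
    VulnerabilityField,
    run_until_fraction,
)

__all__ = [
    "Scenario",
    "InterventionResult",
    "prepare_initial_state",
    "run_scenarios",
    "severity_axis",
    "BASELINE",
]


@dataclass(frozen=True)
class Scenario:
    """Non-negative multipliers on k_a, k_s and all v_i (v clipped to [0, 1])."""

    scale_ka: float = 1.0
    scale_ks: float = 1.0
    scale_v: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        if min(self.scale_ka, self.scale_ks, self.scale_v) < 0:
            raise ValueError("scenario scale factors must be non-negative")
        if not self.label:
            object.__setattr__(self, "label", f"ka{self.scale_ka}_ks{self.scale_ks}_v{self.scale_v}")

    @property
    def is_baseline(self) -> bool:
        return self.scale_ka == self.scale_ks == self.scale_v == 1.0


BASELINE = Scenario(1.0, 1.0, 1.0, label="baseline")


@dataclass
class InterventionResult:
    """Per-scenario trajectories, checkpoint snapshots and endpoints.

    Checkpoints are taken at t0 (the shared initial state), two
    intermediate times (by default 50% and 71% of the t0 -> T_end
    interval) and T_end, where T_end is when the baseline first reaches
    the endpoint fraction.
    """

    t0: float
    t_end: float
    checkpoint_times: Tuple[float, ...]
    trajectories: Dict[str, Trajectory]
    checkpoint_states: Dict[str, Dict[float, AggregationState]]
    final_fractions: Dict[str, float]


def prepare_initial_state(
    arrangement: CellArrangement,
    params: ModelParams,
    vulnerability: VulnerabilityField,
    f0: float,
    rng=None,
) -> AggregationState:
    """Run the unmodified model from all-healthy until the fraction
    aggregated first reaches ``f0``; the returned state is the shared
    starting point for every scenario.  ``f0 = 0`` returns the all-healthy
    state."""
    if not 0 <= f0 < 1:
        raise ValueError("f0 must be in [0, 1)")
    if f0 == 0:
        return AggregationState.all_healthy(arrangement.n_cells)
    traj = run_until_fraction(arrangement, params, vulnerability, f0, rng=rng)
    return traj.final_state


def _scaled(params: ModelParams, vul: VulnerabilityField, sc: Scenario):
    new_params = replace(params, k_a=params.k_a * sc.scale_ka, k_s=params.k_s * sc.scale_ks)
    new_vul = VulnerabilityField(
        np.clip(vul.v * sc.scale_v, 0.0, 1.0), vul.scheme, dict(vul.scheme_params)
    )
    return new_params, new_vul


def run_scenarios(
    arrangement: CellArrangement,
    params: ModelParams,
    vulnerability: VulnerabilityField,
    initial: AggregationState,
    scenarios: Sequence[Scenario],
    f_end: float,
    rng=None,
    checkpoint_fractions: Tuple[float, float] = (0.5, 0.71),
) -> InterventionResult:
    """Run every scenario from byte-identical copies of ``initial``.

    The baseline (which must be included) runs until the fraction
    aggregated first reaches ``f_end``, defining T_end; every other
    scenario then runs for exactly the same simulated time.  Each scenario
    gets a fresh child seed derived deterministically from ``rng``, so
    scenarios are comparable but not artificially coupled.
    """
    scenarios = list(scenarios)
    try:
        base_idx = next(i for i, s in enumerate(scenarios) if s.is_baseline)
    except StopIteration:
        raise ValueError("a baseline scenario (1, 1, 1) must be included") from None
    if f_end <= initial.fraction_aggregated:
        raise ValueError("f_end must exceed the initial fraction aggregated")

    master = rng if isinstance(rng, (int, np.integer)) else np.random.default_rng(rng).integers(2**31)
    child_seeds = np.random.SeedSequence(master).spawn(len(scenarios))

    t0 = initial.t_now
    # Baseline first: it defines T_end.
    base_params, base_vul = _scaled(params, vulnerability, scenarios[base_idx])
    base_eng = Engine(
        arrangement, base_params, base_vul, state=initial.copy(),
        rng=np.random.default_rng(child_seeds[base_idx]),
    )
    base_traj = base_eng.run(target_fraction=f_end)
    t_end = float(base_traj.final_state.t_now)
    delta = t_end - t0
    cp_times = (t0,) + tuple(t0 + c * delta for c in checkpoint_fractions) + (t_end,)

    trajectories: Dict[str, Trajectory] = {}
    checkpoint_states: Dict[str, Dict[float, AggregationState]] = {}
    final_fractions: Dict[str, float] = {}
    for i, sc in enumerate(scenarios):
        if i == base_idx:
            traj = base_traj
        else:
            sc_params, sc_vul = _scaled(params, vulnerability, sc)
            eng = Engine(
                arrangement, sc_params, sc_vul, state=initial.copy(),
                rng=np.random.default_rng(child_seeds[i]),
            )
            traj = eng.run(t_end=t_end, snapshot_times=cp_times[1:-1])
        snaps = {t0: initial.copy()}
        for t_req in cp_times[1:-1]:
            snaps[t_req] = _state_at(traj, t_req, initial)
        snaps[t_end] = traj.final_state
        trajectories[sc.label] = traj
        checkpoint_states[sc.label] = snaps
        final_fractions[sc.label] = traj.final_state.fraction_aggregated
    return InterventionResult(
        t0=t0,
        t_end=t_end,
        checkpoint_times=cp_times,
        trajectories=trajectories,
        checkpoint_states=checkpoint_states,
        final_fractions=final_fractions,
    )


def _state_at(traj: Trajectory, t_req: float, initial: AggregationState) -> AggregationState:
    """Snapshot at the first recorded time >= t_req (falls back to a
    reconstruction from trigger times if no stored snapshot exists)."""
    if t_req in traj.snapshots:
        return traj.snapshots[t_req]
    final = traj.final_state
    x = initial.x | (np.nan_to_num(final.t_trigger, nan=np.inf) <= t_req)
    t_trig = np.where(x, final.t_trigger, np.nan)
    return AggregationState(x, t_trig, t_now=t_req)


def severity_axis(items: Sequence) -> np.ndarray:
    """Common pseudo-severity coordinate: the fraction of aggregated cells.

    Accepts AggregationStates and/or Trajectories (a trajectory contributes
    its final fraction).  Values are returned sorted ascending with a
    stable sort, so ties keep their original input order.
    """
    fractions = []
    for item in items:
        if isinstance(item, Trajectory):
            fractions.append(item.final_state.fraction_aggregated)
        elif isinstance(item, AggregationState):
            fractions.append(item.fraction_aggregated)
        else:
            fractions.append(float(item))
    order = np.argsort(np.asarray(fractions), kind="stable")
    return np.asarray(fractions)[order]
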