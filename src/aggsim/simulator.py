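"""Discrete-time stochastic simulator of cellular aggregation.

Each cell is a two-state unit: healthy, or in a runaway aggregation state
("aggregated").  A healthy cell i switches states in a time step dt with
probability

    p_i = v_i * (1 - exp(-(k_a*dt + lambda_i)))

where k_a is the cell-autonomous trigger rate, v_i in [0, 1] the cell's
vulnerability, and lambda_i the aggregation pressure exerted by aggregated
cells nearby: the expected number of cell-to-cell trigger events on cell i
during the step.  For the default Gaussian coupling kernel,

    lambda_i = k_s*dt / (2*pi*sigma^2*rho_c) * sum_j exp(-d_ij^2 / (2*sigma^2)) * x_j

with x_j = 1 for aggregated cells, k_s the cell-to-cell trigger rate,
sigma the coupling length scale, and rho_c = n/A the overall cell density.
The 1/rho_c factor makes lambda a pure event count (the kernel sum over
cells of a uniform system is ~rho_c): a single aggregated cell exerts a
total aggregation pressure of k_s per unit time summed over all other
cells, so in the well-mixed limit the aggregated fraction obeys
df/dt = k_a*(1-f) + k_s*f*(1-f) exactly, and cell-to-cell triggering
overtakes the cell-autonomous channel at the switch fraction
f_switch = k_a/k_s.  There is no recovered state and no cell death: x_j is
monotone non-decreasing.  The model mirrors spatial SI epidemic models on
a fixed point cloud.

Only the rate ratio k_s/k_a and sigma shape the patterns as a function of
fraction aggregated; the absolute rate scale sets the (arbitrary) time unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .fixtures import CellArrangement

__all__ = [
    "ModelParams",
    "VulnerabilityField",
    "AggregationState",
    "TriggerProbabilities",
    "Trajectory",
    "kernel_weight",
    "aggregation_pressure",
    "step",
    "run_until_fraction",
    "make_vulnerability",
    "NonProgressError",
]

#: per-step combined hazard cap; dt is reduced so max hazard stays below this
HAZARD_CAP = 0.01
#: target expected number of cell-autonomous events in the first step
INITIAL_EVENTS_PER_STEP = 2.0


class NonProgressError(RuntimeError):
    """Raised when a target fraction is unreachable (all rates/vulnerability zero)."""


@dataclass(frozen=True)
class ModelParams:
    """Mechanistic parameter vector (k_a, k_s, sigma, kernel[, dt]).

    k_a, k_s are rates per unit time; sigma is the coupling length scale in
    µm.  ``dt`` is optional: if None (recommended) the step size is chosen
    adaptively — see :func:`run_until_fraction`.  All kernels integrate to 1
    over the plane so k_s keeps its meaning across kernel choices; the
    exponential and uniform-disc kernels are matched to the Gaussian by
    second moment.
    """

    k_a: float
    k_s: float
    sigma: float
    dt: Optional[float] = None
    kernel: str = "gaussian"

    def __post_init__(self) -> None:
        if self.k_a < 0 or self.k_s < 0:
            raise ValueError("rates must be non-negative")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.kernel not in ("gaussian", "exponential", "uniform_disc"):
            raise ValueError(f"unknown kernel {self.kernel!r}")

    @property
    def ratio(self) -> float:
        """k_s / k_a (inf if k_a = 0)."""
        return self.k_s / self.k_a if self.k_a > 0 else np.inf


def kernel_weight(d: np.ndarray, sigma: float, kernel: str = "gaussian") -> np.ndarray:
    """Normalized planar coupling kernel w(d), with unit integral over R^2.

    gaussian:      w = exp(-d^2/(2 sigma^2)) / (2 pi sigma^2)
    exponential:   w = exp(-d/l) / (2 pi l^2),  l = sigma/sqrt(3)
    uniform_disc:  w = 1{d <= R} / (pi R^2),    R = 2 sigma

    The exponential scale l and disc radius R match the Gaussian's second
    moment E[d^2] = 2 sigma^2, so regime comparisons across kernels are at
    equal effective range.
    """
    d = np.asarray(d, dtype=float)
    if kernel == "gaussian":
        return np.exp(-(d**2) / (2.0 * sigma**2)) / (2.0 * np.pi * sigma**2)
    if kernel == "exponential":
        ell = sigma / np.sqrt(3.0)
        return np.exp(-d / ell) / (2.0 * np.pi * ell**2)
    if kernel == "uniform_disc":
        radius = 2.0 * sigma
        return np.where(d <= radius, 1.0 / (np.pi * radius**2), 0.0)
    raise ValueError(f"unknown kernel {kernel!r}")


@dataclass
class AggregationState:
    """Per-cell aggregation state: x_j (binary), trigger times, current time."""

    x: np.ndarray
    t_trigger: np.ndarray
    t_now: float = 0.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=bool)
        self.t_trigger = np.asarray(self.t_trigger, dtype=float)
        if self.x.shape != self.t_trigger.shape:
            raise ValueError("x and t_trigger must have the same length")

    @classmethod
    def all_healthy(cls, n_cells: int) -> "AggregationState":
        return cls(np.zeros(n_cells, dtype=bool), np.full(n_cells, np.nan), 0.0)

    @property
    def n_cells(self) -> int:
        return self.x.shape[0]

    @property
    def n_aggregated(self) -> int:
        return int(self.x.sum())

    @property
    def fraction_aggregated(self) -> float:
        return float(self.x.mean()) if self.n_cells else 0.0

    def copy(self) -> "AggregationState":
        return AggregationState(self.x.copy(), self.t_trigger.copy(), self.t_now)


@dataclass(frozen=True)
class VulnerabilityField:
    """Per-cell vulnerability v_i in [0, 1] (multiplies the trigger probability)."""

    v: np.ndarray
    scheme: str = "constant"
    scheme_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.v, dtype=float)
        if v.size and (v.min() < 0 or v.max() > 1):
            raise ValueError("vulnerability values must lie in [0, 1]")
        object.__setattr__(self, "v", v)

    @classmethod
    def constant(cls, n_cells: int, value: float = 1.0) -> "VulnerabilityField":
        return cls(np.full(n_cells, float(value)), "constant", {"value": value})


def make_vulnerability(
    arrangement: CellArrangement,
    scheme: str = "constant",
    scheme_params: Optional[dict] = None,
    rng: Optional[np.random.Generator] = None,
    density_mask: Optional[np.ndarray] = None,
) -> VulnerabilityField:
    """Build a vulnerability field on an arrangement.

    Schemes
    -------
    constant:     v_i = value (default 1).
    bernoulli:    v_i = v_high with probability p, else v_low (two cell
                  populations of differing resistance).
    uniform:      v_i ~ U(0, 1) i.i.d. (a continuum of resistance).
    spatial_bias: base values multiplied by ``beta`` for cells where
                  ``density_mask`` is True, clipped to [0, 1].
    """
    params = dict(scheme_params or {})
    rng = np.random.default_rng(rng)
    n = arrangement.n_cells
    if scheme == "constant":
        v = np.full(n, float(params.get("value", 1.0)))
    elif scheme == "bernoulli":
        p = float(params.get("p", 0.5))
        lo, hi = float(params.get("v_low", 0.1)), float(params.get("v_high", 1.0))
        v = np.where(rng.random(n) < p, hi, lo)
    elif scheme == "uniform":
        v = rng.random(n)
    elif scheme == "spatial_bias":
        beta = float(params.get("beta", 1.0))
        if not beta > 0:
            raise ValueError(f"bias factor beta must be positive, got {beta}")
        base = np.asarray(params.get("base", np.full(n, 1.0)), dtype=float)
        if density_mask is None:
            raise ValueError("spatial_bias scheme requires a density_mask")
        v = base.copy()
        v[np.asarray(density_mask, dtype=bool)] *= beta
        v = np.clip(v, 0.0, 1.0)
    else:
        raise ValueError(f"unknown vulnerability scheme {scheme!r}")
    return VulnerabilityField(v, scheme, params)


@dataclass(frozen=True)
class TriggerProbabilities:
    """Per-cell, per-step trigger quantities at a given state and dt."""

    lambda_s: np.ndarray  # expected cell-to-cell trigger events per step
    p_s: np.ndarray  # 1 - exp(-lambda_s)
    p_a: np.ndarray  # 1 - exp(-k_a dt)
    p_total: np.ndarray  # v * (1 - exp(-(k_a dt + lambda_s)))


def _kernel_sums(
    arrangement: CellArrangement, x: np.ndarray, sigma: float, kernel: str
) -> np.ndarray:
    """K_i = sum_j w(d_ij) x_j / rho_c over aggregated j != i, for every cell i.

    The division by the overall cell density rho_c makes K_i an expected
    event count per unit k_s*dt (for a uniform system, sum_i w(d_ij) over
    all cells is ~rho_c, so each aggregated cell contributes ~1 in total).
    """
    n = arrangement.n_cells
    K = np.zeros(n)
    agg_idx = np.flatnonzero(x)
    for j in agg_idx:
        w = kernel_weight(arrangement.distances_from(arrangement.positions[j]), sigma, kernel)
        w[j] = 0.0  # self-exclusion
        K += w
    return K / arrangement.density


def aggregation_pressure(
    arrangement: CellArrangement,
    state: AggregationState,
    params: ModelParams,
    dt: Optional[float] = None,
    vulnerability: Optional[VulnerabilityField] = None,
) -> TriggerProbabilities:
    """Per-cell trigger probabilities for one step of length ``dt``.

    ``dt`` defaults to ``params.dt`` and must be given one way or the other.
    A cell with no aggregated cells in range has lambda_i = 0 hence p_s = 0.
    """
    if state.n_cells != arrangement.n_cells:
        raise ValueError("state size does not match arrangement")
    if dt is None:
        dt = params.dt
    if dt is None:
        raise ValueError("dt must be given (params.dt is None)")
    K = _kernel_sums(arrangement, state.x, params.sigma, params.kernel)
    lam = params.k_s * dt * K
    p_s = -np.expm1(-lam)
    p_a = -np.expm1(-params.k_a * dt) * np.ones_like(lam)
    v = vulnerability.v if vulnerability is not None else 1.0
    p_total = v * -np.expm1(-(params.k_a * dt + lam))
    return TriggerProbabilities(lam, p_s, p_a, np.asarray(p_total))


def step(
    arrangement: CellArrangement,
    state: AggregationState,
    params: ModelParams,
    vulnerability: VulnerabilityField,
    rng: np.random.Generator,
    dt: Optional[float] = None,
) -> AggregationState:
    """Advance the state by one time step of length dt.

    Healthy cell i triggers with probability v_i*(1 - exp(-(k_a dt + lambda_i)));
    triggered cells get x_i = 1 and t_trigger = t_now + dt.  Aggregated cells
    never revert.  Draws are made in fixed cell-index order for
    reproducibility.
    """
    if dt is None:
        dt = params.dt
    if dt is None:
        raise ValueError("dt must be given (params.dt is None)")
    probs = aggregation_pressure(arrangement, state, params, dt, vulnerability)
    new = state.copy()
    u = rng.random(state.n_cells)
    triggered = (~state.x) & (u < probs.p_total)
    new.x[triggered] = True
    new.t_trigger[triggered] = state.t_now + dt
    new.t_now = state.t_now + dt
    return new


@dataclass
class Trajectory:
    """Recorded time course of a single simulation run."""

    times: np.ndarray
    fractions: np.ndarray
    snapshots: dict  # {requested fraction or time: AggregationState}
    final_state: AggregationState
    seed: Optional[int] = None


class Engine:
    """Incremental simulation engine.

    Maintains the per-cell kernel sums K_i; when a cell aggregates, its
    (exact, untruncated) kernel contribution is added to all cells in one
    vectorized minimum-image pass, so a step costs O(n + n_events * n).
    The step size shrinks adaptively so the maximum per-step hazard
    k_a*dt + lambda_i stays below ``HAZARD_CAP``; the initial dt resolves
    the cell-autonomous phase (about ``INITIAL_EVENTS_PER_STEP`` expected
    events in the first step).
    """

    def __init__(
        self,
        arrangement: CellArrangement,
        params: ModelParams,
        vulnerability: VulnerabilityField,
        state: Optional[AggregationState] = None,
        rng=None,
    ) -> None:
        self.arrangement = arrangement
        self.params = params
        self.v = vulnerability.v
        self.rng = np.random.default_rng(rng)
        self.state = state.copy() if state is not None else AggregationState.all_healthy(arrangement.n_cells)
        if self.state.n_cells != arrangement.n_cells:
            raise ValueError("state size does not match arrangement")
        if vulnerability.v.shape[0] != arrangement.n_cells:
            raise ValueError("vulnerability size does not match arrangement")
        self.K = _kernel_sums(arrangement, self.state.x, params.sigma, params.kernel)
        self.dt = params.dt if params.dt is not None else self._initial_dt()

    def _initial_dt(self) -> float:
        n = self.arrangement.n_cells
        if self.params.k_a > 0:
            dt = INITIAL_EVENTS_PER_STEP / (n * self.params.k_a)
            return min(dt, HAZARD_CAP / self.params.k_a)
        # No cell-autonomous channel: scale off the coupling rate alone.
        if self.params.k_s > 0:
            peak = kernel_weight(0.0, self.params.sigma, self.params.kernel)
            peak = float(peak) / self.arrangement.density
            return HAZARD_CAP / (self.params.k_s * peak)
        raise NonProgressError("both k_a and k_s are zero; nothing can ever trigger")

    def _add_contribution(self, j: int) -> None:
        w = kernel_weight(
            self.arrangement.distances_from(self.arrangement.positions[j]),
            self.params.sigma,
            self.params.kernel,
        )
        w[j] = 0.0
        self.K += w / self.arrangement.density

    def advance(self) -> int:
        """Run one step; returns the number of newly triggered cells."""
        p = self.params
        st = self.state
        healthy = ~st.x
        rates = p.k_a + p.k_s * self.K
        max_rate = float(rates[healthy].max()) if healthy.any() else 0.0
        if max_rate > 0:
            cap_dt = HAZARD_CAP / max_rate
            if cap_dt < self.dt:
                self.dt = cap_dt
        u = self.rng.random(st.n_cells)
        p_total = self.v * -np.expm1(-rates * self.dt)
        triggered = healthy & (u < p_total)
        t_new = st.t_now + self.dt
        st.x[triggered] = True
        st.t_trigger[triggered] = t_new
        st.t_now = t_new
        for j in np.flatnonzero(triggered):
            self._add_contribution(j)
        return int(triggered.sum())

    def run(
        self,
        target_fraction: Optional[float] = None,
        t_end: Optional[float] = None,
        snapshot_fractions: Sequence[float] = (),
        snapshot_times: Sequence[float] = (),
        max_steps: int = 1_000_000,
        seed: Optional[int] = None,
    ) -> Trajectory:
        if target_fraction is None and t_end is None:
            raise ValueError("need a target fraction or an end time")
        st = self.state
        times = [st.t_now]
        fractions = [st.fraction_aggregated]
        snaps: dict = {}
        pending_f = sorted(f for f in snapshot_fractions if f > st.fraction_aggregated)
        for f in sorted(snapshot_fractions):
            if f <= st.fraction_aggregated and f not in snaps:
                snaps[f] = st.copy()  # already past: snapshot the start
        pending_t = sorted(t for t in snapshot_times if t > st.t_now)
        stalled = 0
        for _ in range(max_steps):
            if target_fraction is not None and st.fraction_aggregated >= target_fraction:
                break
            if t_end is not None and st.t_now >= t_end:
                break
            if t_end is not None:
                # Do not step past the requested end time.
                self.dt = min(self.dt, t_end - st.t_now)
            n_new = self.advance()
            times.append(st.t_now)
            fractions.append(st.fraction_aggregated)
            while pending_f and st.fraction_aggregated >= pending_f[0]:
                snaps[pending_f.pop(0)] = st.copy()
            while pending_t and st.t_now >= pending_t[0]:
                snaps[pending_t.pop(0)] = st.copy()
            stalled = stalled + 1 if n_new == 0 else 0
            if stalled > 50_000:
                raise NonProgressError(
                    "no progress in 50000 consecutive steps; "
                    "check rates and vulnerability"
                )
        else:
            raise NonProgressError(f"target not reached within {max_steps} steps")
        return Trajectory(
            np.asarray(times), np.asarray(fractions), snaps, st.copy(), seed=seed
        )


def run_until_fraction(
    arrangement: CellArrangement,
    params: ModelParams,
    vulnerability: VulnerabilityField,
    target_fraction: float,
    rng=None,
    record: Sequence[float] = (),
    initial_state: Optional[AggregationState] = None,
    max_steps: int = 1_000_000,
) -> Trajectory:
    """Simulate until the aggregated fraction first reaches ``target_fraction``.

    ``record`` lists fractions at which state snapshots are captured (first
    step crossing each).  The step size is handled adaptively unless
    ``params.dt`` is set.  Raises :class:`NonProgressError` if the target is
    unreachable (zero rates or vulnerability) after a step cap.
    """
    if not 0 < target_fraction <= 1:
        raise ValueError("target_fraction must be in (0, 1]")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    eng = Engine(arrangement, params, vulnerability, state=initial_state, rng=rng)
    if params.k_a == 0 and eng.state.n_aggregated == 0 and params.k_s > 0:
        raise NonProgressError("k_a = 0 with no aggregated seed cells: unreachable")
    if not (vulnerability.v > 0).any():
        raise NonProgressError("vulnerability is zero everywhere: unreachable")
    return eng.run(
        target_fraction=target_fraction,
        snapshot_fractions=record,
        max_steps=max_steps,
        seed=seed,
    )
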