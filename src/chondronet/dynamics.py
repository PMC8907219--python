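"""Continuous dynamics of a signed regulatory network.

A network is translated into one ODE per node.  The total input ``omega`` of
a node combines its activators and inhibitors:

* activator block  ``A = ((1 + sum(alpha)) / sum(alpha)) *
  (sum(alpha * x_a) / (1 + sum(alpha * x_a)))``
* inhibitor block  ``I`` analogous with the beta weights;
* ``omega = A * (1 - I)`` when both are present, ``A`` with activators only,
  ``1 - I`` with inhibitors only.

Each regulated node then follows ``dx/dt = phi(omega) - gamma * x`` with the
normalized sigmoid

``phi(w) = (-exp(0.5 h) + exp(-h (w - 0.5)))
           / ((1 - exp(0.5 h)) * (1 + exp(-h (w - 0.5))))``

which satisfies ``phi(0) = 0``, ``phi(0.5) = 0.5`` and ``phi(1) = 1``
algebraically.  States live in ``[0, 1]``; clamped nodes are pinned to their
clamp value; source nodes (no regulators) are held at their initial value by
default (``source_node_policy="hold"``) or decay freely (``"decay"``).

Integration is fixed-step RK4 by default, with a SciPy adaptive alternative.
All heavy paths run through a batched array core so that populations of
perturbations (or candidate topologies) integrate in one vectorized sweep.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Optional

import numpy as np
from scipy.integrate import solve_ivp

from .network import RegulatoryNetwork, Sign

__all__ = [
    "NodeParameters",
    "SolverConfig",
    "PerturbationSpec",
    "SteadyState",
    "ResponseVector",
    "DynamicsError",
    "IntegrationError",
    "ConvergenceError",
    "CompiledSystem",
    "total_input",
    "activation",
    "rhs",
    "integrate_to_steady_state",
    "baseline",
    "response",
]

SOURCE_POLICIES = ("hold", "decay")


class DynamicsError(Exception):
    """Base class for dynamics-layer errors."""


class IntegrationError(DynamicsError):
    """Numerical failure during integration (NaN/Inf or large excursion)."""


class ConvergenceError(DynamicsError):
    """A steady state required by the caller did not converge.

    Carries the partial results in ``baseline`` / ``perturbed``.
    """

    def __init__(self, message, baseline=None, perturbed=None):
        super().__init__(message)
        self.baseline = baseline
        self.perturbed = perturbed


@dataclasses.dataclass(frozen=True)
class NodeParameters:
    """Per-node kinetic parameters: sigmoid gain ``h`` and decay ``gamma``.

    Defaults (h=10, gamma=1) follow the reference parameterization; per-node
    overrides are keyed by node id.
    """

    h: float = 10.0
    gamma: float = 1.0
    h_overrides: Mapping[str, float] = dataclasses.field(default_factory=dict)
    gamma_overrides: Mapping[str, float] = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        values = [self.h, self.gamma]
        values += list(self.h_overrides.values())
        values += list(self.gamma_overrides.values())
        if any(v <= 0 for v in values):
            raise ValueError("h and gamma must be positive")

    def h_vector(self, node_ids) -> np.ndarray:
        return np.array([self.h_overrides.get(n, self.h) for n in node_ids])

    def gamma_vector(self, node_ids) -> np.ndarray:
        return np.array([self.gamma_overrides.get(n, self.gamma) for n in node_ids])


@dataclasses.dataclass(frozen=True)
class SolverConfig:
    """Steady-state solver settings.

    ``method`` is ``rk4_fixed`` (default) or ``adaptive`` (SciPy RK45).
    Convergence is declared when ``max|dx/dt| <= tol``; integration stops at
    ``t_max`` regardless.  ``excursion_tol`` bounds how far outside [0, 1]
    a component may step before clipping is considered an error.
    """

    method: str = "rk4_fixed"
    step: float = 0.01
    tol: float = 1e-6
    t_max: float = 100.0
    excursion_tol: float = 1e-6

    def __post_init__(self):
        if self.method not in ("rk4_fixed", "adaptive"):
            raise ValueError(f"unknown solver method {self.method!r}")
        if self.step <= 0 or self.tol <= 0 or self.t_max <= 0:
            raise ValueError("step, tol and t_max must be positive")


def _check_unit_interval(name: str, mapping: Mapping[str, float]) -> None:
    for node, value in mapping.items():
        if not (0.0 <= value <= 1.0):
            raise ValueError(f"{name}[{node!r}] = {value} outside [0, 1]")


@dataclasses.dataclass(frozen=True)
class PerturbationSpec:
    """Initial-condition overrides plus clamps (nodes held fixed)."""

    initial: Mapping[str, float] = dataclasses.field(default_factory=dict)
    clamps: Mapping[str, float] = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        _check_unit_interval("initial", self.initial)
        _check_unit_interval("clamps", self.clamps)
        overlap = set(self.initial) & set(self.clamps)
        if overlap:
            raise ValueError(
                f"nodes in both initial and clamps: {sorted(overlap)}"
            )
        object.__setattr__(self, "initial", dict(self.initial))
        object.__setattr__(self, "clamps", dict(self.clamps))

    @property
    def nodes(self) -> frozenset:
        return frozenset(self.initial) | frozenset(self.clamps)

    def is_empty(self) -> bool:
        return not self.initial and not self.clamps

    # -- string form used by dataset CSVs and the CLI -------------------
    def to_string(self) -> str:
        parts = [f"{n}={format(v, '.17g')}" for n, v in self.clamps.items()]
        parts += [f"init:{n}={format(v, '.17g')}" for n, v in self.initial.items()]
        return ";".join(parts)

    @classmethod
    def from_string(cls, text: str) -> "PerturbationSpec":
        initial: dict[str, float] = {}
        clamps: dict[str, float] = {}
        for token in filter(None, (t.strip() for t in text.split(";"))):
            if "=" not in token:
                raise ValueError(f"malformed perturbation token {token!r}")
            key, value = token.split("=", 1)
            if key.startswith("init:"):
                initial[key[len("init:"):]] = float(value)
            else:
                clamps[key] = float(value)
        return cls(initial=initial, clamps=clamps)


@dataclasses.dataclass(frozen=True)
class SteadyState:
    """Terminal state of an integration, with convergence metadata."""

    node_ids: tuple
    values: np.ndarray
    converged: bool
    residual: float
    t_end: float

    def __getitem__(self, node_id: str) -> float:
        return float(self.values[self.node_ids.index(node_id)])

    def as_dict(self) -> dict:
        return {n: float(v) for n, v in zip(self.node_ids, self.values)}


@dataclasses.dataclass(frozen=True)
class ResponseVector:
    """Per-node steady-state shift: perturbed minus baseline, in [-1, 1]."""

    node_ids: tuple
    delta: np.ndarray

    def __getitem__(self, node_id: str) -> float:
        return float(self.delta[self.node_ids.index(node_id)])

    def as_dict(self) -> dict:
        return {n: float(v) for n, v in zip(self.node_ids, self.delta)}


# ---------------------------------------------------------------------------
# Scalar operations (reference formulas)
# ---------------------------------------------------------------------------

def activation(omega, h):
    """Normalized sigmoid of the total input, vectorized over ``omega``."""
    omega = np.asarray(omega, dtype=float)
    if np.any(omega < -1e-9) or np.any(omega > 1 + 1e-9):
        raise ValueError(f"omega outside [0, 1]: {omega}")
    e_half = np.exp(0.5 * h)
    e_shift = np.exp(-h * (omega - 0.5))
    out = (-e_half + e_shift) / ((1.0 - e_half) * (1.0 + e_shift))
    return out if out.ndim else float(out)


def total_input(node: str, state: Mapping[str, float], net: RegulatoryNetwork) -> float:
    """Total input ``omega`` of ``node`` given regulator activation levels."""
    activators, inhibitors = net.regulators(node)
    if not activators and not inhibitors:
        raise ValueError(
            f"node {node!r} has no incoming edges; apply the source-node "
            "policy instead of calling total_input"
        )

    def block(regulators):
        total_w = sum(w for _, w in regulators)
        weighted = sum(w * float(state[src]) for src, w in regulators)
        return ((1.0 + total_w) / total_w) * (weighted / (1.0 + weighted))

    if activators and inhibitors:
        return block(activators) * (1.0 - block(inhibitors))
    if activators:
        return block(activators)
    return 1.0 - block(inhibitors)


# ---------------------------------------------------------------------------
# Compiled array form
# ---------------------------------------------------------------------------

class CompiledSystem:
    """Dense-matrix representation of a network for vectorized integration.

    ``wa[t, s]`` / ``wb[t, s]`` hold the activator / inhibitor weight of the
    edge ``s -> t``.  Construction order of the network defines the state
    ordering.
    """

    def __init__(
        self,
        net: RegulatoryNetwork,
        params: Optional[NodeParameters] = None,
        source_node_policy: str = "hold",
    ):
        if source_node_policy not in SOURCE_POLICIES:
            raise ValueError(
                f"source_node_policy must be one of {SOURCE_POLICIES}"
            )
        params = params or NodeParameters()
        self.net = net
        self.node_ids = net.node_ids
        self.index = {n: i for i, n in enumerate(self.node_ids)}
        n = len(self.node_ids)
        self.n = n
        self.wa = np.zeros((n, n))
        self.wb = np.zeros((n, n))
        for edge in net.edges:
            matrix = self.wa if edge.sign is Sign.ACTIVATION else self.wb
            matrix[self.index[edge.target], self.index[edge.source]] += edge.weight
        self.h = params.h_vector(self.node_ids)
        self.gamma = params.gamma_vector(self.node_ids)
        self.source_node_policy = source_node_policy
        self.source_mask = (self.wa.sum(axis=1) + self.wb.sum(axis=1)) == 0

    def perturbation_arrays(self, perturbation: Optional[PerturbationSpec],
                            default_initial: float = 0.0):
        """Build ``(x0, clamp_mask, clamp_values)`` for one perturbation."""
        x0 = np.full(self.n, float(default_initial))
        clamp_mask = np.zeros(self.n, dtype=bool)
        clamp_values = np.zeros(self.n)
        if perturbation is not None:
            for node, value in perturbation.initial.items():
                self._require(node)
                x0[self.index[node]] = value
            for node, value in perturbation.clamps.items():
                self._require(node)
                i = self.index[node]
                x0[i] = value
                clamp_mask[i] = True
                clamp_values[i] = value
        return x0, clamp_mask, clamp_values

    def _require(self, node: str) -> None:
        if node not in self.index:
            raise KeyError(f"unknown node id {node!r}")


def _batch_rhs(x, wa, wb, sum_a, sum_b, has_a, has_b, h, gamma, frozen,
               decay_only):
    """Vectorized dx/dt for a batch of states ``x`` of shape (B, N).

    ``wa``/``wb`` are either shared ``(N, N)`` matrices or per-row stacks
    ``(B, N, N)``; the remaining summaries match their leading shape.
    ``frozen`` marks components with derivative forced to zero (clamps and
    held source nodes); ``decay_only`` marks components following pure decay
    (source nodes under the ``decay`` policy).
    """
    if wa.ndim == 2:
        sa = x @ wa.T
        sb = x @ wb.T
    else:
        sa = np.einsum("bij,bj->bi", wa, x)
        sb = np.einsum("bij,bj->bi", wb, x)
    safe_a = np.where(has_a, sum_a, 1.0)
    safe_b = np.where(has_b, sum_b, 1.0)
    act_block = ((1.0 + sum_a) / safe_a) * (sa / (1.0 + sa))
    inh_block = ((1.0 + sum_b) / safe_b) * (sb / (1.0 + sb))
    omega = np.where(
        has_a & has_b,
        act_block * (1.0 - inh_block),
        np.where(has_a, act_block, np.where(has_b, 1.0 - inh_block, 0.0)),
    )
    e_half = np.exp(0.5 * h)
    e_shift = np.exp(-h * (omega - 0.5))
    phi = (-e_half + e_shift) / ((1.0 - e_half) * (1.0 + e_shift))
    regulated = has_a | has_b
    phi = np.where(regulated, phi, 0.0)
    dx = phi - gamma * x
    dx = np.where(frozen, 0.0, dx)
    if decay_only is not None:
        dx = np.where(decay_only, -gamma * x, dx)
    return dx


@dataclasses.dataclass
class _BatchResult:
    x: np.ndarray           # (B, N) final states
    converged: np.ndarray   # (B,) bool
    residual: np.ndarray    # (B,)
    t_end: np.ndarray       # (B,)


def _integrate_batch(
    wa, wb, h, gamma, x0, clamp_mask, clamp_values,
    solver: SolverConfig, source_node_policy: str, node_ids,
) -> _BatchResult:
    """Fixed-step RK4 over a batch of systems.

    A row is recorded (state, residual, time) the moment its residual drops
    below tolerance, so per-row results are independent of how the batch is
    composed; converged rows are periodically compacted away to keep the
    working set small.
    """
    x = np.array(x0, dtype=float)
    batch, n = x.shape
    if wa.ndim == 2:
        sum_a = wa.sum(axis=1)
        sum_b = wb.sum(axis=1)
    else:
        sum_a = wa.sum(axis=2)
        sum_b = wb.sum(axis=2)
    has_a = sum_a > 0
    has_b = sum_b > 0
    sources = ~(has_a | has_b)
    clamp_mask = np.broadcast_to(clamp_mask, (batch, n))
    clamp_values = np.broadcast_to(clamp_values, (batch, n))
    if source_node_policy == "hold":
        frozen = np.broadcast_to(clamp_mask | sources, (batch, n))
        decay_only = None
    else:
        frozen = clamp_mask
        decay_only = np.broadcast_to(sources & ~clamp_mask, (batch, n))
    # pin clamps from the start
    x = np.where(clamp_mask, clamp_values, x)

    # full-batch outputs
    x_out = x.copy()
    converged = np.zeros(batch, dtype=bool)
    residual = np.full(batch, np.inf)
    t_end = np.full(batch, solver.t_max)

    idx = np.arange(batch)          # working-row -> original-row map
    active = np.ones(batch, dtype=bool)

    def take(array, keep):
        if array is None:
            return None
        if array.ndim >= 2 and array.shape[0] == len(keep):
            return array[keep]
        return array  # shared across the batch

    dt = solver.step
    n_steps = int(np.ceil(solver.t_max / dt))
    t = 0.0
    for _ in range(n_steps):
        k1 = _batch_rhs(x, wa, wb, sum_a, sum_b, has_a, has_b, h, gamma,
                        frozen, decay_only)
        res = np.abs(k1).max(axis=1)
        if np.isnan(res).any():
            bad_row = int(np.where(np.isnan(res))[0][0])
            bad = int(np.where(~np.isfinite(k1[bad_row]))[0][0])
            raise IntegrationError(
                f"non-finite state/derivative at node {node_ids[bad]!r}"
            )
        newly = active & (res <= solver.tol)
        if newly.any():
            rows = idx[newly]
            converged[rows] = True
            residual[rows] = res[newly]
            t_end[rows] = t
            x_out[rows] = x[newly]
            active &= ~newly
        if not active.any():
            return _BatchResult(x_out, converged, residual, t_end)
        if (~active).sum() >= max(1, len(idx) // 4):
            keep = active
            idx = idx[keep]
            x = x[keep]
            k1 = k1[keep]
            wa, wb = take(wa, keep), take(wb, keep)
            if wa.ndim == 3:
                sum_a, sum_b = sum_a[keep], sum_b[keep]
                has_a, has_b = has_a[keep], has_b[keep]
            clamp_mask = clamp_mask[keep]
            clamp_values = clamp_values[keep]
            frozen = frozen[keep]
            decay_only = take(decay_only, keep)
            active = np.ones(len(idx), dtype=bool)

        def rhs_fn(state):
            return _batch_rhs(state, wa, wb, sum_a, sum_b, has_a, has_b, h,
                              gamma, frozen, decay_only)

        k2 = rhs_fn(x + 0.5 * dt * k1)
        k3 = rhs_fn(x + 0.5 * dt * k2)
        k4 = rhs_fn(x + dt * k3)
        x_new = x + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        excess = np.maximum(x_new - 1.0, -x_new)
        worst = excess.max(initial=0.0)
        if worst > solver.excursion_tol:
            flat = int(np.argmax(excess))
            raise IntegrationError(
                f"state excursion {worst:.3g} beyond [0, 1] at node "
                f"{node_ids[flat % n]!r}"
            )
        x_new = np.clip(x_new, 0.0, 1.0)
        x = np.where(clamp_mask, clamp_values, x_new)
        t += dt
    # rows still active at t_max: not converged
    k1 = _batch_rhs(x, wa, wb, sum_a, sum_b, has_a, has_b, h, gamma,
                    frozen, decay_only)
    res = np.abs(k1).max(axis=1)
    rows = idx[active]
    residual[rows] = res[active]
    t_end[rows] = t
    x_out[rows] = x[active]
    return _BatchResult(x_out, converged, residual, t_end)


def _integrate_adaptive(
    wa, wb, h, gamma, x0, clamp_mask, clamp_values,
    solver: SolverConfig, source_node_policy: str, node_ids,
) -> _BatchResult:
    """Adaptive RK45 alternative (single system), chunked convergence checks."""
    sum_a = wa.sum(axis=1)
    sum_b = wb.sum(axis=1)
    has_a = sum_a > 0
    has_b = sum_b > 0
    sources = ~(has_a | has_b)
    if source_node_policy == "hold":
        frozen = clamp_mask | sources
        decay_only = None
    else:
        frozen = clamp_mask
        decay_only = sources & ~clamp_mask

    clamp_mask = np.asarray(clamp_mask).reshape(-1)
    clamp_values = np.asarray(clamp_values).reshape(-1)

    def fun(_t, state):
        return _batch_rhs(state[None, :], wa, wb, sum_a, sum_b, has_a, has_b,
                          h, gamma, frozen, decay_only)[0]

    x = np.where(clamp_mask, clamp_values, np.array(x0, dtype=float).reshape(-1))
    t = 0.0
    chunk = 1.0
    converged = False
    residual = np.inf
    while t < solver.t_max:
        t_next = min(t + chunk, solver.t_max)
        sol = solve_ivp(fun, (t, t_next), x, method="RK45",
                        rtol=1e-9, atol=1e-11)
        if not sol.success:
            raise IntegrationError(f"adaptive solver failed: {sol.message}")
        x = sol.y[:, -1]
        if not np.all(np.isfinite(x)):
            bad = int(np.where(~np.isfinite(x))[0][0])
            raise IntegrationError(
                f"non-finite state/derivative at node {node_ids[bad]!r}"
            )
        x = np.clip(x, 0.0, 1.0)
        x = np.where(clamp_mask, clamp_values, x)
        t = t_next
        residual = float(np.abs(fun(t, x)).max()) if len(x) else 0.0
        if residual <= solver.tol:
            converged = True
            break
    return _BatchResult(
        x=x[None, :],
        converged=np.array([converged]),
        residual=np.array([residual]),
        t_end=np.array([t]),
    )


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def rhs(
    state: Mapping[str, float],
    net: RegulatoryNetwork,
    params: Optional[NodeParameters] = None,
    clamps: Optional[Mapping[str, float]] = None,
    source_node_policy: str = "hold",
) -> dict:
    """Per-node derivative dx/dt for a named state (reference entry point)."""
    system = CompiledSystem(net, params, source_node_policy)
    x = np.array([float(state[n]) for n in system.node_ids])[None, :]
    clamp_mask = np.zeros(system.n, dtype=bool)
    for node in clamps or {}:
        system._require(node)
        clamp_mask[system.index[node]] = True
    sum_a = system.wa.sum(axis=1)
    sum_b = system.wb.sum(axis=1)
    has_a = sum_a > 0
    has_b = sum_b > 0
    sources = ~(has_a | has_b)
    if source_node_policy == "hold":
        frozen = clamp_mask | sources
        decay_only = None
    else:
        frozen = clamp_mask
        decay_only = sources & ~clamp_mask
    dx = _batch_rhs(x, system.wa, system.wb, sum_a, sum_b, has_a, has_b,
                    system.h, system.gamma, frozen, decay_only)[0]
    return {n: float(v) for n, v in zip(system.node_ids, dx)}


def integrate_to_steady_state(
    net: RegulatoryNetwork,
    params: Optional[NodeParameters] = None,
    perturbation: Optional[PerturbationSpec] = None,
    solver: Optional[SolverConfig] = None,
    source_node_policy: str = "hold",
    default_initial: float = 0.0,
    _initial_vector: Optional[np.ndarray] = None,
) -> SteadyState:
    """Integrate until ``max|dx/dt| <= tol`` or ``t_max``; never raises on
    plain non-convergence (the flag is returned instead)."""
    solver = solver or SolverConfig()
    system = CompiledSystem(net, params, source_node_policy)
    x0, clamp_mask, clamp_values = system.perturbation_arrays(
        perturbation, default_initial
    )
    if _initial_vector is not None:
        x0 = np.where(clamp_mask, clamp_values, np.asarray(_initial_vector, float))
    integrator = (
        _integrate_adaptive if solver.method == "adaptive" else _integrate_batch
    )
    result = integrator(
        system.wa, system.wb, system.h, system.gamma,
        x0[None, :], clamp_mask[None, :], clamp_values[None, :],
        solver, source_node_policy, system.node_ids,
    )
    return SteadyState(
        node_ids=system.node_ids,
        values=result.x[0],
        converged=bool(result.converged[0]),
        residual=float(result.residual[0]),
        t_end=float(result.t_end[0]),
    )


def baseline(
    net: RegulatoryNetwork,
    params: Optional[NodeParameters] = None,
    seed: int = 0,
    solver: Optional[SolverConfig] = None,
    source_node_policy: str = "hold",
) -> SteadyState:
    """Unclamped steady state from a seeded random initial condition.

    Initial activations are i.i.d. uniform on [0, 1] drawn from a
    Mersenne-Twister generator (``numpy.random.RandomState(seed)``) in
    network node order; deterministic for a fixed seed.
    """
    if seed < 0:
        raise ValueError("seed must be >= 0")
    x0 = baseline_initial_condition(net, seed)
    return integrate_to_steady_state(
        net, params, perturbation=None, solver=solver,
        source_node_policy=source_node_policy, _initial_vector=x0,
    )


def baseline_initial_condition(net: RegulatoryNetwork, seed: int = 0) -> np.ndarray:
    """The seeded uniform initial condition used by :func:`baseline`."""
    rng = np.random.RandomState(seed)  # Mersenne Twister
    return rng.random_sample(len(net.node_ids))


def baseline_ensemble(
    net: RegulatoryNetwork,
    params: Optional[NodeParameters] = None,
    seeds=(0,),
    solver: Optional[SolverConfig] = None,
    source_node_policy: str = "hold",
) -> list:
    """Baselines for an ensemble of seeds (non-default multi-seed reading
    of the seeded-baseline convention); one SteadyState per seed."""
    return [
        baseline(net, params, seed=s, solver=solver,
                 source_node_policy=source_node_policy)
        for s in seeds
    ]


def response(
    net: RegulatoryNetwork,
    params: Optional[NodeParameters] = None,
    perturbation: Optional[PerturbationSpec] = None,
    seed: int = 0,
    solver: Optional[SolverConfig] = None,
    source_node_policy: str = "hold",
) -> ResponseVector:
    """Steady-state shift ``perturbed - baseline``; components in [-1, 1].

    The perturbed run starts regulated nodes at 0 (plus any explicit
    overrides); under the ``hold`` policy, unclamped source nodes inherit
    their baseline value — they are boundary inputs shared by the two runs.
    """
    base = baseline(net, params, seed=seed, solver=solver,
                    source_node_policy=source_node_policy)
    system = CompiledSystem(net, params, source_node_policy)
    x0, clamp_mask, _ = system.perturbation_arrays(perturbation)
    if source_node_policy == "hold":
        inherit = system.source_mask & ~clamp_mask
        if perturbation is not None:
            for node in perturbation.initial:
                inherit[system.index[node]] = False
        x0 = np.where(inherit, base.values, x0)
    perturbed = integrate_to_steady_state(
        net, params, perturbation=perturbation, solver=solver,
        source_node_policy=source_node_policy, _initial_vector=x0,
    )
    if not base.converged or not perturbed.converged:
        raise ConvergenceError(
            "steady state did not converge "
            f"(baseline converged={base.converged}, "
            f"perturbed converged={perturbed.converged})",
            baseline=base,
            perturbed=perturbed,
        )
    return ResponseVector(
        node_ids=base.node_ids, delta=perturbed.values - base.values
    )
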