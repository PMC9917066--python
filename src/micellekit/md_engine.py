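"""Langevin dynamics integration and energy minimization.

The equation of motion is underdamped Langevin dynamics,

    m x'' = f - gamma v + sqrt(2 gamma kBT) eta(t),

with unit bead masses, white noise ``<eta> = 0``,
``<eta_i(t) eta_j(t')> = delta_ij delta(t - t')``, and conservative forces
``f`` from :mod:`micellekit.force_field`.  The discretization is the BAOAB
splitting: velocity-Verlet half-kicks and half-drifts around an exact
one-step Ornstein-Uhlenbeck velocity update.  This samples the canonical
distribution accurately at the working time step ``dt = 0.01`` with
friction of order 1, and reduces *exactly* to velocity Verlet when
``gamma = 0`` (which is how the integrator is validated against energy
conservation).

Beads marked in ``frozen_mask`` are pinned: their forces and velocities are
zeroed every substep, they never move, and they are excluded from kinetic
energy / temperature estimators.  The two-stage relaxation of the micelle
protocol uses this to equilibrate the hydrophobic core under a fixed
corona scaffold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, TYPE_CHECKING

import numpy as np

from .force_field import ForceFieldParams, compute_forces_energies

if TYPE_CHECKING:  # pragma: no cover
    from .polymer_topology import Topology

__all__ = [
    "SimulationError",
    "SystemState",
    "IntegratorParams",
    "Trajectory",
    "maxwell_boltzmann_velocities",
    "kinetic_temperature",
    "langevin_step",
    "run_md",
    "steepest_descent",
]


class SimulationError(RuntimeError):
    """Non-finite positions or a failed minimization."""


@dataclass
class SystemState:
    """Positions, velocities and the simulation region.

    ``R_conf`` is the radius of the spherical confining wall (open
    boundaries when ``None``).  All bead masses are 1.
    """

    positions: np.ndarray            # (N, 3) float64
    velocities: np.ndarray = None    # (N, 3) float64, zeros by default
    time: float = 0.0
    R_conf: float | None = None

    def __post_init__(self) -> None:
        # always copy: states evolve in place and must not alias caller data
        self.positions = np.array(self.positions, dtype=np.float64, order="C")
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (N, 3)")
        if self.velocities is None:
            self.velocities = np.zeros_like(self.positions)
        else:
            self.velocities = np.array(
                self.velocities, dtype=np.float64, order="C"
            )
            if self.velocities.shape != self.positions.shape:
                raise ValueError("velocities shape must match positions")

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "SystemState":
        return SystemState(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            time=self.time,
            R_conf=self.R_conf,
        )


@dataclass(frozen=True)
class IntegratorParams:
    """Langevin integrator knobs: friction ``gamma``, ``kBT``, ``dt``, seed.

    ``gamma = 1`` is the package default (standard for Kremer-Grest reduced
    units; equilibrium observables do not depend on it), ``dt = 0.01`` is
    the working time step of the model.
    """

    gamma: float = 1.0
    kBT: float = 1.0
    dt: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")

    def with_(self, **kwargs) -> "IntegratorParams":
        return replace(self, **kwargs)


@dataclass
class Trajectory:
    """In-memory frame store produced by :func:`run_md`."""

    times: list = field(default_factory=list)
    positions: list = field(default_factory=list)   # (N, 3) copies
    energies: list = field(default_factory=list)    # term dicts

    def __len__(self) -> int:
        return len(self.times)


def maxwell_boltzmann_velocities(
    n: int, kBT: float, rng: np.random.Generator
) -> np.ndarray:
    """Thermal velocities for unit masses at temperature ``kBT``."""
    return math.sqrt(kBT) * rng.standard_normal((n, 3))


def kinetic_temperature(
    velocities: np.ndarray, free_mask: np.ndarray | None = None
) -> float:
    """Instantaneous kinetic temperature ``2 KE / (3 N_free)``."""
    v = velocities if free_mask is None else velocities[free_mask]
    if v.shape[0] == 0:
        return 0.0
    return float(np.sum(v * v) / (3.0 * v.shape[0]))


def _ou_coefficients(gamma: float, dt: float) -> tuple[float, float]:
    """Exact one-step OU decay/noise amplitudes for the O substep."""
    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt(max(0.0, 1.0 - c1 * c1))
    return c1, c2


def langevin_step(
    state: SystemState,
    topo: "Topology",
    ff: ForceFieldParams,
    ip: IntegratorParams,
    rng: np.random.Generator,
    frozen_mask: np.ndarray | None = None,
    cached_forces: np.ndarray | None = None,
    extra_force: Callable[[np.ndarray], np.ndarray] | None = None,
) -> np.ndarray:
    """Advance the state by one BAOAB step in place.

    Returns the forces at the new positions (pass them back as
    ``cached_forces`` to avoid recomputation).  ``extra_force`` adds an
    arbitrary external force field (e.g. a harmonic trap in tests).
    Bit-reproducible for a fixed ``rng`` stream.
    """
    x, v = state.positions, state.velocities
    dt = ip.dt
    if cached_forces is None:
        cached_forces = _eval_forces(state, topo, ff, extra_force)
    f = cached_forces
    if frozen_mask is not None:
        f[frozen_mask] = 0.0
        v[frozen_mask] = 0.0
    v += 0.5 * dt * f
    x += 0.5 * dt * v
    c1, c2 = _ou_coefficients(ip.gamma, dt)
    if ip.gamma > 0:
        noise = rng.standard_normal(x.shape)
        v *= c1
        v += c2 * math.sqrt(ip.kBT) * noise
        if frozen_mask is not None:
            v[frozen_mask] = 0.0
    x += 0.5 * dt * v
    f = _eval_forces(state, topo, ff, extra_force)
    if frozen_mask is not None:
        f[frozen_mask] = 0.0
    v += 0.5 * dt * f
    if frozen_mask is not None:
        v[frozen_mask] = 0.0
    state.time += dt
    return f


def _eval_forces(state, topo, ff, extra_force=None):
    f, _ = compute_forces_energies(
        state.positions, topo, ff, R_conf=state.R_conf
    )
    if extra_force is not None:
        f = f + extra_force(state.positions)
    return f


def run_md(
    state: SystemState,
    topo: "Topology",
    ff: ForceFieldParams,
    ip: IntegratorParams,
    n_steps: int,
    frozen_mask: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    sample_stride: int = 0,
    extra_force: Callable[[np.ndarray], np.ndarray] | None = None,
    store_positions: bool = True,
) -> tuple[SystemState, Trajectory]:
    """Integrate ``n_steps`` of Langevin dynamics.

    Frames (time, positions copy, energy decomposition) are recorded every
    ``sample_stride`` steps (0 disables sampling).  Positions are checked
    for NaN/overflow at every sample and the run aborts with a diagnostic.
    The input state is evolved in place and also returned.
    """
    if rng is None:
        rng = np.random.default_rng(ip.seed)
    traj = Trajectory()
    f = None
    for step in range(1, n_steps + 1):
        f = langevin_step(
            state, topo, ff, ip, rng,
            frozen_mask=frozen_mask, cached_forces=f,
            extra_force=extra_force,
        )
        if sample_stride and step % sample_stride == 0:
            if not np.all(np.isfinite(state.positions)):
                raise SimulationError(
                    f"non-finite positions at t={state.time:.3f} "
                    f"(step {step})"
                )
            _, terms = compute_forces_energies(
                state.positions, topo, ff, R_conf=state.R_conf
            )
            free = (
                None if frozen_mask is None else ~frozen_mask
            )
            v = state.velocities if free is None else state.velocities[free]
            terms["kinetic"] = float(0.5 * np.sum(v * v))
            traj.times.append(state.time)
            if store_positions:
                traj.positions.append(state.positions.copy())
            traj.energies.append(terms)
    if not np.all(np.isfinite(state.positions)):
        raise SimulationError(f"non-finite positions at t={state.time:.3f}")
    return state, traj


def steepest_descent(
    state: SystemState,
    topo: "Topology",
    ff: ForceFieldParams,
    max_steps: int = 3000,
    force_tol: float = 10.0,
    max_displacement: float = 0.01,
) -> tuple[SystemState, dict]:
    """Remove particle overlaps by force-capped steepest descent.

    Each step moves every bead along its force, with the largest single
    displacement capped at ``max_displacement`` (in sigma).  A trial step
    that raises the potential energy is rejected and the step size halved
    (backtracking); an accepted step grows it again up to the cap, so the
    accepted energy trace is non-increasing.  Terminates when the maximum
    per-bead force drops below ``force_tol``.

    Returns ``(state, info)``; ``info['converged']`` reports success —
    callers decide whether a non-converged minimization is fatal.  FENE
    bonds are kept intact by capping displacements well below ``r_inf``.
    """
    pos = state.positions
    f, terms = compute_forces_energies(pos, topo, ff, R_conf=state.R_conf)
    energy = terms["potential"]
    step_size = max_displacement
    n_steps = 0
    for n_steps in range(1, max_steps + 1):
        fmax = float(np.max(np.abs(f))) if f.size else 0.0
        if fmax < force_tol:
            break
        moved = False
        while step_size > 1e-12:
            trial = pos + f * (step_size / fmax)
            try:
                f_new, terms_new = compute_forces_energies(
                    trial, topo, ff, R_conf=state.R_conf
                )
            except Exception:
                step_size *= 0.5
                continue
            # descend on infinite/overflowed energies unconditionally
            if (not math.isfinite(energy)) or (
                terms_new["potential"] <= energy
            ):
                pos[:] = trial
                energy = terms_new["potential"]
                f = f_new
                step_size = min(step_size * 1.1, max_displacement)
                moved = True
                break
            step_size *= 0.5
        if not moved:
            break
    fmax = float(np.max(np.abs(f))) if f.size else 0.0
    info = {
        "converged": bool(fmax < force_tol),
        "steps": n_steps,
        "max_force": fmax,
        "potential": energy,
    }
    return state, info
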