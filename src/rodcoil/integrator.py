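"""Langevin (implicit-solvent Brownian) dynamics at fixed temperature.

Each bead obeys  m dv/dt = F - Gamma0 v + W(t)  with Gaussian noise W tied to
the friction by the fluctuation-dissipation relation, so the canonical
distribution at temperature T (k_B = 1) is stationary.  The equations are
integrated with the BAOAB velocity-Verlet/Langevin splitting, in which the
Ornstein-Uhlenbeck (O) substep is solved exactly; this keeps equipartition
accurate even for the stiff k = 10^4 springs of the rod blocks.  An
overdamped (inertialess Euler-Maruyama) scheme is available as an option.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .model import ForceField, MixtureComposition, SystemState, build_mixture
from .potentials import NeighborList, _bonded_kernel, _pair_kernel


class IntegrationError(RuntimeError):
    """Raised when the dynamics produce non-finite coordinates."""


@dataclass
class RunParams:
    """Time stepping, thermostat and bookkeeping parameters of one run.

    Defaults are the production values (dt = 0.004, T = 3.0, Gamma0 = 1.0);
    ``n_steps`` defaults to a desk-scale 10^5 (the production scale is
    5 x 10^6 steps, i.e. 20000 time units).
    """

    dt: float = 0.004
    n_steps: int = 100_000
    temperature: float = 3.0
    friction: float = 1.0
    seed: int = 0
    skin: float = 0.4
    snapshot_interval: int = 2000
    scheme: str = "baoab"  # or "overdamped"

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.temperature < 0 or self.friction <= 0:
            raise ValueError("dt and friction must be positive, temperature >= 0")
        if self.n_steps < 0 or self.snapshot_interval <= 0:
            raise ValueError("n_steps >= 0 and snapshot_interval > 0 required")
        if self.scheme not in ("baoab", "overdamped"):
            raise ValueError(f"unknown scheme {self.scheme!r}")

    @property
    def total_time(self) -> float:
        return self.dt * self.n_steps


@dataclass
class Trajectory:
    """Time-ordered configuration snapshots plus run metadata."""

    template: SystemState          # topology/species carrier; final state
    steps: list[int] = field(default_factory=list)
    positions: list[np.ndarray] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.steps)

    @property
    def box_length(self) -> float:
        return self.template.box_length

    def frame(self, index: int) -> SystemState:
        """A SystemState view of one stored frame (zeroed velocities)."""
        pos = self.positions[index]
        return SystemState(
            pos.copy(),
            np.zeros_like(pos),
            self.template.species,
            self.template.chain_id,
            self.template.box_length,
            self.template.topology,
            self.template.masses,
        )

    def append(self, step: int, positions: np.ndarray) -> None:
        self.steps.append(step)
        self.positions.append(positions.copy())


@njit(cache=True)
def _baoab_step(
    pos, vel, forces, inv_m, c1, c2, dt, box,
    bonds, bond_r0, kb2, angles, ka2, cos0,
    pi, pj, pair_eps, pair_rc2, pair_shift, sigma2, noise,
):
    """One BAOAB step in place; returns the potential energy at the new positions."""
    n = pos.shape[0]
    half = 0.5 * dt
    for i in range(n):
        for k in range(3):
            vel[i, k] += half * forces[i, k] * inv_m[i]
            pos[i, k] += half * vel[i, k]
    for i in range(n):
        for k in range(3):
            vel[i, k] = c1[i] * vel[i, k] + c2[i] * noise[i, k]
            pos[i, k] += half * vel[i, k]
    for i in range(n):
        for k in range(3):
            pos[i, k] -= box * np.floor(pos[i, k] / box)
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    energy = _bonded_kernel(pos, box, bonds, bond_r0, kb2, angles, ka2, cos0, forces)
    energy += _pair_kernel(pos, box, pi, pj, pair_eps, pair_rc2, pair_shift, sigma2, forces)
    for i in range(n):
        for k in range(3):
            vel[i, k] += half * forces[i, k] * inv_m[i]
    return energy


@njit(cache=True)
def _overdamped_step(
    pos, forces, dt, gamma, box,
    bonds, bond_r0, kb2, angles, ka2, cos0,
    pi, pj, pair_eps, pair_rc2, pair_shift, sigma2, noise, noise_amp,
):
    """One Euler-Maruyama Brownian step: dx = F dt / Gamma + sqrt(2T dt/Gamma) xi."""
    n = pos.shape[0]
    for i in range(n):
        for k in range(3):
            pos[i, k] += forces[i, k] * dt / gamma + noise_amp * noise[i, k]
            pos[i, k] -= box * np.floor(pos[i, k] / box)
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    energy = _bonded_kernel(pos, box, bonds, bond_r0, kb2, angles, ka2, cos0, forces)
    energy += _pair_kernel(pos, box, pi, pj, pair_eps, pair_rc2, pair_shift, sigma2, forces)
    return energy


class _Driver:
    """Holds the compiled-kernel arguments of one running system."""

    def __init__(self, state: SystemState, ff: ForceField, params: RunParams):
        self.state = state
        self.ff = ff
        self.params = params
        self.neighbors = NeighborList(ff, skin=params.skin)
        self.kb2 = 2.0 * ff.bond_prefactor * ff.k_bond
        self.ka2 = 2.0 * ff.angle_prefactor * ff.k_angle
        self.cos0 = math.cos(ff.theta0)
        m = state.masses
        self.inv_m = 1.0 / m
        g_dt = params.friction * params.dt / m
        self.c1 = np.exp(-g_dt)
        self.c2 = np.sqrt(params.temperature * (1.0 - self.c1**2) / m)
        self.noise_amp = math.sqrt(
            2.0 * params.temperature * params.dt / params.friction
        )
        omega_dt = params.dt * math.sqrt(ff.k_bond / m.min())
        if params.scheme == "baoab" and omega_dt > 0.5:
            warnings.warn(
                f"stiff-spring resolution is marginal (omega*dt = {omega_dt:.2f}); "
                "consider a smaller dt",
                RuntimeWarning,
                stacklevel=3,
            )
        self.neighbors.build(state)
        self.forces, self.energy = self._fresh_forces()

    def _fresh_forces(self):
        forces = np.zeros_like(self.state.positions)
        s, t = self.state, self.state.topology
        energy = _bonded_kernel(
            s.positions, s.box_length, t.bonds, t.bond_r0, self.kb2,
            t.angles, self.ka2, self.cos0, forces,
        )
        nb = self.neighbors
        energy += _pair_kernel(
            s.positions, s.box_length, nb.pi, nb.pj,
            nb.pair_eps, nb.pair_rc2, nb.pair_shift, self.ff.sigma**2, forces,
        )
        return forces, energy

    _CHECK_INTERVAL = 100  # steps between full finiteness/runaway checks

    def step(self, rng: np.random.Generator, step_index: int) -> float:
        s, t, p = self.state, self.state.topology, self.params
        if self.neighbors.is_stale(s):
            self.neighbors.build(s)
        noise = rng.standard_normal(s.positions.shape)
        nb = self.neighbors
        if p.scheme == "baoab":
            energy = _baoab_step(
                s.positions, s.velocities, self.forces, self.inv_m,
                self.c1, self.c2, p.dt, s.box_length,
                t.bonds, t.bond_r0, self.kb2, t.angles, self.ka2, self.cos0,
                nb.pi, nb.pj, nb.pair_eps, nb.pair_rc2, nb.pair_shift,
                self.ff.sigma**2, noise,
            )
        else:
            energy = _overdamped_step(
                s.positions, self.forces, p.dt, p.friction, s.box_length,
                t.bonds, t.bond_r0, self.kb2, t.angles, self.ka2, self.cos0,
                nb.pi, nb.pj, nb.pair_eps, nb.pair_rc2, nb.pair_shift,
                self.ff.sigma**2, noise, self.noise_amp,
            )
        if not math.isfinite(energy):
            raise IntegrationError(
                f"non-finite energy at step {step_index}; the dynamics are unstable "
                f"(dt = {p.dt}, k_bond = {self.ff.k_bond})"
            )
        if step_index % self._CHECK_INTERVAL == 0:
            if not (
                np.all(np.isfinite(s.positions)) and np.all(np.isfinite(s.velocities))
            ):
                raise IntegrationError(
                    f"non-finite coordinates or velocities at step {step_index}"
                )
            t_kin = kinetic_temperature(s)
            if t_kin > max(1e6, 1e4 * max(p.temperature, 1e-12)):
                raise IntegrationError(
                    f"runaway kinetic temperature {t_kin:.3g} at step {step_index}; "
                    f"the dynamics are unstable (dt = {p.dt}, k_bond = {self.ff.k_bond})"
                )
        self.energy = energy
        return energy


def langevin_step(
    state: SystemState,
    ff: ForceField,
    params: RunParams,
    rng: np.random.Generator,
    driver: _Driver | None = None,
) -> SystemState:
    """Advance ``state`` by one Langevin step in place and return it.

    For multi-step runs prefer :func:`run`, which reuses the neighbor list
    and force buffers across steps.
    """
    if driver is None:
        driver = _Driver(state, ff, params)
    driver.step(rng, 0)
    return state


def kinetic_temperature(state: SystemState) -> float:
    """Instantaneous kinetic temperature 2 KE / (3 N) with k_B = 1."""
    n = state.n_beads
    if n == 0:
        raise ValueError("empty system has no temperature")
    ke = 0.5 * float(np.sum(state.masses[:, None] * state.velocities**2))
    return 2.0 * ke / (3.0 * n)


def run(
    system: SystemState | MixtureComposition,
    ff: ForceField,
    params: RunParams,
    box_length: float = 150.0,
) -> Trajectory:
    """Integrate a system for ``params.n_steps`` steps, collecting snapshots.

    ``system`` may be a ready SystemState or a MixtureComposition (built
    deterministically from ``params.seed``).  Snapshots are stored every
    ``params.snapshot_interval`` steps plus the initial and final frames.
    The trajectory metadata records the run parameters and a potential-energy
    series for equilibration diagnostics.
    """
    if isinstance(system, MixtureComposition):
        state = build_mixture(
            system, ff, box_length=box_length, seed=params.seed,
            temperature=params.temperature,
        )
    else:
        state = system.copy()
    rng = np.random.default_rng(params.seed)
    driver = _Driver(state, ff, params)
    traj = Trajectory(
        template=state,
        metadata={
            "seed": params.seed,
            "dt": params.dt,
            "n_steps": params.n_steps,
            "temperature": params.temperature,
            "friction": params.friction,
            "scheme": params.scheme,
            "eps_rr": ff.eps_rr,
            "total_time": params.total_time,
            "potential_energy": [],
            "kinetic_temperature": [],
            "energy_steps": [],
        },
    )

    def record(step_index: int) -> None:
        traj.append(step_index, state.positions)
        traj.metadata["potential_energy"].append(driver.energy)
        traj.metadata["kinetic_temperature"].append(kinetic_temperature(state))
        traj.metadata["energy_steps"].append(step_index)

    record(0)
    for step_index in range(1, params.n_steps + 1):
        driver.step(rng, step_index)
        if step_index % params.snapshot_interval == 0 or step_index == params.n_steps:
            if traj.steps[-1] != step_index:
                record(step_index)
    return traj


__all__ = [
    "RunParams",
    "Trajectory",
    "IntegrationError",
    "langevin_step",
    "kinetic_temperature",
    "run",
]
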