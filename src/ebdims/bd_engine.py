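"""Langevin (Brownian-thermostatted) dynamics of the Cα spring network.

The equation of motion per bead,

    m r̈ = F(r) − γ m ṙ + ξ(t),     ⟨ξ(t)ξ(t′)⟩ = 2 γ m k_B T δ(t−t′),

is integrated with the BBK discretization of velocity Verlet: one Gaussian
random force per step enters both half-kicks, which makes the free-particle
stationary kinetic temperature exactly T at any γΔt (discrete
fluctuation–dissipation).  Friction and noise together act as a thermostat;
there is no separate velocity rescaling.

Units: Å, fs, Da, kcal·mol⁻¹; the friction coefficient is given in ps⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .constants import ACC_CONV, KB, RESIDUE_MASS
from .enm import ENMTopology, potential_energy
from .structures import CAModel, Trajectory

try:
    from numba import njit
    _HAVE_NUMBA = True
except ImportError:      # pragma: no cover - numba is a hard dependency
    _HAVE_NUMBA = False

__all__ = [
    "BDParams",
    "SimState",
    "SimulationBlowupError",
    "init_state",
    "langevin_step",
    "integrate",
    "run_unbiased",
    "kinetic_temperature",
    "maxwell_velocities",
]


class SimulationBlowupError(RuntimeError):
    """Coordinates or velocities left the sanity range."""


@dataclass
class BDParams:
    """Integrator parameters.

    dt : fs;  temperature : K;  gamma : ps⁻¹ (friction rate γ, i.e. the
    velocity relaxation rate γ = ζ/m);  mass : Da per residue.
    """

    dt: float = 1.0
    temperature: float = 300.0
    gamma: float = 50.0
    mass: float = RESIDUE_MASS
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0 or self.temperature < 0 or self.gamma < 0 or self.mass <= 0:
            raise ValueError("invalid BD parameters")

    @property
    def gamma_fs(self) -> float:
        return self.gamma * 1e-3

    @property
    def noise_sd(self) -> float:
        """Per-component random acceleration std-dev, Å·fs⁻² per step."""
        if self.gamma == 0 or self.temperature == 0:
            return 0.0
        return float(np.sqrt(2.0 * self.gamma_fs * KB * self.temperature
                             * ACC_CONV / (self.mass * self.dt)))


@dataclass
class SimState:
    """Instantaneous dynamical state (coordinates Å, velocities Å·fs⁻¹)."""

    coords: np.ndarray
    velocities: np.ndarray
    step: int
    rng: np.random.Generator

    def copy(self) -> "SimState":
        # the generator is shared on purpose: a restored checkpoint keeps
        # consuming the same noise stream (retries explore new branches)
        return replace(self, coords=self.coords.copy(),
                       velocities=self.velocities.copy())


def maxwell_velocities(n: int, params: BDParams,
                       rng: np.random.Generator) -> np.ndarray:
    """Maxwell–Boltzmann velocities at the bath temperature."""
    sd = np.sqrt(KB * params.temperature * ACC_CONV / params.mass)
    return rng.standard_normal((n, 3)) * sd


def init_state(model: CAModel, params: BDParams) -> SimState:
    rng = np.random.default_rng(params.seed)
    v = maxwell_velocities(model.n_residues, params, rng)
    return SimState(model.coords.copy(), v, 0, rng)


def kinetic_temperature(velocities: np.ndarray, mass: float = RESIDUE_MASS) -> float:
    """Instantaneous kinetic temperature, K (3N degrees of freedom)."""
    v2 = float(np.mean(np.sum(np.asarray(velocities) ** 2, axis=1)))
    return v2 * mass / (3.0 * KB * ACC_CONV)


# ---------------------------------------------------------------------------
# BBK kernel.  The same body is compiled with numba when available and used
# as plain Python otherwise, so both paths are bit-identical.

def _bbk_kernel(coords, vels, pi, pj, kk, d0, noise, dt, gamma_fs, acc_scale):
    n = coords.shape[0]
    n_pairs = pi.shape[0]
    c = 0.5 * gamma_fs * dt
    acc = np.zeros((n, 3))
    for p in range(n_pairs):
        i, j = pi[p], pj[p]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        f = -2.0 * kk[p] * (d - d0[p]) / d * acc_scale
        acc[i, 0] += f * dx
        acc[i, 1] += f * dy
        acc[i, 2] += f * dz
        acc[j, 0] -= f * dx
        acc[j, 1] -= f * dy
        acc[j, 2] -= f * dz
    for t in range(noise.shape[0]):
        for i in range(n):
            for x in range(3):
                vh = (1.0 - c) * vels[i, x] + 0.5 * dt * (acc[i, x] + noise[t, i, x])
                vels[i, x] = vh
                coords[i, x] += dt * vh
        acc[:] = 0.0
        for p in range(n_pairs):
            i, j = pi[p], pj[p]
            dx = coords[i, 0] - coords[j, 0]
            dy = coords[i, 1] - coords[j, 1]
            dz = coords[i, 2] - coords[j, 2]
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            if d == 0.0:
                return t
            f = -2.0 * kk[p] * (d - d0[p]) / d * acc_scale
            acc[i, 0] += f * dx
            acc[i, 1] += f * dy
            acc[i, 2] += f * dz
            acc[j, 0] -= f * dx
            acc[j, 1] -= f * dy
            acc[j, 2] -= f * dz
        for i in range(n):
            for x in range(3):
                vels[i, x] = (vels[i, x] + 0.5 * dt * (acc[i, x] + noise[t, i, x])) \
                    / (1.0 + c)
        bad = False
        for i in range(n):
            for x in range(3):
                if not np.isfinite(coords[i, x]) or abs(coords[i, x]) > 1e6:
                    bad = True
        if bad:
            return t
    return -1


if _HAVE_NUMBA:
    _bbk_kernel = njit(cache=True)(_bbk_kernel)


def integrate(state: SimState, topology: ENMTopology, params: BDParams,
              n_steps: int) -> SimState:
    """Advance ``n_steps`` BBK steps in place and return the state.

    The Gaussian random forces for the whole block are drawn up front from
    the state's generator, so a block of n steps consumes exactly the same
    noise stream as n single steps.
    """
    noise = state.rng.standard_normal((n_steps, len(state.coords), 3)) \
        * params.noise_sd
    bad = _bbk_kernel(state.coords, state.velocities,
                      topology.pairs[:, 0].astype(np.int64),
                      topology.pairs[:, 1].astype(np.int64),
                      topology.K, topology.d0, noise,
                      params.dt, params.gamma_fs, ACC_CONV / params.mass)
    if bad >= 0:
        raise SimulationBlowupError(
            f"numerical blow-up at step {state.step + bad + 1}")
    state.step += n_steps
    return state


def langevin_step(state: SimState, topology: ENMTopology,
                  params: BDParams) -> SimState:
    """One BBK velocity-Verlet update (friction, spring and random forces)."""
    return integrate(state, topology, params, 1)


def run_unbiased(model: CAModel, topology: ENMTopology, params: BDParams,
                 n_steps: int, stride: int = 100,
                 remove_com: bool = False) -> tuple[Trajectory, pd.DataFrame]:
    """Free (unbiased) thermostatted dynamics from ``model``.

    Returns every ``stride``-th frame plus a per-frame log of step index,
    kinetic temperature and potential energy.  With ``remove_com`` the
    centre-of-mass drift and mean velocity are removed at each checkpoint;
    forces, friction and noise are per-particle, so internal (pairwise
    distance) dynamics are unaffected.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    state = init_state(model, params)
    com0 = model.coords.mean(axis=0)
    frames, steps, temps, pots = [], [], [], []
    done = 0
    while done < n_steps:
        block = min(stride, n_steps - done)
        integrate(state, topology, params, block)
        done += block
        if remove_com:
            state.coords += com0 - state.coords.mean(axis=0)
            state.velocities -= state.velocities.mean(axis=0)
        frames.append(state.coords.copy())
        steps.append(state.step)
        temps.append(kinetic_temperature(state.velocities, params.mass))
        pots.append(potential_energy(topology, state.coords))
    log = pd.DataFrame({"step": steps, "temperature": temps,
                        "potential": pots})
    return Trajectory(np.asarray(frames), np.asarray(steps)), log
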