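"""Thermal sampling of the EVB mapping potential across the FEP schedule.

The protocol mirrors standard EVB/FEP practice: the system is equilibrated
at lambda = 0, each replica redraws Maxwell-Boltzmann velocities from its own
seed, relaxes briefly, and then walks the lambda schedule window by window,
carrying its configuration forward.  Within each window a BAOAB Langevin
integrator samples the mapping potential; recorded samples (after discarding
an equilibration fraction) are converted to diabatic, mapping and adiabatic
ground-state energies.

All randomness is derived from ``FEPSchedule.base_seed`` through
``numpy.random.SeedSequence`` spawn keys, so a run is a pure function of
(system, schedule, restraints, replicas).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from . import _kernel
from .constants import KB, KCAL_TO_INTERNAL
from .core import Configuration, EVBSystem, adiabatic_ground_energy, diabatic_energy, mapping_energy
from .free_energy import FEPFrame

__all__ = [
    "FEPSchedule",
    "RestraintSet",
    "ReplicaSpec",
    "DynamicsDivergenceError",
    "default_restraints",
    "equilibrate",
    "sample_window",
    "run_fep",
]

logger = logging.getLogger(__name__)


class DynamicsDivergenceError(RuntimeError):
    """Raised when sampled energies exceed the configured divergence cap."""


@dataclass
class FEPSchedule:
    """The lambda schedule and integrator settings of one FEP run.

    Defaults follow the 51-step protocol with 2% product-character increments;
    each window runs 20,000 BAOAB steps of 0.5 fs (10 ps) with friction
    1 ps^-1, recording every 10th step and discarding the first 10% of the
    recorded samples as intra-window equilibration.
    """

    n_windows: int = 51
    lambdas: tuple[float, ...] | None = None
    steps_per_window: int = 20_000
    equilibration_fraction: float = 0.1
    timestep: float = 0.5  # fs
    friction: float = 1.0  # 1/ps
    base_seed: int = 0
    sample_stride: int = 10
    divergence_cap: float = 1.0e5  # kcal/mol

    def __post_init__(self) -> None:
        if self.lambdas is None:
            self.lambdas = tuple(np.linspace(0.0, 1.0, self.n_windows))
        else:
            self.lambdas = tuple(float(x) for x in self.lambdas)
        lams = np.asarray(self.lambdas)
        if len(lams) != self.n_windows:
            raise ValueError("n_windows must equal len(lambdas)")
        if lams[0] != 0.0 or lams[-1] != 1.0 or np.any(np.diff(lams) <= 0):
            raise ValueError("lambdas must increase strictly from 0 to 1")
        if self.steps_per_window <= 0:
            raise ValueError("steps_per_window must be > 0")
        if not 0.0 <= self.equilibration_fraction < 1.0:
            raise ValueError("equilibration_fraction must lie in [0, 1)")
        if self.timestep <= 0 or self.friction < 0:
            raise ValueError("timestep must be > 0 and friction >= 0")
        if self.sample_stride <= 0 or self.sample_stride > self.steps_per_window:
            raise ValueError("sample_stride must be in [1, steps_per_window]")

    def to_dict(self) -> dict:
        return {
            "n_windows": self.n_windows,
            "steps_per_window": self.steps_per_window,
            "equilibration_fraction": self.equilibration_fraction,
            "timestep_fs": self.timestep,
            "friction_per_ps": self.friction,
            "base_seed": self.base_seed,
            "sample_stride": self.sample_stride,
        }


@dataclass
class RestraintSet:
    """Harmonic positional restraints: (coordinate index, center, k)."""

    terms: tuple[tuple[int, float, float], ...] = ()

    def __post_init__(self) -> None:
        for idx, _center, k in self.terms:
            if k < 0:
                raise ValueError(f"restraint force constant on coordinate {idx} must be >= 0")

    def combined(self, ndim: int) -> tuple[np.ndarray, np.ndarray]:
        """Collapse per-coordinate harmonics into one (k, center) pair each."""
        ks = np.zeros(ndim)
        kc = np.zeros(ndim)
        for idx, center, k in self.terms:
            ks[idx] += k
            kc[idx] += k * center
        centers = np.where(ks > 0, kc / np.where(ks > 0, ks, 1.0), 0.0)
        return ks, centers


def default_restraints(system: EVBSystem, k: float = 0.5) -> RestraintSet:
    """Weak positional restraints on the reacting coordinates.

    The transfer coordinate is tethered at the midpoint between the two bond
    minima (the bias across the ~0.5 Å well separation is ~0.01 kcal/mol at
    the default k = 0.5 kcal/(mol Å^2)); in the gas phase, where the solvent
    coordinate is decoupled from both states, it is tethered at zero to keep
    it bounded.
    """
    R = system.coordinate_spec.donor_acceptor_R
    mid = 0.5 * (system.state1.bond_r0 + (R - system.state2.bond_r0))
    terms = [(0, mid, k)]
    if system.state1.solvent_coupling_k == 0.0 and system.state2.solvent_coupling_k == 0.0:
        terms.append((1, 0.0, k))
    return RestraintSet(tuple(terms))


@dataclass
class ReplicaSpec:
    """Replica batch: velocity-randomized independent FEP pathways."""

    n_replicas: int = 10
    relaxation_steps: int = 2_000

    def __post_init__(self) -> None:
        if self.n_replicas < 1:
            raise ValueError("n_replicas must be >= 1")
        if self.relaxation_steps < 0:
            raise ValueError("relaxation_steps must be >= 0")

    def replica_seeds(self, base_seed: int) -> list[int]:
        """Distinct per-replica seeds derived from the base seed."""
        seeds = [
            int(np.random.SeedSequence(entropy=base_seed, spawn_key=(0, r)).generate_state(1)[0])
            % 2**31
            for r in range(self.n_replicas)
        ]
        if len(set(seeds)) != len(seeds):  # pragma: no cover - astronomically unlikely
            raise ValueError("replica seeds collided; choose a different base_seed")
        return seeds


def _ou_coefficients(friction_per_ps: float, dt_fs: float) -> tuple[float, float]:
    gamma = friction_per_ps * 1.0e-3  # 1/fs
    c1 = math.exp(-gamma * dt_fs)
    return c1, math.sqrt(max(0.0, 1.0 - c1 * c1))


def _kernel_args(system: EVBSystem, restraints: RestraintSet):
    s1, s2 = system.state1, system.state2
    spec = system.coordinate_spec
    ks, centers = restraints.combined(spec.ndim)
    return (
        s1.bond_D, s1.bond_beta, s1.bond_r0, s1.nonbonded_repulsion,
        s1.solvent_coupling_k, s1.solvent_eq,
        s2.bond_D, s2.bond_beta, s2.bond_r0, s2.nonbonded_repulsion,
        s2.solvent_coupling_k, s2.solvent_eq,
        spec.donor_acceptor_R,
        s1.ts_well_depth, s1.ts_well_center, s1.ts_well_width,
    ), ks, centers


def _integrate(
    system: EVBSystem,
    config: Configuration,
    lam: float,
    n_steps: int,
    schedule: FEPSchedule,
    restraints: RestraintSet,
    rng: np.random.Generator,
    stride: int,
) -> np.ndarray:
    """Advance ``config`` in place; return recorded positions (may be empty)."""
    params, ks, centers = _kernel_args(system, restraints)
    c1, c2 = _ou_coefficients(schedule.friction, schedule.timestep)
    m_r, m_s = system.coordinate_spec.masses
    kbt = KB * system.temperature
    noise = rng.standard_normal((n_steps, 2))
    n_rec = n_steps // stride if stride > 0 else 0
    out = np.empty((max(n_rec, 1), 2))
    x = config.coordinates.astype(float).copy()
    v = config.velocities.astype(float).copy()
    n_out = _kernel.baoab_window(
        x, v, n_steps, schedule.timestep, c1, c2, kbt, m_r, m_s,
        *params, lam, ks[0], centers[0], ks[1], centers[1],
        noise, stride if stride > 0 else n_steps + 1, out,
    )
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(v))):
        raise DynamicsDivergenceError(
            f"dynamics diverged at lambda={lam:.4f} (non-finite coordinates)"
        )
    config.coordinates = x
    config.velocities = v
    return out[:n_out]


def _draw_velocities(system: EVBSystem, rng: np.random.Generator) -> np.ndarray:
    masses = np.asarray(system.coordinate_spec.masses)
    sigma = np.sqrt(KB * system.temperature * KCAL_TO_INTERNAL / masses)
    return sigma * rng.standard_normal(masses.shape)


def equilibrate(
    system: EVBSystem,
    config: Configuration,
    n_steps: int,
    seed: int,
    schedule: FEPSchedule | None = None,
    restraints: RestraintSet | None = None,
) -> Configuration:
    """Langevin equilibration at lambda = 0; deterministic given ``seed``."""
    schedule = schedule or FEPSchedule()
    restraints = default_restraints(system) if restraints is None else restraints
    out = Configuration(config.coordinates.copy(), config.velocities.copy())
    if n_steps == 0:
        return out
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    _integrate(system, out, 0.0, n_steps, schedule, restraints, rng, stride=0)
    _check_energies(system, out.coordinates[None, :], 0.0, schedule, context="equilibration")
    return out


def _check_energies(system, positions, lam, schedule, context=""):
    c = Configuration(positions[-1] if positions.ndim == 2 else positions)
    e1 = diabatic_energy(system.state1, c, system.coordinate_spec.donor_acceptor_R)
    e2 = diabatic_energy(system.state2, c, system.coordinate_spec.donor_acceptor_R)
    cap = schedule.divergence_cap
    if abs(e1) > cap or abs(e2) > cap:
        raise DynamicsDivergenceError(
            f"energy exceeded cap {cap:g} kcal/mol during {context} at lambda={lam:.4f}"
        )


def sample_window(
    system: EVBSystem,
    config: Configuration,
    lam: float,
    schedule: FEPSchedule,
    restraints: RestraintSet,
    seed: int,
    replica_id: int = 0,
) -> FEPFrame:
    """Sample one lambda window, advancing ``config`` in place.

    Returns the post-equilibration samples of (e1, e2, em, Eg) at this
    lambda.  The sampling Hamiltonian is the mapping potential plus the
    restraints; recorded energies are the pure diabatic values.
    """
    if not any(math.isclose(lam, x, abs_tol=1e-12) for x in schedule.lambdas):
        raise ValueError(f"lambda {lam} is not part of the schedule")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    positions = _integrate(
        system, config, lam, schedule.steps_per_window, schedule, restraints, rng,
        stride=schedule.sample_stride,
    )
    n_skip = int(round(len(positions) * schedule.equilibration_fraction))
    positions = positions[n_skip:]
    R = system.coordinate_spec.donor_acceptor_R
    pc = Configuration(positions)
    eps1 = np.asarray(diabatic_energy(system.state1, pc, R))
    eps2 = np.asarray(diabatic_energy(system.state2, pc, R))
    cap = schedule.divergence_cap
    if np.max(np.abs(eps1)) > cap or np.max(np.abs(eps2)) > cap:
        step = int(np.argmax(np.maximum(np.abs(eps1), np.abs(eps2))))
        raise DynamicsDivergenceError(
            f"energy exceeded cap {cap:g} kcal/mol at lambda={lam:.4f}, sample {step}"
        )
    emap = mapping_energy(eps1, eps2, lam)
    h12 = system.coupling.h12(positions[:, 0], system.state1.ts_well_center)
    eg = adiabatic_ground_energy(eps1, eps2, h12)
    return FEPFrame(
        lam=lam, eps1=eps1, eps2=eps2, emap=np.asarray(emap), eg=np.asarray(eg),
        replica_id=replica_id, seed=seed,
    )


def run_fep(
    system: EVBSystem,
    schedule: FEPSchedule,
    restraints: RestraintSet | None = None,
    replicas: ReplicaSpec | None = None,
    equilibration_steps: int = 50_000,
    start: Configuration | None = None,
) -> list[FEPFrame]:
    """Run the full replica-batch FEP protocol.

    Every replica starts from a shared equilibrated configuration with
    re-randomized Maxwell-Boltzmann velocities, relaxes briefly, then runs
    the lambda windows sequentially.  Output frames are ordered by
    (replica, window).  A diverged window aborts its replica; fewer than two
    surviving replicas is a hard error (unless only one was requested).
    """
    restraints = default_restraints(system) if restraints is None else restraints
    replicas = replicas or ReplicaSpec()
    if start is None:
        R = system.coordinate_spec.donor_acceptor_R
        start = Configuration(np.array([system.state1.bond_r0, system.state1.solvent_eq]))
    eq_seed = int(
        np.random.SeedSequence(entropy=schedule.base_seed, spawn_key=(2, 0)).generate_state(1)[0]
        % 2**31
    )
    shared = equilibrate(system, start, equilibration_steps, eq_seed, schedule, restraints)

    frames: list[FEPFrame] = []
    survivors = 0
    for r, rseed in enumerate(replicas.replica_seeds(schedule.base_seed)):
        vel_rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(rseed)))
        config = Configuration(shared.coordinates.copy(), _draw_velocities(system, vel_rng))
        try:
            if replicas.relaxation_steps:
                _integrate(
                    system, config, 0.0, replicas.relaxation_steps, schedule, restraints,
                    vel_rng, stride=0,
                )
            replica_frames = []
            for w, lam in enumerate(schedule.lambdas):
                wseed = int(
                    np.random.SeedSequence(
                        entropy=schedule.base_seed, spawn_key=(1, r, w)
                    ).generate_state(1)[0]
                    % 2**31
                )
                replica_frames.append(
                    sample_window(system, config, lam, schedule, restraints, wseed, replica_id=r)
                )
        except DynamicsDivergenceError as err:
            logger.warning("replica %d aborted: %s", r, err)
            continue
        frames.extend(replica_frames)
        survivors += 1
    if survivors < min(2, replicas.n_replicas):
        raise DynamicsDivergenceError(
            f"only {survivors} replica(s) survived; need at least "
            f"{min(2, replicas.n_replicas)}"
        )
    return frames
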