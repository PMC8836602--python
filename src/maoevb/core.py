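"""Two-state empirical valence bond (EVB) energy model.

A reaction is represented by two diabatic valence states -- reactants
(state 1) and products (state 2) -- each described by a cheap classical
potential, coupled by an off-diagonal element ``H12``.  The adiabatic
ground-state surface is the lower eigenvalue of the 2x2 EVB Hamiltonian

    Eg = 1/2 [(e1 + e2) - sqrt((e1 - e2)^2 + 4 H12^2)]

and sampling along the reaction is driven by the linear mapping potential
``em = (1 - lam) e1 + lam e2``.  The generalized reaction coordinate is the
diabatic energy gap ``de = e1 - e2``.

The model here is deliberately reduced: two dynamical coordinates, the
donor-hydride distance ``r`` (Å) and a dimensionless collective solvent
coordinate ``s``, with the donor-acceptor distance ``R`` held fixed.  Each
diabatic state carries a Morse term for its own bond (breaking C-H in state
1, forming N5-H in state 2), an r^-12 repulsion against the opposite heavy
site, a harmonic solvent term, the calibrated gas shift ``alpha`` (state 2),
a static environment shift, and an optional transition-state-region
stabilization well shared by both states (so the gap coordinate is
unaffected by it).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "DiabaticState",
    "CouplingModel",
    "CoordinateSpec",
    "EVBSystem",
    "Configuration",
    "diabatic_energy",
    "adiabatic_ground_energy",
    "mapping_energy",
    "energy_gap",
    "forces",
]


def _require_finite(name: str, value) -> None:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        bad = np.argwhere(~np.isfinite(arr))
        raise ValueError(f"non-finite value in {name} at index {bad[0].tolist()}")


@dataclass
class DiabaticState:
    """One valence state of the two-state EVB Hamiltonian.

    ``bond_D``/``bond_beta``/``bond_r0`` parametrize the Morse well of the
    transferring hydride's bond: to the donor carbon in state 1 (coordinate
    ``r``) and to the flavin N5 acceptor in state 2 (coordinate ``R - r``).
    ``gas_shift_alpha`` is the calibrated EVB gas shift (zero for state 1);
    ``env_shift`` is the static stabilization supplied by the surrounding
    environment surrogate (zero in the gas phase).
    """

    state_index: int
    bond_D: float
    bond_beta: float
    bond_r0: float
    nonbonded_repulsion: float = 0.02
    solvent_coupling_k: float = 0.0
    solvent_eq: float = 0.0
    charge_set: tuple[float, ...] = ()
    gas_shift_alpha: float = 0.0
    env_shift: float = 0.0
    # transition-state-region stabilization (shared by both states so that
    # the energy gap is left untouched); depth >= 0 stabilizes
    ts_well_depth: float = 0.0
    ts_well_center: float = 0.0
    ts_well_width: float = 0.1

    def __post_init__(self) -> None:
        if self.state_index not in (1, 2):
            raise ValueError("state_index must be 1 (reactants) or 2 (products)")
        if self.bond_D <= 0 or self.bond_beta <= 0 or self.bond_r0 <= 0:
            raise ValueError("Morse parameters bond_D, bond_beta, bond_r0 must be > 0")
        if self.nonbonded_repulsion < 0:
            raise ValueError("nonbonded_repulsion must be >= 0")
        if self.solvent_coupling_k < 0:
            raise ValueError("solvent_coupling_k must be >= 0")
        if self.ts_well_depth < 0 or self.ts_well_width <= 0:
            raise ValueError("ts well requires depth >= 0 and width > 0")
        if self.charge_set and abs(sum(self.charge_set)) > 1e-9:
            raise ValueError("charge_set must sum to the state's formal charge (0)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["charge_set"] = list(self.charge_set)
        return {
            "state_index": d["state_index"],
            "bond_D_kcal_mol": d["bond_D"],
            "bond_beta_per_A": d["bond_beta"],
            "bond_r0_A": d["bond_r0"],
            "nonbonded_repulsion_kcal_A12_mol": d["nonbonded_repulsion"],
            "solvent_coupling_k_kcal_mol": d["solvent_coupling_k"],
            "solvent_eq": d["solvent_eq"],
            "charge_set_e": d["charge_set"],
            "gas_shift_alpha_kcal_mol": d["gas_shift_alpha"],
            "env_shift_kcal_mol": d["env_shift"],
            "ts_well_depth_kcal_mol": d["ts_well_depth"],
            "ts_well_center_A": d["ts_well_center"],
            "ts_well_width_A": d["ts_well_width"],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiabaticState":
        return cls(
            state_index=d["state_index"],
            bond_D=d["bond_D_kcal_mol"],
            bond_beta=d["bond_beta_per_A"],
            bond_r0=d["bond_r0_A"],
            nonbonded_repulsion=d["nonbonded_repulsion_kcal_A12_mol"],
            solvent_coupling_k=d["solvent_coupling_k_kcal_mol"],
            solvent_eq=d["solvent_eq"],
            charge_set=tuple(d.get("charge_set_e", ())),
            gas_shift_alpha=d["gas_shift_alpha_kcal_mol"],
            env_shift=d["env_shift_kcal_mol"],
            ts_well_depth=d["ts_well_depth_kcal_mol"],
            ts_well_center=d["ts_well_center_A"],
            ts_well_width=d["ts_well_width_A"],
        )


@dataclass
class CouplingModel:
    """Off-diagonal EVB element H12, constant by default (mu = 0)."""

    h12_constant: float
    distance_decay_mu: float = 0.0

    def __post_init__(self) -> None:
        if self.h12_constant < 0:
            raise ValueError("h12_constant must be >= 0")
        if self.distance_decay_mu < 0:
            raise ValueError("distance_decay_mu must be >= 0")

    def h12(self, r: float = 0.0, r_ref: float = 0.0):
        """Coupling at donor-hydride distance ``r`` (constant when mu = 0)."""
        if self.distance_decay_mu == 0.0:
            return self.h12_constant
        return self.h12_constant * np.exp(-self.distance_decay_mu * np.abs(r - r_ref))

    def to_dict(self) -> dict:
        return {
            "h12_constant_kcal_mol": self.h12_constant,
            "distance_decay_mu_per_A": self.distance_decay_mu,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CouplingModel":
        return cls(d["h12_constant_kcal_mol"], d.get("distance_decay_mu_per_A", 0.0))


@dataclass
class CoordinateSpec:
    """Names, masses (amu) and dimensionality of the dynamical coordinates."""

    names: tuple[str, ...] = ("r", "s")
    masses: tuple[float, ...] = (1.0, 10.0)
    donor_acceptor_R: float = 2.6

    def __post_init__(self) -> None:
        if len(self.names) != len(self.masses):
            raise ValueError("names and masses must have equal length")
        if any(m <= 0 for m in self.masses):
            raise ValueError("masses must be > 0")
        if self.donor_acceptor_R <= 0:
            raise ValueError("donor_acceptor_R must be > 0")

    @property
    def ndim(self) -> int:
        return len(self.names)


@dataclass
class EVBSystem:
    """A reactive two-state surface in a given environment."""

    state1: DiabaticState
    state2: DiabaticState
    coupling: CouplingModel
    environment_tag: str = "gas"
    substrate_tag: str = "HIS"
    temperature: float = 300.0
    coordinate_spec: CoordinateSpec = field(default_factory=CoordinateSpec)

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.environment_tag not in ("gas", "water", "enzyme"):
            raise ValueError("environment_tag must be one of gas, water, enzyme")
        if self.state1.state_index != 1 or self.state2.state_index != 2:
            raise ValueError("state1/state2 must carry state_index 1/2")

    def to_dict(self) -> dict:
        return {
            "state1": self.state1.to_dict(),
            "state2": self.state2.to_dict(),
            "coupling": self.coupling.to_dict(),
            "environment_tag": self.environment_tag,
            "substrate_tag": self.substrate_tag,
            "temperature_K": self.temperature,
            "coordinates": {
                "names": list(self.coordinate_spec.names),
                "masses_amu": list(self.coordinate_spec.masses),
                "donor_acceptor_R_A": self.coordinate_spec.donor_acceptor_R,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EVBSystem":
        coords = d["coordinates"]
        return cls(
            state1=DiabaticState.from_dict(d["state1"]),
            state2=DiabaticState.from_dict(d["state2"]),
            coupling=CouplingModel.from_dict(d["coupling"]),
            environment_tag=d["environment_tag"],
            substrate_tag=d["substrate_tag"],
            temperature=d["temperature_K"],
            coordinate_spec=CoordinateSpec(
                names=tuple(coords["names"]),
                masses=tuple(coords["masses_amu"]),
                donor_acceptor_R=coords["donor_acceptor_R_A"],
            ),
        )


@dataclass
class Configuration:
    """A point in the system's coordinate (and velocity) space."""

    coordinates: np.ndarray
    velocities: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        _require_finite("coordinates", self.coordinates)
        if self.velocities is None:
            self.velocities = np.zeros_like(self.coordinates)
        else:
            self.velocities = np.asarray(self.velocities, dtype=float)
            _require_finite("velocities", self.velocities)
        if self.velocities.shape != self.coordinates.shape:
            raise ValueError("velocities must match coordinates in shape")


def _morse(D: float, beta: float, x, x0: float):
    e = np.exp(-beta * (np.asarray(x, dtype=float) - x0))
    return D * (1.0 - e) ** 2 - D


def diabatic_energy(state: DiabaticState, config: Configuration, R: float = 2.6):
    """Energy (kcal/mol) of one diabatic state at a configuration.

    ``config.coordinates`` may be a single point ``(r, s)`` or an array of
    shape ``(n, 2)``; a matching scalar or array is returned.  ``R`` is the
    fixed donor-acceptor distance.
    """
    coords = np.asarray(config.coordinates, dtype=float)
    _require_finite("coordinates", coords)
    single = coords.ndim == 1
    pts = np.atleast_2d(coords)
    if pts.shape[1] != 2:
        raise ValueError("configuration must provide coordinates (r, s)")
    r = pts[:, 0]
    s = pts[:, 1]
    if state.state_index == 1:
        bond = _morse(state.bond_D, state.bond_beta, r, state.bond_r0)
        rep = state.nonbonded_repulsion / (R - r) ** 12
    else:
        bond = _morse(state.bond_D, state.bond_beta, R - r, state.bond_r0)
        rep = state.nonbonded_repulsion / r ** 12
    solvent = 0.5 * state.solvent_coupling_k * (s - state.solvent_eq) ** 2
    tsw = -state.ts_well_depth * np.exp(
        -0.5 * ((r - state.ts_well_center) / state.ts_well_width) ** 2
    )
    e = bond + rep + solvent + tsw + state.gas_shift_alpha + state.env_shift
    return float(e[0]) if single else e


def adiabatic_ground_energy(eps1, eps2, h12):
    """Lower eigenvalue of the 2x2 EVB Hamiltonian (kcal/mol)."""
    h12 = np.asarray(h12, dtype=float)
    if np.any(h12 < 0):
        raise ValueError("h12 must be >= 0")
    eps1 = np.asarray(eps1, dtype=float)
    eps2 = np.asarray(eps2, dtype=float)
    out = 0.5 * ((eps1 + eps2) - np.sqrt((eps1 - eps2) ** 2 + 4.0 * h12 ** 2))
    return float(out) if out.ndim == 0 else out


def mapping_energy(eps1, eps2, lam: float):
    """FEP mapping potential em = (1 - lam) e1 + lam e2 (kcal/mol)."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    eps1 = np.asarray(eps1, dtype=float)
    eps2 = np.asarray(eps2, dtype=float)
    out = (1.0 - lam) * eps1 + lam * eps2
    return float(out) if out.ndim == 0 else out


def energy_gap(eps1, eps2):
    """Diabatic energy gap de = e1 - e2, the EVB reaction coordinate."""
    out = np.asarray(eps1, dtype=float) - np.asarray(eps2, dtype=float)
    return float(out) if out.ndim == 0 else out


def _diabatic_gradient(state: DiabaticState, r: float, s: float, R: float) -> np.ndarray:
    if state.state_index == 1:
        e = math.exp(-state.bond_beta * (r - state.bond_r0))
        dbond = 2.0 * state.bond_D * state.bond_beta * (1.0 - e) * e
        drep = 12.0 * state.nonbonded_repulsion / (R - r) ** 13
    else:
        e = math.exp(-state.bond_beta * (R - r - state.bond_r0))
        dbond = -2.0 * state.bond_D * state.bond_beta * (1.0 - e) * e
        drep = -12.0 * state.nonbonded_repulsion / r ** 13
    u = (r - state.ts_well_center) / state.ts_well_width
    dtsw = (
        state.ts_well_depth
        * u
        / state.ts_well_width
        * math.exp(-0.5 * u * u)
    )
    dr = dbond + drep + dtsw
    ds = state.solvent_coupling_k * (s - state.solvent_eq)
    return np.array([dr, ds])


def forces(
    system: EVBSystem,
    config: Configuration,
    lam: float,
    restraints: Sequence[tuple[int, float, float]] = (),
) -> np.ndarray:
    """Force (negative gradient) of the mapping potential plus restraints.

    ``restraints`` is a sequence of ``(coordinate_index, center, k)`` harmonic
    terms with k in kcal/(mol Å^2).  Units: kcal/mol/Å.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    coords = np.asarray(config.coordinates, dtype=float)
    _require_finite("coordinates", coords)
    r, s = float(coords[0]), float(coords[1])
    R = system.coordinate_spec.donor_acceptor_R
    g1 = _diabatic_gradient(system.state1, r, s, R)
    g2 = _diabatic_gradient(system.state2, r, s, R)
    grad = (1.0 - lam) * g1 + lam * g2
    f = -grad
    for idx, center, k in restraints:
        f[idx] -= k * (coords[idx] - center)
    return f
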