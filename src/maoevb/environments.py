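"""Synthetic gas / water / enzyme surrogates for the HIS and NMH pipelines.

The surrogates are calibrated stand-ins, not predictive physics: they encode
the statistical structure the analysis rests on --

* hydration: about two more waters near histamine (HIS) than near
  N-methylhistamine (NMH) in water, about one more in the enzyme active site;
* hydrophobic contacts: nearly two more nonpolar contacts for NMH in the
  enzyme, increasing toward the transition state for both substrates;
* polarity: the reacting moiety's dipole grows from 8.9 to 12.8 D (HIS) and
  from 9.4 to 13.4 D (NMH) between reactant and transition state;

-- and map it onto the reduced EVB surface.  Water stabilizes the
charge-separated product state in proportion to how well the substrate is
hydrated (a bulk dielectric term plus a per-water term, with an extra
transition-state-region term because the dipole, and hence the
susceptibility to solvation, peaks there).  The enzyme supplies a
preorganized electrostatic field whose effect is *attenuated* by local
waters (dielectric shielding), plus dispersion stabilization from nonpolar
contacts that is strongest at the transition state.  Default strengths are
committed configuration, tuned once so the full pipeline lands near the
published barrier pattern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .core import Configuration, CouplingModel, CoordinateSpec, DiabaticState, EVBSystem, diabatic_energy
from .descriptors import Snapshot, dipole_moment, WATER_CUTOFF, CONTACT_CUTOFF

__all__ = [
    "SoluteModel",
    "EnvironmentSpec",
    "DescriptorEnsemble",
    "BASE_SURFACE",
    "REFERENCE_GAS_TARGETS",
    "PKA",
    "default_solute",
    "default_environment",
    "build_system",
    "sample_descriptor_ensemble",
]

#: Shared gas-phase Morse/repulsion surface of the hydride-transfer step.
#: Both substrates use the same reduced surface; their differences live in
#: the calibrated EVB parameters (alpha, H12), as in standard EVB practice.
BASE_SURFACE = {
    "bond_D": 90.0,  # kcal/mol
    "bond_beta": 3.0,  # 1/Å
    "r0_donor": 1.09,  # C-H, Å
    "r0_acceptor": 1.03,  # N5-H, Å
    "repulsion": 0.02,  # kcal Å^12 / mol
    "donor_acceptor_R": 2.6,  # Å
}

#: Gas-phase reference activation / reaction free energies (kcal/mol) for
#: the hydride abstraction, consumed as plain configuration values from
#: quantum-chemical reference calculations: the barriers differ by
#: 1.06 kcal/mol (NMH lower) and the gas-phase step is strongly endergonic
#: (~25 kcal/mol) for both substrates.
REFERENCE_GAS_TARGETS = {
    "HIS": {"dg_act": 33.00, "dg_rxn": 25.00},
    "NMH": {"dg_act": 31.94, "dg_rxn": 25.00},
}

#: Aqueous pKa of the ethylamino group (monocation -> neutral).
PKA = {"HIS": 9.75, "NMH": 9.57}

#: Reactant / transition-state dipole targets in Debye.
DIPOLE_TARGETS = {"HIS": (8.9, 12.8), "NMH": (9.4, 13.4)}


def _imidazole_template(with_methyl: bool) -> tuple[np.ndarray, list[str]]:
    """Rough heavy-atom template: planar imidazole ring + ethylamine chain."""
    side = 1.37
    rr = side / (2.0 * math.sin(math.pi / 5.0))
    angles = np.deg2rad([90.0, 162.0, 234.0, 306.0, 18.0])
    ring = np.column_stack([rr * np.cos(angles), rr * np.sin(angles), np.zeros(5)])
    labels = ["N_tau", "C_eps", "N_pi", "C_delta", "C_gamma"]
    # ethylamine chain off C_gamma, zig-zagging out of the ring plane
    c_gamma = ring[4]
    u = c_gamma / np.linalg.norm(c_gamma)
    cb = c_gamma + 1.50 * u + np.array([0.0, 0.0, 0.3])
    ca = cb + 1.53 * u + np.array([0.0, 0.0, -0.5])
    n_am = ca + 1.47 * u + np.array([0.0, 0.0, 0.4])
    sites = [*ring, cb, ca, n_am]
    labels += ["C_beta", "C_alpha", "N_amine"]
    if with_methyl:
        n_tau = ring[0]
        u_t = n_tau / np.linalg.norm(n_tau)
        sites.append(n_tau + 1.47 * u_t)
        labels.append("C_methyl")
    return np.array(sites), labels


# Unit-free charge patterns (sum to zero); scaled per substrate so the
# computed dipole hits the reactant / TS targets exactly.
_REACTANT_PATTERN = {
    "N_amine": -0.50,
    "C_alpha": 0.15,
    "C_beta": 0.10,
    "N_pi": -0.20,
    "N_tau": -0.15,
    "C_eps": 0.20,
    "C_delta": 0.20,
    "C_gamma": 0.20,
}
_TS_PATTERN = {
    "N_amine": -0.35,
    "C_alpha": 0.55,  # hydride departs from the alpha carbon
    "C_beta": 0.25,
    "N_pi": -0.30,
    "N_tau": -0.25,
    "C_eps": 0.05,
    "C_delta": 0.05,
    "C_gamma": 0.00,
}


@dataclass
class SoluteModel:
    """Heavy-atom template, charge sets and hydrophobicity proxy of a substrate."""

    substrate_tag: str
    site_positions: np.ndarray
    site_labels: list[str]
    reactant_charges: np.ndarray
    ts_charges: np.ndarray
    dipole_targets: tuple[float, float]
    hydrophobicity: float

    def __post_init__(self) -> None:
        if self.substrate_tag not in ("HIS", "NMH"):
            raise ValueError("substrate_tag must be HIS or NMH")
        for q in (self.reactant_charges, self.ts_charges):
            if abs(float(np.sum(q))) > 1e-9:
                raise ValueError("charge sets must sum to zero")
        if not self.dipole_targets[1] > self.dipole_targets[0]:
            raise ValueError("TS dipole target must exceed the reactant target")

    @property
    def n_heavy_sites(self) -> int:
        return len(self.site_positions)

    def dipole(self, state: str) -> float:
        q = self.reactant_charges if state == "reactant" else self.ts_charges
        return dipole_moment(q, self.site_positions)

    def to_dict(self) -> dict:
        return {
            "substrate_tag": self.substrate_tag,
            "site_labels": list(self.site_labels),
            "site_positions_A": self.site_positions.tolist(),
            "reactant_charges_e": self.reactant_charges.tolist(),
            "ts_charges_e": self.ts_charges.tolist(),
            "dipole_targets_debye": list(self.dipole_targets),
            "hydrophobicity": self.hydrophobicity,
        }


def _scaled_charges(pattern: dict, labels: list[str], positions: np.ndarray, target: float) -> np.ndarray:
    q = np.array([pattern.get(lab, 0.0) for lab in labels])
    q -= q.sum() / len(q)  # enforce exact neutrality
    base = dipole_moment(q, positions)
    return q * (target / base)


def default_solute(substrate: str) -> SoluteModel:
    """The committed HIS / NMH solute models (dipoles hit their targets)."""
    if substrate not in DIPOLE_TARGETS:
        raise ValueError("substrate must be HIS or NMH")
    positions, labels = _imidazole_template(with_methyl=(substrate == "NMH"))
    react_t, ts_t = DIPOLE_TARGETS[substrate]
    return SoluteModel(
        substrate_tag=substrate,
        site_positions=positions,
        site_labels=labels,
        reactant_charges=_scaled_charges(_REACTANT_PATTERN, labels, positions, react_t),
        ts_charges=_scaled_charges(_TS_PATTERN, labels, positions, ts_t),
        dipole_targets=(react_t, ts_t),
        # ChEMBL logP: NMH -0.08, HIS -0.09; the methyl makes NMH the more
        # hydrophobic of the pair
        hydrophobicity=-0.08 if substrate == "NMH" else -0.09,
    )


@dataclass
class EnvironmentSpec:
    """Strengths and statistics of one environment surrogate.

    ``solvent_coupling`` is the per-water static stabilization of the
    charge-separated product state; ``bulk_stabilization`` the
    substrate-independent dielectric response; ``ts_hydration_coupling`` the
    per-water transition-state-region stabilization (the TS dipole is larger,
    so solvation bites hardest there).  Enzyme-only terms:
    ``preorganized_field`` (stabilization of the charge-separated state by
    the preorganized active site), attenuated by ``shielding_per_water`` for
    every local water, and ``contact_coupling`` (per nonpolar contact,
    acting in the transition-state region).
    """

    environment_tag: str
    solvent_coupling: float = 0.0
    bulk_stabilization: float = 0.0
    ts_hydration_coupling: float = 0.0
    preorganized_field: float = 0.0
    shielding_per_water: float = 0.0
    contact_coupling: float = 0.0
    solvent_k: float = 0.0
    solvent_displacement: float = 0.0
    hydration_mean: dict = field(default_factory=dict)
    contact_mean: dict = field(default_factory=dict)
    contact_ts_increment: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.environment_tag not in ("gas", "water", "enzyme"):
            raise ValueError("environment_tag must be gas, water or enzyme")
        for name in (
            "solvent_coupling",
            "bulk_stabilization",
            "ts_hydration_coupling",
            "preorganized_field",
            "shielding_per_water",
            "contact_coupling",
            "solvent_k",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        return {
            "environment_tag": self.environment_tag,
            "solvent_coupling_kcal_mol_per_water": self.solvent_coupling,
            "bulk_stabilization_kcal_mol": self.bulk_stabilization,
            "ts_hydration_coupling_kcal_mol_per_water": self.ts_hydration_coupling,
            "preorganized_field_kcal_mol": self.preorganized_field,
            "shielding_per_water": self.shielding_per_water,
            "contact_coupling_kcal_mol_per_contact": self.contact_coupling,
            "solvent_k_kcal_mol": self.solvent_k,
            "solvent_displacement": self.solvent_displacement,
            "hydration_mean": dict(self.hydration_mean),
            "contact_mean": dict(self.contact_mean),
            "contact_ts_increment": dict(self.contact_ts_increment),
        }


# Committed default environment configurations.  Hydration and contact means
# encode the reported count differences (2 waters in water, 1 water and ~2
# contacts in the enzyme); coupling strengths were tuned once against the
# dense-grid reference so the corrected barriers land near the published
# pattern, and are configuration, not fitted physics.
_DEFAULT_ENVIRONMENTS = {
    "gas": dict(environment_tag="gas"),
    "water": dict(
        environment_tag="water",
        solvent_coupling=1.389,
        bulk_stabilization=13.934,
        ts_hydration_coupling=0.263,
        solvent_k=1.5,
        solvent_displacement=2.0,
        hydration_mean={"HIS": 6.0, "NMH": 4.0},
        contact_mean={"HIS": 0.0, "NMH": 0.0},
        contact_ts_increment={"HIS": 0.0, "NMH": 0.0},
    ),
    "enzyme": dict(
        environment_tag="enzyme",
        preorganized_field=32.556,
        shielding_per_water=0.030,
        contact_coupling=0.152,
        solvent_k=1.5,
        solvent_displacement=1.2,
        hydration_mean={"HIS": 3.0, "NMH": 2.0},
        contact_mean={"HIS": 4.0, "NMH": 6.0},
        contact_ts_increment={"HIS": 0.5, "NMH": 1.5},
    ),
}


def default_environment(tag: str) -> EnvironmentSpec:
    """The committed gas / water / enzyme surrogate configuration."""
    if tag not in _DEFAULT_ENVIRONMENTS:
        raise ValueError("environment must be gas, water or enzyme")
    return EnvironmentSpec(**_DEFAULT_ENVIRONMENTS[tag])


def _crossing_point(state1: DiabaticState, state2: DiabaticState, R: float) -> float:
    """Donor-hydride distance where the (shifted) diabats cross."""
    s_mid = 0.5 * (state1.solvent_eq + state2.solvent_eq)

    def gap(r: float) -> float:
        c = Configuration(np.array([r, s_mid]))
        return diabatic_energy(state1, c, R) - diabatic_energy(state2, c, R)

    lo = state1.bond_r0 + 0.02
    hi = R - state2.bond_r0 - 0.02
    return float(brentq(gap, lo, hi))


def build_system(
    substrate: SoluteModel,
    env: EnvironmentSpec,
    calibrated=None,
    temperature: float = 300.0,
) -> EVBSystem:
    """Assemble the EVB system for a substrate in an environment surrogate.

    For water and enzyme the calibrated gas parameters (alpha, H12) are
    required and frozen; the environment enters as a static stabilization of
    the charge-separated state 2, a harmonic solvent coordinate displaced
    between the states, and a transition-state-region well shared by both
    states (so the gap coordinate is untouched).
    """
    if env.environment_tag != "gas" and calibrated is None:
        raise ValueError("water/enzyme systems require calibrated gas parameters")
    tag = substrate.substrate_tag
    alpha = calibrated.alpha if calibrated is not None else 0.0
    h12 = calibrated.h12 if calibrated is not None else 2.5

    base = dict(
        bond_D=BASE_SURFACE["bond_D"],
        bond_beta=BASE_SURFACE["bond_beta"],
        nonbonded_repulsion=BASE_SURFACE["repulsion"],
    )
    R = BASE_SURFACE["donor_acceptor_R"]

    if env.environment_tag == "gas":
        k_s, s2_eq, shift2, ts_depth = 0.0, 0.0, 0.0, 0.0
    else:
        hyd = env.hydration_mean[tag]
        k_s = env.solvent_k
        s2_eq = env.solvent_displacement
        if env.environment_tag == "water":
            shift2 = -(env.bulk_stabilization + env.solvent_coupling * hyd)
            ts_depth = env.ts_hydration_coupling * hyd
        else:
            shield = max(0.0, 1.0 - env.shielding_per_water * hyd)
            shift2 = -env.preorganized_field * shield
            contacts_at_ts = env.contact_mean[tag] + env.contact_ts_increment[tag]
            ts_depth = env.contact_coupling * contacts_at_ts

    state1 = DiabaticState(
        state_index=1,
        bond_r0=BASE_SURFACE["r0_donor"],
        solvent_coupling_k=k_s,
        solvent_eq=0.0,
        charge_set=tuple(substrate.reactant_charges),
        gas_shift_alpha=0.0,
        env_shift=0.0,
        **base,
    )
    state2 = DiabaticState(
        state_index=2,
        bond_r0=BASE_SURFACE["r0_acceptor"],
        solvent_coupling_k=k_s,
        solvent_eq=s2_eq,
        charge_set=tuple(substrate.ts_charges),
        gas_shift_alpha=alpha,
        env_shift=shift2,
        **base,
    )
    if ts_depth > 0.0:
        center = _crossing_point(state1, state2, R)
        state1 = replace(state1, ts_well_depth=ts_depth, ts_well_center=center, ts_well_width=0.08)
        state2 = replace(state2, ts_well_depth=ts_depth, ts_well_center=center, ts_well_width=0.08)
    return EVBSystem(
        state1=state1,
        state2=state2,
        coupling=CouplingModel(h12_constant=h12),
        environment_tag=env.environment_tag,
        substrate_tag=tag,
        temperature=temperature,
        coordinate_spec=CoordinateSpec(donor_acceptor_R=R),
    )


@dataclass
class DescriptorEnsemble:
    """Seed-reproducible snapshots emulating trajectory frames for counting."""

    snapshots: list
    substrate_tag: str
    environment_tag: str
    seed: int

    def __len__(self) -> int:
        return len(self.snapshots)


def _place_shell(rng, anchors: np.ndarray, n: int, r_lo: float, r_hi: float) -> np.ndarray:
    """``n`` sites, each within (r_lo, r_hi] of a randomly chosen anchor."""
    if n == 0:
        return np.empty((0, 3))
    idx = rng.integers(0, len(anchors), size=n)
    vec = rng.standard_normal((n, 3))
    vec /= np.linalg.norm(vec, axis=1, keepdims=True)
    rad = rng.uniform(r_lo, r_hi, size=n)
    return anchors[idx] + vec * rad[:, None]


def sample_descriptor_ensemble(
    substrate: SoluteModel,
    env: EnvironmentSpec,
    n: int,
    seed: int,
) -> DescriptorEnsemble:
    """Draw ``n`` snapshots per reaction-state label (reactant and TS).

    Water counts are Poisson around the substrate's hydration mean for this
    environment; contact counts Poisson around the contact mean, raised by
    the TS increment in transition-state snapshots.  A few far-field waters
    beyond the counting cutoff are added so the cutoff actually selects.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    tag = substrate.substrate_tag
    hyd = env.hydration_mean.get(tag, 0.0)
    cmean = env.contact_mean.get(tag, 0.0)
    cinc = env.contact_ts_increment.get(tag, 0.0)
    anchors = substrate.site_positions
    extent = float(np.max(np.linalg.norm(anchors, axis=1)))
    far_lo = extent + WATER_CUTOFF + 0.5
    snapshots = []
    for label in ("reactant", "TS"):
        for _ in range(n):
            n_w = rng.poisson(hyd)
            n_far = rng.poisson(2.0)
            waters = np.vstack(
                [
                    _place_shell(rng, anchors, n_w, 2.4, WATER_CUTOFF),
                    _place_shell(rng, np.zeros((1, 3)), n_far, far_lo, far_lo + 3.0),
                ]
            )
            n_c = rng.poisson(cmean + (cinc if label == "TS" else 0.0))
            contacts = _place_shell(rng, anchors, n_c, 3.6, CONTACT_CUTOFF)
            snapshots.append(
                Snapshot(
                    solute_positions=anchors,
                    water_positions=waters,
                    contact_positions=contacts,
                    label=label,
                )
            )
    return DescriptorEnsemble(
        snapshots=snapshots,
        substrate_tag=tag,
        environment_tag=env.environment_tag,
        seed=seed,
    )
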