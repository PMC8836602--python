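"""Independent reference implementations used as test oracles.

Everything here is deliberately written *without* reusing the package's
estimator code paths: plain-loop term summation, finite differences, dense
2D-grid Boltzmann integration, and exhaustive stationary-point scans.
"""

from __future__ import annotations

import math

import numpy as np

KB = 1.987204e-3


def term_by_term_energy(state, r: float, s: float, R: float) -> float:
    """Brute-force re-evaluation of one diabatic energy, term by term."""
    if state.state_index == 1:
        x = r - state.bond_r0
        rep = state.nonbonded_repulsion / (R - r) ** 12
    else:
        x = (R - r) - state.bond_r0
        rep = state.nonbonded_repulsion / r ** 12
    morse = state.bond_D * (1.0 - math.exp(-state.bond_beta * x)) ** 2 - state.bond_D
    solvent = 0.5 * state.solvent_coupling_k * (s - state.solvent_eq) ** 2
    tsw = -state.ts_well_depth * math.exp(
        -0.5 * ((r - state.ts_well_center) / state.ts_well_width) ** 2
    )
    return morse + rep + solvent + tsw + state.gas_shift_alpha + state.env_shift


def finite_difference_gradient(fn, x: np.ndarray, h: float = 1e-5) -> np.ndarray:
    """Central finite differences of a scalar function of a vector."""
    g = np.zeros_like(x, dtype=float)
    for i in range(len(x)):
        xp = x.astype(float).copy()
        xm = x.astype(float).copy()
        xp[i] += h
        xm[i] -= h
        g[i] = (fn(xp) - fn(xm)) / (2.0 * h)
    return g


def exhaustive_stationary_points(dG) -> tuple[int, int, int]:
    """Exhaustive scan for (reactant, ts, product) bin indices.

    The transition state is the highest bin with at least one strictly lower
    bin on each side (first such bin on ties); the flanking minima are the
    lowest bins on either side (first on ties).  Plain loops throughout.
    """
    values = [float(v) for v in dG]
    n = len(values)
    best_j, best_val = None, None
    for j in range(1, n - 1):
        has_lower_left = any(values[i] < values[j] for i in range(j))
        has_lower_right = any(values[k] < values[j] for k in range(j + 1, n))
        if has_lower_left and has_lower_right:
            if best_val is None or values[j] > best_val:
                best_j, best_val = j, values[j]
    if best_j is None:
        raise ValueError("no interior maximum between two minima")
    left = values[:best_j]
    right = values[best_j + 1 :]
    reactant = left.index(min(left))
    product = best_j + 1 + right.index(min(right))
    return reactant, best_j, product


def grid_reference_profile(
    system,
    n_bins: int = 50,
    r_range: tuple[float, float] = (0.85, 1.65),
    s_range: tuple[float, float] = (-5.0, 7.5),
    nr: int = 700,
    ns: int = 281,
) -> tuple[float, float]:
    """(dG_act, dG_rxn) by dense-grid Boltzmann integration over the
    adiabatic ground-state surface, binned on the energy gap.

    Energies are evaluated here directly from the model's functional form
    (via term_by_term_energy), independent of the sampler and the FEP
    estimator chain.
    """
    R = system.coordinate_spec.donor_acceptor_R
    kbt = KB * system.temperature
    r = np.linspace(*r_range, nr)
    s = np.linspace(*s_range, ns)
    rr, ss = np.meshgrid(r, s, indexing="ij")
    e1 = np.empty(rr.size)
    e2 = np.empty(rr.size)
    flat_r = rr.ravel()
    flat_s = ss.ravel()
    # vectorized re-implementation of term_by_term_energy for both states
    for arr, state in ((e1, system.state1), (e2, system.state2)):
        if state.state_index == 1:
            x = flat_r - state.bond_r0
            rep = state.nonbonded_repulsion / (R - flat_r) ** 12
        else:
            x = (R - flat_r) - state.bond_r0
            rep = state.nonbonded_repulsion / flat_r ** 12
        morse = state.bond_D * (1.0 - np.exp(-state.bond_beta * x)) ** 2 - state.bond_D
        solv = 0.5 * state.solvent_coupling_k * (flat_s - state.solvent_eq) ** 2
        tsw = -state.ts_well_depth * np.exp(
            -0.5 * ((flat_r - state.ts_well_center) / state.ts_well_width) ** 2
        )
        arr[:] = morse + rep + solv + tsw + state.gas_shift_alpha + state.env_shift
    h12 = float(system.coupling.h12_constant)
    eg = 0.5 * ((e1 + e2) - np.sqrt((e1 - e2) ** 2 + 4.0 * h12 ** 2))
    gap = e1 - e2
    w = np.exp(-(eg - eg.min()) / kbt)
    # bin range from thermally relevant points (zero-weight grid corners
    # would otherwise inflate the range and coarsen the bins)
    relevant = gap[w > 1e-13]
    edges = np.linspace(relevant.min(), relevant.max(), n_bins + 1)
    idx = np.clip(np.searchsorted(edges, gap, side="right") - 1, 0, n_bins - 1)
    pb = np.bincount(idx, weights=w, minlength=n_bins)
    valid = pb > 0
    dG = -kbt * np.log(pb[valid])
    reac, ts, prod = exhaustive_stationary_points(dG)
    return float(dG[ts] - dG[reac]), float(dG[prod] - dG[reac])


def harmonic_fep_closed_form(k1: float, k2: float, T: float) -> float:
    """Partition-function ratio for a harmonic frequency change at fixed center."""
    return 0.5 * KB * T * math.log(k2 / k1)
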