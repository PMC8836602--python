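"""Interpretive observables: hydration counts, hydrophobic contacts, dipoles.

These are the quantities used to rationalize the barrier orderings: how many
water oxygens sit near the substrate, how many nonpolar sites it contacts,
and how polar the reacting moiety is in the reactant versus transition
state.  Counting is boundary-inclusive (distance <= cutoff) over water
oxygen / nonpolar contact sites within the cutoff of *any* solute heavy
site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .constants import DEBYE_PER_E_ANGSTROM

__all__ = [
    "Snapshot",
    "DescriptorReport",
    "WATER_CUTOFF",
    "CONTACT_CUTOFF",
    "count_waters",
    "count_contacts",
    "dipole_moment",
    "describe_ensemble",
]

#: First-hydration-shell cutoff for water-oxygen counting (Å, inclusive).
WATER_CUTOFF = 3.5
#: Van-der-Waals contact cutoff for nonpolar sites (Å, inclusive).
CONTACT_CUTOFF = 4.5


@dataclass
class Snapshot:
    """One 3D configuration: solute heavy sites plus environment sites."""

    solute_positions: np.ndarray
    water_positions: np.ndarray
    contact_positions: np.ndarray
    label: str = "reactant"  # "reactant" | "TS"

    def __post_init__(self) -> None:
        self.solute_positions = np.asarray(self.solute_positions, dtype=float).reshape(-1, 3)
        self.water_positions = np.asarray(self.water_positions, dtype=float).reshape(-1, 3)
        self.contact_positions = np.asarray(self.contact_positions, dtype=float).reshape(-1, 3)
        for name in ("solute_positions", "water_positions", "contact_positions"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite positions in {name}")


def _count_within(solute: np.ndarray, sites: np.ndarray, cutoff: float) -> int:
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if len(sites) == 0 or len(solute) == 0:
        return 0
    d = cdist(sites, solute)
    return int(np.sum(d.min(axis=1) <= cutoff))


def count_waters(config: Snapshot, cutoff: float = WATER_CUTOFF) -> int:
    """Water oxygens within ``cutoff`` of any solute heavy site (inclusive)."""
    return _count_within(config.solute_positions, config.water_positions, cutoff)


def count_contacts(config: Snapshot, cutoff: float = CONTACT_CUTOFF) -> int:
    """Nonpolar contact sites within ``cutoff`` of any solute site (inclusive)."""
    return _count_within(config.solute_positions, config.contact_positions, cutoff)


def dipole_moment(charges, positions) -> float:
    """Dipole magnitude in Debye of a point-charge set.

    For neutral sets the result is origin-independent; for sets with net
    charge the moment is evaluated about the center of absolute charge
    (a declared convention).
    """
    q = np.asarray(charges, dtype=float)
    r = np.asarray(positions, dtype=float).reshape(-1, 3)
    if q.size == 0:
        raise ValueError("dipole_moment requires at least one charge site")
    if q.shape[0] != r.shape[0]:
        raise ValueError("charges and positions must have matching length")
    if not (np.all(np.isfinite(q)) and np.all(np.isfinite(r))):
        raise ValueError("non-finite charges or positions")
    if abs(q.sum()) > 1e-9:
        w = np.abs(q)
        origin = (w[:, None] * r).sum(axis=0) / w.sum()
        r = r - origin
    mu = (q[:, None] * r).sum(axis=0)
    return float(np.linalg.norm(mu) * DEBYE_PER_E_ANGSTROM)


@dataclass
class DescriptorReport:
    """Ensemble means/spreads of counts, plus dipoles per reaction state."""

    water_mean: dict = field(default_factory=dict)
    water_sd: dict = field(default_factory=dict)
    contact_mean: dict = field(default_factory=dict)
    contact_sd: dict = field(default_factory=dict)
    dipole_debye: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "water_count": {"mean": self.water_mean, "sd": self.water_sd},
            "contact_count": {"mean": self.contact_mean, "sd": self.contact_sd},
            "dipole_debye": self.dipole_debye,
        }


def describe_ensemble(
    snapshots: list[Snapshot],
    charge_sets: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
    water_cutoff: float = WATER_CUTOFF,
    contact_cutoff: float = CONTACT_CUTOFF,
) -> DescriptorReport:
    """Summarize an ensemble of snapshots, grouped by reaction-state label.

    ``charge_sets`` optionally maps a label to (charges, positions) from
    which the per-state dipole is computed.
    """
    report = DescriptorReport()
    by_label: dict[str, list[Snapshot]] = {}
    for snap in snapshots:
        by_label.setdefault(snap.label, []).append(snap)
    for label, group in sorted(by_label.items()):
        waters = np.array([count_waters(s, water_cutoff) for s in group], dtype=float)
        contacts = np.array([count_contacts(s, contact_cutoff) for s in group], dtype=float)
        report.water_mean[label] = float(waters.mean())
        report.water_sd[label] = float(waters.std(ddof=1)) if len(group) > 1 else 0.0
        report.contact_mean[label] = float(contacts.mean())
        report.contact_sd[label] = float(contacts.std(ddof=1)) if len(group) > 1 else 0.0
    if charge_sets:
        for label, (q, pos) in charge_sets.items():
            report.dipole_debye[label] = dipole_moment(q, pos)
    return report
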