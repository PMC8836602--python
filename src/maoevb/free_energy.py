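"""Free-energy profiles along the EVB energy gap from FEP samples.

Two estimators are combined, following standard EVB post-processing:

1. The Zwanzig (exponential-averaging) FEP estimator gives the free energy
   of each mapping potential relative to lambda = 0,

       dG(lam -> lam') = -kBT ln < exp(-(em' - em) / kBT) >_lam ,

   accumulated bidirectionally (forward/backward averaged) over the schedule.

2. Each window's samples are then reweighted from the mapping potential to
   the adiabatic ground state and binned on the energy gap de = e1 - e2:

       dG(de bin) = dG_FEP(lam_m) - kBT ln < 1{de in bin} exp(-(Eg - em)/kBT) >_m

   with window contributions to a bin combined by their sample counts.

The barrier dG_act and reaction free energy dG_rxn are read off the binned
profile: the reactant and product minima and the intervening maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .constants import KB

__all__ = [
    "FEPFrame",
    "FreeEnergyProfile",
    "ReplicaStatistics",
    "UnconvergedProfileError",
    "zwanzig_increment",
    "fep_free_energy_curve",
    "gap_binned_profile",
    "extract_barrier",
    "replica_statistics",
    "analyze_replicas",
]


class UnconvergedProfileError(RuntimeError):
    """Raised when the binned profile has no resolvable two-well structure."""


@dataclass
class FEPFrame:
    """Per-window samples of one replica: diabatic, mapping and adiabatic energies."""

    lam: float
    eps1: np.ndarray
    eps2: np.ndarray
    emap: np.ndarray
    eg: np.ndarray
    replica_id: int = 0
    seed: int = 0
    #: consistency tolerance for emap; raised when energies come from a
    #: fixed-precision TSV round-trip
    emap_atol: float = 1e-9

    def __post_init__(self) -> None:
        for name in ("eps1", "eps2", "emap", "eg"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.eps1)
        if n < 1 or any(len(getattr(self, k)) != n for k in ("eps2", "emap", "eg")):
            raise ValueError("energy arrays must have equal length >= 1")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lam must lie in [0, 1]")
        expected = (1.0 - self.lam) * self.eps1 + self.lam * self.eps2
        tol = self.emap_atol * max(1.0, float(np.max(np.abs(expected))))
        if np.max(np.abs(expected - self.emap)) > tol:
            raise ValueError("emap is inconsistent with (1-lam)*eps1 + lam*eps2")

    @property
    def gap(self) -> np.ndarray:
        """Energy-gap reaction coordinate de = e1 - e2 per sample."""
        return self.eps1 - self.eps2

    @property
    def n_samples(self) -> int:
        return len(self.eps1)


@dataclass
class FreeEnergyProfile:
    """Gap-binned free energy curve with identified stationary points."""

    bin_centers: np.ndarray
    dG: np.ndarray
    counts: np.ndarray
    n_contributing_windows: np.ndarray
    reactant_min: int
    ts: int
    product_min: int

    @property
    def barrier(self) -> float:
        """Activation free energy dG_act (kcal/mol)."""
        return float(self.dG[self.ts] - self.dG[self.reactant_min])

    @property
    def reaction_dG(self) -> float:
        """Reaction free energy dG_rxn (kcal/mol)."""
        return float(self.dG[self.product_min] - self.dG[self.reactant_min])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center_gap": self.bin_centers,
                "dG": self.dG,
                "count": self.counts,
                "n_contributing_windows": self.n_contributing_windows,
            }
        )


@dataclass
class ReplicaStatistics:
    """Replica mean / spread of the barrier and reaction free energy."""

    n: int
    barriers: tuple[float, ...]
    reaction_dGs: tuple[float, ...]
    barrier_mean: float = field(init=False)
    barrier_sd: float = field(init=False)
    barrier_sem: float = field(init=False)
    reaction_mean: float = field(init=False)
    reaction_sd: float = field(init=False)
    reaction_sem: float = field(init=False)

    def __post_init__(self) -> None:
        if self.n < 2 or len(self.barriers) != self.n or len(self.reaction_dGs) != self.n:
            raise ValueError("replica statistics require n >= 2 matching values")
        b = np.asarray(self.barriers)
        q = np.asarray(self.reaction_dGs)
        self.barrier_mean = float(b.mean())
        self.barrier_sd = float(b.std(ddof=1))
        self.barrier_sem = self.barrier_sd / np.sqrt(self.n)
        self.reaction_mean = float(q.mean())
        self.reaction_sd = float(q.std(ddof=1))
        self.reaction_sem = self.reaction_sd / np.sqrt(self.n)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "barrier": {
                "per_replica": list(self.barriers),
                "mean": self.barrier_mean,
                "sd": self.barrier_sd,
                "sem": self.barrier_sem,
            },
            "reaction_dG": {
                "per_replica": list(self.reaction_dGs),
                "mean": self.reaction_mean,
                "sd": self.reaction_sd,
                "sem": self.reaction_sem,
            },
        }


def zwanzig_increment(frame: FEPFrame, lam_next: float, T: float) -> float:
    """Free-energy step from ``frame.lam`` to ``lam_next`` by exponential averaging.

    Evaluated with log-sum-exp, so constant perturbations are exact and large
    energy differences cannot overflow.
    """
    if not 0.0 <= lam_next <= 1.0:
        raise ValueError("lam_next must lie in [0, 1]")
    if lam_next == frame.lam:
        raise ValueError("lam_next must differ from the frame's lambda")
    kbt = KB * T
    # em(lam') - em(lam) = (lam' - lam) * (e2 - e1)
    du = (lam_next - frame.lam) * (frame.eps2 - frame.eps1)
    n = len(du)
    return float(-kbt * (logsumexp(-du / kbt) - np.log(n)))


def fep_free_energy_curve(frames: list[FEPFrame], T: float) -> pd.DataFrame:
    """Cumulative dG(lambda) from bidirectionally averaged Zwanzig steps.

    ``frames`` must cover one replica's full schedule; returns a table with
    columns ``lam`` and ``dG`` where dG(0) = 0.
    """
    ordered = sorted(frames, key=lambda f: f.lam)
    lams = [f.lam for f in ordered]
    if len(set(lams)) != len(lams):
        raise ValueError("duplicate lambda windows in one replica's schedule")
    if not ordered or ordered[0].lam != 0.0 or ordered[-1].lam != 1.0:
        missing = 0.0 if (not ordered or ordered[0].lam != 0.0) else 1.0
        raise ValueError(f"schedule is missing the window at lambda={missing}")
    dg = np.zeros(len(ordered))
    for i in range(len(ordered) - 1):
        fwd = zwanzig_increment(ordered[i], ordered[i + 1].lam, T)
        bwd = zwanzig_increment(ordered[i + 1], ordered[i].lam, T)
        dg[i + 1] = dg[i] + 0.5 * (fwd - bwd)
    return pd.DataFrame({"lam": lams, "dG": dg})


def _locate_stationary_points(dG: np.ndarray) -> tuple[int, int, int]:
    """Reactant minimum, transition state, product minimum bin indices.

    The TS is the highest bin that has a strictly lower bin somewhere on each
    side (first such bin on ties); the flanking minima are the lowest bins on
    either side of it (first on ties).
    """
    n = len(dG)
    best = None
    for j in range(1, n - 1):
        if np.min(dG[:j]) < dG[j] and np.min(dG[j + 1 :]) < dG[j]:
            if best is None or dG[j] > dG[best]:
                best = j
    if best is None:
        raise UnconvergedProfileError("profile has fewer than two local minima")
    ts = best
    reactant = int(np.argmin(dG[:ts]))
    product = ts + 1 + int(np.argmin(dG[ts + 1 :]))
    return reactant, ts, product


def gap_binned_profile(
    frames: list[FEPFrame],
    T: float,
    n_bins: int = 50,
    min_count: int = 10,
) -> FreeEnergyProfile:
    """Free energy along the energy gap from FEP frames.

    Samples of every window are reweighted from the mapping potential to the
    adiabatic ground state and histogrammed on de = e1 - e2; window
    contributions to each bin are combined weighted by sample count.  Bins
    holding fewer than ``min_count`` samples are excluded.  The reactant
    minimum is shifted to zero.

    Frames may come from one replica or pool several; each replica present
    must cover the full schedule (its own FEP curve anchors its windows).
    """
    if n_bins < 10:
        raise ValueError("n_bins must be >= 10")
    dg_fep: dict[tuple[int, float], float] = {}
    by_replica: dict[int, list[FEPFrame]] = {}
    for f in frames:
        by_replica.setdefault(f.replica_id, []).append(f)
    for rid, group in by_replica.items():
        curve = fep_free_energy_curve(group, T)
        for lam, dg in zip(curve["lam"], curve["dG"]):
            dg_fep[(rid, lam)] = dg
    kbt = KB * T

    all_gaps = np.concatenate([f.gap for f in frames])
    lo, hi = float(all_gaps.min()), float(all_gaps.max())
    if hi <= lo:
        raise UnconvergedProfileError("energy gap is constant; no profile to bin")
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    # accumulate count-weighted window estimates per bin
    weight_sum = np.zeros(n_bins)
    weighted_dg = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    nwin = np.zeros(n_bins, dtype=int)
    for f in frames:
        idx = np.clip(np.searchsorted(edges, f.gap, side="right") - 1, 0, n_bins - 1)
        du = (f.eg - f.emap) / kbt  # <= 0, so exp is safe
        n_m = f.n_samples
        for b in np.unique(idx):
            mask = idx == b
            n_mb = int(mask.sum())
            dg_b = dg_fep[(f.replica_id, f.lam)] - kbt * (logsumexp(-du[mask]) - np.log(n_m))
            weighted_dg[b] += n_mb * dg_b
            weight_sum[b] += n_mb
            counts[b] += n_mb
            nwin[b] += 1

    valid = counts >= min_count
    if valid.sum() < 3:
        raise UnconvergedProfileError(
            f"only {int(valid.sum())} bins reached min_count={min_count}"
        )
    dG = weighted_dg[valid] / weight_sum[valid]
    centers = centers[valid]
    counts_v = counts[valid]
    nwin_v = nwin[valid]
    try:
        reactant, ts, product = _locate_stationary_points(dG)
    except UnconvergedProfileError as err:
        raise UnconvergedProfileError(
            f"unconverged profile: {err} (bins={int(valid.sum())})"
        ) from None
    dG = dG - dG[reactant]
    return FreeEnergyProfile(
        bin_centers=centers,
        dG=dG,
        counts=counts_v,
        n_contributing_windows=nwin_v,
        reactant_min=reactant,
        ts=ts,
        product_min=product,
    )


def extract_barrier(profile: FreeEnergyProfile) -> tuple[float, float]:
    """(dG_act, dG_rxn) re-identified from the profile's dG array."""
    reactant, ts, product = _locate_stationary_points(profile.dG)
    return (
        float(profile.dG[ts] - profile.dG[reactant]),
        float(profile.dG[product] - profile.dG[reactant]),
    )


def replica_statistics(per_replica: list[tuple[float, float]]) -> ReplicaStatistics:
    """Mean, sample sd and SEM (sd / sqrt(n)) over replica (dG_act, dG_rxn)."""
    if len(per_replica) < 2:
        raise ValueError("replica statistics require at least 2 replicas")
    barriers = tuple(float(b) for b, _ in per_replica)
    rxns = tuple(float(q) for _, q in per_replica)
    return ReplicaStatistics(n=len(per_replica), barriers=barriers, reaction_dGs=rxns)


def analyze_replicas(
    frames: list[FEPFrame],
    T: float,
    n_bins: int = 50,
    min_count: int = 10,
) -> tuple[list[FreeEnergyProfile], ReplicaStatistics]:
    """Per-replica gap-binned profiles plus replica statistics."""
    by_replica: dict[int, list[FEPFrame]] = {}
    for f in frames:
        by_replica.setdefault(f.replica_id, []).append(f)
    profiles = [
        gap_binned_profile(by_replica[r], T, n_bins=n_bins, min_count=min_count)
        for r in sorted(by_replica)
    ]
    stats = replica_statistics([(p.barrier, p.reaction_dG) for p in profiles])
    return profiles, stats
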