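"""Free-energy estimator tests against closed forms and grid integration."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from maoevb import (
    FEPFrame,
    FEPSchedule,
    ReplicaSpec,
    UnconvergedProfileError,
    extract_barrier,
    fep_free_energy_curve,
    gap_binned_profile,
    replica_statistics,
    run_fep,
    zwanzig_increment,
)
from maoevb.constants import KB
from maoevb.free_energy import FreeEnergyProfile, _locate_stationary_points
from conftest import make_toy_system
from oracles import (
    exhaustive_stationary_points,
    grid_reference_profile,
    harmonic_fep_closed_form,
)

T = 300.0
KBT = KB * T


def make_frame(lam, eps1, eps2, **kw):
    eps1 = np.asarray(eps1, dtype=float)
    eps2 = np.asarray(eps2, dtype=float)
    emap = (1 - lam) * eps1 + lam * eps2
    return FEPFrame(lam=lam, eps1=eps1, eps2=eps2, emap=emap, eg=np.minimum(eps1, eps2), **kw)


def harmonic_frames(k1, k2, n_windows=51, n_samples=4000, seed=0):
    """Exact canonical samples of the mapping potential for a harmonic
    frequency change: em(s) = k_lam/2 s^2 with k_lam = (1-lam) k1 + lam k2."""
    rng = np.random.default_rng(seed)
    frames = []
    for lam in np.linspace(0.0, 1.0, n_windows):
        k_lam = (1 - lam) * k1 + lam * k2
        s = rng.normal(0.0, np.sqrt(KBT / k_lam), size=n_samples)
        frames.append(make_frame(lam, 0.5 * k1 * s**2, 0.5 * k2 * s**2))
    return frames


class TestZwanzigIncrement:
    def test_constant_perturbation_is_exact(self):
        # eps2 = eps1 + c: em(lam') - em(lam) = (lam' - lam) c for any samples
        rng = np.random.default_rng(1)
        eps1 = rng.normal(-20.0, 3.0, 500)
        frame = make_frame(0.3, eps1, eps1 + 7.0)
        assert zwanzig_increment(frame, 0.5, T) == pytest.approx(0.2 * 7.0, abs=1e-12)

    def test_identical_hamiltonians_give_zero(self):
        frame = make_frame(0.2, np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))
        assert zwanzig_increment(frame, 0.4, T) == 0.0

    def test_same_lambda_rejected(self):
        frame = make_frame(0.2, np.array([1.0]), np.array([2.0]))
        with pytest.raises(ValueError):
            zwanzig_increment(frame, 0.2, T)

    def test_overflow_guarded_for_huge_energy_differences(self):
        frame = make_frame(0.0, np.array([0.0, 0.0]), np.array([5.0e4, 5.1e4]))
        val = zwanzig_increment(frame, 1.0, T)
        assert np.isfinite(val)
        assert val == pytest.approx(5.0e4, rel=1e-3)

    def test_harmonic_frequency_change_matches_partition_ratio(self):
        # cumulative FEP over a dense schedule vs (kBT/2) ln(k2/k1)
        frames = harmonic_frames(1.5, 3.0, seed=42)
        curve = fep_free_energy_curve(frames, T)
        exact = harmonic_fep_closed_form(1.5, 3.0, T)
        assert curve["dG"].iloc[-1] == pytest.approx(exact, abs=0.05)


class TestFreeEnergyCurve:
    def test_identical_windows_give_flat_curve(self):
        eps = np.array([-5.0, -4.0, -6.0, -5.5])
        frames = [make_frame(lam, eps, eps) for lam in (0.0, 0.5, 1.0)]
        curve = fep_free_energy_curve(frames, T)
        assert np.allclose(curve["dG"], 0.0)

    def test_constant_offset_telescopes_to_endpoint_difference(self):
        rng = np.random.default_rng(3)
        frames = []
        for lam in np.linspace(0.0, 1.0, 51):
            eps1 = rng.normal(-10.0, 1.0, 200)
            frames.append(make_frame(lam, eps1, eps1 + 12.5))
        curve = fep_free_energy_curve(frames, T)
        assert curve["dG"].iloc[0] == 0.0
        assert curve["dG"].iloc[-1] == pytest.approx(12.5, abs=1e-9)

    def test_missing_window_is_named(self):
        frames = [make_frame(0.0, np.array([1.0]), np.array([2.0]))]
        with pytest.raises(ValueError, match="lambda=1.0"):
            fep_free_energy_curve(frames, T)

    def test_reversed_schedule_negates_total(self, toy_gas_system):
        schedule = FEPSchedule(n_windows=21, steps_per_window=8_000, base_seed=31)
        frames = run_fep(
            toy_gas_system, schedule,
            replicas=ReplicaSpec(n_replicas=1, relaxation_steps=500),
            equilibration_steps=5_000,
        )
        fwd = fep_free_energy_curve(frames, T)["dG"].iloc[-1]
        # reverse: relabel lam -> 1-lam with states swapped (emap unchanged)
        rev_frames = [
            FEPFrame(lam=1.0 - f.lam, eps1=f.eps2, eps2=f.eps1, emap=f.emap, eg=f.eg)
            for f in frames
        ]
        rev = fep_free_energy_curve(rev_frames, T)["dG"].iloc[-1]
        assert rev == pytest.approx(-fwd, abs=0.1)


class TestGapBinnedProfile:
    def test_umbrella_factor_is_unity_for_uncoupled_endpoint_window(self):
        # With H12 = 0 and eps1 < eps2 on every sample, the lam = 0 window has
        # Eg = em sample by sample, so its bins reduce to plain histogram free
        # energies: dG_b = -kBT ln(count_b) up to one additive constant.
        rng = np.random.default_rng(5)
        n = 50_000
        gap0 = np.concatenate(
            [rng.normal(-5.0, 0.8, n // 2), rng.normal(-7.5, 0.8, n // 2)]
        )
        eps1_0 = np.zeros(n)
        frames = [FEPFrame(lam=0.0, eps1=eps1_0, eps2=-gap0, emap=eps1_0, eg=eps1_0)]
        # remaining windows live in a disjoint gap region (constant gap -14)
        for lam in (0.5, 1.0):
            e1 = np.zeros(5_000)
            e2 = np.full(5_000, 14.0)
            frames.append(
                FEPFrame(lam=lam, eps1=e1, eps2=e2, emap=(1 - lam) * e1 + lam * e2, eg=e1)
            )
        prof = gap_binned_profile(frames, T)
        solo = (prof.n_contributing_windows == 1) & (prof.bin_centers > -13.0)
        assert solo.sum() >= 10
        const = prof.dG[solo] + KBT * np.log(prof.counts[solo])
        assert np.std(const) < 1e-9

    def test_gauge_invariance_constant_shift_of_both_states(self, toy_gas_system):
        schedule = FEPSchedule(n_windows=21, steps_per_window=6_000, base_seed=8)
        frames = run_fep(
            toy_gas_system, schedule,
            replicas=ReplicaSpec(n_replicas=1, relaxation_steps=500),
            equilibration_steps=4_000,
        )
        prof = gap_binned_profile(frames, T)
        c = 17.3
        shifted = [
            FEPFrame(lam=f.lam, eps1=f.eps1 + c, eps2=f.eps2 + c, emap=f.emap + c, eg=f.eg + c)
            for f in frames
        ]
        prof_shifted = gap_binned_profile(shifted, T)
        assert prof_shifted.barrier == pytest.approx(prof.barrier, abs=1e-9)
        assert prof_shifted.reaction_dG == pytest.approx(prof.reaction_dG, abs=1e-9)
        assert np.allclose(prof_shifted.bin_centers, prof.bin_centers, atol=1e-9)

    @pytest.mark.parametrize("kind", ["toy-1d", "solvated-2d"])
    def test_barrier_matches_dense_grid_boltzmann_integration(self, kind):
        # replica-averaged FEP estimate vs dense-grid Boltzmann integration
        from maoevb import build_system, default_environment, default_solute, measure_system
        from maoevb.calibration import CalibrationResult

        if kind == "toy-1d":
            system = make_toy_system(alpha=3.0, h12=1.5)
        else:
            cal = CalibrationResult(
                alpha=25.0, h12=4.0, achieved=(0.0, 0.0), iterations=0, converged=True, tol=0.1
            )
            system = build_system(default_solute("HIS"), default_environment("water"), cal)
        barrier, rxn, _sb, _sq = measure_system(
            system, FEPSchedule(base_seed=77), ReplicaSpec(n_replicas=10)
        )
        ref_barrier, ref_rxn = grid_reference_profile(system)
        assert barrier == pytest.approx(ref_barrier, abs=0.2)
        assert rxn == pytest.approx(ref_rxn, abs=0.2)

    def test_unconverged_profile_raises(self):
        # constant energy gap: nothing to bin, no two-well structure
        rng = np.random.default_rng(9)
        frames = []
        for lam in (0.0, 1.0):
            eps1 = rng.normal(0.0, 0.1, 2_000)
            eps2 = eps1 - 5.0
            emap = (1 - lam) * eps1 + lam * eps2
            frames.append(FEPFrame(lam=lam, eps1=eps1, eps2=eps2, emap=emap, eg=np.minimum(eps1, eps2)))
        with pytest.raises(UnconvergedProfileError):
            gap_binned_profile(frames, T)

    def test_too_few_bins_rejected(self):
        frame = make_frame(0.0, np.zeros(100), np.linspace(-1, 1, 100))
        with pytest.raises(ValueError, match="n_bins"):
            gap_binned_profile([frame], T, n_bins=5)



class TestExtractBarrier:
    def _profile(self, dG):
        dG = np.asarray(dG, dtype=float)
        r, ts, p = _locate_stationary_points(dG)
        return FreeEnergyProfile(
            bin_centers=np.arange(len(dG), dtype=float), dG=dG,
            counts=np.full(len(dG), 100), n_contributing_windows=np.ones(len(dG), dtype=int),
            reactant_min=r, ts=ts, product_min=p,
        )

    def test_piecewise_example(self):
        prof = self._profile([0.0, 5.0, 1.0])
        assert extract_barrier(prof) == (5.0, 1.0)

    def test_symmetric_double_well_has_zero_reaction_free_energy(self):
        x = np.linspace(-2, 2, 41)
        dG = (x**2 - 1.0) ** 2  # symmetric double well
        prof = self._profile(dG)
        barrier, rxn = extract_barrier(prof)
        assert rxn == pytest.approx(0.0, abs=1e-12)
        assert barrier == pytest.approx(1.0)

    def test_monotone_profile_rejected(self):
        with pytest.raises(UnconvergedProfileError):
            self._profile(np.linspace(0.0, 5.0, 20))

    @given(st.lists(st.floats(-10.0, 10.0), min_size=5, max_size=60))
    def test_agrees_with_exhaustive_scan_on_random_curves(self, values):
        dG = np.asarray(values)
        try:
            expected = exhaustive_stationary_points(dG)
        except ValueError:
            with pytest.raises(UnconvergedProfileError):
                _locate_stationary_points(dG)
            return
        assert _locate_stationary_points(dG) == expected


class TestReplicaStatistics:
    def test_identical_replicas_have_zero_sem(self):
        stats = replica_statistics([(5.0, 1.0)] * 10)
        assert stats.barrier_sem == 0.0
        assert stats.reaction_sem == 0.0

    def test_hand_computed_sample_statistics(self):
        vals = [(float(i), 0.0) for i in range(1, 11)]
        stats = replica_statistics(vals)
        assert stats.n == 10
        assert stats.barrier_mean == pytest.approx(5.5)
        assert stats.barrier_sd == pytest.approx(3.02765, abs=1e-5)
        assert stats.barrier_sem == pytest.approx(0.95743, abs=1e-5)

    def test_sem_recomputes_as_sd_over_sqrt_n(self):
        rng = np.random.default_rng(13)
        vals = [(float(v), float(w)) for v, w in rng.normal(5, 1, (7, 2))]
        stats = replica_statistics(vals)
        b = np.array([v for v, _ in vals])
        assert stats.barrier_sem == pytest.approx(b.std(ddof=1) / np.sqrt(7), abs=1e-12)

    def test_fewer_than_two_replicas_rejected(self):
        with pytest.raises(ValueError):
            replica_statistics([(5.0, 1.0)])


class TestSEMTrend:
    def test_quadrupling_replicas_roughly_halves_sem(self, toy_gas_system):
        # SEM ~ sd/sqrt(n): with 4x the replicas the SEM of the barrier
        # should drop by ~2 (tolerance factor 1.5 on the ratio)
        def sem_with(n, seed):
            schedule = FEPSchedule(n_windows=11, steps_per_window=4_000, base_seed=seed)
            frames = run_fep(
                toy_gas_system, schedule,
                replicas=ReplicaSpec(n_replicas=n, relaxation_steps=500),
                equilibration_steps=4_000,
            )
            per = {}
            for f in frames:
                per.setdefault(f.replica_id, []).append(f)
            vals = [
                (p.barrier, p.reaction_dG)
                for p in (gap_binned_profile(fs, T) for fs in per.values())
            ]
            return replica_statistics(vals).barrier_sem

        ratios = []
        for seed in (51, 52, 53):
            ratios.append(sem_with(4, seed) / sem_with(16, seed))
        mean_ratio = np.mean(ratios)
        assert 2.0 / 1.5 < mean_ratio < 2.0 * 1.5
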