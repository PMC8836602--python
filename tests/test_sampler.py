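"""Sampler tests: determinism, endpoint identities, canonical statistics."""

import numpy as np
import pytest
from scipy import stats as sps

from maoevb import (
    Configuration,
    FEPSchedule,
    ReplicaSpec,
    RestraintSet,
    equilibrate,
    run_fep,
    sample_window,
)
from maoevb.constants import KB
from conftest import make_toy_system


@pytest.fixture(scope="module")
def short_schedule():
    return FEPSchedule(n_windows=5, steps_per_window=2_000, base_seed=42)


class TestEquilibrate:
    def test_zero_steps_returns_input_unchanged(self, toy_gas_system):
        start = Configuration(np.array([1.05, 0.3]), np.array([0.01, -0.02]))
        out = equilibrate(toy_gas_system, start, 0, seed=1)
        assert np.array_equal(out.coordinates, start.coordinates)
        assert np.array_equal(out.velocities, start.velocities)
        assert out is not start

    def test_same_seed_gives_identical_output(self, toy_gas_system):
        start = Configuration(np.array([1.05, 0.0]))
        a = equilibrate(toy_gas_system, start, 5_000, seed=9)
        b = equilibrate(toy_gas_system, start, 5_000, seed=9)
        assert np.array_equal(a.coordinates, b.coordinates)
        assert np.array_equal(a.velocities, b.velocities)

    def test_equipartition_variance_of_harmonic_coordinate(self):
        # solvent coordinate is harmonic with k = 2.0; long-run variance must
        # approach kB T / k (both states share the same solvent term at lam=0);
        # friction 5/ps decorrelates the soft mode within the run length
        system = make_toy_system(solvent_k=2.0, solvent_eq2=0.0)
        schedule = FEPSchedule(
            n_windows=2, steps_per_window=800_000, base_seed=5, sample_stride=20, friction=5.0
        )
        config = equilibrate(system, Configuration(np.array([1.05, 0.0])), 10_000, seed=3,
                             schedule=schedule)
        from maoevb.sampler import _integrate

        rng = np.random.default_rng(12)
        cfg2 = Configuration(config.coordinates.copy())
        restraints = RestraintSet(((0, 1.2, 0.5),))  # none on s
        pos = _integrate(system, cfg2, 0.0, 800_000, schedule, restraints, rng, stride=20)
        var = np.var(pos[:, 1])
        assert var == pytest.approx(KB * 300.0 / 2.0, rel=0.05)


class TestSampleWindow:
    def test_endpoint_identity_lambda_zero(self, toy_gas_system, short_schedule):
        config = Configuration(np.array([1.05, 0.0]))
        restraints = RestraintSet(((0, 1.2, 0.5),))
        frame = sample_window(toy_gas_system, config, 0.0, short_schedule, restraints, seed=4)
        assert np.array_equal(frame.emap, frame.eps1)
        # thermal offset above the well minimum is of order kB T
        assert -25.0 < frame.eps1.mean() < -23.0

    def test_endpoint_identity_lambda_one(self, toy_gas_system, short_schedule):
        config = Configuration(np.array([1.35, 0.0]))
        restraints = RestraintSet()
        frame = sample_window(toy_gas_system, config, 1.0, short_schedule, restraints, seed=4)
        assert np.array_equal(frame.emap, frame.eps2)

    def test_zero_force_constant_equals_restraint_free_run(self, toy_gas_system, short_schedule):
        a = sample_window(
            toy_gas_system, Configuration(np.array([1.05, 0.0])), 0.0, short_schedule,
            RestraintSet(((0, 1.2, 0.0), (1, 0.0, 0.0))), seed=6,
        )
        b = sample_window(
            toy_gas_system, Configuration(np.array([1.05, 0.0])), 0.0, short_schedule,
            RestraintSet(), seed=6,
        )
        assert np.array_equal(a.eps1, b.eps1)
        assert np.array_equal(a.eps2, b.eps2)

    def test_midpoint_mapping_identity_on_emitted_frame(self, toy_gas_system):
        schedule = FEPSchedule(n_windows=3, steps_per_window=2_000, base_seed=2)
        frame = sample_window(
            toy_gas_system, Configuration(np.array([1.2, 0.0])), 0.5, schedule,
            RestraintSet(), seed=3,
        )
        lhs = (frame.eps1 - frame.emap).mean()
        rhs = ((frame.eps1 - frame.eps2) / 2.0).mean()
        assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_lambda_not_in_schedule_rejected(self, toy_gas_system, short_schedule):
        with pytest.raises(ValueError, match="not part of the schedule"):
            sample_window(
                toy_gas_system, Configuration(np.array([1.05, 0.0])), 0.123,
                short_schedule, RestraintSet(), seed=1,
            )

    def test_sample_count_contract(self, toy_gas_system):
        schedule = FEPSchedule(n_windows=2, steps_per_window=10_000, base_seed=1)
        frame = sample_window(
            toy_gas_system, Configuration(np.array([1.05, 0.0])), 0.0, schedule,
            RestraintSet(), seed=1,
        )
        expected = int(10_000 / 10 * (1 - 0.1))
        assert frame.n_samples == expected


class TestRunFEP:
    def test_shape_contract_single_replica_two_windows(self, toy_gas_system):
        schedule = FEPSchedule(n_windows=2, lambdas=(0.0, 1.0), steps_per_window=1_000, base_seed=7)
        frames = run_fep(
            toy_gas_system, schedule, replicas=ReplicaSpec(n_replicas=1, relaxation_steps=100),
            equilibration_steps=500,
        )
        assert len(frames) == 2
        assert [f.lam for f in frames] == [0.0, 1.0]

    def test_rerun_with_same_seed_is_bit_identical(self, toy_gas_system):
        schedule = FEPSchedule(n_windows=3, steps_per_window=1_500, base_seed=11)
        reps = ReplicaSpec(n_replicas=2, relaxation_steps=200)
        a = run_fep(toy_gas_system, schedule, replicas=reps, equilibration_steps=1_000)
        b = run_fep(toy_gas_system, schedule, replicas=reps, equilibration_steps=1_000)
        for fa, fb in zip(a, b):
            assert np.array_equal(fa.eps1, fb.eps1)
            assert np.array_equal(fa.emap, fb.emap)
            assert fa.seed == fb.seed

    def test_replicas_differ_but_overlap_statistically(self, toy_gas_system):
        # friction 10/ps decorrelates the energies within ~0.1 ps, so every
        # 50th recorded sample (250 fs apart) is effectively independent
        schedule = FEPSchedule(
            n_windows=2, lambdas=(0.0, 1.0), steps_per_window=20_000, base_seed=13, friction=10.0
        )
        frames = run_fep(
            toy_gas_system, schedule, replicas=ReplicaSpec(n_replicas=2, relaxation_steps=500),
            equilibration_steps=2_000,
        )
        r0 = [f for f in frames if f.replica_id == 0 and f.lam == 0.0][0]
        r1 = [f for f in frames if f.replica_id == 1 and f.lam == 0.0][0]
        assert not np.array_equal(r0.eps1, r1.eps1)
        # same Hamiltonian and temperature: energy distributions must overlap
        _stat, p = sps.mannwhitneyu(r0.eps1[::50], r1.eps1[::50])
        assert p > 0.01

    def test_output_ordering_is_replica_major(self, toy_gas_system):
        schedule = FEPSchedule(n_windows=3, steps_per_window=800, base_seed=3)
        frames = run_fep(
            toy_gas_system, schedule, replicas=ReplicaSpec(n_replicas=2, relaxation_steps=100),
            equilibration_steps=400,
        )
        assert [(f.replica_id, f.lam) for f in frames] == [
            (r, lam) for r in (0, 1) for lam in schedule.lambdas
        ]

    def test_replica_seeds_distinct(self):
        spec = ReplicaSpec(n_replicas=10)
        seeds = spec.replica_seeds(999)
        assert len(set(seeds)) == 10
        assert all(0 <= s < 2**31 for s in seeds)


class TestBoltzmannSampling:
    def test_harmonic_energy_histogram_matches_boltzmann(self):
        # single harmonic coordinate: sampled potential energies follow the
        # 1-dof Boltzmann (gamma(1/2)) density; KS distance below threshold
        system = make_toy_system(solvent_k=2.0)
        schedule = FEPSchedule(n_windows=2, steps_per_window=600_000, base_seed=17, sample_stride=30)
        from maoevb.sampler import _integrate, RestraintSet as RS

        rng = np.random.default_rng(19)
        cfg = Configuration(np.array([1.05, 0.0]))
        pos = _integrate(system, cfg, 0.0, 600_000, schedule, RS(((0, 1.2, 0.5),)), rng, stride=30)
        u = 0.5 * 2.0 * pos[:, 1] ** 2 / (KB * 300.0)  # in kB T
        # u ~ Gamma(k=1/2, theta=1)
        d, _p = sps.kstest(u[2_000:], sps.gamma(a=0.5).cdf)
        assert d < 0.02
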