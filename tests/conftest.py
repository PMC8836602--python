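import pytest
from hypothesis import HealthCheck, settings

from maoevb import (
    CoordinateSpec,
    CouplingModel,
    DiabaticState,
    EVBSystem,
)
from maoevb.io import validate_config
from maoevb.pipeline import calibrate_substrate, run_environment

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_toy_system(
    alpha: float = 3.0,
    h12: float = 1.5,
    solvent_k: float = 0.0,
    solvent_eq2: float = 0.0,
    env_shift2: float = 0.0,
    ts_depth: float = 0.0,
    ts_center: float = 1.2,
    temperature: float = 300.0,
) -> EVBSystem:
    """A soft two-well toy surface (barrier a few kcal/mol) for oracle checks."""
    common = dict(bond_D=25.0, bond_beta=1.5, nonbonded_repulsion=0.02)
    state1 = DiabaticState(
        state_index=1, bond_r0=1.05, solvent_coupling_k=solvent_k, solvent_eq=0.0,
        ts_well_depth=ts_depth, ts_well_center=ts_center, **common,
    )
    state2 = DiabaticState(
        state_index=2, bond_r0=1.00, solvent_coupling_k=solvent_k, solvent_eq=solvent_eq2,
        gas_shift_alpha=alpha, env_shift=env_shift2,
        ts_well_depth=ts_depth, ts_well_center=ts_center, **common,
    )
    return EVBSystem(
        state1=state1,
        state2=state2,
        coupling=CouplingModel(h12_constant=h12),
        environment_tag="gas" if solvent_k == 0.0 else "water",
        substrate_tag="HIS",
        temperature=temperature,
        coordinate_spec=CoordinateSpec(donor_acceptor_R=2.4),
    )


@pytest.fixture(scope="session")
def toy_gas_system():
    return make_toy_system()


@pytest.fixture(scope="session")
def toy_solvated_system():
    return make_toy_system(solvent_k=1.5, solvent_eq2=1.5, env_shift2=-2.0)


@pytest.fixture(scope="session")
def default_config():
    cfg = validate_config({})
    cfg.seed = 123
    return cfg


@pytest.fixture(scope="session")
def calibrations(default_config):
    """Gas-phase calibrations of both substrates under the default protocol."""
    return {sub: calibrate_substrate(default_config, sub) for sub in ("HIS", "NMH")}


@pytest.fixture(scope="session")
def pipeline_runs(default_config, calibrations):
    """Replica statistics for every (environment, substrate) over three seeds.

    Fresh seeds (distinct from the calibration seed) so gas-phase runs are
    genuine re-measurements of the calibrated surfaces.
    """
    runs = {}
    for seed in (101, 202, 303):
        cfg = validate_config({})
        cfg.seed = seed
        for env in ("gas", "water", "enzyme"):
            for sub in ("HIS", "NMH"):
                run = run_environment(cfg, sub, env, calibrations[sub])
                runs[(env, sub, seed)] = run.stats
    return runs
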