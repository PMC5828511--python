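import numpy as np
import pytest

from plumetrack.crossings import ExclusionPolicy, apply_exclusions, extract_all_crossings
from plumetrack.geometry import GaussianPlume, WindTunnelGeometry
from plumetrack.synthetic import SyntheticEffects, generate_dataset
from plumetrack.walkers import SurgeParams, WalkerParams, draw_batch_geometry, simulate_batch


@pytest.fixture(scope="session")
def env():
    return WindTunnelGeometry()


@pytest.fixture(scope="session")
def plume():
    return GaussianPlume(sigma0=0.02, detection_threshold=0.1)


@pytest.fixture(scope="session")
def wide_plume():
    # wide enough that a 4 cm lattice contains plume cells
    return GaussianPlume(sigma0=0.05, detection_threshold=0.1)


@pytest.fixture(scope="session")
def walker_params():
    return WalkerParams()


@pytest.fixture(scope="session")
def synth_dataset(env, plume):
    """Moderate synthetic dataset with both effects injected."""
    effects = SyntheticEffects(
        n_traj=250, conc_gain=1.0, history_factor=0.5, seed=42
    )
    return generate_dataset(effects, env, plume)


@pytest.fixture(scope="session")
def synth_crossings(synth_dataset, env, plume):
    crossings = extract_all_crossings(synth_dataset, plume.detection_threshold)
    return apply_exclusions(crossings, ExclusionPolicy(), env)


@pytest.fixture(scope="session")
def surge_cast_batch(env, wide_plume, walker_params):
    rng = np.random.default_rng(7)
    n_steps, starts = draw_batch_geometry(150, env, rng)
    return simulate_batch(
        walker_params, env, wide_plume, n_steps, starts, rng,
        mode="surge", surge=SurgeParams(), id_prefix="surgecast",
    )


@pytest.fixture(scope="session")
def surge_cast_crossings(surge_cast_batch, env, wide_plume):
    crossings = extract_all_crossings(
        surge_cast_batch, wide_plume.detection_threshold
    )
    return apply_exclusions(crossings, ExclusionPolicy(), env)


@pytest.fixture(scope="session")
def infotaxis_batch(env, wide_plume):
    from plumetrack.infotaxis import InfotaxisPlumeModel, run_infotaxis_batch

    model = InfotaxisPlumeModel(V=env.wind_speed)
    return run_infotaxis_batch(
        60, model, wide_plume, env, seed=11, lattice_spacing=0.04
    )


@pytest.fixture(scope="session")
def infotaxis_crossings(infotaxis_batch, env, wide_plume):
    trajs, _ = infotaxis_batch
    crossings = extract_all_crossings(trajs, wide_plume.detection_threshold)
    return apply_exclusions(crossings, ExclusionPolicy(), env)
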