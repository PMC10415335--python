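import numpy as np
import pytest

import footspring as fs
from footspring import io, kinematics


@pytest.fixture(scope="session")
def template():
    return fs.build_default_template()


@pytest.fixture(scope="session")
def config():
    return fs.RunConfig()


def _roundtrip(sex, template, config, noise=0.0, seed=11):
    """Generate a noise-free preset trial and push it through the pipeline."""
    params = fs.preset_params(sex, marker_noise_mm=noise)
    trial, truth = fs.generate_drop_jump_trial(template, params, seed=seed)
    standing = fs.generate_standing_trial(
        template, fs.Subject("S1", sex, params.body_mass), seed=seed + 1
    )
    model = fs.scale_to_subject(template, standing, params.body_mass, "S1")
    reference = kinematics.standing_reference(model, standing)
    result = io.process_trial(model, trial, config, reference)
    return {
        "params": params,
        "trial": trial,
        "truth": truth,
        "standing": standing,
        "model": model,
        "result": result,
    }


@pytest.fixture(scope="session")
def female_run(template, config):
    return _roundtrip("female", template, config)


@pytest.fixture(scope="session")
def male_run(template, config):
    return _roundtrip("male", template, config)


@pytest.fixture(scope="session")
def female_model(female_run):
    return female_run["model"]


def make_static_pose_series(n_frames, rotation=None, translation=None):
    """Constant PoseSeries helper used by the dynamics/PA oracles."""
    from footspring.foot_model import PoseSeries

    r = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
    return PoseSeries(
        np.tile(r, (n_frames, 1, 1)),
        np.tile(t, (n_frames, 1)),
        np.zeros(n_frames),
        np.ones(n_frames, dtype=bool),
    )
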