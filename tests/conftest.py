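import numpy as np
import pytest

import cochleapy as cp


@pytest.fixture
def planar_params() -> cp.SpiralParams:
    """A 9.0 x 6.5 mm, 2.6-turn cochlea with a flat basal plane, for
    exact-recovery tests free of projection effects."""
    return cp.SpiralParams(
        basal_diameter_A=9.0, width_B=6.5, turns=2.6, axial_height=0.0
    )


@pytest.fixture
def planar_truth(planar_params) -> cp.CochleaTruth:
    return cp.generate_cochlea(planar_params)


@pytest.fixture
def truth_3d() -> cp.CochleaTruth:
    """A non-planar cochlea (apex drop 2.5 mm) with an implanted array."""
    truth = cp.generate_cochlea(
        cp.SpiralParams(basal_diameter_A=9.0, width_B=6.5, turns=2.6, axial_height=2.5)
    )
    return truth.with_array(cp.place_electrode(truth))


@pytest.fixture
def noiseless_profile() -> cp.ModalityProfile:
    return cp.ModalityProfile(
        name="exact", slice_thickness_um=99.0, landmark_noise_sd=0.0
    )


def observe_exact(truth, **kwargs) -> cp.LandmarkSet:
    """Noiseless, untransformed observation of a ground-truth ear."""
    profile = cp.ModalityProfile(
        name="exact", slice_thickness_um=99.0, landmark_noise_sd=0.0
    )
    kwargs.setdefault("apply_rigid_transform", False)
    return cp.observe(truth, profile, series_id=1, seed=0, **kwargs)


def random_rigid(rng: np.random.Generator):
    """An independent random rotation + translation for invariance tests."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, [0, 1]] = q[:, [1, 0]]
    return q, rng.normal(0.0, 15.0, size=3)


def transform_landmarks(ls: cp.LandmarkSet, rot, trans) -> cp.LandmarkSet:
    return cp.LandmarkSet(
        subject_id=ls.subject_id,
        group=ls.group,
        modality=ls.modality,
        series=ls.series,
        round_window=rot @ ls.round_window + trans,
        modiolus=rot @ ls.modiolus + trans,
        wall=ls.wall @ rot.T + trans,
        contacts=None if ls.contacts is None else ls.contacts @ rot.T + trans,
    )
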