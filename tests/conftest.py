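"""Shared synthetic scenes.

Session-scoped ground truths keep the suite fast: tests must not mutate
fixture volumes in place (stage operations return clones).
"""

import numpy as np
import pytest
from hypothesis import settings

import phantomcal as pc
from phantomcal.synthetic_ct import INSERT_BASE

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")

FEMUR_SHAPE = (150, 100, 100)
FEMUR_SPACING = (0.16, 0.16, 0.16)


@pytest.fixture(scope="session")
def phantom_spec():
    return pc.default_phantom_spec()


@pytest.fixture(scope="session")
def phantom_gt(phantom_spec):
    shape, spacing = pc.default_phantom_grid(phantom_spec)
    return pc.generate_phantom(phantom_spec, shape, spacing)


@pytest.fixture(scope="session")
def femur_params():
    return pc.BonePhantomParams(seed=11)


@pytest.fixture(scope="session")
def femur_gt(femur_params):
    return pc.generate_femur(femur_params, FEMUR_SHAPE, FEMUR_SPACING)


@pytest.fixture(scope="session")
def femur_small():
    params = pc.BonePhantomParams(
        outer_radius_mm=(6.5, 5.5), cortical_thickness_mm=1.5, seed=4
    )
    return pc.generate_femur(params, (80, 60, 60), (0.25, 0.25, 0.25))


@pytest.fixture(scope="session")
def stage_params():
    return pc.SurgicalStageParams(debris_retention=1.0, seed=5)


@pytest.fixture(scope="session")
def calibrate(phantom_gt, phantom_spec):
    """Factory: render the phantom under a protocol and fit the line."""

    def _fit(protocol):
        scan = pc.render_scan(phantom_gt, protocol)
        labels = pc.segment_inserts(scan, phantom_spec)
        hists = pc.mean_intensity_per_label(
            scan, labels, [INSERT_BASE + k for k in range(len(phantom_spec.inserts))]
        )
        points = [
            (hists[INSERT_BASE + k].mean, ins.density_gcc)
            for k, ins in enumerate(phantom_spec.inserts)
        ]
        return pc.fit_calibration(points)

    return _fit


def label_volume(mask, spacing, origin=(0.0, 0.0, 0.0)):
    return pc.LabelVolume(np.asarray(mask).astype(np.int32), spacing, origin)
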