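"""Shared fixtures: all test data are generated programmatically.

Expensive micro-FE solutions are session-scoped; the geometries are chosen
small enough that the whole suite runs on one CPU in a few minutes.
"""

from __future__ import annotations

import logging

import pytest

import osteoadapt as oa
from osteoadapt.fitting import FitData

logging.getLogger("osteoadapt").setLevel(logging.ERROR)

#: segmentation threshold of the default phantom calibration
#: (background gray 40, bone gray 200)
PHANTOM_THRESHOLD = 120.0


@pytest.fixture(scope="session")
def tiny_tube():
    """A fast annulus phantom for FE unit tests: OD 12 / ID 7 voxels, 30
    slices (~2.4k elements)."""
    spec = oa.standard_tube_spec(n_slices=30, outer_radius_vox=6.0, inner_radius_vox=3.5)
    image, mask = oa.make_phantom(spec)
    return spec, image, mask


@pytest.fixture(scope="session")
def tiny_solution(tiny_tube):
    """Solved combined-load problem on the tiny tube."""
    _, _, mask = tiny_tube
    material = oa.Material()
    load = oa.LoadCase("combined", bw=22.0)
    problem = oa.build_problem(mask, material, load)
    solution = oa.solve(problem)
    sed = oa.element_sed(problem, solution)
    return problem, solution, sed


@pytest.fixture(scope="session")
def small_tube():
    """The recovery-experiment tube: OD 20 / ID 12 voxels, 60 slices."""
    spec = oa.standard_tube_spec(n_slices=60, outer_radius_vox=10.0, inner_radius_vox=6.0)
    image, mask = oa.make_phantom(spec)
    return spec, image, mask


@pytest.fixture(scope="session")
def recovery_truth():
    return oa.RemodelingParams(0.15, 0.2, 6000.0)


@pytest.fixture(scope="session")
def recovery_pair(small_tube, recovery_truth):
    """Burned-in baseline and one-step follow-up generated by the forward
    model itself (ground truth known)."""
    spec, image, _ = small_tube
    load = oa.LoadCase("physio", bw=22.0)
    base = oa.evolve_phantom(
        image, recovery_truth, load, spec.calibration, steps=2,
        threshold=PHANTOM_THRESHOLD,
    )
    follow = oa.evolve_phantom(
        base, recovery_truth, load, spec.calibration, steps=1,
        threshold=PHANTOM_THRESHOLD,
    )
    return base, follow, load, spec.calibration


@pytest.fixture(scope="session")
def recovery_data(recovery_pair):
    base, follow, load, calib = recovery_pair
    return FitData.from_images(base, follow, load, calib, threshold=PHANTOM_THRESHOLD)
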