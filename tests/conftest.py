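"""Shared fixtures: phantoms at the study scale and a reduced scale.

The full-scale phantom (64³ at 2.5 mm) carries the default study
conditions; the small phantom (48³) keeps geometry proportions but shrinks
the field of view so expensive operations (deformable registration
variants, CLI round trips) stay fast. Session scope avoids regenerating
identical deterministic volumes.
"""

from __future__ import annotations

import pytest

import sirtplan as sp


def noiseless_spec(**kw) -> sp.PhantomSpec:
    base = dict(ct_noise_hu=0.0, pet_noise_suv=0.0, cbct_noise_hu=0.0,
                deformation=sp.DeformationSpec(amplitude_mm=0.0))
    base.update(kw)
    return sp.PhantomSpec(**base)


def small_spec(**kw) -> sp.PhantomSpec:
    """48³ phantom with proportionally scaled geometry."""
    base = dict(
        shape=(48, 48, 48), spacing=(2.5, 2.5, 2.5),
        liver_center_mm=(58.0, 56.0, 60.0),
        liver_semiaxes_mm=(40.0, 30.0, 34.0),
        plane_normal=(0.94, 0.25, 0.23),
        plane_point_mm=(50.0, 56.0, 60.0),
        body_semiaxes_mm=(56.0, 52.0, 60.0),
        spine_center_xy_mm=(58.0, 14.0),
        tumors=(sp.TumorSpec(center_mm=(74.0, 60.0, 64.0), radius_mm=8.0, peak_suv=8.0),),
    )
    base.update(kw)
    return sp.PhantomSpec(**base)


@pytest.fixture(scope="session")
def noiseless_study() -> sp.PhantomStudy:
    return sp.generate_phantom(noiseless_spec())


@pytest.fixture(scope="session")
def noisy_study() -> sp.PhantomStudy:
    """Default study conditions: CT noise 20 HU, PET noise 0.3 SUV, 6 mm
    deformation between the FDG and MAA frames."""
    return sp.generate_phantom(sp.PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def deformable_result(noisy_study):
    """One full-scale deformable registration, shared by the tests that
    check alignment quality, Jacobian QC and warped-PET topology."""
    st = noisy_study
    fixed = sp.median_filter_stack(st.ct_maa, 1)
    moving = sp.median_filter_stack(st.ct_fdg, 1)
    classes = sp.classify_tissue(fixed, st.truth.liver)
    field = sp.register_deformable(moving, fixed, classes, iterations=80)
    return st, field
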