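"""Shared fixtures: small phantoms and a registered pair, built once."""

from __future__ import annotations

import numpy as np
import pytest

from erosiotrack import (
    PhantomSpec,
    RigidTransform,
    implant_lesion,
    make_followup,
    make_phantom,
)

#: grid small enough to register in seconds, large enough to hold lesions
#: with in-plane margin for ~10-voxel translations
SMALL_SHAPE = (64, 64, 112)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    return PhantomSpec(grid_shape=SMALL_SHAPE, followup_slices=96, seed=1)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return make_phantom(small_spec)


@pytest.fixture(scope="session")
def lesion_sites(small_spec):
    """Erosion (on cortex) and enthesiophyte (just outside) seed points."""
    centers = small_spec.head_centers_vox()
    r = small_spec.radius_vox
    ero = (
        int(centers[0][0] + 12),
        int(centers[0][1] + r - 1),
        int(centers[0][2]),
    )
    ent = (
        int(centers[1][0] + 12),
        int(centers[1][1]),
        int(centers[1][2] + r * small_spec.head_radius_scale[1] + 1),
    )
    return ero, ent


@pytest.fixture(scope="session")
def lesioned_pair(small_spec, lesion_sites):
    """Baseline with two lesions, follow-up with known motion and growth."""
    ero, ent = lesion_sites
    base, peri = make_phantom(small_spec)
    base, les_e = implant_lesion(base, peri, "erosion", ero, 4.2, small_spec, 0)
    base, les_n = implant_lesion(
        base, peri, "enthesiophyte", ent, 3.4, small_spec, 1
    )
    # proximal z-shift and small in-plane motion: the longer follow-up
    # stack then covers the whole baseline slab, as in the scan protocol
    motion = RigidTransform.from_euler(
        np.deg2rad([5.0, 0.0, 0.0]), (-0.5, -0.2, 0.3), center_mm=base.center_mm()
    )
    followup, lesions, t5 = make_followup(
        small_spec, [les_e, les_n], motion, {0: 0.6, 1: 0.4}, noise_sd=0.0
    )
    return {
        "spec": small_spec,
        "baseline": base,
        "periosteal": peri,
        "followup": followup,
        "motion": motion,
        "lesions": lesions,
        "t5_scene": t5,
        "seeds": {"erosion": ero, "enthesiophyte": ent},
    }
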