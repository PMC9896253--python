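"""Shared fixtures: small phantoms and cohorts generated at test time."""

import numpy as np
import pytest

from csficv import phantom as phm


@pytest.fixture(scope="session")
def default_phantom():
    """Default 64^3 phantom at mid atrophy: tissue map, truth, noisy CT, atlas."""
    spec = phm.PhantomSpec(atrophy=0.5, seed=11)
    tmap = phm.make_tissue_map(spec)
    return {
        "spec": spec,
        "tmap": tmap,
        "truth": phm.true_volumes(tmap),
        "ct": phm.render_ct(tmap, spec),
        "atlas": phm.make_atlas(tmap),
    }


@pytest.fixture(scope="session")
def extended_cohort():
    """A calibrated extended-model cohort at n=4000 (shared, read-only)."""
    spec = phm.default_cohort_spec("extended", n=4000, seed=42)
    return phm.simulate_cohort(spec)


def make_uniform_tissue_map(shape=(10, 10, 10), voxel=(1.0, 1.0, 1.0), csf=1.0, gm=0.0, wm=0.0):
    """Handmade tissue map with constant per-voxel fractions."""
    bg = 1.0 - (csf + gm + wm)
    fractions = np.empty(shape + (4,))
    fractions[..., 0] = csf
    fractions[..., 1] = gm
    fractions[..., 2] = wm
    fractions[..., 3] = bg
    return phm.TissueMap(fractions=fractions, voxel_size=voxel)
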