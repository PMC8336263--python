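"""Shared fixtures: small synthetic plants and bundles.

Unit tests use a scaled-down rosette (one canvas, default geometry but a
small panel) so the suite stays fast; the acceptance tests build the full
default panel themselves.
"""

from __future__ import annotations

import numpy as np
import pytest

import xrfquant as xq


@pytest.fixture(scope="session")
def small_spec() -> xq.PanelSpec:
    """A 4-accession × 3-replicate panel spec with default geometry."""
    return xq.PanelSpec(n_accessions=4, n_reps=3, seed=7)


@pytest.fixture(scope="session")
def small_panel(small_spec):
    return xq.generate_panel(small_spec)


@pytest.fixture(scope="session")
def one_plant(small_panel):
    """One synthetic bundle with its ground truth."""
    plants, _ = small_panel
    return plants[0]


@pytest.fixture(scope="session")
def noiseless_plant():
    """A clean rosette: no pixel noise, no leaf heterogeneity, fixed scale."""
    spec = xq.PanelSpec(
        n_accessions=1, n_reps=1,
        noise_sd=0.0, compton_noise_sd=0.0, sigma_leaf=0.0,
        sigma_g=0.0, sigma_e=0.0, geom_sigma_g=0.0, geom_sigma_e=0.0,
        seed=11,
    )
    plants, _ = xq.generate_panel(spec)
    return plants[0]


@pytest.fixture(scope="session")
def segmented_plant(one_plant):
    bundle, truth = one_plant
    return bundle, truth, xq.segment(bundle)


def make_uniform_bundle(shape=(20, 20), value=7, sample_id="uniform"):
    rasters = {
        e: xq.IntensityRaster(np.full(shape, value, dtype=np.uint8), e)
        for e in xq.ELEMENTS
    }
    return xq.ScanBundle(rasters=rasters, sample_id=sample_id)


@pytest.fixture()
def uniform_bundle():
    return make_uniform_bundle()
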