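"""Shared synthetic fixtures.

Everything is generated programmatically at session scope; the heavier
mosaics are reused across test modules.
"""

import numpy as np
import pytest

from popdcquant import synth


@pytest.fixture(scope="session")
def clean_biopsy():
    """Small noise-free biopsy: exact means, exact masks."""
    spec = synth.BiopsySpec(
        n_fibers=8,
        field_size_px=(220, 220),
        noise_sd=0.0,
        intensity_cv=0.0,
        group_effect=1.0,
        seed=11,
    )
    return spec, *synth.generate_biopsy(spec)


@pytest.fixture(scope="session")
def noisy_biopsy():
    """100-fiber mosaic with the default study noise conditions."""
    spec = synth.BiopsySpec(n_fibers=100, field_size_px=(540, 540), seed=21)
    return spec, *synth.generate_biopsy(spec)


@pytest.fixture(scope="session")
def clean_cell_field():
    spec = synth.CellFieldSpec(
        n_cells=12,
        reporter_ratios={"rep": 5.0},
        noise_sd=0.0,
        intensity_cv=0.0,
        background=0.0,
        seed=31,
    )
    return spec, *synth.generate_cell_field(spec)


@pytest.fixture(scope="session")
def bifc_half_field():
    spec = synth.BifcFieldSpec(
        n_cells=60,
        transfected_fraction=0.5,
        efficiency=0.5,
        noise_sd=0.0,
        intensity_cv=0.0,
        seed=41,
    )
    return spec, *synth.generate_bifc_field(spec)
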