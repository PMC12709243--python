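import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from segfcs import AcquisitionMeta, LineScanCarpet, SimulationConfig, simulate_carpet


def make_meta(
    n_lines=1000,
    n_pixels=16,
    line_frequency=1400.0,
    damage_line_end=99,
    damage_pixels=(6, 9),
):
    return AcquisitionMeta(
        line_frequency=line_frequency,
        pixel_size=0.097,
        n_pixels=n_pixels,
        n_lines=n_lines,
        damage_line_start=0,
        damage_line_end=damage_line_end,
        damage_pixel_start=damage_pixels[0],
        damage_pixel_end=damage_pixels[1],
        excitation_power_label="test",
    )


@pytest.fixture
def small_meta():
    return make_meta()


@pytest.fixture
def constant_carpet(small_meta):
    counts = np.full((2, small_meta.n_lines, small_meta.n_pixels), 3, dtype=np.int64)
    return LineScanCarpet(counts=counts, meta=small_meta)


@pytest.fixture(scope="session")
def binding_sim():
    """A 21-s binding-strip acquisition shared by segmentation/correlation tests."""
    cfg = SimulationConfig(
        n_particles=250,
        n_lines=30_000,
        D_free=3.8,
        k_on=20.0,
        tau_B=0.8,
        bleach_rate=0.0,
        seed=123,
    )
    carpet, truth = simulate_carpet(cfg)
    return cfg, carpet, truth


@pytest.fixture(scope="session")
def null_sim():
    """A homogeneous (no binding, no bleaching) acquisition."""
    cfg = SimulationConfig(
        n_particles=150,
        n_pixels=64,
        n_lines=30_000,
        D_free=3.8,
        k_on=0.0,
        bleach_rate=0.0,
        damage_on_time=0.0,
        seed=42,
    )
    carpet, truth = simulate_carpet(cfg)
    return cfg, carpet, truth
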