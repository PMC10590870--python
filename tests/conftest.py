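import dataclasses

import numpy as np
import pytest

import rimspec as rs
from rimspec.pipeline import run_mrsi_stage


@pytest.fixture(scope="session")
def default_subject():
    """One subject phantom at the default study conditions."""
    return rs.generate_subject(rs.PhantomConfig(seed=0))


@pytest.fixture(scope="session")
def noise_free_subject():
    """Noise-free phantom with a balanced iron-type mix (4 of each)."""
    cfg = rs.PhantomConfig(n_lesions=16, seed=5).noise_free()
    types = [rs.IronType(t)
             for t in ("non_iron", "area", "transition", "rim")] * 4
    return rs.generate_subject(cfg, iron_types=types), cfg


@pytest.fixture(scope="session")
def periphery_subject():
    """Noise-free periphery-calibrated phantom for layer-profile checks."""
    cfg = dataclasses.replace(
        rs.PhantomConfig(n_lesions=8, seed=3,
                         lesion_radius_range_mm=(3.2, 4.4)).noise_free(),
        lesion_scaling="periphery")
    types = [rs.IronType.RIM] * 4 + [rs.IronType.NON_IRON] * 4
    return rs.generate_subject(cfg, iron_types=types)


@pytest.fixture(scope="session")
def default_basis():
    return rs.build_basis(config=rs.SpectrumConfig())


@pytest.fixture(scope="session")
def default_mrsi_stage(default_subject):
    """Fitted MRSI slab of the default subject (shared by quality checks)."""
    rng = np.random.default_rng(7)
    return run_mrsi_stage(default_subject, rng,
                          spectrum_config=rs.SpectrumConfig())
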