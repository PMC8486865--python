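"""Shared fixtures: the default domain and the expensive protocol runs.

Protocol runs are session-scoped — each takes seconds to tens of seconds —
and are shared between the module tests and the acceptance suite.
"""

import numpy as np
import pytest

from oncotherm.geometry import build_domain
from oncotherm.hifu import (AcousticMedium, AxisymGrid, TransducerSpec,
                            classify_ablation_zones, compute_acoustic_field,
                            solve_focal_bioheat)
from oncotherm.protocols import default_protocol_config, run_protocol

DAY = 86400.0


@pytest.fixture(scope="session")
def domain_zones():
    return build_domain()


@pytest.fixture(scope="session")
def classical_50(domain_zones):
    dom, zn = domain_zones
    return run_protocol(default_protocol_config("classical_chemo", 50.0), dom, zn)


@pytest.fixture(scope="session")
def classical_100_6h(domain_zones):
    dom, zn = domain_zones
    return run_protocol(default_protocol_config("classical_chemo", 100.0,
                                                6 * 3600.0), dom, zn)


@pytest.fixture(scope="session")
def classical_150_6h(domain_zones):
    dom, zn = domain_zones
    return run_protocol(default_protocol_config("classical_chemo", 150.0,
                                                6 * 3600.0), dom, zn)


@pytest.fixture(scope="session")
def thermochemo_50(domain_zones):
    dom, zn = domain_zones
    return run_protocol(default_protocol_config("thermochemo", 50.0), dom, zn)


@pytest.fixture(scope="session")
def thermodox_50(domain_zones):
    dom, zn = domain_zones
    return run_protocol(default_protocol_config("thermodox", 50.0), dom, zn)


@pytest.fixture(scope="session")
def ablation_chemo(domain_zones):
    """Ablation immediately followed by thermochemotherapy (free drug)."""
    dom, zn = domain_zones
    cfg = default_protocol_config("ablation_then_medication", 50.0,
                                  agent="free_dox")
    return run_protocol(cfg, dom, zn)


@pytest.fixture(scope="session")
def hifu_run():
    """Default 30 W / 1.44 MHz / 60 s sonication: field, heating, lesion."""
    spec = TransducerSpec()
    medium = AcousticMedium()
    grid = AxisymGrid.around_focus(spec, half_width=8e-3)
    field = compute_acoustic_field(spec, medium, grid, n_rings=128,
                                   n_azimuth=128)
    heating = solve_focal_bioheat(field)
    lesion = classify_ablation_zones(heating.cem43, heating.peak_T, grid)
    return spec, medium, grid, field, heating, lesion
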