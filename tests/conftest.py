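"""Shared fixtures: reference bead models and precomputed Debye curves.

Heavy objects (the 33k-bead sphere and its scattering curve) are built once
per session and shared across the analytic-limit tests.
"""

import numpy as np
import pytest

from torusfit import assembly, saxs_core, synthetic_data


@pytest.fixture(scope="session")
def dimer():
    return synthetic_data.make_core_dimer(49, seed=1)


@pytest.fixture(scope="session")
def ring12(dimer):
    """Open 6-dimer (12-chain) partial ring."""
    return assembly.ring_layout(dimer, 6)


@pytest.fixture(scope="session")
def ring16(dimer):
    """Closed 8-dimer (16-chain) torus."""
    return assembly.ring_layout(dimer, 8)


@pytest.fixture(scope="session")
def sphere():
    """Uniform bead sphere (R = 30 A, 1.5 A grid) and its effective radius."""
    coords, r_eff = synthetic_data.make_sphere_model(30.0, 1.5)
    return coords, r_eff


@pytest.fixture(scope="session")
def sphere_curve(sphere):
    """Debye curve of the bead sphere on a 200-point grid to q = 0.5."""
    coords, _ = sphere
    q = np.linspace(0.0025, 0.5, 200)
    return saxs_core.debye_intensity(coords, q, bin_width=0.5)


def sphere_form_factor(q, radius):
    """Analytic form factor of a uniform sphere, normalized to 1 at q = 0."""
    x = np.asarray(q) * radius
    return (3.0 * (np.sin(x) - x * np.cos(x)) / x**3) ** 2
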