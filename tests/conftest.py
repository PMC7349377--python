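"""Shared fixtures and the independent transfer-matrix oracle."""

import numpy as np
import pytest

import thzpad as tp


@pytest.fixture(scope="session")
def library():
    return tp.material_library()


@pytest.fixture(scope="session")
def geometry(library):
    return tp.Geometry(window=library["quartz"])


@pytest.fixture(scope="session")
def reference():
    """Default reference pulse (2048 points over 40 ps, 0.4 ps FWHM)."""
    return tp.make_reference_pulse()


@pytest.fixture(scope="session")
def default_corpus(tmp_path_factory):
    """One full default corpus (seed 1), shared across tests."""
    out = tmp_path_factory.mktemp("corpus")
    manifest = tp.generate_dataset(tp.DatasetConfig(seed=1), out)
    return out, manifest


def tmm_reflection_p(N0, layers, N_sub, theta1_deg, nu_thz):
    """Characteristic-matrix (Born & Wolf) p-polarised reflection oracle.

    Independent of the package's Airy-recursion optics: admittances
    eta = N/cos(theta) and 2x2 layer matrices.  ``layers`` is a list of
    (N(nu) array, thickness_um); all N arguments are arrays over
    ``nu_thz``.  Sign convention: normal incidence reduces to
    (n0 - n_sub)/(n0 + n_sub).
    """
    nu = np.asarray(nu_thz, dtype=float)
    k0 = 2.0 * np.pi * nu / 299.792458  # rad/um
    kx = N0 * np.sin(np.radians(theta1_deg))

    def cos_theta(N):
        # principal root: forward-propagating / decaying for passive media
        return np.sqrt(1.0 - (kx / N) ** 2 + 0j)

    def eta_p(N):
        return N / cos_theta(N)

    m11 = np.ones_like(nu, dtype=complex)
    m12 = np.zeros_like(nu, dtype=complex)
    m21 = np.zeros_like(nu, dtype=complex)
    m22 = np.ones_like(nu, dtype=complex)
    for N, d_um in layers:
        delta = k0 * N * cos_theta(N) * d_um
        e = eta_p(N)
        c, s = np.cos(delta), np.sin(delta)
        a11, a12 = c, -1j * s / e
        a21, a22 = -1j * e * s, c
        m11, m12, m21, m22 = (m11 * a11 + m12 * a21, m11 * a12 + m12 * a22,
                              m21 * a11 + m22 * a21, m21 * a12 + m22 * a22)
    e0, es = eta_p(np.asarray(N0, dtype=complex)), eta_p(np.asarray(N_sub, dtype=complex))
    B = m11 + m12 * es
    C = m21 + m22 * es
    return (e0 * B - C) / (e0 * B + C)
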