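"""Optical material tables for the THz band.

Materials are stored as tabulated refractive index n(nu) and absorption
coefficient alpha(nu) on a common frequency grid (THz).  The built-in
library encodes the window crystal (z-cut alpha-quartz), the five spoof
materials, and an average-skin trend as smooth parametric curves pinned to
their published anchor values (quartz n = 2.10; Play-Doh n = 2.5 at
0.1 THz falling to about 2.2, alpha = 70 cm^-1 at 1 THz; water
alpha of about 170 cm^-1 at 1 THz).

Group labels follow the spoof-material taxonomy: ``group1`` for the
low-loss overlays (silicone, latex, plasticine; alpha < 10 cm^-1 in band),
``group2`` for the water-rich high-loss ones (gelatin/water, Play-Doh),
``window`` for the quartz window (and air), ``skin`` for tissue, and
``artificial`` for composed what-if materials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "OpticalMaterial",
    "kappa_from_alpha",
    "alpha_from_kappa",
    "complex_index_at",
    "compose_artificial",
    "material_library",
    "read_material_csv",
    "write_material_csv",
    "GROUPS",
    "C_UM_PS",
]

#: speed of light, micrometres per picosecond
C_UM_PS = 299.792458

GROUPS = ("window", "group1", "group2", "skin", "artificial")

_BAND = (0.1, 2.0)  # useful spectral range, THz
_GRID_LIMITS = (0.05, 3.0)


def kappa_from_alpha(alpha_cm1, nu_thz):
    """Extinction coefficient kappa from absorption coefficient alpha.

    Uses alpha = 4 pi nu kappa / c, i.e. kappa = alpha c / (4 pi nu),
    with alpha in cm^-1 and nu in THz.

    Parameters
    ----------
    alpha_cm1 : float or array
        Absorption coefficient in cm^-1 (power attenuation).
    nu_thz : float or array
        Frequency in THz; must be strictly positive.

    Returns
    -------
    float or ndarray
        Dimensionless extinction coefficient.
    """
    alpha_cm1 = np.asarray(alpha_cm1, dtype=float)
    nu_thz = np.asarray(nu_thz, dtype=float)
    if np.any(nu_thz <= 0):
        raise ValueError("frequency must be positive for the alpha -> kappa conversion")
    if np.any(alpha_cm1 < 0):
        raise ValueError("absorption coefficient must be non-negative")
    # alpha: cm^-1 -> m^-1 (x100); nu: THz -> Hz (x1e12); c in m/s
    kappa = alpha_cm1 * 100.0 * 299792458.0 / (4.0 * np.pi * nu_thz * 1e12)
    return kappa if kappa.ndim else float(kappa)


def alpha_from_kappa(kappa, nu_thz):
    """Inverse of :func:`kappa_from_alpha`; returns alpha in cm^-1."""
    kappa = np.asarray(kappa, dtype=float)
    nu_thz = np.asarray(nu_thz, dtype=float)
    if np.any(nu_thz <= 0):
        raise ValueError("frequency must be positive")
    alpha = kappa * 4.0 * np.pi * nu_thz * 1e12 / 299792458.0 / 100.0
    return alpha if alpha.ndim else float(alpha)


@dataclass(frozen=True)
class OpticalMaterial:
    """Tabulated complex optical response of one material.

    ``nu`` is a strictly ascending frequency grid in THz shared by the
    refractive-index and absorption tables.  ``alpha`` is stored in the
    customary cm^-1 and converted to the extinction coefficient only
    inside formulas.
    """

    name: str
    group: str
    nu: np.ndarray
    n: np.ndarray
    alpha: np.ndarray
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        nu = np.asarray(self.nu, dtype=float)
        n = np.asarray(self.n, dtype=float)
        alpha = np.asarray(self.alpha, dtype=float)
        object.__setattr__(self, "nu", nu)
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "alpha", alpha)
        if self.group not in GROUPS:
            raise ValueError(f"unknown material group {self.group!r}")
        if nu.size == 0 or nu.size != n.size or nu.size != alpha.size:
            raise ValueError("nu, n, alpha tables must be non-empty and equally long")
        if np.any(np.diff(nu) <= 0):
            raise ValueError("frequency grid must be strictly ascending")
        if nu[0] < _GRID_LIMITS[0] - 1e-12 or nu[-1] > _GRID_LIMITS[1] + 1e-12:
            raise ValueError(f"frequency grid must lie within {_GRID_LIMITS} THz")
        if np.any(n <= 0):
            raise ValueError("refractive index must be positive at every node")
        if np.any(alpha < 0):
            raise ValueError("absorption coefficient must be non-negative")
        self._check_group_bound()

    def _check_group_bound(self):
        lo, hi = _BAND
        sel = (self.nu >= lo) & (self.nu <= hi)
        if self.group == "group1" and np.any(self.alpha[sel] >= 10.0):
            raise ValueError(f"{self.name}: group1 materials require alpha < 10 cm^-1 in band")
        if self.group == "window" and self.name != "air" and np.any(self.alpha[sel] >= 1.0):
            raise ValueError(f"{self.name}: window material requires alpha < 1 cm^-1 in band")

    # -- queries ---------------------------------------------------------

    def n_at(self, nu_thz):
        """Refractive index, linearly interpolated, flat beyond the table."""
        return np.interp(self._check_nu(nu_thz), self.nu, self.n)

    def alpha_at(self, nu_thz):
        """Absorption coefficient (cm^-1), interpolated like :meth:`n_at`."""
        return np.interp(self._check_nu(nu_thz), self.nu, self.alpha)

    def _check_nu(self, nu_thz):
        nu_thz = np.asarray(nu_thz, dtype=float)
        if np.any(nu_thz <= 0):
            raise ValueError("frequency must be positive")
        return nu_thz


def complex_index_at(material: OpticalMaterial, nu_thz):
    """Complex refractive index N = n + i kappa at frequency ``nu_thz`` (THz).

    Tables are linearly interpolated between nodes and extrapolated flat
    outside their range (constant end values avoid nonphysical negative
    n or alpha).  kappa is derived from the interpolated alpha at the
    query frequency.
    """
    nu_arr = np.asarray(nu_thz, dtype=float)
    if np.any(nu_arr <= 0):
        raise ValueError("frequency must be positive")
    n = material.n_at(nu_arr)
    alpha = material.alpha_at(nu_arr)
    kappa = np.where(alpha > 0, kappa_from_alpha(np.maximum(alpha, 0.0), nu_arr), 0.0)
    N = n + 1j * kappa
    return complex(N) if np.ndim(nu_thz) == 0 else N


def compose_artificial(n_source: OpticalMaterial, kappa_source: OpticalMaterial,
                       name: str | None = None) -> OpticalMaterial:
    """Hybrid what-if material: n from one source, kappa (alpha) from another.

    Models a hypothetical spoof whose refractive-index profile comes from
    ``n_source`` while its attenuation comes from ``kappa_source``
    (e.g. silicone-n with Play-Doh-kappa, and vice versa).  The result is
    tabulated on the union of both grids restricted to their overlap.
    """
    lo = max(n_source.nu[0], kappa_source.nu[0])
    hi = min(n_source.nu[-1], kappa_source.nu[-1])
    if lo >= hi:
        raise ValueError(
            f"materials {n_source.name!r} and {kappa_source.name!r} have disjoint frequency ranges"
        )
    nu = np.union1d(n_source.nu, kappa_source.nu)
    nu = nu[(nu >= lo) & (nu <= hi)]
    return OpticalMaterial(
        name=name or f"{n_source.name}_n+{kappa_source.name}_kappa",
        group="artificial",
        nu=nu,
        n=n_source.n_at(nu),
        alpha=kappa_source.alpha_at(nu),
    )


# -- built-in library ----------------------------------------------------

_NU = np.round(np.linspace(0.05, 3.0, 60), 6)


def _mat(name, group, n_fn, alpha_fn):
    return OpticalMaterial(name, group, _NU, n_fn(_NU), alpha_fn(_NU))


def material_library() -> dict[str, OpticalMaterial]:
    """Built-in materials keyed by name.

    Curves are smooth parametric trends consistent with the published
    anchor values rather than digitised spectra; see the methods note.
    ``gelatin`` aliases the water tables (the gelatin mix is water
    dominated and cannot be measured in transmission).
    """
    lib = {
        "air": OpticalMaterial("air", "window", np.array([0.05, 3.0]),
                               np.array([1.0, 1.0]), np.array([0.0, 0.0])),
        "quartz": _mat("quartz", "window",
                       lambda nu: np.full_like(nu, 2.10),
                       lambda nu: np.full_like(nu, 0.2)),
        "silicone": _mat("silicone", "group1",
                         lambda nu: 1.73 - 0.02 * nu,
                         lambda nu: 1.2 * nu ** 2),
        "latex": _mat("latex", "group1",
                      lambda nu: 1.55 - 0.015 * nu,
                      lambda nu: 0.8 + 1.8 * nu ** 1.5),
        "plasticine": _mat("plasticine", "group1",
                           lambda nu: 1.87 - 0.03 * nu,
                           lambda nu: 1.5 + 2.0 * nu),
        "playdoh": _mat("playdoh", "group2",
                        lambda nu: 2.25 + 0.25 * np.exp(-(nu - 0.1) / 0.35),
                        lambda nu: 70.0 * nu ** 1.25),
        "water": _mat("water", "group2",
                      lambda nu: 2.15 + 1.4 * np.exp(-nu / 0.55),
                      lambda nu: 220.0 * nu / (nu + 0.3)),
        # outer skin (stratum corneum dominated): drier, mildly dispersive,
        # index crossing the window's 2.10 near 1 THz; absorption grows
        # superlinearly so the extinction coefficient (and with it the
        # reflectance) rises again towards the top of the band
        "skin": _mat("skin", "skin",
                     lambda nu: 1.98 + 0.60 * np.exp(-nu / 0.65),
                     lambda nu: 15.0 + 15.0 * nu + 35.0 * nu ** 2),
        # viable epidermis: wetter, higher index and loss
        "epidermis": _mat("epidermis", "skin",
                          lambda nu: 2.40 + 0.90 * np.exp(-nu / 0.6),
                          lambda nu: 80.0 + 150.0 * nu),
    }
    lib["gelatin"] = OpticalMaterial("gelatin", "group2", lib["water"].nu,
                                     lib["water"].n, lib["water"].alpha)
    lib["m1"] = compose_artificial(lib["silicone"], lib["playdoh"], name="m1")
    lib["m2"] = compose_artificial(lib["playdoh"], lib["silicone"], name="m2")
    return lib


# -- CSV interface -------------------------------------------------------

_CSV_COLUMNS = ["frequency_thz", "n", "alpha_cm1"]


def read_material_csv(path, name: str | None = None, group: str = "artificial") -> OpticalMaterial:
    """Read a material table from CSV with header ``frequency_thz,n,alpha_cm1``."""
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return OpticalMaterial(
        name=name or Path(path).stem,
        group=group,
        nu=df["frequency_thz"].to_numpy(float),
        n=df["n"].to_numpy(float),
        alpha=df["alpha_cm1"].to_numpy(float),
    )


def write_material_csv(material: OpticalMaterial, path) -> None:
    df = pd.DataFrame({
        "frequency_thz": material.nu,
        "n": material.n,
        "alpha_cm1": material.alpha,
    })
    df.to_csv(path, index=False, float_format="%.12g")
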