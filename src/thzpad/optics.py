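"""Fresnel reflection and reflected-signal synthesis for the TDS geometry.

The measurement geometry: a p-polarised THz pulse travels inside a quartz
window (n_Q = 2.10) and strikes its upper surface at the internal angle
theta_1 (about 20 deg for 45 deg external incidence).  Whatever sits on the
window -- air (the reference), a spoof overlay, or a finger -- sets the
amplitude reflection coefficient of that interface.  Reflected time traces
are synthesised by multiplying the reference spectrum with the relative
reflection coefficient r(nu) = r_sample(nu) / r_air(nu) and transforming
back.

Sign convention
---------------
The amplitude coefficient is positive when the beam goes from the higher
index into the lower one (quartz -> air gives r > 0, quartz -> wet tissue
gives r < 0), matching the observed pulse polarity; at normal incidence it
reduces to (n_Q - n) / (n_Q + n).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .materials import C_UM_PS, OpticalMaterial, complex_index_at
from .signals import TimeTrace

__all__ = [
    "Geometry",
    "Layer",
    "LayerStack",
    "SkinParams",
    "snell_angle",
    "fresnel_p",
    "relative_reflection",
    "stack_reflection",
    "simulate_thick_reflection",
    "simulate_thin_overlay",
    "simulate_finger",
]


def snell_angle(theta_in_deg: float, n_in: float, n_out: float) -> float:
    """Refraction angle (degrees) via Snell's law, n_in sin(t_in) = n_out sin(t_out).

    Raises on total internal reflection, naming the critical angle.
    """
    if not 0.0 <= theta_in_deg < 90.0:
        raise ValueError("incidence angle must be in [0, 90) degrees")
    if n_in <= 0 or n_out <= 0:
        raise ValueError("refractive indices must be positive")
    s = n_in * math.sin(math.radians(theta_in_deg)) / n_out
    if s > 1.0:
        critical = math.degrees(math.asin(n_out / n_in))
        raise ValueError(
            f"total internal reflection: incidence {theta_in_deg:g} deg exceeds "
            f"the critical angle {critical:.2f} deg for n={n_in:g} -> n={n_out:g}"
        )
    return math.degrees(math.asin(s))


@dataclass(frozen=True)
class Geometry:
    """Incidence geometry of the reflection setup.

    theta0_deg is the external incidence angle on the window's bottom
    face; the internal angle theta1 at the upper face follows from
    Snell's law using the window index at a fixed reference frequency
    (quartz is nearly dispersion free, so a single angle suffices).
    """

    theta0_deg: float = 45.0
    window: OpticalMaterial | None = None
    ref_frequency_thz: float = 1.0

    def __post_init__(self):
        if self.window is None:
            from .materials import material_library
            object.__setattr__(self, "window", material_library()["quartz"])
        if not 0.0 <= self.theta0_deg < 90.0:
            raise ValueError("theta0 must be in [0, 90) degrees")

    @property
    def n_window(self) -> float:
        return float(self.window.n_at(self.ref_frequency_thz))

    @property
    def theta1_deg(self) -> float:
        """Internal angle at the window/sample interface, degrees."""
        return snell_angle(self.theta0_deg, 1.0, self.n_window)

    def to_dict(self) -> dict:
        return {"theta0_deg": self.theta0_deg, "ref_frequency_thz": self.ref_frequency_thz,
                "window": self.window.name}


def _kz(N, kx):
    """Normal wavevector component (units of omega/c), decaying branch.

    The principal square root keeps Re >= 0 (forward propagation) and
    maps negative real arguments to +i|.| (evanescent decay); for every
    passive sample this is the branch with non-negative imaginary part.
    """
    return np.sqrt(N ** 2 - kx ** 2 + 0j)


def _rp(eps_i, kz_i, eps_j, kz_j):
    """p-polarised amplitude reflection for i -> j with shared transverse kx."""
    return (eps_i * kz_j - eps_j * kz_i) / (eps_i * kz_j + eps_j * kz_i)


def fresnel_p(N_window, N_sample, theta1_deg: float):
    """p-polarised amplitude reflection coefficient, window -> sample.

    ``N_window``/``N_sample`` are complex refractive indices (scalars or
    arrays); ``theta1_deg`` is the propagation angle inside the window.
    The complex square root is taken on the branch with non-negative
    imaginary part so the transmitted wave decays into a lossy sample.
    """
    N1 = np.asarray(N_window, dtype=complex)
    N2 = np.asarray(N_sample, dtype=complex)
    if np.any(np.real(N1) <= 0):
        raise ValueError("window index must have positive real part")
    kx = N1 * math.sin(math.radians(theta1_deg))
    r = _rp(N1 ** 2, _kz(N1, kx), N2 ** 2, _kz(N2, kx))
    return complex(r) if r.ndim == 0 else r


def relative_reflection(material: OpticalMaterial, geometry: Geometry, nu_grid) -> np.ndarray:
    """Complex r(nu) = r_sample(nu) / r_air(nu) on ``nu_grid`` (THz).

    The air-referenced ratio is how reflectance is reported by the
    instrument; |r| may exceed 1 because air is an imperfect mirror.
    """
    nu = np.asarray(nu_grid, dtype=float)
    theta1 = geometry.theta1_deg
    N_Q = complex_index_at(geometry.window, nu)
    r0 = fresnel_p(N_Q, np.ones_like(nu, dtype=complex), theta1)
    if np.any(np.abs(r0) == 0):
        raise ValueError("window/air reference reflection vanishes; cannot normalise")
    r_sam = fresnel_p(N_Q, complex_index_at(material, nu), theta1)
    return r_sam / r0


# -- layered media -------------------------------------------------------

@dataclass(frozen=True)
class Layer:
    material: OpticalMaterial
    thickness_mm: float  # finite layers only

    def __post_init__(self):
        if self.thickness_mm <= 0:
            raise ValueError("layer thickness must be positive")


@dataclass(frozen=True)
class LayerStack:
    """Finite layers on the window, terminated by a semi-infinite backing."""

    layers: tuple[Layer, ...]
    backing: OpticalMaterial

    def __post_init__(self):
        if len(self.layers) == 0:
            raise ValueError("stack needs at least one layer")
        object.__setattr__(self, "layers", tuple(self.layers))

    def to_json(self) -> str:
        return json.dumps({
            "layers": [{"material": l.material.name, "thickness_mm": l.thickness_mm}
                       for l in self.layers],
            "backing": self.backing.name,
        })

    @classmethod
    def from_json(cls, text: str, library: dict[str, OpticalMaterial]) -> "LayerStack":
        obj = json.loads(text)
        layers = tuple(Layer(library[d["material"]], d["thickness_mm"]) for d in obj["layers"])
        return cls(layers=layers, backing=library[obj["backing"]])


def stack_reflection(stack: LayerStack, geometry: Geometry, nu_grid) -> np.ndarray:
    """Exact (all internal orders) reflection of a layered stack on the window.

    Uses the recursive Airy formula r = (r01 + r1b e^{2 i beta}) /
    (1 + r01 r1b e^{2 i beta}) applied from the backing upward, with the
    one-way layer phase beta = (omega/c) d N cos(theta_layer).
    """
    nu = np.asarray(nu_grid, dtype=float)
    theta1 = geometry.theta1_deg
    N_Q = np.asarray(complex_index_at(geometry.window, nu), dtype=complex)
    kx = N_Q * math.sin(math.radians(theta1))
    k0 = 2.0 * np.pi * nu / C_UM_PS  # rad / um

    media = [N_Q] + [np.asarray(complex_index_at(l.material, nu), dtype=complex)
                     for l in stack.layers]
    media.append(np.asarray(complex_index_at(stack.backing, nu), dtype=complex))
    thick_um = [None] + [l.thickness_mm * 1000.0 for l in stack.layers] + [None]

    # recurse from the deepest interface up
    r = _rp(media[-2] ** 2, _kz(media[-2], kx), media[-1] ** 2, _kz(media[-1], kx))
    for i in range(len(media) - 3, -1, -1):
        r_top = _rp(media[i] ** 2, _kz(media[i], kx), media[i + 1] ** 2, _kz(media[i + 1], kx))
        phase = np.exp(2j * k0 * thick_um[i + 1] * _kz(media[i + 1], kx))
        r = (r_top + r * phase) / (1.0 + r_top * r * phase)
    return r


# -- reflected-signal synthesis ------------------------------------------

def _apply_transfer(E0: TimeTrace, r_of_nu, meta: dict) -> TimeTrace:
    """Filter the reference trace with a frequency-domain transfer function.

    ``r_of_nu`` maps a positive-frequency grid (THz) to complex r.  The DC
    bin is evaluated at the first positive frequency (materials are only
    defined for nu > 0; pulses carry no DC power).

    The optics above uses the physics field convention e^{i(kz - wt)};
    numpy's DFT analyses with the opposite temporal sign, so the transfer
    function is conjugated here to keep delays causal.
    """
    amp = np.asarray(E0.amplitude, dtype=float)
    n = amp.size
    dt = E0.dt
    nu = np.fft.rfftfreq(n, dt)  # THz, since dt is in ps
    nu_safe = np.where(nu < nu[1], nu[1], nu)
    r = np.conj(np.asarray(r_of_nu(nu_safe), dtype=complex))
    out = np.fft.irfft(r * np.fft.rfft(amp), n=n)
    return TimeTrace(t=E0.t.copy(), amplitude=out, meta={**E0.meta, **meta})


def simulate_thick_reflection(E0: TimeTrace, material: OpticalMaterial,
                              geometry: Geometry) -> TimeTrace:
    """Reflected trace for an optically thick (semi-infinite) sample.

    E1(t) = IFFT( r(nu) FFT(E0) ) with the air-referenced relative
    reflection of the single window/sample interface.
    """
    return _apply_transfer(
        E0, lambda nu: relative_reflection(material, geometry, nu),
        {"model": "thick", "material": material.name},
    )


def simulate_thin_overlay(E0: TimeTrace, overlay: OpticalMaterial, thickness_mm: float,
                          backing: OpticalMaterial, geometry: Geometry,
                          orders: int | None = 2) -> TimeTrace:
    """Reflected trace for a thin overlay on the window with a given backing.

    The first echo is the window/overlay Fresnel reflection; the second is
    the round trip through the overlay reflected off the overlay/backing
    interface, attenuated by two-way absorption and delayed by
    tau = 2 n d cos(theta_s) / c (theta_s the in-overlay angle; the cosine
    accounts for the oblique wavefront, which is what the time-of-flight
    depth formula inverts).  ``orders`` counts echoes; ``orders=None``
    sums the full geometric series, reproducing the exact layered
    (transfer-matrix) result.
    """
    if thickness_mm <= 0:
        raise ValueError("overlay thickness must be positive")
    if orders is not None and (not isinstance(orders, (int, np.integer)) or orders < 1):
        raise ValueError("orders must be a positive integer or None for the full series")
    theta1 = geometry.theta1_deg
    d_um = thickness_mm * 1000.0

    def r_of_nu(nu):
        N_Q = np.asarray(complex_index_at(geometry.window, nu), dtype=complex)
        N_s = np.asarray(complex_index_at(overlay, nu), dtype=complex)
        N_b = np.asarray(complex_index_at(backing, nu), dtype=complex)
        kx = N_Q * math.sin(math.radians(theta1))
        kz_q, kz_s, kz_b = _kz(N_Q, kx), _kz(N_s, kx), _kz(N_b, kx)
        r01 = _rp(N_Q ** 2, kz_q, N_s ** 2, kz_s)
        r1b = _rp(N_s ** 2, kz_s, N_b ** 2, kz_b)
        k0 = 2.0 * np.pi * np.asarray(nu) / C_UM_PS
        ph = np.exp(2j * k0 * d_um * kz_s)  # one round trip: delay + absorption
        x = -r01 * r1b * ph
        if orders is None:
            series = 1.0 / (1.0 - x)
        else:
            m = np.arange(max(orders - 1, 0))
            series = np.sum(x[..., None] ** m, axis=-1) if m.size else np.zeros_like(x)
        r_air = _rp(N_Q ** 2, kz_q, np.ones_like(N_Q), _kz(np.ones_like(N_Q), kx))
        return (r01 + (1.0 - r01 ** 2) * r1b * ph * series) / r_air

    return _apply_transfer(E0, r_of_nu, {
        "model": "overlay", "material": overlay.name,
        "thickness_mm": thickness_mm, "backing": backing.name, "orders": orders,
    })


# -- two-layer skin model ------------------------------------------------

@dataclass(frozen=True)
class SkinParams:
    """Two-layer finger-pad model: stratum corneum over wetter epidermis.

    The stratum corneum (0.2-0.6 mm on finger pads) sits on viable
    epidermis whose higher water content raises its refractive index,
    creating the internal interface whose echo trails the main pulse by
    tau = 2 n_sc d cos(theta_s) / c.  ``pressure_factor`` scales the whole
    reflected amplitude (harder pressing lowers it).
    """

    sc_thickness_mm: float
    sc: OpticalMaterial
    epidermis: OpticalMaterial
    pressure_factor: float = 1.0

    def __post_init__(self):
        if not 0.05 < self.sc_thickness_mm < 1.0:
            raise ValueError("stratum corneum thickness must be within (0.05, 1.0) mm")
        if not 0.0 < self.pressure_factor <= 1.0:
            raise ValueError("pressure_factor must be in (0, 1]")
        nu = np.linspace(0.1, 2.0, 40)
        if np.any(self.epidermis.n_at(nu) <= self.sc.n_at(nu)):
            raise ValueError("epidermis index must exceed the stratum corneum index in band")

    def to_dict(self) -> dict:
        return {"sc_thickness_mm": self.sc_thickness_mm, "sc": self.sc.name,
                "epidermis": self.epidermis.name, "pressure_factor": self.pressure_factor}


def simulate_finger(E0: TimeTrace, skin: SkinParams, geometry: Geometry,
                    orders: int | None = 2) -> TimeTrace:
    """Reflected trace for a genuine finger (two-layer skin model).

    The main pulse has negative polarity (the tissue index exceeds the
    window's over the energetic part of the band) and the stratum-corneum
    base produces a delayed internal echo.
    """
    out = simulate_thin_overlay(E0, skin.sc, skin.sc_thickness_mm,
                                skin.epidermis, geometry, orders=orders)
    return replace(out, amplitude=out.amplitude * skin.pressure_factor,
                   meta={**out.meta, "model": "finger", **skin.to_dict()})
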