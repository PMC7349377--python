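"""Time/frequency-domain processing of THz-TDS traces.

Covers apodization (4-term Blackman-Harris, asymmetric), one-sided power
spectra, air-referenced relative power reflectance, the deconvolution
response function with the double-Gaussian filter, and time-of-flight
depth estimation from echo delays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TimeTrace",
    "Spectrum",
    "ReflectanceSpectrum",
    "DeconvolutionParams",
    "BAND_THZ",
    "apodize",
    "power_spectrum",
    "reflectance",
    "response_function",
    "find_echoes",
    "estimate_interface_depth",
]

#: useful spectral range of the instrument, THz
BAND_THZ = (0.1, 2.0)

_C_UM_PS = 299.792458


@dataclass(frozen=True)
class TimeTrace:
    """Uniformly sampled field amplitude vs time (ps, arbitrary units)."""

    t: np.ndarray
    amplitude: np.ndarray
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        a = np.asarray(self.amplitude, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "amplitude", a)
        if t.size < 16 or t.size != a.size:
            raise ValueError("trace needs >= 16 samples with matching time grid")
        steps = np.diff(t)
        if np.any(np.abs(steps - steps[0]) > 1e-9):
            raise ValueError("time grid must be uniform to 1e-9 ps")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def span(self) -> float:
        return float(self.t[-1] - self.t[0]) + self.dt

    def same_grid(self, other: "TimeTrace", tol: float = 1e-9) -> bool:
        return self.t.size == other.t.size and bool(np.all(np.abs(self.t - other.t) <= tol))

    def to_csv(self, path) -> None:
        """Write as two-column CSV ``time_ps,amplitude`` (12 significant digits)."""
        df = pd.DataFrame({"time_ps": self.t, "amplitude": self.amplitude})
        df.to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path, meta: dict | None = None) -> "TimeTrace":
        df = pd.read_csv(path)
        for col in ("time_ps", "amplitude"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing column {col!r}")
        return cls(t=df["time_ps"].to_numpy(float),
                   amplitude=df["amplitude"].to_numpy(float),
                   meta=meta or {})


@dataclass(frozen=True)
class Spectrum:
    """One-sided spectrum: frequency grid (THz, ascending) and values."""

    nu: np.ndarray
    value: np.ndarray

    def __post_init__(self):
        nu = np.asarray(self.nu, dtype=float)
        object.__setattr__(self, "nu", nu)
        object.__setattr__(self, "value", np.asarray(self.value))
        if nu.size != self.value.size or nu.size == 0:
            raise ValueError("frequency and value arrays must match")
        if nu[0] < 0 or np.any(np.diff(nu) <= 0):
            raise ValueError("frequency grid must be ascending and non-negative")

    def to_csv(self, path) -> None:
        pd.DataFrame({"frequency_thz": self.nu, "value": np.real(self.value)}) \
            .to_csv(path, index=False, float_format="%.12g")


@dataclass(frozen=True)
class ReflectanceSpectrum:
    """Relative power reflectance R(nu) = |E1|^2 / |E0|^2 (air referenced)."""

    nu: np.ndarray
    R: np.ndarray

    def __post_init__(self):
        nu = np.asarray(self.nu, dtype=float)
        R = np.asarray(self.R, dtype=float)
        object.__setattr__(self, "nu", nu)
        object.__setattr__(self, "R", R)
        if nu.size != R.size or nu.size == 0:
            raise ValueError("frequency and reflectance arrays must match")
        if np.any(np.diff(nu) <= 0):
            raise ValueError("frequency grid must be ascending")
        if np.any(R < 0):
            raise ValueError("reflectance must be non-negative")

    def at(self, nu_thz: float) -> float:
        """Linear interpolation on the frequency grid."""
        if nu_thz < self.nu[0] or nu_thz > self.nu[-1]:
            raise ValueError(f"frequency {nu_thz} THz outside spectrum coverage")
        return float(np.interp(nu_thz, self.nu, self.R))

    def to_csv(self, path) -> None:
        pd.DataFrame({"frequency_thz": self.nu, "value": self.R}) \
            .to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path) -> "ReflectanceSpectrum":
        df = pd.read_csv(path)
        return cls(nu=df["frequency_thz"].to_numpy(float), R=df["value"].to_numpy(float))


# -- apodization ---------------------------------------------------------

# 4-term Blackman-Harris coefficients (-92 dB sidelobes)
_BH4 = (0.35875, 0.48829, 0.14128, 0.01168)


def _bh4(x):
    """Blackman-Harris window on x in [0, 1], peak value 1 at x = 0.5."""
    a0, a1, a2, a3 = _BH4
    return (a0 - a1 * np.cos(2 * np.pi * x) + a2 * np.cos(4 * np.pi * x)
            - a3 * np.cos(6 * np.pi * x))


def apodize(trace: TimeTrace, center: float, rise: float, fall: float) -> TimeTrace:
    """Asymmetric 4-term Blackman-Harris taper around ``center``.

    The taper rises over ``[center - rise, center]`` and falls over
    ``[center, center + fall]``; beyond the taper the window sits at the
    Blackman-Harris endpoint (about 6e-5).  A zero rise (fall) length
    disables the taper on that side, so ``rise = fall = 0`` is the
    identity.  The taper never exceeds 1, so signal energy cannot grow.
    """
    if rise < 0 or fall < 0:
        raise ValueError("rise and fall must be non-negative")
    if not trace.t[0] <= center <= trace.t[-1]:
        raise ValueError("apodization center must lie inside the time grid")
    if rise > trace.span or fall > trace.span:
        raise ValueError("taper length exceeds the trace span")
    t = trace.t
    w = np.ones_like(t)
    if rise > 0:
        x = 0.5 * (t - (center - rise)) / rise
        left = _bh4(np.clip(x, 0.0, 0.5))
        w = np.where(t < center, left, w)
    if fall > 0:
        x = 0.5 + 0.5 * (t - center) / fall
        right = _bh4(np.clip(x, 0.5, 1.0))
        w = np.where(t > center, np.minimum(w, right), w)
    return TimeTrace(t=t.copy(), amplitude=trace.amplitude * w,
                     meta={**trace.meta, "apodized": True})


# -- spectra -------------------------------------------------------------

def power_spectrum(trace: TimeTrace) -> Spectrum:
    """One-sided power spectrum |E(nu)|^2 with Parseval normalisation.

    Values are ``w_k |dt X_k|^2`` with w = 2 on interior bins (1 at DC and
    Nyquist), so that sum(|E(t)|^2) dt == sum(P) dnu.  The frequency
    resolution is 1/span (0.025 THz for the default 2048-point, 40 ps
    grid).
    """
    a = trace.amplitude
    n = a.size
    dt = trace.dt
    X = np.fft.rfft(a)
    P = np.abs(dt * X) ** 2
    w = np.full(P.size, 2.0)
    w[0] = 1.0
    if n % 2 == 0:
        w[-1] = 1.0
    return Spectrum(nu=np.fft.rfftfreq(n, dt), value=w * P)


def reflectance(E1: TimeTrace, E0: TimeTrace, band: tuple[float, float] = BAND_THZ,
                floor_rel: float = 1e-10) -> ReflectanceSpectrum:
    """Relative power reflectance R = |E1(nu)|^2 / |E0(nu)|^2.

    Restricted to the useful band and masked (dropped) where the reference
    power falls below ``floor_rel`` times its maximum.  R may exceed 1:
    air, not a mirror, is the reference.
    """
    if not E1.same_grid(E0):
        raise ValueError("sample and reference traces must share the same time grid")
    P1 = power_spectrum(E1)
    P0 = power_spectrum(E0)
    keep = ((P1.nu >= band[0]) & (P1.nu <= band[1])
            & (np.real(P0.value) >= floor_rel * np.real(P0.value).max()))
    if not np.any(keep):
        raise ValueError("no usable bins in the requested band")
    return ReflectanceSpectrum(nu=P1.nu[keep],
                               R=np.real(P1.value[keep]) / np.real(P0.value[keep]))


# -- deconvolution -------------------------------------------------------

@dataclass(frozen=True)
class DeconvolutionParams:
    """Double-Gaussian band-pass for the response function.

    ``lf``/``hf`` are the low- and high-frequency coefficients in sample
    units (defaults 12 and 2048: hf equals the standard trace length, so
    the time variable of the filter is the sample index).
    """

    lf: float = 12.0
    hf: float = 2048.0

    def __post_init__(self):
        if not 0 < self.lf < self.hf:
            raise ValueError("need 0 < lf < hf")


def response_function(E1: TimeTrace, E0: TimeTrace,
                      params: DeconvolutionParams | None = None,
                      floor_rel: float = 1e-6) -> TimeTrace:
    """Deconvolved impulse response rf = IFFT(FFT(filter) FFT(E1) / FFT(E0)).

    The filter is filter(t) = exp(-t^2/hf^2)/hf - exp(-t^2/lf^2)/lf on the
    wrap-around sample-index axis (symmetric about index 0).  Reference
    bins with |FFT(E0)| below ``floor_rel`` times its maximum are floored
    in magnitude (phase kept) to regularise the division.  The returned
    trace is indexed by delay, starting at 0 ps.
    """
    if params is None:
        params = DeconvolutionParams()
    if not E1.same_grid(E0):
        raise ValueError("sample and reference traces must share the same time grid")
    n = E1.amplitude.size
    idx = np.fft.fftfreq(n) * n  # wrapped sample index, symmetric about 0
    filt = (np.exp(-(idx / params.hf) ** 2) / params.hf
            - np.exp(-(idx / params.lf) ** 2) / params.lf)
    X0 = np.fft.fft(E0.amplitude)
    X1 = np.fft.fft(E1.amplitude)
    mag = np.abs(X0)
    floor = floor_rel * mag.max()
    phase = np.where(mag > 0, X0 / np.where(mag > 0, mag, 1.0), 1.0)
    X0_reg = phase * np.maximum(mag, floor)
    rf = np.real(np.fft.ifft(np.fft.fft(filt) * X1 / X0_reg))
    delay = np.arange(n) * E1.dt
    return TimeTrace(t=delay, amplitude=rf, meta={"kind": "response_function",
                                                  "lf": params.lf, "hf": params.hf})


def find_echoes(rf: TimeTrace, n_echoes: int = 2, min_separation_ps: float = 1.0,
                max_delay_ps: float | None = None) -> list[tuple[float, float]]:
    """Locate the strongest extrema of a response function.

    Returns ``(delay_ps, amplitude)`` pairs ordered by decreasing |amplitude|,
    greedily suppressing ``min_separation_ps`` around each pick.  Delays
    beyond ``max_delay_ps`` (default: half the span, to avoid the
    wrap-around mirror) are ignored.
    """
    a = rf.amplitude.copy()
    dt = rf.dt
    if max_delay_ps is None:
        max_delay_ps = rf.t[-1] / 2
    a[rf.t > max_delay_ps] = 0.0
    guard = max(int(round(min_separation_ps / dt)), 1)
    picks = []
    for _ in range(n_echoes):
        k = int(np.argmax(np.abs(a)))
        if a[k] == 0.0:
            break
        picks.append((float(rf.t[k]), float(a[k])))
        a[max(0, k - guard):k + guard + 1] = 0.0
    return picks


def estimate_interface_depth(tau_ps: float, n: float, theta1_deg: float) -> float:
    """Interface depth (um) from echo delay: d = c tau / (2 n cos(theta1)).

    ``tau_ps`` is the delay between the surface reflection and the
    internal echo, ``n`` the refractive index of the layer, ``theta1_deg``
    the internal propagation angle.
    """
    if tau_ps < 0:
        raise ValueError("delay must be non-negative")
    if n <= 0:
        raise ValueError("refractive index must be positive")
    if not 0 <= theta1_deg < 90:
        raise ValueError("angle must be in [0, 90) degrees")
    return _C_UM_PS * tau_ps / (2.0 * n * math.cos(math.radians(theta1_deg)))
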