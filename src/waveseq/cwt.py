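"""Continuous wavelet transform of window-count tracks.

The transform follows the standard FFT formulation: the signal is
zero-padded to the next power of two, multiplied in the Fourier domain
by the conjugated, scaled mother-wavelet spectrum, and inverse
transformed. Two mother wavelets are supported:

* Morlet — a plane wave under a Gaussian envelope, non-dimensional
  frequency ``omega0`` (default 6, the smallest standard admissible
  choice); complex-valued and analytic, so its spectrum lives on
  positive frequencies only.
* Mexican hat — the negative second derivative of a Gaussian (DOG
  order 2); real and symmetric.

Each scaled spectrum carries the unit-energy factor sqrt(2*pi*s/dt) so
wavelet power is comparable across scales. The scale convention is the
standard one: larger ``s`` means a wider wavelet responding to broader
features.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import gamma, pi, sqrt

import numpy as np

MORLET_OMEGA0 = 6.0
_DOG_ORDER = 2


@dataclass(frozen=True)
class MotherWavelet:
    kind: str  # "morlet" | "mexican_hat"
    omega0: float = MORLET_OMEGA0

    def __post_init__(self) -> None:
        if self.kind not in ("morlet", "mexican_hat"):
            raise ValueError(f"unknown wavelet kind {self.kind!r}")
        if self.kind == "morlet" and self.omega0 < 5:
            raise ValueError("Morlet omega0 must be >= 5 for admissibility")

    @property
    def is_complex(self) -> bool:
        return self.kind == "morlet"

    def fourier_period(self, scale: float) -> float:
        """Equivalent Fourier period of the wavelet at ``scale``."""
        if self.kind == "morlet":
            return 4 * pi * scale / (self.omega0 + sqrt(2 + self.omega0**2))
        return 2 * pi * scale / sqrt(_DOG_ORDER + 0.5)

    def scale_for_period(self, period: float) -> float:
        """Scale whose equivalent Fourier period equals ``period``."""
        return period * self.fourier_period(1.0) ** -1

    def efolding(self, scale: float) -> float:
        """Cone-of-influence e-folding distance at ``scale`` (windows)."""
        return sqrt(2) * scale

    def time_domain(self, eta: np.ndarray) -> np.ndarray:
        """Sampled mother wavelet psi0(eta) (unscaled, unit time step)."""
        eta = np.asarray(eta, dtype=float)
        if self.kind == "morlet":
            return pi**-0.25 * np.exp(1j * self.omega0 * eta) * np.exp(-(eta**2) / 2)
        m = _DOG_ORDER
        norm = (-1) ** (m + 1) / sqrt(gamma(m + 0.5))
        # d^2/deta^2 exp(-eta^2/2) = (eta^2 - 1) exp(-eta^2/2)
        return norm * (eta**2 - 1) * np.exp(-(eta**2) / 2)


def wavelet_fourier_basis(wavelet: MotherWavelet, scale: float,
                          angular_frequencies: np.ndarray) -> np.ndarray:
    """Normalized Fourier transform of the scaled wavelet.

    Includes the sqrt(2*pi*s/dt) unit-energy factor (dt = 1 window).
    Morlet support is restricted to strictly positive frequencies; the
    DC component is zero for both wavelets (zero mean / admissibility).
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    w = np.asarray(angular_frequencies, dtype=float)
    norm = sqrt(2 * pi * scale)
    if wavelet.kind == "morlet":
        spectrum = np.zeros_like(w, dtype=float)
        pos = w > 0
        spectrum[pos] = pi**-0.25 * np.exp(-((scale * w[pos] - wavelet.omega0) ** 2) / 2)
        return norm * spectrum.astype(complex)
    m = _DOG_ORDER
    sw = scale * w
    # -(i)^m / sqrt(Gamma(m+1/2)) * (sw)^m * exp(-(sw)^2/2); real for m = 2
    spectrum = (1.0 / sqrt(gamma(m + 0.5))) * sw**m * np.exp(-(sw**2) / 2)
    return norm * spectrum.astype(complex)


@dataclass(frozen=True)
class ScaleGrid:
    """Dyadic grid of wavelet scales s_j = s0 * 2**(j*dj), in window units."""

    s0: float = 2.0
    dj: float = 0.25
    J: int = 37

    def __post_init__(self) -> None:
        if self.s0 < 1:
            raise ValueError("smallest scale must be >= 1 window")
        if self.J < 1 or self.dj <= 0:
            raise ValueError("need J >= 1 and dj > 0")

    @property
    def scales(self) -> np.ndarray:
        return self.s0 * 2.0 ** (self.dj * np.arange(self.J))

    @classmethod
    def for_signal(cls, signal_length: int, s0: float = 2.0, dj: float = 0.25,
                   max_scale: float = 1024.0) -> "ScaleGrid":
        """Grid reaching min(max_scale, signal_length/4), at least one scale."""
        target = min(max_scale, signal_length / 4)
        if target <= s0:
            return cls(s0=s0, dj=dj, J=1)
        J = int(np.ceil(np.log2(target / s0) / dj)) + 1
        return cls(s0=s0, dj=dj, J=J)


@dataclass
class CWTResult:
    """Wavelet coefficients and power for one signal.

    ``coefficients`` holds the real part of W(s, t) (sign carries
    peak-vs-trough information); ``power`` is |W|^2.
    """

    coefficients: np.ndarray  # J x T, real part
    power: np.ndarray  # J x T
    grid: ScaleGrid
    wavelet: MotherWavelet
    signal_length: int

    def coi_mask(self) -> np.ndarray:
        """J x T boolean mask: True where the position lies inside the
        cone of influence (within e-folding distance of either end)."""
        T = self.signal_length
        idx = np.arange(T)
        dist = np.minimum(idx, T - 1 - idx)
        ef = np.array([self.wavelet.efolding(s) for s in self.grid.scales])
        return dist[None, :] < ef[:, None]


def _next_pow2(n: int) -> int:
    return 1 << (n - 1).bit_length()


def pad_length(T: int) -> int:
    """FFT length for a signal of T samples: next power of two >= 4T.

    Padding well past the signal keeps the circular FFT convolution
    equal to the linear one to ~1e-12 even at the largest grid scale
    (T/4), where the wavelet envelope spans a sizable fraction of the
    signal.
    """
    return _next_pow2(4 * T)


def cwt(signal: np.ndarray, grid: ScaleGrid, wavelet: MotherWavelet) -> CWTResult:
    """FFT-based continuous wavelet transform of a count vector.

    The signal is zero-padded (see :func:`pad_length`); padding is
    trimmed from the returned matrices. Positions near the ends are
    contaminated by the padding — use :meth:`CWTResult.coi_mask`.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("signal must be a 1-D vector of length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    T = x.size
    n = pad_length(T)
    xhat = np.fft.fft(x, n)
    w = 2 * pi * np.fft.fftfreq(n)  # angular frequency, dt = 1 window
    scales = grid.scales
    coef = np.empty((grid.J, T))
    power = np.empty((grid.J, T))
    for j, s in enumerate(scales):
        basis = wavelet_fourier_basis(wavelet, s, w)
        wave = np.fft.ifft(xhat * np.conj(basis))[:T]
        coef[j] = wave.real
        power[j] = np.abs(wave) ** 2 if wavelet.is_complex else wave.real**2
    return CWTResult(coefficients=coef, power=power, grid=grid,
                     wavelet=wavelet, signal_length=T)


def power_spectrum(result: CWTResult) -> np.ndarray:
    """The J x T wavelet power matrix (squared coefficient modulus)."""
    return result.power


def dump_power_matrix(result: CWTResult, path) -> None:
    """Write the power matrix as TSV with a scales header (diagnostic)."""
    header = "\t".join(f"{s:.6g}" for s in result.grid.scales)
    np.savetxt(path, result.power.T, delimiter="\t", header=header, comments="# scales: ")
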