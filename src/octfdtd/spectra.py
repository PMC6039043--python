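"""Discrete spectra, Gaussian bandwidth fits and Fresnel validation.

The source bandwidth is characterised by a least-squares Gaussian fit, in
wavelength, to the dominant lobe of the pulse spectrum.  A Gaussian pulse of
temporal standard deviation ``sigma_t`` has an amplitude spectrum of width
``sigma_nu = 1/(2*pi*sigma_t)``, i.e. ``sigma_lambda ~ lambda0^2*sigma_nu/c``
— the quantity quoted for SLD sources — so bandwidth fits are performed on
the amplitude spectrum (the power spectrum is narrower by sqrt(2)).

Transmission across a planar dielectric interface is validated per
wavelength bin against the normal-incidence Fresnel intensity coefficient
``T = 4 n1 n2 / (n1 + n2)^2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .constants import C
from .solver import ProbeTrace
from .source import SourceSpec, source_amplitude

__all__ = [
    "Spectrum",
    "GaussianFit",
    "power_spectrum",
    "gaussian_fit",
    "fresnel_transmission",
    "measure_transmission",
    "source_spectral_sigma",
]


@dataclass
class Spectrum:
    """One-sided discrete spectrum on frequency and wavelength axes.

    Bins are stored in increasing-frequency (decreasing-wavelength is the
    reverse view) order, excluding the zero-frequency bin; ``total_power``
    preserves the full Parseval sum including DC.
    """

    frequencies: np.ndarray
    wavelengths: np.ndarray
    power: np.ndarray
    total_power: float | None = None  # integral of power incl. the DC bin

    def __post_init__(self) -> None:
        d = np.diff(self.wavelengths)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavelength axis must be strictly monotone")
        if np.any(self.power < 0):
            raise ValueError("spectral power must be non-negative")

    @property
    def peak_wavelength(self) -> float:
        return float(self.wavelengths[np.argmax(self.power)])


@dataclass(frozen=True)
class GaussianFit:
    centre: float
    sigma: float
    amplitude: float
    residual_norm: float


def power_spectrum(trace: ProbeTrace, pad_factor: int = 4, kind: str = "power") -> Spectrum:
    """DFT spectrum of a uniformly sampled, zero-padded trace.

    ``kind="power"`` returns the one-sided spectral power density
    ``S(nu)`` satisfying Parseval (``sum |x|^2 dt == S total over nu``,
    including the DC bin kept in ``total_power``); ``kind="amplitude"``
    returns ``sqrt(S)``, proportional to ``|E(nu)|`` in the band interior.
    """
    if pad_factor < 1:
        raise ValueError("pad_factor must be >= 1")
    if kind not in ("power", "amplitude"):
        raise ValueError(f"unknown spectrum kind {kind!r}")
    dt = trace.dt  # raises for traces too short; validates uniform sampling
    x = trace.amplitudes
    n = int(pad_factor * x.size)
    X = np.fft.rfft(x, n=n) * dt
    freqs = np.fft.rfftfreq(n, d=dt)
    weights = np.full(X.size, 2.0)
    weights[0] = 1.0
    if n % 2 == 0:
        weights[-1] = 1.0
    dnu = freqs[1] - freqs[0]
    power = weights * np.abs(X) ** 2  # one-sided spectral energy density
    total = float(power.sum() * dnu)
    power = power[1:]  # drop DC: no finite wavelength
    freqs = freqs[1:]
    wavelengths = C / freqs
    if kind == "amplitude":
        power = np.sqrt(power)
    return Spectrum(frequencies=freqs, wavelengths=wavelengths, power=power,
                    total_power=total)


def gaussian_fit(spec: Spectrum, lobe_threshold: float = 0.01) -> GaussianFit:
    """Least-squares Gaussian (in wavelength) over the dominant spectral lobe.

    Only the contiguous bins around the peak above ``lobe_threshold`` of the
    peak power enter the fit, so side structure from numerical dispersion is
    ignored.
    """
    lam = spec.wavelengths
    p = spec.power
    k = int(np.argmax(p))
    cut = lobe_threshold * p[k]
    lo = k
    while lo > 0 and p[lo - 1] > cut:
        lo -= 1
    hi = k
    while hi < p.size - 1 and p[hi + 1] > cut:
        hi += 1
    lam_f, p_f = lam[lo : hi + 1], p[lo : hi + 1]
    if lam_f.size < 5:
        raise RuntimeError("dominant lobe too narrow for a Gaussian fit")

    def model(x, a, mu, sigma):
        return a * np.exp(-((x - mu) ** 2) / (2 * sigma**2))

    w = np.abs(np.trapezoid(p_f, lam_f)) / (p_f.max() + 0.0)
    p0 = (float(p_f.max()), float(lam_f[np.argmax(p_f)]), float(abs(w) / math.sqrt(2 * math.pi)))
    try:
        popt, _ = curve_fit(model, lam_f, p_f, p0=p0, maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - fit divergence
        raise RuntimeError(f"Gaussian fit did not converge: {exc}") from exc
    resid = p_f - model(lam_f, *popt)
    return GaussianFit(
        centre=float(popt[1]),
        sigma=float(abs(popt[2])),
        amplitude=float(popt[0]),
        residual_norm=float(np.linalg.norm(resid) / np.linalg.norm(p_f)),
    )


def fresnel_transmission(n1: float, n2: float) -> float:
    """Normal-incidence intensity transmission ``4 n1 n2 / (n1 + n2)^2``."""
    if n1 < 1 or n2 < 1:
        raise ValueError("refractive indices must be >= 1")
    return 4.0 * n1 * n2 / (n1 + n2) ** 2


def measure_transmission(
    incident: ProbeTrace,
    transmitted: ProbeTrace,
    n1: float,
    n2: float,
    pad_factor: int = 4,
    power_threshold: float = 0.01,
) -> Spectrum:
    """Per-wavelength intensity transmission ``(n2/n1) |E_t/E_i|^2``.

    Both traces must share the time axis (gate them to isolate the incident
    and transmitted pulses).  Bins where the incident power falls below
    ``power_threshold`` of its peak are excluded to avoid division noise.
    """
    spec_i = power_spectrum(incident, pad_factor=pad_factor)
    spec_t = power_spectrum(transmitted, pad_factor=pad_factor)
    if spec_i.frequencies.shape != spec_t.frequencies.shape:
        raise ValueError("traces must share a time axis")
    usable = spec_i.power >= power_threshold * spec_i.power.max()
    T = (n2 / n1) * spec_t.power[usable] / spec_i.power[usable]
    return Spectrum(
        frequencies=spec_i.frequencies[usable],
        wavelengths=spec_i.wavelengths[usable],
        power=T,
    )


def source_spectral_sigma(
    pulse_length: float,
    lambda0: float = 850e-9,
    oversample: int = 20,
    pad_factor: int = 8,
) -> tuple[GaussianFit, int]:
    """Fitted spectral sigma (in metres of wavelength) of the pulsed source.

    Builds the source time series at ``oversample`` samples per carrier
    period, takes the amplitude spectrum, converts to wavelength and fits a
    Gaussian to the dominant lobe.  Returns the fit and the number of time
    samples used.
    """
    src = SourceSpec(lambda0=lambda0, pulse_length=pulse_length)
    dt = src.carrier_period / oversample
    t_end = src.t0 + 8.0 * src.sigma_t
    times = np.arange(1, int(t_end / dt) + 1) * dt
    trace = ProbeTrace((0.0, 0.0), 1, times, source_amplitude(src, times))
    spec = power_spectrum(trace, pad_factor=pad_factor, kind="amplitude")
    return gaussian_fit(spec), times.size
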