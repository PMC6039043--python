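"""Broadband pulsed source: a Gaussian-enveloped carrier emulating an SLD.

The low-coherence gate of a time-domain OCT source is reproduced by a short
pulse: the shorter the pulse, the broader its spectrum.  The nominal pulse
"length" ``W`` (e.g. 25 fs or 150 fs) is calibrated as five temporal standard
deviations, ``sigma_t = W/5``; with an 850 nm carrier this yields amplitude
spectra of width ~76 nm (25 fs) and ~13 nm (150 fs), matching common and
low-cost SLDs respectively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import C

__all__ = ["SourceSpec", "source_amplitude", "coherence_length"]

#: Ratio between the nominal pulse length and the temporal standard deviation.
PULSE_LENGTH_SIGMAS = 5.0


@dataclass(frozen=True)
class SourceSpec:
    """Gaussian pulse parameters and injection geometry.

    Parameters
    ----------
    lambda0:
        Carrier (central) wavelength in metres.
    pulse_length:
        Nominal pulse length ``W`` in seconds; ``sigma_t`` defaults to ``W/5``.
    sigma_t:
        Temporal standard deviation of the envelope (s).
    t0:
        Envelope peak time (s); defaults to ``5*sigma_t`` so the pulse starts
        near zero amplitude, and must be at least ``4*sigma_t``.
    x:
        Injection plane position along the propagation axis (m).
    y:
        Transverse position for a point source (m); ignored for line sources.
    injection_mode:
        ``"soft-line"`` (additive line spanning the transverse extent,
        approximating a plane wave) or ``"point"`` (single-node soft source).
    """

    lambda0: float
    pulse_length: float
    sigma_t: float | None = None
    t0: float | None = None
    x: float = 0.0
    y: float | None = None
    injection_mode: str = "soft-line"

    def __post_init__(self) -> None:
        if self.lambda0 <= 0 or self.pulse_length <= 0:
            raise ValueError("lambda0 and pulse_length must be positive")
        if self.sigma_t is None:
            object.__setattr__(self, "sigma_t", self.pulse_length / PULSE_LENGTH_SIGMAS)
        if self.sigma_t <= 0:
            raise ValueError("sigma_t must be positive")
        if self.t0 is None:
            object.__setattr__(self, "t0", PULSE_LENGTH_SIGMAS * self.sigma_t)
        if self.t0 < 4.0 * self.sigma_t * (1 - 1e-12):
            raise ValueError("t0 must be at least 4*sigma_t (pulse must start near zero)")
        if self.injection_mode not in ("soft-line", "point"):
            raise ValueError(f"unknown injection_mode {self.injection_mode!r}")

    @property
    def carrier_frequency(self) -> float:
        return C / self.lambda0

    @property
    def carrier_period(self) -> float:
        return self.lambda0 / C

    def check_resolution(self, dx: float, minimum: float = 20.0) -> None:
        """Enforce the convergence floor on cells per carrier wavelength."""
        if self.lambda0 / dx < minimum:
            raise ValueError(
                f"lambda0/dx = {self.lambda0 / dx:.1f} < {minimum}: grid too coarse "
                "for a convergent FDTD run"
            )


def source_amplitude(src: SourceSpec, t):
    """Field amplitude of the source at time(s) ``t`` (peak magnitude 1 at t0).

    ``cos(2*pi*c*(t - t0)/lambda0) * exp(-(t - t0)^2 / (2*sigma_t^2))``
    """
    t = np.asarray(t, dtype=float)
    tau = t - src.t0
    return np.cos(2.0 * math.pi * C * tau / src.lambda0) * np.exp(
        -(tau**2) / (2.0 * src.sigma_t**2)
    )


def coherence_length(lambda0: float, sigma_lambda: float) -> float:
    """Round-trip coherence length of a Gaussian source (m).

    Uses the standard Gaussian-spectrum axial resolution
    ``l_c = (2 ln 2 / pi) * lambda0^2 / FWHM_lambda`` with
    ``FWHM = 2 sqrt(2 ln 2) * sigma_lambda``.
    """
    if lambda0 <= 0 or sigma_lambda <= 0:
        raise ValueError("wavelength and bandwidth must be positive")
    fwhm = 2.0 * math.sqrt(2.0 * math.log(2.0)) * sigma_lambda
    return (2.0 * math.log(2.0) / math.pi) * lambda0**2 / fwhm
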