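"""Low-coherence interferometry post-processing: from probe traces to A-scans.

The detector intensity is formed by summing the reference-arm (mirror) and
sample-arm field traces and squaring; the A-scan is the envelope of that
interference pattern, mapped from time to depth.  Because the simulation is
time-domain, each detected instant corresponds to a round-trip optical path:
depth advances by ``c*dt/(2*n)`` per time step, with ``n`` the local layer
index (layer-aware mapping) or a single global index (literal mapping).

A differential scan subtracts the active-nerve A-scan from the inactive one,
normalised to the incoming light intensity, and can carry a Poisson
(shot-noise) band for a given photon budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, hilbert

from .constants import C
from .materials import AxialProfile
from .solver import ProbeTrace

__all__ = [
    "InterferenceTrace",
    "TimeEnvelope",
    "AScan",
    "DifferentialScan",
    "interfere",
    "envelope",
    "time_to_depth",
    "differential_scan",
    "poisson_band",
    "ascan_peaks",
    "round_trip_time",
    "incoming_intensity",
]


@dataclass
class InterferenceTrace:
    """Detected intensity ``(E_ref + E_sample)^2`` per subsampled step."""

    times: np.ndarray
    intensity: np.ndarray
    self_intensity: np.ndarray | None = None  # ref^2 + sample^2, for DC removal
    normalisation: float | None = None  # incoming-light intensity

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.times.shape != self.intensity.shape:
            raise ValueError("times and intensity must share a shape")
        if np.any(self.intensity < -1e-30):
            raise ValueError("interference intensity must be non-negative")


@dataclass
class TimeEnvelope:
    """Envelope of the interference pattern, still on the time axis."""

    times: np.ndarray
    envelope: np.ndarray


@dataclass
class AScan:
    """Depth-resolved OCT signal (depth zeroed at a named interface)."""

    depth: np.ndarray
    envelope: np.ndarray
    zero_interface: str = ""

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        self.envelope = np.asarray(self.envelope, dtype=float)
        if np.any(np.diff(self.depth) <= 0):
            raise ValueError("depth axis must be strictly increasing")
        if np.any(self.envelope < 0):
            raise ValueError("envelope must be non-negative")


@dataclass
class DifferentialScan:
    """Signed difference of two A-scans, normalised to the incoming light."""

    depth: np.ndarray
    delta: np.ndarray
    noise_band: np.ndarray | None = None


def _check_same_axis(a: np.ndarray, b: np.ndarray, what: str) -> None:
    if a.shape != b.shape or not np.allclose(a, b, rtol=1e-12, atol=0):
        raise ValueError(f"mismatched {what}")


def interfere(ref: ProbeTrace, sample: ProbeTrace) -> InterferenceTrace:
    """Sum the two arm traces and square: the intensity interference pattern."""
    _check_same_axis(ref.times, sample.times, "time axes")
    total = ref.amplitudes + sample.amplitudes
    return InterferenceTrace(
        times=ref.times.copy(),
        intensity=total**2,
        self_intensity=ref.amplitudes**2 + sample.amplitudes**2,
    )


def envelope(
    trace: InterferenceTrace,
    dc: str | float = "mean",
    carrier_period: float | None = None,
) -> TimeEnvelope:
    """Magnitude of the analytic signal of the DC-removed interference term.

    ``dc`` selects the baseline removed before the Hilbert transform:
    ``"mean"`` (global mean — the echo train carried by the self terms stays
    in the envelope), ``"self"`` (subtract ``ref^2 + sample^2``, leaving only
    the cross term), ``"none"``, or an explicit numeric baseline (use one
    shared baseline when two scans will be differenced, so a baseline offset
    cannot couple the arms).
    """
    n = trace.intensity.size
    if n < 4:
        raise ValueError("trace too short for envelope extraction")
    if carrier_period is not None:
        span = trace.times[-1] - trace.times[0]
        if span < carrier_period:
            raise ValueError("trace shorter than one carrier period")
    if isinstance(dc, (int, float)) and not isinstance(dc, bool):
        signal = trace.intensity - float(dc)
    elif dc == "mean":
        signal = trace.intensity - trace.intensity.mean()
    elif dc == "self":
        if trace.self_intensity is None:
            raise ValueError("trace carries no self-intensity for dc='self'")
        signal = trace.intensity - trace.self_intensity
    elif dc == "none":
        signal = trace.intensity
    else:
        raise ValueError(f"unknown dc mode {dc!r}")
    env = np.abs(hilbert(signal))
    return TimeEnvelope(times=trace.times.copy(), envelope=env)


def round_trip_time(
    profile: AxialProfile, x_source: float, x_probe: float, x_target: float, t0: float
) -> float:
    """Arrival time at the probe of the echo from ``x_target``.

    The pulse peak leaves the source plane at ``t0``, accumulates optical
    path to the target and back to the probe at the local ``c/n``.
    """
    dx = float(profile.x[1] - profile.x[0])

    def opl(a: float, b: float) -> float:
        lo, hi = sorted((a, b))
        cells = (profile.x >= lo) & (profile.x < hi)
        return float(profile.n[cells].sum() * dx)

    return t0 + (opl(x_source, x_target) + opl(x_probe, x_target)) / C


def _interp_with_extrapolation(t: np.ndarray, tau: np.ndarray, z: np.ndarray) -> np.ndarray:
    out = np.interp(t, tau, z)
    lo = t < tau[0]
    if np.any(lo):
        slope = (z[1] - z[0]) / (tau[1] - tau[0])
        out[lo] = z[0] + (t[lo] - tau[0]) * slope
    hi = t > tau[-1]
    if np.any(hi):
        slope = (z[-1] - z[-2]) / (tau[-1] - tau[-2])
        out[hi] = z[-1] + (t[hi] - tau[-1]) * slope
    return out


def time_to_depth(
    env: TimeEnvelope,
    profile: AxialProfile,
    zero_interface: str,
    x_source: float,
    x_probe: float,
    t0: float,
    mode: str = "layered",
    n_uniform: float | None = None,
) -> AScan:
    """Convert a time envelope into a depth-resolved A-scan.

    In ``"layered"`` mode each time increment advances depth by
    ``c*dt/(2*n(z))`` using the axial index profile, so geometric layer
    thicknesses are recovered; ``"uniform"`` mode uses the single index
    ``n_uniform`` throughout.  Depth zero sits at ``zero_interface``.
    """
    x0 = profile.interface_x(zero_interface)
    if mode == "uniform":
        if n_uniform is None or n_uniform < 1:
            raise ValueError("uniform mode requires n_uniform >= 1")
        flat = AxialProfile(
            x=profile.x, n=np.full_like(profile.n, float(n_uniform)),
            labels=profile.labels, interfaces=profile.interfaces,
        )
        return time_to_depth(env, flat, zero_interface, x_source, x_probe, t0, "layered")
    if mode != "layered":
        raise ValueError(f"unknown depth mode {mode!r}")

    dx = float(profile.x[1] - profile.x[0])
    start = max(x_source, x_probe)
    k0 = int(np.searchsorted(profile.x, start))
    xs = profile.x[k0:]
    # echo arrival time for each node at and beyond the probe
    opl_src = np.concatenate(([0.0], np.cumsum(profile.n[k0:-1]))) * dx
    off_src = np.sum(profile.n[(profile.x >= min(x_source, start)) & (profile.x < start)]) * dx
    off_probe = np.sum(profile.n[(profile.x >= min(x_probe, start)) & (profile.x < start)]) * dx
    tau = t0 + (2.0 * opl_src + off_src + off_probe) / C
    depth = _interp_with_extrapolation(env.times, tau, xs) - x0
    return AScan(depth=depth, envelope=env.envelope, zero_interface=zero_interface)


def differential_scan(
    inactive: AScan, active: AScan, normalisation: float,
    noise_band: np.ndarray | None = None,
) -> DifferentialScan:
    """``(inactive - active) / normalisation`` on a shared depth axis."""
    _check_same_axis(inactive.depth, active.depth, "depth axes")
    if normalisation <= 0:
        raise ValueError("normalisation must be positive")
    delta = (inactive.envelope - active.envelope) / normalisation
    return DifferentialScan(depth=inactive.depth.copy(), delta=delta, noise_band=noise_band)


def poisson_band(
    ascan: AScan, photon_budget: float, incoming_intensity: float = 1.0
) -> np.ndarray:
    """Relative shot-noise standard deviation of the detected intensity.

    With ``I_norm = envelope / incoming_intensity`` and an expected photon
    count ``I_norm * photon_budget``, the Poisson relative noise is
    ``sqrt(I_norm / photon_budget)``.
    """
    if photon_budget <= 0:
        raise ValueError("photon budget must be positive")
    if incoming_intensity <= 0:
        raise ValueError("incoming intensity must be positive")
    return np.sqrt(ascan.envelope / incoming_intensity / photon_budget)


def incoming_intensity(ref: ProbeTrace) -> float:
    """Peak intensity of the source pulse as seen at the probe.

    Measured on the reference arm: the squared magnitude of the analytic
    signal of the reference trace at its maximum.
    """
    env = np.abs(hilbert(ref.amplitudes))
    return float(env.max() ** 2)


def ascan_peaks(
    ascan: AScan, threshold_frac: float = 0.05, min_separation: float | None = None
) -> np.ndarray:
    """Indices of envelope peaks above ``threshold_frac`` of the maximum.

    ``min_separation`` (m) enforces at least one coherence length between
    detected peaks when provided.
    """
    if not 0 < threshold_frac < 1:
        raise ValueError("threshold_frac must lie in (0, 1)")
    dz = float(np.median(np.diff(ascan.depth)))
    distance = max(1, int(round(min_separation / dz))) if min_separation else 1
    peaks, _ = find_peaks(
        ascan.envelope, height=threshold_frac * ascan.envelope.max(), distance=distance
    )
    return peaks
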