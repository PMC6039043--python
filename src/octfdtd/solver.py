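"""2D Yee-lattice FDTD engine (transverse-magnetic mode).

Fields: one out-of-plane electric component ``E`` on cell corners and two
in-plane magnetic components ``H1`` (y-staggered) and ``H2`` (x-staggered).
The leapfrog update advances H half a step from the curl of E, then E from
the curl of H scaled by ``1/n^2`` per cell.  The outermost E nodes are a
perfect electric conductor; a CPML slab just inside them absorbs outgoing
waves.  The transverse (y) boundary can instead be periodic, which turns a
line source into an exact plane wave for quasi-1D validation runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .boundary import PMLCoefficients, PMLSpec, attach_absorbing_boundary
from .constants import EPS0, MU0
from .grid import GridSpec
from .materials import MaterialMap
from .source import SourceSpec, source_amplitude

__all__ = [
    "FieldState",
    "ProbeTrace",
    "FieldSnapshot",
    "SimulationResult",
    "Solver",
    "FDTDInstabilityError",
    "step_fields",
    "run_simulation",
]

DEFAULT_SUBSAMPLE = 10  # probe cadence in time steps


class FDTDInstabilityError(RuntimeError):
    """Raised when the fields become non-finite (blow-up)."""

    def __init__(self, step: int):
        super().__init__(f"non-finite field values detected at step {step}")
        self.step = step


@dataclass
class FieldState:
    """Snapshot of the three field arrays at one time index."""

    E: np.ndarray
    H1: np.ndarray
    H2: np.ndarray
    time_index: int = 0


@dataclass(frozen=True)
class FieldSnapshot:
    step: int
    E: np.ndarray
    H1: np.ndarray
    H2: np.ndarray


@dataclass
class ProbeTrace:
    """Subsampled time series of the E amplitude at one detection point."""

    position: tuple[float, float]
    subsample_every: int
    times: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.times.shape != self.amplitudes.shape:
            raise ValueError("times and amplitudes must share a shape")
        if self.times.size >= 2:
            steps = np.diff(self.times)
            if np.any(steps <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=1e-9, atol=0):
                raise ValueError("times must be uniformly spaced")

    @property
    def dt(self) -> float:
        if self.times.size < 2:
            raise ValueError("trace too short to define a sampling step")
        return float(self.times[1] - self.times[0])

    def windowed(self, t_lo: float, t_hi: float) -> "ProbeTrace":
        """Copy with amplitudes zeroed outside [t_lo, t_hi] (time gating).

        The time axis is preserved so gated traces stay spectrally
        comparable bin-for-bin.
        """
        keep = (self.times >= t_lo) & (self.times <= t_hi)
        return ProbeTrace(
            self.position, self.subsample_every, self.times, np.where(keep, self.amplitudes, 0.0)
        )


@dataclass
class SimulationResult:
    traces: list[ProbeTrace]
    snapshots: list[FieldSnapshot] = field(default_factory=list)


class Solver:
    """Stateful stepping engine for one (grid, material, boundary) setup."""

    def __init__(
        self,
        grid: GridSpec,
        material: MaterialMap,
        pml: PMLCoefficients | None = None,
        periodic_y: bool = False,
        source: SourceSpec | None = None,
        mirror_x: float | None = None,
        check_finite_every: int = 200,
    ):
        material.validate_grid(grid)
        if pml is not None and periodic_y and pml.y is not None:
            raise ValueError("periodic y boundary is incompatible with a y PML")
        self.grid = grid
        self.material = material
        self.pml = pml
        self.periodic_y = periodic_y
        self.check_finite_every = check_finite_every
        nx, ny = grid.shape

        self.ce = grid.dt / (EPS0 * material.n_grid**2)
        self.ch = grid.dt / MU0
        self._inv_dx = 1.0 / grid.dx
        self._inv_dy = 1.0 / grid.dy

        self.E = np.zeros((nx, ny))
        self.H1 = np.zeros((nx, ny) if periodic_y else (nx, ny - 1))
        self.H2 = np.zeros((nx - 1, ny))
        self.time_index = 0

        # psi accumulators restricted to the PML slabs (zero-size when absent)
        ncols = ny if periodic_y else ny - 2
        Lx = pml.x.thickness if (pml is not None and pml.x is not None) else 0
        Ly = pml.y.thickness if (pml is not None and pml.y is not None) else 0
        self._psi_h2_lo = np.zeros((Lx, ny))
        self._psi_h2_hi = np.zeros((Lx, ny))
        self._psi_e_x_lo = np.zeros((max(Lx - 1, 0), ncols))
        self._psi_e_x_hi = np.zeros((max(Lx - 1, 0), ncols))
        self._psi_h1_lo = np.zeros((nx, Ly))
        self._psi_h1_hi = np.zeros((nx, Ly))
        self._psi_e_y_lo = np.zeros((nx - 2, max(Ly - 1, 0)))
        self._psi_e_y_hi = np.zeros((nx - 2, max(Ly - 1, 0)))
        empty = np.zeros(0)
        if Lx:
            self._cx = (pml.x.b_e_lo, pml.x.c_e_lo, pml.x.b_h_lo, pml.x.c_h_lo,
                        pml.x.b_e_hi, pml.x.c_e_hi, pml.x.b_h_hi, pml.x.c_h_hi)
        else:
            self._cx = (empty,) * 8
        if Ly:
            self._cy = (pml.y.b_e_lo, pml.y.c_e_lo, pml.y.b_h_lo, pml.y.c_h_lo,
                        pml.y.b_e_hi, pml.y.c_e_hi, pml.y.b_h_hi, pml.y.c_h_hi)
        else:
            self._cy = (empty,) * 8
        self._Lx, self._Ly = Lx, Ly
        self._use_numba = _kernels.HAVE_NUMBA

        self.source = source
        if source is not None:
            source.check_resolution(grid.dx)
            self._i_src = grid.x_index(source.x)
            if source.injection_mode == "point":
                j = grid.y_index(source.y) if source.y is not None else ny // 2
                self._src_cols = slice(j, j + 1)
            elif periodic_y:
                self._src_cols = slice(0, ny)
            else:
                margin = pml.y.thickness if (pml is not None and pml.y is not None) else 1
                self._src_cols = slice(margin, ny - margin)
        self._i_mirror = grid.x_index(mirror_x) if mirror_x is not None else None

    # -- geometry helpers ---------------------------------------------------
    def interior_x_range(self) -> tuple[int, int]:
        L = self.pml.x.thickness if (self.pml and self.pml.x) else 1
        return L, self.grid.n_cells_x - L

    def interior_y_range(self) -> tuple[int, int]:
        if self.periodic_y:
            return 0, self.grid.n_cells_y
        L = self.pml.y.thickness if (self.pml and self.pml.y) else 1
        return L, self.grid.n_cells_y - L

    def total_energy(self) -> float:
        """Electromagnetic field energy (J per unit out-of-plane length)."""
        cell = self.grid.dx * self.grid.dy
        u_e = 0.5 * EPS0 * np.sum(self.material.n_grid**2 * self.E**2)
        u_h = 0.5 * MU0 * (np.sum(self.H1**2) + np.sum(self.H2**2))
        return float((u_e + u_h) * cell)

    # -- core update --------------------------------------------------------
    def step(self) -> None:
        """One leapfrog update: H half-step, E full step, mirror, source."""
        if self._use_numba:
            args = (self.E, self.H1, self.H2, self.ce, self.ch,
                    self._inv_dx, self._inv_dy, self._Lx, *self._cx,
                    self._psi_h2_lo, self._psi_h2_hi,
                    self._psi_e_x_lo, self._psi_e_x_hi)
            if self.periodic_y:
                _kernels.step_periodic(*args)
            else:
                _kernels.step_pec(*args, self._Ly, *self._cy,
                                  self._psi_h1_lo, self._psi_h1_hi,
                                  self._psi_e_y_lo, self._psi_e_y_hi)
        else:
            self._update_fields()

        if self._i_mirror is not None:
            self.E[self._i_mirror, :] = 0.0

        self.time_index += 1
        if self.source is not None:
            t = self.time_index * self.grid.dt
            self.E[self._i_src, self._src_cols] += source_amplitude(self.source, t)

        if self.check_finite_every and self.time_index % self.check_finite_every == 0:
            self._check_finite()

    def _update_fields(self) -> None:
        E, H1, H2 = self.E, self.H1, self.H2
        ch, inv_dx, inv_dy = self.ch, self._inv_dx, self._inv_dy
        pml_x = self.pml.x if self.pml else None
        pml_y = self.pml.y if self.pml else None

        # H half-step from curl E
        if self.periodic_y:
            dEy = (np.roll(E, -1, axis=1) - E) * inv_dy
        else:
            dEy = (E[:, 1:] - E[:, :-1]) * inv_dy
        H1 -= ch * dEy
        dEx = (E[1:, :] - E[:-1, :]) * inv_dx
        H2 += ch * dEx

        if pml_x is not None:
            L = pml_x.thickness
            p = self._psi_h2_lo
            p *= pml_x.b_h_lo[:, None]
            p += pml_x.c_h_lo[:, None] * dEx[:L]
            H2[:L] += ch * p
            p = self._psi_h2_hi
            p *= pml_x.b_h_hi[:, None]
            p += pml_x.c_h_hi[:, None] * dEx[-L:]
            H2[-L:] += ch * p
        if pml_y is not None:
            L = pml_y.thickness
            p = self._psi_h1_lo
            p *= pml_y.b_h_lo[None, :]
            p += pml_y.c_h_lo[None, :] * dEy[:, :L]
            H1[:, :L] -= ch * p
            p = self._psi_h1_hi
            p *= pml_y.b_h_hi[None, :]
            p += pml_y.c_h_hi[None, :] * dEy[:, -L:]
            H1[:, -L:] -= ch * p

        # E full step from curl H, scaled by 1/n^2
        if self.periodic_y:
            dHy = (H2[1:, :] - H2[:-1, :]) * inv_dx  # rows i = 1..nx-2
            dHx = (H1 - np.roll(H1, 1, axis=1))[1:-1, :] * inv_dy
            ce = self.ce[1:-1, :]
            E[1:-1, :] += ce * (dHy - dHx)
            if pml_x is not None:
                L = pml_x.thickness
                p = self._psi_e_x_lo
                p *= pml_x.b_e_lo[:, None]
                p += pml_x.c_e_lo[:, None] * dHy[: L - 1]
                E[1:L, :] += self.ce[1:L, :] * p
                p = self._psi_e_x_hi
                p *= pml_x.b_e_hi[:, None]
                p += pml_x.c_e_hi[:, None] * dHy[-(L - 1) :]
                E[-L:-1, :] += self.ce[-L:-1, :] * p
        else:
            dHy = (H2[1:, 1:-1] - H2[:-1, 1:-1]) * inv_dx  # (nx-2, ny-2)
            dHx = (H1[1:-1, 1:] - H1[1:-1, :-1]) * inv_dy
            E[1:-1, 1:-1] += self.ce[1:-1, 1:-1] * (dHy - dHx)
            if pml_x is not None:
                L = pml_x.thickness
                p = self._psi_e_x_lo
                p *= pml_x.b_e_lo[:, None]
                p += pml_x.c_e_lo[:, None] * dHy[: L - 1]
                E[1:L, 1:-1] += self.ce[1:L, 1:-1] * p
                p = self._psi_e_x_hi
                p *= pml_x.b_e_hi[:, None]
                p += pml_x.c_e_hi[:, None] * dHy[-(L - 1) :]
                E[-L:-1, 1:-1] += self.ce[-L:-1, 1:-1] * p
            if pml_y is not None:
                L = pml_y.thickness
                p = self._psi_e_y_lo
                p *= pml_y.b_e_lo[None, :]
                p += pml_y.c_e_lo[None, :] * dHx[:, : L - 1]
                E[1:-1, 1:L] -= self.ce[1:-1, 1:L] * p
                p = self._psi_e_y_hi
                p *= pml_y.b_e_hi[None, :]
                p += pml_y.c_e_hi[None, :] * dHx[:, -(L - 1) :]
                E[1:-1, -L:-1] -= self.ce[1:-1, -L:-1] * p

    def _check_finite(self) -> None:
        if not (np.all(np.isfinite(self.E)) and np.all(np.isfinite(self.H2))):
            raise FDTDInstabilityError(self.time_index)

    def state(self) -> FieldState:
        return FieldState(self.E.copy(), self.H1.copy(), self.H2.copy(), self.time_index)

    def set_state(self, state: FieldState) -> None:
        if state.E.shape != self.E.shape or state.H1.shape != self.H1.shape:
            raise ValueError("state shapes do not match this solver")
        self.E = state.E.copy()
        self.H1 = state.H1.copy()
        self.H2 = state.H2.copy()
        self.time_index = state.time_index


def step_fields(
    state: FieldState,
    material: MaterialMap,
    grid: GridSpec,
    pml: PMLCoefficients | None = None,
    periodic_y: bool = False,
    source: SourceSpec | None = None,
) -> FieldState:
    """One functional leapfrog update (convenience wrapper around Solver).

    Builds a fresh solver each call; use :class:`Solver` directly for long
    runs.  Note PML recursion accumulators are not carried across calls.
    """
    solver = Solver(grid, material, pml=pml, periodic_y=periodic_y, source=source,
                    check_finite_every=1)
    solver.set_state(state)
    solver.step()
    return solver.state()


def run_simulation(
    grid: GridSpec,
    material: MaterialMap,
    src: SourceSpec | None,
    probes: list[tuple[float, float]],
    n_steps: int,
    *,
    pml_spec: PMLSpec | None = PMLSpec(),
    periodic_y: bool = False,
    mirror_x: float | None = None,
    subsample_every: int = DEFAULT_SUBSAMPLE,
    snapshot_every: int | None = None,
    initial_state: FieldState | None = None,
) -> SimulationResult:
    """Run the two-field leapfrog for ``n_steps`` and record probe traces.

    Probes are sampled every ``subsample_every`` steps (default 10).  The run
    is fully deterministic: identical inputs give bit-identical traces.
    """
    if n_steps <= 0:
        raise ValueError("n_steps must be positive")
    if subsample_every < 1:
        raise ValueError("subsample_every must be >= 1")
    pml = None
    if pml_spec is not None:
        axes = ("x",) if periodic_y else ("x", "y")
        pml = attach_absorbing_boundary(
            grid, pml_spec.thickness_cells, pml_spec.grading_order,
            pml_spec.target_reflection, axes=axes,
        )
    solver = Solver(grid, material, pml=pml, periodic_y=periodic_y, source=src,
                    mirror_x=mirror_x)
    if initial_state is not None:
        solver.set_state(initial_state)

    i_lo, i_hi = solver.interior_x_range()
    j_lo, j_hi = solver.interior_y_range()
    probe_idx = []
    for (px, py) in probes:
        i, j = grid.x_index(px), grid.y_index(py)
        if not (i_lo <= i < i_hi and j_lo <= j < j_hi):
            raise ValueError(f"probe at ({px}, {py}) lies inside the absorbing boundary")
        probe_idx.append((i, j))

    n_samples = n_steps // subsample_every
    samples = np.zeros((len(probe_idx), n_samples))
    snapshots: list[FieldSnapshot] = []
    k = 0
    for q in range(1, n_steps + 1):
        solver.step()
        if q % subsample_every == 0:
            for p, (i, j) in enumerate(probe_idx):
                samples[p, k] = solver.E[i, j]
            k += 1
        if snapshot_every and q % snapshot_every == 0:
            snapshots.append(
                FieldSnapshot(q, solver.E.copy(), solver.H1.copy(), solver.H2.copy())
            )
    solver._check_finite()

    times = np.arange(1, n_samples + 1) * subsample_every * grid.dt
    traces = [
        ProbeTrace((grid.dx * i, grid.dy * j), subsample_every, times, samples[p])
        for p, (i, j) in enumerate(probe_idx)
    ]
    return SimulationResult(traces=traces, snapshots=snapshots)
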