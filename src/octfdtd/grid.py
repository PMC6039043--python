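"""Uniform square Yee grid and the Courant stability relation.

The simulator discretises space on a square 2D lattice (``dx == dy``) and
derives the time step from the Courant number ``Sc = c*dt/dx``, which must
satisfy ``Sc <= 1/sqrt(D)`` in ``D`` spatial dimensions for the leapfrog
update to be stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .constants import C

__all__ = ["GridSpec", "courant_dt", "COURANT_2D"]

#: Largest stable Courant number in two dimensions.
COURANT_2D = 1.0 / math.sqrt(2.0)

_SC_SLACK = 1e-12  # tolerate round-off when sc == 1/sqrt(D)


def courant_dt(dx: float, ndims: int = 2, sc_fraction: float | None = None) -> float:
    """Time step ``dt = Sc * dx / c`` for a stable FDTD run.

    Parameters
    ----------
    dx:
        Spatial step in metres (square cells).
    ndims:
        Number of spatial dimensions (1, 2 or 3).
    sc_fraction:
        Courant number ``Sc``; defaults to the stability limit ``1/sqrt(ndims)``.

    Raises
    ------
    ValueError
        If ``dx`` is not positive or ``sc_fraction`` exceeds the stability
        limit ``1/sqrt(ndims)`` (the scheme would be unstable).
    """
    if dx <= 0:
        raise ValueError(f"dx must be positive, got {dx!r}")
    if ndims not in (1, 2, 3):
        raise ValueError(f"ndims must be 1, 2 or 3, got {ndims!r}")
    limit = 1.0 / math.sqrt(ndims)
    if sc_fraction is None:
        sc_fraction = limit
    if not 0.0 < sc_fraction <= limit + _SC_SLACK:
        raise ValueError(
            f"Courant fraction {sc_fraction!r} outside (0, 1/sqrt({ndims})] — unstable"
        )
    return sc_fraction * dx / C


@dataclass(frozen=True)
class GridSpec:
    """Geometry and time discretisation of a simulation domain.

    Use :meth:`create` to derive the cell counts and time step; the
    constructor validates the invariants (square cells, stable Courant
    number, consistent ``dt``).
    """

    dx: float
    dy: float
    extent_x: float
    extent_y: float
    courant_fraction: float
    dt: float
    n_cells_x: int
    n_cells_y: int
    n_steps: int | None = field(default=None)

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("spatial steps must be positive")
        if not math.isclose(self.dx, self.dy, rel_tol=1e-12):
            raise ValueError("grid must be square: dx == dy")
        if not 0 < self.courant_fraction <= COURANT_2D + _SC_SLACK:
            raise ValueError("courant_fraction must lie in (0, 1/sqrt(2)] for 2D")
        expected_dt = courant_dt(self.dx, 2, self.courant_fraction)
        if not math.isclose(self.dt, expected_dt, rel_tol=1e-12):
            raise ValueError("dt must equal courant_fraction*dx/c")
        if self.n_cells_x < 1 or self.n_cells_y < 1:
            raise ValueError("grid must contain at least one cell per axis")
        if self.n_cells_x != round(self.extent_x / self.dx) or self.n_cells_y != round(
            self.extent_y / self.dy
        ):
            raise ValueError("cell counts inconsistent with extents")
        if self.n_steps is not None and self.n_steps <= 0:
            raise ValueError("n_steps must be positive")

    @classmethod
    def create(
        cls,
        dx: float,
        extent_x: float,
        extent_y: float,
        courant_fraction: float = COURANT_2D,
        n_steps: int | None = None,
    ) -> "GridSpec":
        """Build a grid from the spatial step and physical extents."""
        nx = max(1, round(extent_x / dx))
        ny = max(1, round(extent_y / dx))
        return cls(
            dx=dx,
            dy=dx,
            extent_x=nx * dx,
            extent_y=ny * dx,
            courant_fraction=courant_fraction,
            dt=courant_dt(dx, 2, courant_fraction),
            n_cells_x=nx,
            n_cells_y=ny,
            n_steps=n_steps,
        )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_cells_x, self.n_cells_y)

    def x_index(self, x: float) -> int:
        """Nearest E-node column index for a physical x coordinate."""
        i = round(x / self.dx)
        if not 0 <= i < self.n_cells_x:
            raise ValueError(f"x={x!r} m outside domain")
        return i

    def y_index(self, y: float) -> int:
        j = round(y / self.dy)
        if not 0 <= j < self.n_cells_y:
            raise ValueError(f"y={y!r} m outside domain")
        return j

    def cells_per_wavelength(self, lambda0: float) -> float:
        return lambda0 / self.dx
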