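"""Polynomial-graded convolutional PML terminating the grid.

The absorbing layer uses the standard recursive-convolution formulation with
unit stretching (``kappa = 1``) and a conductivity profile graded as
``sigma(d) = sigma_max * (d/L)^m`` from the inner interface, with
``sigma_max = -(m+1) * eps0 * c * ln(R0) / (2 L)`` chosen so a normally
incident wave makes a round trip through the layer with design power
reflection ``R0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import C, EPS0
from .grid import GridSpec

__all__ = ["PMLSpec", "AxisPML", "PMLCoefficients", "attach_absorbing_boundary"]


@dataclass(frozen=True)
class PMLSpec:
    """User-facing PML parameters (community-standard defaults)."""

    thickness_cells: int = 10
    grading_order: int = 3
    target_reflection: float = 1e-6

    def __post_init__(self) -> None:
        if self.thickness_cells < 4:
            raise ValueError("PML must be at least 4 cells thick")
        if self.grading_order < 1:
            raise ValueError("grading_order must be >= 1")
        if not 0 < self.target_reflection < 1:
            raise ValueError("target_reflection must lie in (0, 1)")


@dataclass(frozen=True)
class AxisPML:
    """Recursion coefficients for one axis (E at integer, H at half nodes).

    ``b = exp(-sigma*dt/eps0)`` and ``c = b - 1`` implement
    ``psi <- b*psi + c*(spatial derivative)``; the low/high suffixes refer to
    the domain edge the slab terminates.
    """

    thickness: int
    b_e_lo: np.ndarray  # E nodes i = 1 .. L-1 (node 0 is the PEC backing)
    c_e_lo: np.ndarray
    b_h_lo: np.ndarray  # H half-nodes i = 0 .. L-1
    c_h_lo: np.ndarray
    b_e_hi: np.ndarray
    c_e_hi: np.ndarray
    b_h_hi: np.ndarray
    c_h_hi: np.ndarray


def _axis_coefficients(n_cells: int, dx: float, dt: float, spec: PMLSpec) -> AxisPML:
    L = spec.thickness_cells
    m = spec.grading_order
    sigma_max = -(m + 1) * EPS0 * C * math.log(spec.target_reflection) / (2.0 * L * dx)

    def bc(rho: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        sigma = sigma_max * rho**m
        b = np.exp(-sigma * dt / EPS0)
        return b, b - 1.0

    i = np.arange(L)
    rho_e_lo = (L - i[1:]) / L  # E nodes 1..L-1, depth grows toward the edge
    rho_h_lo = (L - i - 0.5) / L  # H half-nodes 0..L-1
    b_e_lo, c_e_lo = bc(rho_e_lo)
    b_h_lo, c_h_lo = bc(rho_h_lo)
    # mirrored profiles on the high edge
    b_e_hi, c_e_hi = bc(rho_e_lo[::-1])
    b_h_hi, c_h_hi = bc(rho_h_lo[::-1])
    return AxisPML(L, b_e_lo, c_e_lo, b_h_lo, c_h_lo, b_e_hi, c_e_hi, b_h_hi, c_h_hi)


@dataclass(frozen=True)
class PMLCoefficients:
    """Per-axis CPML coefficient tables attached to a grid."""

    spec: PMLSpec
    x: AxisPML | None
    y: AxisPML | None


def attach_absorbing_boundary(
    grid: GridSpec,
    thickness_cells: int = 10,
    grading_order: int = 3,
    target_reflection: float = 1e-6,
    axes: tuple[str, ...] = ("x", "y"),
) -> PMLCoefficients:
    """Build graded-conductivity PML coefficients for the domain edges.

    ``axes`` selects which axes are terminated by PML; omit ``"y"`` when the
    transverse direction is periodic.
    """
    spec = PMLSpec(thickness_cells, grading_order, target_reflection)
    for axis, n in (("x", grid.n_cells_x), ("y", grid.n_cells_y)):
        if axis in axes and 2 * thickness_cells > n:
            raise ValueError(
                f"PML thickness {thickness_cells} exceeds half the domain along {axis}"
            )
    return PMLCoefficients(
        spec=spec,
        x=_axis_coefficients(grid.n_cells_x, grid.dx, grid.dt, spec) if "x" in axes else None,
        y=_axis_coefficients(grid.n_cells_y, grid.dy, grid.dt, spec) if "y" in axes else None,
    )
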