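"""Per-cell refractive-index maps and axial index profiles.

A :class:`MaterialMap` carries the refractive index at every E-node of the
grid together with a categorical region label per cell and a provenance table
recording which index value each label used.  Media are non-dispersive:
``n`` is constant over the source band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import GridSpec

__all__ = ["MaterialMap", "AxialProfile"]


@dataclass(frozen=True)
class AxialProfile:
    """Refractive index along the propagation axis at one transverse row.

    ``interfaces`` maps ``"left_label/right_label"`` to the x coordinate of
    the first E-node of the right-hand region.
    """

    x: np.ndarray  # E-node coordinates (m), strictly increasing
    n: np.ndarray
    labels: tuple[str, ...]
    interfaces: dict[str, float] = field(default_factory=dict)

    def interface_x(self, name: str) -> float:
        try:
            return self.interfaces[name]
        except KeyError:
            raise KeyError(
                f"unknown interface {name!r}; available: {sorted(self.interfaces)}"
            ) from None


@dataclass
class MaterialMap:
    """Refractive index over the 2D grid plus region labelling.

    ``labels`` holds integer codes; ``label_names`` maps code -> name and
    ``provenance`` maps name -> the index value assigned to that region.
    """

    n_grid: np.ndarray
    labels: np.ndarray
    label_names: dict[int, str]
    provenance: dict[str, float]

    def __post_init__(self) -> None:
        self.n_grid = np.asarray(self.n_grid, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.n_grid.shape != self.labels.shape:
            raise ValueError("n_grid and labels must share a shape")
        if np.any(self.n_grid < 1.0):
            raise ValueError("refractive indices must be >= 1")
        for code, name in self.label_names.items():
            cells = self.n_grid[self.labels == code]
            if cells.size and not np.allclose(cells, cells.flat[0], rtol=0, atol=1e-15):
                raise ValueError(f"region {name!r} carries more than one index value")

    @property
    def shape(self) -> tuple[int, int]:
        return self.n_grid.shape

    def validate_grid(self, grid: GridSpec) -> None:
        if self.shape != grid.shape:
            raise ValueError(
                f"material shape {self.shape} does not match grid {grid.shape}"
            )

    def mask(self, label: str) -> np.ndarray:
        codes = [c for c, name in self.label_names.items() if name == label]
        if not codes:
            raise KeyError(f"no region labelled {label!r}")
        return np.isin(self.labels, codes)

    def copy(self) -> "MaterialMap":
        return MaterialMap(
            self.n_grid.copy(),
            self.labels.copy(),
            dict(self.label_names),
            dict(self.provenance),
        )

    @classmethod
    def uniform(cls, grid: GridSpec, n: float, label: str = "background") -> "MaterialMap":
        return cls(
            np.full(grid.shape, float(n)),
            np.zeros(grid.shape, dtype=np.int16),
            {0: label},
            {label: float(n)},
        )

    def axial_profile(self, grid: GridSpec, y: float | None = None) -> AxialProfile:
        """Index vs x at the row nearest ``y`` (domain centre by default)."""
        j = grid.y_index(y) if y is not None else grid.n_cells_y // 2
        n_row = self.n_grid[:, j].copy()
        code_row = self.labels[:, j]
        names = tuple(self.label_names[int(c)] for c in code_row)
        x = np.arange(grid.n_cells_x) * grid.dx
        interfaces: dict[str, float] = {}
        for i in range(1, len(names)):
            if names[i] != names[i - 1]:
                key = f"{names[i - 1]}/{names[i]}"
                interfaces.setdefault(key, x[i])
        return AxialProfile(x=x, n=n_row, labels=names, interfaces=interfaces)
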