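"""Optical phantoms: refractive-index models and sample geometries.

Two samples are modelled.  A glass rod immersed in water and filled with a
water-sucrose solution, whose index follows the degree-Brix scale
(``n = m * Bx + n_w``, with the intercept translated to the water index at
the working wavelength); and a cross-section of a myelinated peripheral
nerve (single fascicle, e.g. a Xenopus laevis sciatic nerve): a Ringer's
solution half, an epineurium band containing elastic fibres, and an
endoneurial region packed with myelinated axons.  Tissue indices follow
linear volume-fraction mixture rules.

Neural activity is emulated by a discrete, tiny shift of the axoplasm index
(default +1.45e-5, the index change of a 0.01 degree-Brix sucrose solution
relative to water).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .grid import GridSpec
from .materials import MaterialMap

__all__ = [
    "BrixModel",
    "brix_index",
    "mixture_index",
    "epineurium_index",
    "myelin_index",
    "TISSUE_INDICES",
    "GlassRodSpec",
    "NerveSpec",
    "build_glass_rod",
    "build_nerve",
    "build_two_layer",
    "build_slab",
    "perturb_axons",
    "ACTIVE_DELTA_N",
]

#: Registry of tissue refractive indices at 850 nm used by the nerve phantom.
TISSUE_INDICES: dict[str, float] = {
    "ringer": 1.3290,       # Ringer's solution, treated as water
    "epineurium": 1.4,      # loose connective sheath (mixture rule, below)
    "elastic_fibre": 1.41,  # taken from scleral fibrils
    "axon": 1.338,          # axoplasm + membrane
    "myelin": 1.4,          # lipid-rich sheath (mixture rule, below)
    "endoneurium": 1.335,   # endoneurial fluid ~ cerebrospinal fluid
}

#: Axoplasm index shift emulating the active nerve: the index change of a
#: 0.01 degree-Brix sucrose solution relative to pure water.
ACTIVE_DELTA_N = 1.45e-5


@dataclass(frozen=True)
class BrixModel:
    """Linear sucrose-concentration model ``n = slope * Bx + n_water``.

    The intercept is the water index at the working wavelength (1.3290 at
    850 nm); the slope is kept wavelength-independent.
    """

    slope: float = 0.00145  # refractive-index units per degree Brix
    n_water: float = 1.3290

    def __post_init__(self) -> None:
        if self.slope <= 0 or self.n_water <= 1:
            raise ValueError("BrixModel requires slope > 0 and n_water > 1")


def brix_index(brix: float, model: BrixModel = BrixModel()) -> float:
    """Refractive index of a water-sucrose solution at ``brix`` degrees Brix."""
    if brix < 0:
        raise ValueError("sucrose concentration cannot be negative")
    return model.slope * brix + model.n_water


def mixture_index(components: list[tuple[float, float]]) -> float:
    """Volume-weighted mean index of a mixture ``[(index, fraction), ...]``.

    Fractions must be non-negative and sum to 1 within 1e-9.
    """
    fractions = np.array([f for _, f in components], dtype=float)
    indices = np.array([n for n, _ in components], dtype=float)
    if np.any(fractions < 0):
        raise ValueError("volume fractions must be non-negative")
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError(f"volume fractions sum to {fractions.sum()!r}, expected 1")
    return float(np.dot(fractions, indices))


def epineurium_index(
    fluid_fraction: float = 0.40,
    n_fluid: float = 1.345,
    fibre_dry_fraction: float = 0.70,
    n_fibre: float = 1.43,
    n_lipid: float = 1.45,
) -> float:
    """Epineurium index: ground substance plus a fibre/lipid dry mass."""
    dry = mixture_index([(n_fibre, fibre_dry_fraction), (n_lipid, 1 - fibre_dry_fraction)])
    return mixture_index([(n_fluid, fluid_fraction), (dry, 1 - fluid_fraction)])


def myelin_index(
    water_fraction: float = 0.40,
    n_water: float = 1.3290,
    lipid_dry_fraction: float = 0.70,
    n_lipid: float = 1.45,
    n_protein: float = 1.5,
) -> float:
    """Myelin index: 40% water plus a 70/30 lipid/protein dry mass."""
    dry = mixture_index([(n_lipid, lipid_dry_fraction), (n_protein, 1 - lipid_dry_fraction)])
    return mixture_index([(n_water, water_fraction), (dry, 1 - water_fraction)])


# ---------------------------------------------------------------------------
# Glass rod
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GlassRodSpec:
    """Three-layer glass-rod sample: water | glass wall | sucrose solution."""

    water_glass_x: float
    glass_solution_x: float
    brix: float = 0.0
    water_n: float = 1.3272
    glass_n: float = 1.5098
    brix_model: BrixModel = field(default_factory=BrixModel)

    def __post_init__(self) -> None:
        if not 0 < self.water_glass_x < self.glass_solution_x:
            raise ValueError("layer boundaries must be strictly increasing and positive")

    @property
    def solution_n(self) -> float:
        return brix_index(self.brix, self.brix_model)


_GLASS_ROD_CODES = {0: "water", 1: "glass", 2: "solution"}


def build_glass_rod(spec: GlassRodSpec, grid: GridSpec) -> MaterialMap:
    """Material map for the glass-rod sample along the propagation (x) axis."""
    if spec.glass_solution_x >= grid.extent_x:
        raise ValueError("layer boundaries must lie inside the domain")
    x = np.arange(grid.n_cells_x) * grid.dx
    labels = np.zeros(grid.shape, dtype=np.int16)
    labels[x >= spec.water_glass_x, :] = 1
    labels[x >= spec.glass_solution_x, :] = 2
    values = {0: spec.water_n, 1: spec.glass_n, 2: spec.solution_n}
    n_grid = np.take(np.array([values[c] for c in range(3)]), labels)
    return MaterialMap(
        n_grid,
        labels,
        dict(_GLASS_ROD_CODES),
        {name: values[code] for code, name in _GLASS_ROD_CODES.items()},
    )


def build_two_layer(interface_x: float, n1: float, n2: float, grid: GridSpec) -> MaterialMap:
    """Single planar interface: ``layer1`` (x < interface) then ``layer2``."""
    if not 0 < interface_x < grid.extent_x:
        raise ValueError("interface must lie inside the domain")
    x = np.arange(grid.n_cells_x) * grid.dx
    labels = np.zeros(grid.shape, dtype=np.int16)
    labels[x >= interface_x, :] = 1
    n_grid = np.where(labels == 0, float(n1), float(n2))
    return MaterialMap(n_grid, labels, {0: "layer1", 1: "layer2"},
                       {"layer1": float(n1), "layer2": float(n2)})


def build_slab(
    slab_start_x: float, thickness: float, n_slab: float, n_background: float,
    grid: GridSpec,
) -> MaterialMap:
    """A slab of ``n_slab`` embedded in a uniform background."""
    end = slab_start_x + thickness
    if not 0 < slab_start_x < end < grid.extent_x:
        raise ValueError("slab must lie inside the domain")
    x = np.arange(grid.n_cells_x) * grid.dx
    labels = np.zeros(grid.shape, dtype=np.int16)
    labels[(x >= slab_start_x) & (x < end), :] = 1
    n_grid = np.where(labels == 1, float(n_slab), float(n_background))
    return MaterialMap(n_grid, labels, {0: "background", 1: "slab"},
                       {"background": float(n_background), "slab": float(n_slab)})


# ---------------------------------------------------------------------------
# Nerve
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NerveSpec:
    """Geometry and indices of the peripheral-nerve phantom.

    The first ``split_fraction`` of the domain along x is Ringer's solution;
    the nerve follows: an epineurium band of ``epineurium_thickness``
    containing ``n_fibres`` circular elastic fibres, then endoneurial fluid
    packed with myelinated axons (axoplasm core + myelin annulus) on a
    jittered hexagonal lattice.
    """

    split_fraction: float = 0.5
    epineurium_thickness: float = 5e-6
    n_fibres: int = 3
    fibre_radius: float = 0.5e-6
    fibre_centres: tuple[tuple[float, float], ...] | None = None
    axon_diameter: float = 2e-6
    myelin_thickness: float = 0.3e-6
    axon_gap: float = 0.3e-6
    packing_jitter: float = 0.1  # fraction of the lattice pitch
    edge_margin: float = 0.5e-6  # clearance kept free of axons at domain edges
    indices: dict[str, float] = field(default_factory=lambda: dict(TISSUE_INDICES))

    def __post_init__(self) -> None:
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must lie in (0, 1)")
        for name in ("epineurium_thickness", "fibre_radius", "axon_diameter",
                     "myelin_thickness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(n <= 1 for n in self.indices.values()):
            raise ValueError("all tissue indices must exceed 1")
        missing = set(TISSUE_INDICES) - set(self.indices)
        if missing:
            raise ValueError(f"missing tissue indices: {sorted(missing)}")


_NERVE_CODES = {
    0: "ringer", 1: "epineurium", 2: "elastic_fibre",
    3: "endoneurium", 4: "myelin", 5: "axon",
}


def _hex_axon_centres(
    spec: NerveSpec, grid: GridSpec, x_start: float, rng: np.random.Generator
) -> list[tuple[float, float]]:
    r_out = spec.axon_diameter / 2 + spec.myelin_thickness
    pitch = 2 * r_out + spec.axon_gap
    col_dx = pitch * math.sqrt(3) / 2
    jitter = spec.packing_jitter * pitch
    x_lo = x_start + r_out
    x_hi = grid.extent_x - r_out - spec.edge_margin
    y_lo = spec.edge_margin + r_out
    y_hi = grid.extent_y - spec.edge_margin - r_out
    centres: list[tuple[float, float]] = []
    k = 0
    x = x_lo
    while x <= x_hi:
        y = y_lo + (pitch / 2 if k % 2 else 0.0)
        while y <= y_hi:
            # jitter, clamped back into the feasible box; overlapping
            # candidates are skipped so sheaths never intersect
            cx = min(max(x + rng.uniform(-jitter, jitter), x_lo), x_hi)
            cy = min(max(y + rng.uniform(-jitter, jitter), y_lo), y_hi)
            if all(
                (cx - ox) ** 2 + (cy - oy) ** 2 >= (2 * r_out) ** 2
                for ox, oy in centres
            ):
                centres.append((cx, cy))
            y += pitch
        x += col_dx
        k += 1
    return centres


def build_nerve(spec: NerveSpec, grid: GridSpec, seed: int | None = 0) -> MaterialMap:
    """Material map for the nerve phantom (deterministic given ``seed``)."""
    rng = np.random.default_rng(seed)
    nerve_x = spec.split_fraction * grid.extent_x
    epi_hi = nerve_x + spec.epineurium_thickness
    if epi_hi >= grid.extent_x:
        raise ValueError("epineurium band does not fit inside the domain")

    x = (np.arange(grid.n_cells_x) * grid.dx)[:, None]
    y = (np.arange(grid.n_cells_y) * grid.dy)[None, :]
    labels = np.zeros(grid.shape, dtype=np.int16)
    labels[(x >= nerve_x) & (x < epi_hi) & np.ones_like(y, dtype=bool)] = 1
    labels[(x >= epi_hi) & np.ones_like(y, dtype=bool)] = 3

    # elastic fibres inside the epineurium band
    if spec.fibre_centres is not None:
        fibres = list(spec.fibre_centres)
    else:
        depth_fracs = np.linspace(0.3, 0.7, spec.n_fibres)
        span_fracs = np.linspace(0.3, 0.7, spec.n_fibres)
        fibres = [
            (nerve_x + f * spec.epineurium_thickness, g * grid.extent_y)
            for f, g in zip(depth_fracs, span_fracs)
        ]
    for cx, cy in fibres:
        if not (nerve_x + spec.fibre_radius <= cx <= epi_hi - spec.fibre_radius):
            raise ValueError("elastic fibre does not fit inside the epineurium band")
        inside = (x - cx) ** 2 + (y - cy) ** 2 <= spec.fibre_radius**2
        labels[inside] = 2

    # myelinated axons in the endoneurial region
    r_core = spec.axon_diameter / 2
    r_out = r_core + spec.myelin_thickness
    centres = _hex_axon_centres(spec, grid, epi_hi, rng)
    if not centres:
        raise ValueError("no axons fit in the endoneurial region; enlarge the domain")
    for cx, cy in centres:
        d2 = (x - cx) ** 2 + (y - cy) ** 2
        labels[(d2 <= r_out**2) & (labels == 3)] = 4
        labels[d2 <= r_core**2] = 5

    values = {code: spec.indices[name] for code, name in _NERVE_CODES.items()}
    n_grid = np.take(np.array([values[c] for c in range(6)]), labels)
    return MaterialMap(
        n_grid,
        labels,
        dict(_NERVE_CODES),
        {name: values[code] for code, name in _NERVE_CODES.items()},
    )


def perturb_axons(mmap: MaterialMap, delta_n: float, label: str = "axon") -> MaterialMap:
    """Copy of the map with the axoplasm index shifted by ``delta_n``.

    Every cell outside the ``label`` region is bit-identical to the input.
    """
    mask = mmap.mask(label)  # raises if the label is absent
    out = mmap.copy()
    out.n_grid[mask] += delta_n
    if np.any(out.n_grid < 1.0):
        raise ValueError("perturbation would push the index below 1")
    out.provenance[label] = out.provenance[label] + delta_n
    return out
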