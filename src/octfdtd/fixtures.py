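"""Reduced-scale experiment fixtures that keep the full-scale topology.

The canonical full-scale run (8.5 nm cells, 100x17 um^2, 100 cells per
wavelength) takes hours per arm; these fixtures shrink the domain and the
resolution but never the physics code path: layer ordering, fibre count and
the axon region match the full design, so every pipeline stage is testable
in minutes.  ``scale`` divides the cells-per-wavelength (scale 1 keeps the
canonical 100; scales above 5 are rejected because lambda0/dx would drop
below the convergence floor of 20).
"""

from __future__ import annotations

from .config import (
    BoundaryConfig,
    ExperimentConfig,
    GlassRodPhantom,
    GridConfig,
    NervePhantom,
    ProbeConfig,
    SlabPhantom,
    SourceConfig,
    TwoLayerPhantom,
    VacuumPhantom,
)

__all__ = ["make_fixture", "canonical_nerve_config", "FIXTURE_KINDS"]

LAMBDA0 = 850e-9
BASE_CELLS_PER_WAVELENGTH = 100.0
MIN_CELLS_PER_WAVELENGTH = 20.0

FIXTURE_KINDS = ("vacuum", "slab", "glass_rod_small", "nerve_small", "fresnel")


def make_fixture(kind: str, scale: float = 1.0, seed: int = 0) -> ExperimentConfig:
    """Build a reduced-scale experiment configuration.

    Parameters
    ----------
    kind:
        One of ``vacuum``, ``slab``, ``glass_rod_small``, ``nerve_small`` or
        ``fresnel`` (single water-glass interface on a quasi-1D plane-wave
        domain).
    scale:
        Resolution divisor (>= 1); ``dx = lambda0 / (100/scale)``.
    seed:
        Governs every stochastic choice downstream (axon packing).
    """
    if scale < 1:
        raise ValueError("scale must be >= 1")
    cpw = BASE_CELLS_PER_WAVELENGTH / scale
    if cpw < MIN_CELLS_PER_WAVELENGTH:
        raise ValueError(
            f"scale {scale} pushes lambda0/dx to {cpw:.1f} < {MIN_CELLS_PER_WAVELENGTH}"
        )
    dx = LAMBDA0 / cpw
    um = 1e-6

    if kind == "vacuum":
        return ExperimentConfig(
            grid=GridConfig(dx=dx, extent_x=15 * um, extent_y=1 * um),
            source=SourceConfig(x=1.5 * um),
            phantom=VacuumPhantom(),
            probes=[ProbeConfig(x=3 * um)],
            boundary=BoundaryConfig(periodic_y=True),
            seed=seed,
        )
    if kind == "fresnel":
        return ExperimentConfig(
            grid=GridConfig(dx=dx, extent_x=20 * um, extent_y=4 * um),
            source=SourceConfig(x=2 * um),
            phantom=TwoLayerPhantom(interface_x=12 * um),
            probes=[ProbeConfig(x=5 * um), ProbeConfig(x=17.5 * um)],
            boundary=BoundaryConfig(periodic_y=True),
            seed=seed,
        )
    if kind == "slab":
        return ExperimentConfig(
            grid=GridConfig(dx=dx, extent_x=20 * um, extent_y=1 * um),
            source=SourceConfig(x=1.5 * um),
            phantom=SlabPhantom(slab_start_x=10 * um, thickness=4 * um),
            probes=[ProbeConfig(x=4 * um)],
            boundary=BoundaryConfig(periodic_y=True),
            seed=seed,
        )
    if kind == "glass_rod_small":
        return ExperimentConfig(
            grid=GridConfig(dx=dx, extent_x=20 * um, extent_y=4 * um),
            source=SourceConfig(x=1.5 * um),
            phantom=GlassRodPhantom(water_glass_x=10 * um, glass_solution_x=14 * um, brix=0.1),
            probes=[ProbeConfig(x=4 * um)],
            seed=seed,
        )
    if kind == "nerve_small":
        return ExperimentConfig(
            grid=GridConfig(dx=dx, extent_x=20 * um, extent_y=4 * um),
            source=SourceConfig(x=1.5 * um),
            phantom=NervePhantom(
                epineurium_thickness=2.5 * um,
                fibre_radius=0.35 * um,
                edge_margin=0.6 * um,
            ),
            probes=[ProbeConfig(x=4 * um)],
            seed=seed,
        )
    raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")


def canonical_nerve_config(seed: int = 0) -> ExperimentConfig:
    """The full-scale nerve run: 8.5 nm cells, 100x17 um^2, 850 nm carrier.

    Provided for completeness — a single arm takes hours on one core; use
    :func:`make_fixture` for routine work.
    """
    um = 1e-6
    return ExperimentConfig(
        grid=GridConfig(dx=8.5e-9, extent_x=100 * um, extent_y=17 * um),
        source=SourceConfig(x=5 * um),
        phantom=NervePhantom(),
        probes=[ProbeConfig(x=10 * um)],
        seed=seed,
    )
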