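"""Validated experiment configuration (YAML-backed, pydantic schema).

An :class:`ExperimentConfig` fully describes a two-arm OCT simulation:
grid, source, phantom, probes, boundary treatment and post-processing
options.  ``load_config``/``dump_config`` round-trip losslessly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Annotated, Literal, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .grid import COURANT_2D, GridSpec
from .phantoms import ACTIVE_DELTA_N, TISSUE_INDICES
from .source import SourceSpec

__all__ = ["ExperimentConfig", "load_config", "dump_config"]


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class BoundaryConfig(_Model):
    pml_cells: int = Field(10, ge=4)
    grading_order: int = Field(3, ge=1)
    target_reflection: float = Field(1e-6, gt=0, lt=1)
    periodic_y: bool = False


class GridConfig(_Model):
    dx: float = Field(gt=0, description="spatial step (m); dy == dx")
    extent_x: float = Field(gt=0)
    extent_y: float = Field(gt=0)
    courant_fraction: float = Field(COURANT_2D, gt=0, le=COURANT_2D + 1e-12)

    def build(self, n_steps: int | None = None) -> GridSpec:
        return GridSpec.create(
            self.dx, self.extent_x, self.extent_y, self.courant_fraction, n_steps
        )


class SourceConfig(_Model):
    lambda0: float = Field(850e-9, gt=0)
    pulse_length: float = Field(25e-15, gt=0)
    x: float = Field(gt=0, description="injection plane (m)")
    y: float | None = None
    injection_mode: Literal["soft-line", "point"] = "soft-line"

    def build(self) -> SourceSpec:
        return SourceSpec(
            lambda0=self.lambda0,
            pulse_length=self.pulse_length,
            x=self.x,
            y=self.y,
            injection_mode=self.injection_mode,
        )


class ProbeConfig(_Model):
    x: float = Field(gt=0)
    y: float | None = None
    subsample_every: int = Field(10, ge=1)


class VacuumPhantom(_Model):
    kind: Literal["vacuum"] = "vacuum"
    n: float = Field(1.0, ge=1)


class TwoLayerPhantom(_Model):
    kind: Literal["two_layer"] = "two_layer"
    interface_x: float = Field(gt=0)
    n1: float = Field(1.3272, ge=1)
    n2: float = Field(1.5098, ge=1)


class SlabPhantom(_Model):
    kind: Literal["slab"] = "slab"
    slab_start_x: float = Field(gt=0)
    thickness: float = Field(gt=0)
    n_slab: float = Field(1.5098, ge=1)
    n_background: float = Field(1.3272, ge=1)


class GlassRodPhantom(_Model):
    kind: Literal["glass_rod"] = "glass_rod"
    water_glass_x: float = Field(gt=0)
    glass_solution_x: float = Field(gt=0)
    brix: float = Field(0.1, ge=0)
    variant_brix: float | None = Field(
        0.0, ge=0, description="second run's concentration for the differential scan"
    )
    water_n: float = Field(1.3272, ge=1)
    glass_n: float = Field(1.5098, ge=1)

    @model_validator(mode="after")
    def _ordered(self) -> "GlassRodPhantom":
        if self.glass_solution_x <= self.water_glass_x:
            raise ValueError("glass_solution_x must exceed water_glass_x")
        return self


class NervePhantom(_Model):
    kind: Literal["nerve"] = "nerve"
    split_fraction: float = Field(0.5, gt=0, lt=1)
    epineurium_thickness: float = Field(5e-6, gt=0)
    n_fibres: int = Field(3, ge=0)
    fibre_radius: float = Field(0.5e-6, gt=0)
    axon_diameter: float = Field(2e-6, gt=0)
    myelin_thickness: float = Field(0.3e-6, gt=0)
    axon_gap: float = Field(0.3e-6, ge=0)
    packing_jitter: float = Field(0.1, ge=0, le=0.4)
    edge_margin: float = Field(0.5e-6, ge=0)
    indices: dict[str, float] = Field(default_factory=lambda: dict(TISSUE_INDICES))
    active_delta_n: float | None = ACTIVE_DELTA_N


Phantom = Annotated[
    Union[VacuumPhantom, TwoLayerPhantom, SlabPhantom, GlassRodPhantom, NervePhantom],
    Field(discriminator="kind"),
]

#: interfaces each phantom kind can zero the depth axis at
_KNOWN_INTERFACES = {
    "vacuum": set(),
    "two_layer": {"layer1/layer2"},
    "slab": {"background/slab", "slab/background"},
    "glass_rod": {"water/glass", "glass/solution"},
    "nerve": {"ringer/epineurium", "epineurium/endoneurium", "epineurium/elastic_fibre"},
}

DEFAULT_ZERO_INTERFACE = {
    "vacuum": None,
    "two_layer": "layer1/layer2",
    "slab": "background/slab",
    "glass_rod": "water/glass",
    "nerve": "ringer/epineurium",
}


class PostConfig(_Model):
    dc_mode: Literal["mean", "self", "none"] = "mean"
    depth_mode: Literal["layered", "uniform"] = "layered"
    n_uniform: float | None = None
    zero_interface: str | None = None  # None -> kind default
    photon_budget: float = Field(1e6, gt=0)
    peak_threshold: float = Field(0.05, gt=0, lt=1)
    # depth window of the reported A-scan; depth_min None crops halfway
    # between the probe and the zero interface, removing the incident pass
    depth_min: float | None = None
    depth_max: float | None = None


class ExperimentConfig(_Model):
    grid: GridConfig
    source: SourceConfig
    phantom: Phantom
    probes: list[ProbeConfig] = Field(min_length=1)
    boundary: BoundaryConfig = Field(default_factory=BoundaryConfig)
    post: PostConfig = Field(default_factory=PostConfig)
    mirror_x: float | None = None  # None -> front interface of the phantom
    n_steps: int | None = Field(None, gt=0)  # None -> derived from geometry
    seed: int = 0

    @model_validator(mode="after")
    def _cross_checks(self) -> "ExperimentConfig":
        pml = self.boundary.pml_cells * self.grid.dx
        x_lo, x_hi = pml, self.grid.extent_x - pml
        if self.grid.extent_x < 4 * pml:
            raise ValueError("domain too short for the requested PML thickness")
        if self.source.lambda0 / self.grid.dx < 20:
            raise ValueError("lambda0/dx below 20: grid too coarse to converge")
        if not x_lo < self.source.x < x_hi:
            raise ValueError("source plane lies inside the absorbing boundary")
        for p in self.probes:
            if not x_lo < p.x < x_hi:
                raise ValueError(f"probe at x={p.x} lies inside the absorbing boundary")
            if p.y is not None and not 0 < p.y < self.grid.extent_y:
                raise ValueError(f"probe at y={p.y} lies outside the domain")
        zi = self.post.zero_interface
        if zi is not None and zi not in _KNOWN_INTERFACES[self.phantom.kind]:
            raise ValueError(
                f"zero_interface {zi!r} unknown for phantom kind {self.phantom.kind!r}"
            )
        if self.post.depth_mode == "uniform" and (
            self.post.n_uniform is None or self.post.n_uniform < 1
        ):
            raise ValueError("uniform depth mode requires n_uniform >= 1")
        if self.mirror_x is not None and not x_lo < self.mirror_x < x_hi:
            raise ValueError("mirror plane lies inside the absorbing boundary")
        return self

    @property
    def zero_interface(self) -> str | None:
        return self.post.zero_interface or DEFAULT_ZERO_INTERFACE[self.phantom.kind]

    def cells_per_wavelength(self) -> float:
        return self.source.lambda0 / self.grid.dx


def load_config(path: str | Path) -> ExperimentConfig:
    """Parse and fully validate a YAML experiment configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a YAML mapping at top level")
    return ExperimentConfig.model_validate(raw)


def dump_config(config: ExperimentConfig, path: str | Path) -> None:
    """Write a configuration to YAML (load(dump(c)) == c)."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=True)
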