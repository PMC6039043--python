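"""Experiment orchestration: two-arm runs, post-processing and artefacts.

``run_experiment`` executes the reference (mirror) arm and the sample arm —
plus an "active"/variant arm when the phantom defines one (perturbed axons
for the nerve, a second sucrose concentration for the glass rod) — then
interferes, envelopes, depth-maps, differences and noise-bands the signals,
and optionally writes every artefact plus a manifest to an output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np

from .boundary import PMLSpec
from .config import ExperimentConfig
from .constants import C
from .grid import GridSpec
from .materials import AxialProfile, MaterialMap
from .oct import (
    AScan,
    DifferentialScan,
    differential_scan,
    envelope,
    incoming_intensity,
    interfere,
    poisson_band,
    round_trip_time,
    time_to_depth,
)
from .phantoms import (
    GlassRodSpec,
    NerveSpec,
    build_glass_rod,
    build_nerve,
    build_slab,
    build_two_layer,
    perturb_axons,
)
from .solver import ProbeTrace, run_simulation
from .source import SourceSpec
from .spectra import fresnel_transmission, measure_transmission

__all__ = [
    "build_material",
    "auto_n_steps",
    "run_arm",
    "run_experiment",
    "ExperimentResult",
    "fresnel_validation",
    "FresnelResult",
    "StageError",
]

log = logging.getLogger("octfdtd")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def build_material(
    config: ExperimentConfig, grid: GridSpec, variant: bool = False
) -> MaterialMap | None:
    """Material map for the configured phantom (or its variant arm)."""
    ph = config.phantom
    if ph.kind == "vacuum":
        return None if variant else MaterialMap.uniform(grid, ph.n, "vacuum")
    if ph.kind == "two_layer":
        return None if variant else build_two_layer(ph.interface_x, ph.n1, ph.n2, grid)
    if ph.kind == "slab":
        return None if variant else build_slab(
            ph.slab_start_x, ph.thickness, ph.n_slab, ph.n_background, grid
        )
    if ph.kind == "glass_rod":
        brix = ph.variant_brix if variant else ph.brix
        if brix is None:
            return None
        spec = GlassRodSpec(
            water_glass_x=ph.water_glass_x,
            glass_solution_x=ph.glass_solution_x,
            brix=brix,
            water_n=ph.water_n,
            glass_n=ph.glass_n,
        )
        return build_glass_rod(spec, grid)
    if ph.kind == "nerve":
        spec = NerveSpec(
            split_fraction=ph.split_fraction,
            epineurium_thickness=ph.epineurium_thickness,
            n_fibres=ph.n_fibres,
            fibre_radius=ph.fibre_radius,
            axon_diameter=ph.axon_diameter,
            myelin_thickness=ph.myelin_thickness,
            axon_gap=ph.axon_gap,
            packing_jitter=ph.packing_jitter,
            edge_margin=ph.edge_margin,
            indices=ph.indices,
        )
        base = build_nerve(spec, grid, seed=config.seed)
        if not variant:
            return base
        if ph.active_delta_n is None:
            return None
        return perturb_axons(base, ph.active_delta_n)
    raise ValueError(f"unknown phantom kind {ph.kind!r}")


def _mirror_x(config: ExperimentConfig, profile: AxialProfile, grid: GridSpec) -> float:
    if config.mirror_x is not None:
        return config.mirror_x
    zi = config.zero_interface
    if zi is not None and zi in profile.interfaces:
        return profile.interfaces[zi]
    if profile.interfaces:
        return min(profile.interfaces.values())
    return grid.extent_x / 2


def auto_n_steps(
    config: ExperimentConfig, grid: GridSpec, src: SourceSpec, material: MaterialMap
) -> int:
    """Steps covering a full round trip through the phantom plus pulse tails."""
    if config.n_steps is not None:
        return config.n_steps
    profile = material.axial_profile(grid, config.probes[0].y)
    opl = float(np.sum(profile.n[profile.x >= src.x]) * grid.dx)
    t_end = src.t0 + 2.0 * opl / C + 4.0 * src.pulse_length
    sub = config.probes[0].subsample_every
    return int(math.ceil(t_end / grid.dt / sub)) * sub


def _pml_spec(config: ExperimentConfig) -> PMLSpec:
    b = config.boundary
    return PMLSpec(b.pml_cells, b.grading_order, b.target_reflection)


def run_arm(config: ExperimentConfig, arm: str = "sample") -> list[ProbeTrace]:
    """Run one simulation arm: ``sample``, ``active`` or ``reference``.

    The reference arm replaces the phantom with its front medium and a
    perfect-mirror plane at the sample's front interface (configurable via
    ``mirror_x``), so zero optical delay aligns with that interface.
    """
    grid = config.grid.build()
    src = config.source.build()
    sample = build_material(config, grid)
    if sample is None:
        raise ValueError("phantom builds no sample material")
    profile = sample.axial_profile(grid, config.probes[0].y)
    n_steps = auto_n_steps(config, grid, src, sample)

    mirror_x = None
    if arm == "sample":
        material = sample
    elif arm == "active":
        material = build_material(config, grid, variant=True)
        if material is None:
            raise ValueError(f"phantom kind {config.phantom.kind!r} defines no variant arm")
    elif arm == "reference":
        material = MaterialMap.uniform(grid, float(profile.n[0]), "reference")
        mirror_x = _mirror_x(config, profile, grid)
    else:
        raise ValueError(f"unknown arm {arm!r}")

    log.info(
        "arm=%s: grid %dx%d cells, dt=%.3e s, Sc=%.4f, lambda0/dx=%.1f, "
        "PML %d cells order %d R0=%.1e, n_steps=%d",
        arm, grid.n_cells_x, grid.n_cells_y, grid.dt, grid.courant_fraction,
        config.cells_per_wavelength(), config.boundary.pml_cells,
        config.boundary.grading_order, config.boundary.target_reflection, n_steps,
    )
    probes = [
        (p.x, p.y if p.y is not None else grid.extent_y / 2) for p in config.probes
    ]
    result = run_simulation(
        grid, material, src, probes, n_steps,
        pml_spec=_pml_spec(config),
        periodic_y=config.boundary.periodic_y,
        mirror_x=mirror_x,
        subsample_every=config.probes[0].subsample_every,
    )
    return result.traces


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    traces: dict[str, ProbeTrace]
    ascan: AScan
    ascan_active: AScan | None
    differential: DifferentialScan | None
    noise_band: np.ndarray
    incoming: float
    manifest: dict = field(default_factory=dict)


def _config_hash(config: ExperimentConfig) -> str:
    blob = json.dumps(config.model_dump(mode="json"), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def run_experiment(
    config: ExperimentConfig, out_dir: str | Path | None = None
) -> ExperimentResult:
    """Full two-arm pipeline; writes artefacts and a manifest under out_dir."""
    out = Path(out_dir) if out_dir is not None else None
    handler = None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out / "run.log", mode="w")
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(handler)
        if log.level == logging.NOTSET:
            log.setLevel(logging.INFO)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "code_version": _package_version(),
        "seed": config.seed,
        "stages": [],
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    stage = "setup"
    try:
        grid = config.grid.build()
        src = config.source.build()
        sample_map = build_material(config, grid)
        if sample_map is None:
            raise ValueError("phantom builds no sample material")
        profile = sample_map.axial_profile(grid, config.probes[0].y)

        stage = "reference-arm"
        ref = run_arm(config, "reference")[0]
        manifest["stages"].append(stage)

        stage = "sample-arm"
        sample = run_arm(config, "sample")[0]
        manifest["stages"].append(stage)

        active = None
        has_variant = build_material(config, grid, variant=True) is not None
        if has_variant:
            stage = "active-arm"
            active = run_arm(config, "active")[0]
            manifest["stages"].append(stage)

        stage = "post-processing"
        incoming = incoming_intensity(ref)
        zi = config.zero_interface
        if zi is None:
            raise ValueError(
                f"phantom kind {config.phantom.kind!r} has no depth-zero interface; "
                "A-scan post-processing is undefined"
            )
        kwargs = dict(
            profile=profile, zero_interface=zi,
            x_source=src.x, x_probe=config.probes[0].x, t0=src.t0,
            mode=config.post.depth_mode, n_uniform=config.post.n_uniform,
        )
        interference = interfere(ref, sample)
        # one shared baseline for both arms: a per-arm mean would couple the
        # arms through a constant offset and smear the differential
        dc: str | float = config.post.dc_mode
        if dc == "mean":
            dc = float(interference.intensity.mean())
        env = envelope(interference, dc=dc)
        ascan = time_to_depth(env, **kwargs)
        band = poisson_band(ascan, config.post.photon_budget, incoming)
        ascan_active = None
        diff = None
        if active is not None:
            env_a = envelope(interfere(ref, active), dc=dc)
            ascan_active = time_to_depth(env_a, **kwargs)
        ascan, ascan_active, band = _crop_depth(
            config, profile, ascan, ascan_active, band
        )
        if ascan_active is not None:
            diff = differential_scan(ascan, ascan_active, incoming, noise_band=band)
        manifest["stages"].append(stage)
        manifest.update(
            n_steps=auto_n_steps(config, grid, src, sample_map),
            dt_s=grid.dt,
            cells=[grid.n_cells_x, grid.n_cells_y],
            cells_per_wavelength=config.cells_per_wavelength(),
            incoming_intensity=incoming,
        )

        traces = {"reference": ref, "sample": sample}
        if active is not None:
            traces["active"] = active
        result = ExperimentResult(
            config=config, traces=traces, ascan=ascan, ascan_active=ascan_active,
            differential=diff, noise_band=band, incoming=incoming, manifest=manifest,
        )
        if out is not None:
            stage = "write-artefacts"
            _write_artefacts(result, out)
            manifest["stages"].append(stage)
            from .io import write_manifest

            write_manifest(manifest, out / "manifest.json")
        return result
    except Exception as exc:
        log.error("stage %s failed: %s", stage, exc)
        if out is not None:
            manifest["failed_stage"] = stage
            from .io import write_manifest

            write_manifest(manifest, out / "manifest.json")
        raise StageError(stage, exc) from exc
    finally:
        if handler is not None:
            handler.close()
            log.removeHandler(handler)


def _crop_depth(
    config: ExperimentConfig,
    profile: AxialProfile,
    ascan: AScan,
    ascan_active: AScan | None,
    band: np.ndarray,
) -> tuple[AScan, AScan | None, np.ndarray]:
    """Restrict the A-scan to the configured depth window.

    The default lower bound sits halfway between the probe and the zero
    interface, which removes the incident pulse passing the probe (it maps
    to depth ``x_probe - x_interface``) while keeping the full echo train.
    """
    dmin = config.post.depth_min
    if dmin is None:
        x0 = profile.interfaces.get(config.zero_interface)
        x_probe = config.probes[0].x
        dmin = 0.5 * (x_probe - x0) if (x0 is not None and x_probe < x0) else -np.inf
    dmax = config.post.depth_max if config.post.depth_max is not None else np.inf
    keep = (ascan.depth >= dmin) & (ascan.depth <= dmax)
    if not np.any(keep):
        raise ValueError("depth window excludes the entire A-scan")
    cropped = AScan(ascan.depth[keep], ascan.envelope[keep], ascan.zero_interface)
    cropped_active = None
    if ascan_active is not None:
        cropped_active = AScan(
            ascan_active.depth[keep], ascan_active.envelope[keep],
            ascan_active.zero_interface,
        )
    return cropped, cropped_active, band[keep]


def _package_version() -> str:
    try:
        return version("octfdtd")
    except PackageNotFoundError:  # pragma: no cover - not installed
        return "unknown"


def _write_artefacts(result: ExperimentResult, out: Path) -> None:
    from . import io

    tr = out / "traces"
    tr.mkdir(exist_ok=True)
    for name, trace in result.traces.items():
        io.write_trace_csv(trace, tr / f"{name}.csv")
    io.write_ascan_tsv(result.ascan, out / "ascan.tsv", noise_band=result.noise_band)
    if result.ascan_active is not None:
        io.write_ascan_tsv(result.ascan_active, out / "ascan_active.tsv")
    if result.differential is not None:
        io.write_differential_tsv(result.differential, out / "differential.tsv")


# ---------------------------------------------------------------------------
# Fresnel validation
# ---------------------------------------------------------------------------

@dataclass
class FresnelResult:
    wavelengths: np.ndarray
    t_simulated: np.ndarray
    t_theory: float
    r_simulated: np.ndarray

    @property
    def max_relative_error(self) -> float:
        return float(np.max(np.abs(self.t_simulated - self.t_theory)) / self.t_theory)


def fresnel_validation(
    config: ExperimentConfig,
    pad_factor: int = 4,
    power_threshold: float = 0.01,
) -> FresnelResult:
    """Simulated vs Fresnel transmission across a single planar interface.

    Runs the two-probe ``two_layer`` configuration once, time-gates the
    incident-side probe into incident and reflected pulses at the midpoint
    between their arrival times, and forms per-wavelength intensity
    transmission ``(n2/n1)|E_t/E_i|^2`` and reflection ``|E_r/E_i|^2``.
    """
    ph = config.phantom
    if ph.kind != "two_layer":
        raise ValueError("fresnel_validation requires a two_layer phantom")
    if len(config.probes) < 2:
        raise ValueError("need an incident-side and a transmitted-side probe")
    grid = config.grid.build()
    src = config.source.build()
    material = build_material(config, grid)
    traces = run_arm(config, "sample")
    front, back = traces[0], traces[1]
    profile = material.axial_profile(grid, config.probes[0].y)

    x_probe = config.probes[0].x
    t_pass = round_trip_time(profile, src.x, x_probe, x_probe, src.t0)
    t_echo = round_trip_time(profile, src.x, x_probe, ph.interface_x, src.t0)
    t_mid = 0.5 * (t_pass + t_echo)
    incident = front.windowed(0.0, t_mid)
    reflected = front.windowed(t_mid, float(front.times[-1]))

    t_spec = measure_transmission(
        incident, back, ph.n1, ph.n2, pad_factor=pad_factor, power_threshold=power_threshold
    )
    r_spec = measure_transmission(
        incident, reflected, ph.n1, ph.n1, pad_factor=pad_factor,
        power_threshold=power_threshold,
    )
    return FresnelResult(
        wavelengths=t_spec.wavelengths,
        t_simulated=t_spec.power,
        t_theory=fresnel_transmission(ph.n1, ph.n2),
        r_simulated=r_spec.power,
    )
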