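"""Readers and writers for the package's artefact formats.

Traces and spectra are CSV, A-scans and differential scans TSV, field
snapshots and material maps HDF5, manifests JSON.  Every writer's output is
re-readable by the matching reader.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .grid import GridSpec
from .materials import MaterialMap
from .oct import AScan, DifferentialScan
from .solver import FieldSnapshot, ProbeTrace
from .spectra import GaussianFit, Spectrum

__all__ = [
    "write_trace_csv", "read_trace_csv",
    "write_ascan_tsv", "read_ascan_tsv",
    "write_differential_tsv", "read_differential_tsv",
    "write_spectrum_csv", "read_spectrum_csv",
    "write_manifest", "read_manifest",
    "write_material_hdf5", "read_material_hdf5",
    "write_snapshots_hdf5",
    "write_fit_report",
    "material_png", "ascan_png",
]


def write_trace_csv(trace: ProbeTrace, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# x={trace.position[0]!r} y={trace.position[1]!r} "
            f"subsample_every={trace.subsample_every}\n"
        )
        pd.DataFrame({"time_s": trace.times, "amplitude": trace.amplitudes}).to_csv(
            fh, index=False
        )


def read_trace_csv(path: str | Path) -> ProbeTrace:
    with open(path) as fh:
        header = fh.readline()
    meta = dict(item.split("=") for item in header.lstrip("# ").split())
    df = pd.read_csv(path, comment="#")
    return ProbeTrace(
        position=(float(meta.get("x", 0.0)), float(meta.get("y", 0.0))),
        subsample_every=int(meta.get("subsample_every", 1)),
        times=df["time_s"].to_numpy(),
        amplitudes=df["amplitude"].to_numpy(),
    )


def write_ascan_tsv(
    ascan: AScan, path: str | Path, noise_band: np.ndarray | None = None
) -> None:
    cols = {"depth_m": ascan.depth, "value": ascan.envelope}
    if noise_band is not None:
        cols["noise_band"] = noise_band
    with open(path, "w") as fh:
        fh.write(f"# zero_interface={ascan.zero_interface}\n")
        pd.DataFrame(cols).to_csv(fh, index=False, sep="\t")


def read_ascan_tsv(path: str | Path) -> tuple[AScan, np.ndarray | None]:
    with open(path) as fh:
        header = fh.readline()
    zero = header.lstrip("# ").strip().split("=", 1)[1]
    df = pd.read_csv(path, comment="#", sep="\t")
    band = df["noise_band"].to_numpy() if "noise_band" in df else None
    return AScan(df["depth_m"].to_numpy(), df["value"].to_numpy(), zero), band


def write_differential_tsv(diff: DifferentialScan, path: str | Path) -> None:
    cols = {"depth_m": diff.depth, "value": diff.delta}
    if diff.noise_band is not None:
        cols["noise_band"] = diff.noise_band
    pd.DataFrame(cols).to_csv(path, index=False, sep="\t")


def read_differential_tsv(path: str | Path) -> DifferentialScan:
    df = pd.read_csv(path, sep="\t")
    band = df["noise_band"].to_numpy() if "noise_band" in df else None
    return DifferentialScan(df["depth_m"].to_numpy(), df["value"].to_numpy(), band)


def write_spectrum_csv(spec: Spectrum, path: str | Path) -> None:
    pd.DataFrame({"wavelength_m": spec.wavelengths, "power": spec.power}).to_csv(
        path, index=False
    )


def read_spectrum_csv(path: str | Path) -> Spectrum:
    df = pd.read_csv(path)
    lam = df["wavelength_m"].to_numpy()
    from .constants import C

    return Spectrum(frequencies=C / lam, wavelengths=lam, power=df["power"].to_numpy())


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_material_hdf5(mmap: MaterialMap, grid: GridSpec, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("n", data=mmap.n_grid)
        f.create_dataset("labels", data=mmap.labels)
        f.attrs["dx"] = grid.dx
        f.attrs["label_names"] = json.dumps({str(k): v for k, v in mmap.label_names.items()})
        f.attrs["provenance"] = json.dumps(mmap.provenance)


def read_material_hdf5(path: str | Path) -> MaterialMap:
    with h5py.File(path, "r") as f:
        names = {int(k): v for k, v in json.loads(f.attrs["label_names"]).items()}
        return MaterialMap(f["n"][...], f["labels"][...], names,
                           json.loads(f.attrs["provenance"]))


def write_snapshots_hdf5(
    snapshots: list[FieldSnapshot], grid: GridSpec, path: str | Path
) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["dx"] = grid.dx
        f.attrs["dt"] = grid.dt
        for snap in snapshots:
            g = f.create_group(f"step_{snap.step:08d}")
            g.attrs["step"] = snap.step
            g.attrs["dx"] = grid.dx
            g.attrs["dt"] = grid.dt
            g.create_dataset("E", data=snap.E)
            g.create_dataset("H1", data=snap.H1)
            g.create_dataset("H2", data=snap.H2)


def write_fit_report(fit: GaussianFit, path: str | Path) -> None:
    write_manifest(
        {"centre_m": fit.centre, "sigma_m": fit.sigma, "amplitude": fit.amplitude,
         "residual_norm": fit.residual_norm},
        path,
    )


def material_png(mmap: MaterialMap, path: str | Path) -> None:
    """Index heat-map for visual inspection (x horizontal, y vertical)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    im = ax.imshow(mmap.n_grid.T, origin="lower", aspect="auto", cmap="viridis")
    fig.colorbar(im, ax=ax, label="refractive index")
    ax.set_xlabel("x cell")
    ax.set_ylabel("y cell")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def ascan_png(
    ascan: AScan, path: str | Path, noise_band: np.ndarray | None = None
) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    z = ascan.depth * 1e6
    ax.plot(z, ascan.envelope, lw=0.8, color="k")
    if noise_band is not None:
        ax.fill_between(z, -noise_band, noise_band, color="grey", alpha=0.4)
    ax.set_xlabel("depth (um)")
    ax.set_ylabel("OCT signal (a.u.)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
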