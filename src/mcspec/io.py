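"""Readers and writers for the on-disk artifacts.

Every reader is the inverse of its writer: HDF5 spectrum cubes,
two-column text spectra/profiles (``#`` comments ignored), 32-bit TIFF
maps with PNG renderings carrying the thickness isolines, and CSV
tables.  Malformed files raise :class:`FileFormatError` naming the
offending location.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .waxs import Profile1D
from .xanes import XanesSpectrum
from .xrf import SpectrumCube

__all__ = [
    "FileFormatError",
    "write_cube",
    "read_cube",
    "write_two_column",
    "read_two_column",
    "read_profile",
    "write_profile",
    "read_xanes",
    "write_xanes",
    "write_map_tiff",
    "read_map_tiff",
    "write_map_png",
]


class FileFormatError(ValueError):
    """Raised when an on-disk artifact cannot be parsed."""


# ---------------------------------------------------------------------------
# HDF5 spectrum cubes
# ---------------------------------------------------------------------------

def write_cube(path, cube: SpectrumCube) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("counts", data=cube.counts, compression="gzip")
        if cube.transmission is not None:
            f.create_dataset("transmission", data=cube.transmission)
        f.create_dataset("i0", data=np.asarray(cube.i0))
        cal = f.create_group("calibration")
        cal.attrs["gain"] = cube.gain_kev
        cal.attrs["offset"] = cube.offset_kev
        meta = f.create_group("meta")
        meta.attrs["E_in"] = cube.e_in
        meta.attrs["live_time"] = cube.live_time_s


def read_cube(path) -> SpectrumCube:
    try:
        with h5py.File(path, "r") as f:
            counts = f["counts"][...]
            trans = f["transmission"][...] if "transmission" in f else None
            i0 = f["i0"][...]
            cal = f["calibration"].attrs
            meta = f["meta"].attrs
            return SpectrumCube(counts, float(meta["E_in"]), float(cal["gain"]),
                                float(cal["offset"]), float(meta["live_time"]),
                                transmission=trans,
                                i0=float(i0) if i0.ndim == 0 else i0)
    except (OSError, KeyError) as exc:
        raise FileFormatError(f"cannot read spectrum cube {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Two-column text
# ---------------------------------------------------------------------------

def write_two_column(path, x: np.ndarray, y: np.ndarray,
                     header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for xi, yi in zip(x, y):
            fh.write(f"{xi:.9g} {yi:.9g}\n")


def read_two_column(path) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            if len(parts) < 2:
                raise FileFormatError(f"{path}: line {ln}: expected two columns")
            try:
                xs.append(float(parts[0]))
                ys.append(float(parts[1]))
            except ValueError as exc:
                raise FileFormatError(f"{path}: line {ln}: {exc}") from exc
    if not xs:
        raise FileFormatError(f"{path}: no data rows")
    return np.array(xs), np.array(ys)


def write_profile(path, profile: Profile1D) -> None:
    write_two_column(path, profile.q_nm, profile.intensity,
                     header="q_nm^-1 intensity")


def read_profile(path) -> Profile1D:
    q, i = read_two_column(path)
    return Profile1D(q, i)


def write_xanes(path, spec: XanesSpectrum) -> None:
    write_two_column(path, spec.energy_ev, spec.mu,
                     header=f"energy_eV mu mode={spec.mode} "
                            f"normalized={spec.normalized}")


def read_xanes(path, mode: str = "transmission") -> XanesSpectrum:
    e, mu = read_two_column(path)
    return XanesSpectrum(e, mu, mode=mode)


# ---------------------------------------------------------------------------
# Maps
# ---------------------------------------------------------------------------

def write_map_tiff(path, data: np.ndarray) -> None:
    import tifffile
    tifffile.imwrite(path, np.asarray(data, dtype=np.float32))


def read_map_tiff(path) -> np.ndarray:
    import tifffile
    try:
        return np.asarray(tifffile.imread(path), dtype=float)
    except Exception as exc:   # tifffile raises several types
        raise FileFormatError(f"cannot read map {path}: {exc}") from exc


def write_map_png(path, data: np.ndarray,
                  thickness_um: np.ndarray | None = None,
                  isolines=(0.3, 0.5, 1.0),
                  title: str = "", cmap: str = "viridis") -> None:
    """Render a map to PNG with the thickness interpretation contours."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(data, cmap=cmap, origin="upper")
    if thickness_um is not None:
        colors = ["white", "red", "black"]
        for level, color in zip(isolines, colors):
            ax.contour(thickness_um, levels=[level], colors=[color],
                       linewidths=0.8)
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
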