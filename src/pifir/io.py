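"""File I/O: spectra tables, scan TIFFs, hyperspectral cube containers.

Formats
-------
* spectra table: delimited text with a ``wavenumber`` first column and
  one column per spectrum, plus an optional JSON sidecar
  (``<stem>.labels.json``) carrying per-spectrum labels and the reference
  spectrum;
* scan map: 32-bit float TIFF plus a JSON sidecar with channel,
  wavenumber and pixel size;
* cube: either an HDF5 container (datasets ``cube`` and ``wavenumber``,
  attribute ``pixel_size_nm``) or a directory of per-wavenumber TIFFs
  with an ``axis.json``; both round-trip losslessly and are
  auto-detected on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .axes import WavenumberAxis
from .images import HyperspectralCube, ScanImage
from .spectra import ReferenceSpectrum, SpectraSet

__all__ = [
    "write_spectra_table",
    "read_spectra_table",
    "write_scan",
    "read_scan",
    "write_cube",
    "read_cube",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".labels.json")


def write_spectra_table(spectra: SpectraSet, path: str | Path, sep: str = "\t") -> Path:
    path = Path(path)
    cols = {"wavenumber": spectra.axis.values}
    for i in range(len(spectra)):
        cols[f"spectrum_{i:03d}"] = spectra.intensities[i]
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False, float_format="%.17g")
    sidecar = {
        "labels": spectra.labels.to_dict(orient="records"),
        "axis": {"start": spectra.axis.start, "stop": spectra.axis.stop, "step": spectra.axis.step},
    }
    if spectra.reference is not None:
        sidecar["reference"] = {
            "intensity": spectra.reference.intensity.tolist(),
            "source": spectra.reference.source,
        }
    _sidecar(path).write_text(json.dumps(sidecar))
    return path


def read_spectra_table(path: str | Path, sep: str = "\t") -> SpectraSet:
    path = Path(path)
    table = pd.read_csv(path, sep=sep)
    if table.columns[0] != "wavenumber":
        raise ValueError("first column must be 'wavenumber'")
    nu = table["wavenumber"].to_numpy(float)
    values = table.drop(columns="wavenumber").to_numpy(float).T
    if nu.size >= 2 and nu[0] > nu[-1]:  # enforce ascending convention
        import warnings

        warnings.warn("descending wavenumber axis reordered to ascending", stacklevel=2)
        nu = nu[::-1]
        values = values[:, ::-1]
    steps = np.diff(nu)
    if nu.size >= 2 and (np.any(steps <= 0) or not np.allclose(steps, steps[0])):
        raise ValueError("wavenumber axis must be uniform and monotone")
    axis = WavenumberAxis(float(nu[0]), float(nu[-1]), float(steps[0]) if nu.size >= 2 else 1.0)
    labels = pd.DataFrame({"group": ["unlabeled"] * values.shape[0]})
    reference = None
    sidecar = _sidecar(path)
    if sidecar.exists():
        info = json.loads(sidecar.read_text())
        if info.get("labels"):
            labels = pd.DataFrame.from_records(info["labels"])
        if "reference" in info:
            reference = ReferenceSpectrum(
                axis, np.asarray(info["reference"]["intensity"]), info["reference"]["source"]
            )
    return SpectraSet(axis, values, labels, reference=reference)


def write_scan(scan: ScanImage, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, scan.data.astype(np.float32))
    meta = {
        "channel": scan.channel,
        "wavenumber": scan.wavenumber,
        "pixel_size_nm": scan.pixel_size_nm,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))
    return path


def read_scan(path: str | Path) -> ScanImage:
    path = Path(path)
    data = tifffile.imread(path).astype(float)
    meta_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return ScanImage(
        data,
        channel=meta.get("channel", "pif"),
        wavenumber=meta.get("wavenumber"),
        pixel_size_nm=meta.get("pixel_size_nm", 20.0),
    )


def write_cube(cube: HyperspectralCube, path: str | Path, dialect: str = "hdf5") -> Path:
    """Write a cube as HDF5 (default) or as a per-wavenumber TIFF directory."""
    path = Path(path)
    if dialect == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("cube", data=cube.data)
            f.create_dataset("wavenumber", data=cube.axis.values)
            f.attrs["pixel_size_nm"] = cube.pixel_size_nm
    elif dialect == "tiff_dir":
        path.mkdir(parents=True, exist_ok=True)
        for i, nu in enumerate(cube.axis.values):
            tifffile.imwrite(path / f"slice_{i:04d}_{nu:.2f}.tif", cube.data[:, :, i])
        (path / "axis.json").write_text(
            json.dumps(
                {
                    "start": cube.axis.start,
                    "stop": cube.axis.stop,
                    "step": cube.axis.step,
                    "pixel_size_nm": cube.pixel_size_nm,
                }
            )
        )
    else:
        raise ValueError("dialect must be 'hdf5' or 'tiff_dir'")
    return path


def read_cube(path: str | Path) -> HyperspectralCube:
    """Read a cube container; the dialect is auto-detected."""
    path = Path(path)
    if path.is_dir():
        axis_file = path / "axis.json"
        if not axis_file.exists():
            raise ValueError(f"{path} is not a cube directory (missing axis.json)")
        info = json.loads(axis_file.read_text())
        axis = WavenumberAxis(info["start"], info["stop"], info["step"])
        slices = sorted(path.glob("slice_*.tif"))
        if len(slices) != axis.n_bins:
            raise ValueError("cube directory slice count does not match its axis")
        data = np.dstack([tifffile.imread(p) for p in slices])
        return HyperspectralCube(data, axis, pixel_size_nm=info.get("pixel_size_nm", 13.0))
    with h5py.File(path, "r") as f:
        if "wavenumber" not in f or "cube" not in f:
            raise ValueError("cube file must contain 'cube' and 'wavenumber' datasets")
        nu = np.asarray(f["wavenumber"])
        data = np.asarray(f["cube"])
        if data.shape[2] != nu.size:
            raise ValueError("cube spectral dimension does not match the wavenumber axis")
        axis = WavenumberAxis(float(nu[0]), float(nu[-1]), float(nu[1] - nu[0]) if nu.size > 1 else 1.0)
        return HyperspectralCube(data, axis, pixel_size_nm=float(f.attrs.get("pixel_size_nm", 13.0)))
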