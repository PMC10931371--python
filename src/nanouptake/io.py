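"""File formats and run configuration.

Confocal stacks travel as TIFF (one multi-page file per channel, pages =
z-planes, or a single 4-D file with a channel axis).  Raman cubes use an
open container: long-format CSV with columns (x, y, z, wavenumber,
intensity) in micrometres/cm^-1, or an HDF5 binary layout (datasets
``axis`` and ``intensities`` plus step-size attributes) for lossless
round-trips.  Run configuration is a strict JSON/YAML mapping: unknown
keys are rejected.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .fluor import CHANNEL_ROLES, ConfocalStack, UptakeRecord
from .raman import RamanCube

logger = logging.getLogger(__name__)

__all__ = [
    "read_stack",
    "write_stack",
    "read_cube",
    "write_cube",
    "write_records_csv",
    "read_records_csv",
    "write_endmembers_csv",
    "RunConfig",
    "load_config",
]


# --------------------------------------------------------------------------
# confocal stacks


def write_stack(stack: ConfocalStack, path: str | Path) -> None:
    """Write a stack as a single TIFF with axes (z, channel, y, x).

    The channel order and pixel sizes are stored in the image description.
    """
    path = Path(path)
    roles = sorted(stack.channels)
    data = np.stack([stack.channels[r] for r in roles], axis=1)
    meta = {
        "channel_roles": roles,
        "pixel_size_um": stack.pixel_size_um,
        "z_step_um": stack.z_step_um,
    }
    tifffile.imwrite(
        path, data, description=json.dumps(meta), photometric="minisblack"
    )


def read_stack(
    path: str | Path | Mapping[str, str | Path],
    channel_map: Mapping[str, int] | None = None,
    pixel_size_um: float | None = None,
    z_step_um: float | None = None,
) -> ConfocalStack:
    """Read a confocal stack from TIFF.

    ``path`` is either a single file with axes (z, channel, y, x) — with
    ``channel_map`` mapping role to channel index, or roles recovered from
    the embedded description — or a mapping role -> per-channel z-stack
    file.  An explicit ``pixel_size_um`` overrides any value found in the
    file metadata (a warning is logged on conflict).
    """
    if isinstance(path, Mapping):
        channels = {}
        for role, p in path.items():
            if role not in CHANNEL_ROLES:
                raise ValueError(f"unknown channel role {role!r}")
            arr = tifffile.imread(Path(p))
            channels[role] = arr if arr.ndim == 3 else arr[None]
        meta = {}
    else:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            desc = tf.pages[0].description
        meta = {}
        if desc:
            try:
                meta = json.loads(desc)
            except (json.JSONDecodeError, TypeError):
                meta = {}
        if data.ndim != 4:
            raise ValueError("stack TIFF must have axes (z, channel, y, x)")
        if channel_map is None:
            roles = meta.get("channel_roles")
            if roles is None:
                raise ValueError(
                    "no channel_map given and none stored in the file"
                )
            channel_map = {r: i for i, r in enumerate(roles)}
        channels = {}
        for role, idx in channel_map.items():
            if role not in CHANNEL_ROLES:
                raise ValueError(f"unknown channel role {role!r}")
            if not 0 <= idx < data.shape[1]:
                raise ValueError(
                    f"channel index {idx} for role {role!r} out of range"
                )
            channels[role] = data[:, idx]
    for required in ("nuclei", "beads"):
        if required not in channels:
            raise ValueError(f"stack is missing the {required!r} channel")

    meta_px = meta.get("pixel_size_um")
    if pixel_size_um is None:
        if meta_px is None:
            raise ValueError(
                "pixel size not found in metadata; pass pixel_size_um"
            )
        px = float(meta_px)
    else:
        px = float(pixel_size_um)
        if meta_px is not None and not np.isclose(px, float(meta_px)):
            warnings.warn(
                f"pixel size conflict: metadata {meta_px}, config {px}; "
                "using the config value",
                stacklevel=2,
            )
            logger.warning(
                "pixel size conflict (metadata %s vs config %s): config wins",
                meta_px, px,
            )
    zs = float(
        z_step_um
        if z_step_um is not None
        else meta.get("z_step_um", 1.0)
    )
    return ConfocalStack(channels=channels, pixel_size_um=px, z_step_um=zs)


# --------------------------------------------------------------------------
# Raman cubes


def write_cube(cube: RamanCube, path: str | Path) -> None:
    """Write a cube as long CSV (.csv) or HDF5 (.h5/.hdf5)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        nz, ny, nx = cube.grid_shape
        z, y, x = np.meshgrid(
            np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
        )
        n = cube.axis.size
        df = pd.DataFrame(
            {
                "x": np.repeat(x.ravel() * cube.step_um, n),
                "y": np.repeat(y.ravel() * cube.step_um, n),
                "z": np.repeat(z.ravel() * cube.z_step_um, n),
                "wavenumber": np.tile(cube.axis, nz * ny * nx),
                "intensity": cube.as_matrix().ravel(),
            }
        )
        df.to_csv(path, index=False)
    elif path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("axis", data=cube.axis)
            f.create_dataset("intensities", data=cube.intensities)
            f.attrs["step_um"] = cube.step_um
            f.attrs["z_step_um"] = cube.z_step_um
    else:
        raise ValueError(f"unsupported cube container {path.suffix!r}")


def read_cube(path: str | Path) -> RamanCube:
    """Read a cube written by :func:`write_cube`.

    The CSV reader is order-independent: rows are sorted by (z, y, x,
    wavenumber) before reassembly.  A repeated wavenumber or ragged pixel
    spectra raise ``ValueError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        need = {"x", "y", "z", "wavenumber", "intensity"}
        if not need <= set(df.columns):
            raise ValueError(f"cube CSV must have columns {sorted(need)}")
        axis = np.sort(df["wavenumber"].unique())
        if axis.size > 1 and not np.all(np.diff(axis) > 0):
            raise ValueError("wavenumber axis is not strictly increasing")
        xs = np.sort(df["x"].unique())
        ys = np.sort(df["y"].unique())
        zs = np.sort(df["z"].unique())
        if len(df) != xs.size * ys.size * zs.size * axis.size:
            raise ValueError(
                "ragged cube CSV: row count does not factor into a full grid"
            )
        df = df.sort_values(["z", "y", "x", "wavenumber"], kind="mergesort")
        # duplicate (pixel, wavenumber) pairs would survive the length
        # check only by omitting another pair, caught above; a repeated
        # wavenumber per pixel is a ragged spectrum
        counts = df.groupby(["z", "y", "x"])["wavenumber"].nunique()
        if (counts != axis.size).any():
            raise ValueError("repeated wavenumber within a pixel spectrum")
        intens = df["intensity"].to_numpy().reshape(
            zs.size, ys.size, xs.size, axis.size
        )
        step = float(xs[1] - xs[0]) if xs.size > 1 else 1.0
        zstep = float(zs[1] - zs[0]) if zs.size > 1 else 1.0
        return RamanCube(
            axis=axis, intensities=intens, step_um=step, z_step_um=zstep
        )
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            axis = f["axis"][()]
            if axis.size > 1 and not np.all(np.diff(axis) > 0):
                raise ValueError("wavenumber axis is not strictly increasing")
            return RamanCube(
                axis=axis,
                intensities=f["intensities"][()],
                step_um=float(f.attrs["step_um"]),
                z_step_um=float(f.attrs["z_step_um"]),
            )
    raise ValueError(f"unsupported cube container {path.suffix!r}")


# --------------------------------------------------------------------------
# tabular outputs


RECORD_COLUMNS = [
    "cell_line", "concentration", "time_h", "replicate",
    "bead_pixels", "n_nuclei", "bead_px_per_cell",
    "bead_area_um2", "fov_area_um2", "valid", "cell_mask_source",
]


def write_records_csv(records: list[UptakeRecord], path: str | Path) -> None:
    """One CSV row per field of view."""
    rows = [{c: getattr(r, c) for c in RECORD_COLUMNS} for r in records]
    pd.DataFrame(rows, columns=RECORD_COLUMNS).to_csv(Path(path), index=False)


def read_records_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    missing = set(RECORD_COLUMNS[:7]) - set(df.columns)
    if missing:
        raise ValueError(f"records CSV missing columns {sorted(missing)}")
    return df


def write_endmembers_csv(endmembers, path: str | Path) -> None:
    """Endmember spectra as CSV: wavenumber axis plus one column per EM."""
    cols = {"wavenumber": endmembers.axis}
    for i, (spec, lab) in enumerate(
        zip(endmembers.spectra, endmembers.labels), start=1
    ):
        cols[f"EM{i}_{lab}"] = spec
    pd.DataFrame(cols).to_csv(Path(path), index=False)


# --------------------------------------------------------------------------
# run configuration


_KNOWN_KEYS = {
    "inputs", "output_dir", "channel_map", "pixel_size_um", "z_step_um",
    "segmentation", "preprocess", "unmixing", "stats", "seed", "synthetic",
}
_KNOWN_UNMIXING = {"k", "n_restarts"}


@dataclass
class RunConfig:
    """Validated run configuration.

    A mandatory ``seed`` governs every stochastic stage; unknown top-level
    keys are rejected so typos fail loudly.
    """

    seed: int
    inputs: dict = field(default_factory=dict)
    output_dir: str = "."
    channel_map: dict = field(default_factory=dict)
    pixel_size_um: float | None = None
    z_step_um: float | None = None
    segmentation: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)
    unmixing: dict = field(default_factory=lambda: {"k": 3, "n_restarts": 5})
    stats: dict = field(default_factory=dict)
    synthetic: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in raw:
            raise ValueError("config must provide a seed")
        bad = set(raw.get("unmixing", {})) - _KNOWN_UNMIXING
        if bad:
            raise ValueError(f"unknown unmixing keys: {sorted(bad)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load a JSON or YAML run configuration."""
    path = Path(path)
    text = path.read_text()
    raw = (
        json.loads(text)
        if path.suffix.lower() == ".json"
        else yaml.safe_load(text)
    )
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    return RunConfig.from_dict(raw)
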