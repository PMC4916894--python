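"""Multi-channel image stacks, TIFF round-tripping, and z-projections.

The analysis consumes 2D images; microscopy delivers multi-channel z-stacks.
This module holds the in-memory stack container with named channel roles
(counterstain / reference / test), reads and writes multi-page TIFF via
tifffile, and reduces stacks to 2D by maximum-intensity or average
projection.  Quantification downstream always runs on MIP images; average
projections over a physical z-window are provided for display parity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile

from .errors import RoleError, ContractError

ROLE_COUNTERSTAIN = "counterstain"
ROLE_REFERENCE = "reference"
ROLE_TEST = "test"
REQUIRED_ROLES = (ROLE_COUNTERSTAIN, ROLE_REFERENCE, ROLE_TEST)


@dataclass
class ImageStack:
    """A (channel, z, y, x) raster with named channel roles.

    Pixel data are promoted to float64 at construction; the original dtype
    is kept in ``source_dtype`` for provenance.  ``pixel_size`` and
    ``z_step`` are micrometers when known.
    """

    data: np.ndarray
    roles: dict[str, int]
    pixel_size: float | None = None
    z_step: float | None = None
    source_dtype: np.dtype | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 4:
            raise ContractError(f"stack data must be (C, Z, Y, X), got shape {arr.shape}")
        if self.source_dtype is None:
            self.source_dtype = arr.dtype
        self.data = arr.astype(np.float64, copy=False)
        n_channels = arr.shape[0]
        for role, idx in self.roles.items():
            if not (0 <= idx < n_channels):
                raise RoleError(f"role {role!r} maps to channel {idx}, but stack has {n_channels} channels")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_slices(self) -> int:
        return self.data.shape[1]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def channel_index(self, channel: int | str) -> int:
        if isinstance(channel, str):
            if channel not in self.roles:
                raise RoleError(f"stack has no channel with role {channel!r} (roles: {sorted(self.roles)})")
            return self.roles[channel]
        if not (0 <= channel < self.n_channels):
            raise RoleError(f"channel index {channel} out of range for {self.n_channels} channels")
        return channel

    def require_roles(self, roles: tuple[str, ...] = REQUIRED_ROLES) -> None:
        """Check that exactly one channel carries each required role."""
        missing = [r for r in roles if r not in self.roles]
        if missing:
            raise RoleError(f"stack is missing required channel roles: {missing}")
        indices = [self.roles[r] for r in roles]
        if len(set(indices)) != len(indices):
            raise RoleError(f"channel roles must map to distinct channels, got {self.roles}")


@dataclass
class Image2D:
    """A single 2D channel image with its projection provenance."""

    data: np.ndarray
    provenance: str = "single-slice"
    channel: int | str | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.float64)
        if arr.ndim != 2:
            raise ContractError(f"Image2D data must be 2D, got shape {arr.shape}")
        self.data = arr


def read_stack(
    path: str | Path,
    role_map: Mapping[str, int],
    layout: str = "auto",
    pixel_size: float | None = None,
    z_step: float | None = None,
) -> ImageStack:
    """Read a multi-page TIFF into an :class:`ImageStack`.

    ``layout`` resolves the axis meaning for 3D files: ``"CYX"`` treats
    pages as channels (the default for ``auto``), ``"ZYX"`` as z-slices.
    4D files are taken as ``CZYX`` (``"ZCYX"`` to transpose).  Sidecar
    metadata written by :func:`write_stack` overrides ``auto``.
    """
    path = Path(path)
    arr = tifffile.imread(path)
    if layout == "auto":
        sidecar = path.with_suffix(path.suffix + ".json")
        layout = "CYX" if arr.ndim == 3 else "CZYX"
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            layout = meta.get("layout", layout)
            pixel_size = pixel_size if pixel_size is not None else meta.get("pixel_size")
            z_step = z_step if z_step is not None else meta.get("z_step")
    if arr.ndim == 2:
        data = arr[None, None]
    elif arr.ndim == 3:
        if layout == "CYX":
            data = arr[:, None]
        elif layout == "ZYX":
            data = arr[None, :]
        else:
            raise ContractError(f"layout {layout!r} invalid for a 3D TIFF (use 'CYX' or 'ZYX')")
    elif arr.ndim == 4:
        if layout == "ZCYX":
            arr = np.swapaxes(arr, 0, 1)
        elif layout != "CZYX":
            raise ContractError(f"layout {layout!r} invalid for a 4D TIFF (use 'CZYX' or 'ZCYX')")
        data = arr
    else:
        raise ContractError(f"cannot interpret TIFF with {arr.ndim} dimensions")
    return ImageStack(
        data=data,
        roles=dict(role_map),
        pixel_size=pixel_size,
        z_step=z_step,
        source_dtype=arr.dtype,
    )


def write_stack(stack: ImageStack, path: str | Path, extra_meta: dict | None = None) -> Path:
    """Write a stack as a multi-page TIFF plus a JSON sidecar with roles.

    The array is written as (C, Z, Y, X) pages so a read with
    ``layout="CZYX"`` round-trips bit-identically.
    """
    path = Path(path)
    tifffile.imwrite(path, stack.data)
    meta = {
        "layout": "CZYX",
        "roles": stack.roles,
        "pixel_size": stack.pixel_size,
        "z_step": stack.z_step,
    }
    if extra_meta:
        meta.update(extra_meta)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2, default=_jsonable))
    return path


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def max_intensity_projection(stack: ImageStack, channel: int | str) -> Image2D:
    """Per-pixel maximum over z for one channel (MIP)."""
    idx = stack.channel_index(channel)
    return Image2D(stack.data[idx].max(axis=0), provenance="MIP", channel=channel)


def slices_for_window(z_step: float, window_um: float = 1.0) -> int:
    """Number of z-slices spanned by a physical window (e.g. 1 um at 0.2 um step -> 5)."""
    if z_step <= 0:
        raise ContractError("z_step must be positive")
    return max(1, round(window_um / z_step))


def average_projection(
    stack: ImageStack,
    channel: int | str,
    z_range: tuple[int, int] | None = None,
    window_um: float | None = None,
    center: int | None = None,
) -> Image2D:
    """Per-pixel mean over a slice range (or a physical window around ``center``)."""
    idx = stack.channel_index(channel)
    n = stack.n_slices
    if z_range is None:
        if window_um is not None:
            if stack.z_step is None:
                raise ContractError("window_um requires a known z_step")
            half = slices_for_window(stack.z_step, window_um)
            c = n // 2 if center is None else center
            z_range = (max(0, c - half // 2), min(n, c - half // 2 + half))
        else:
            z_range = (0, n)
    lo, hi = z_range
    if not (0 <= lo < hi <= n):
        raise ContractError(f"empty or out-of-range z_range {z_range} for {n} slices")
    return Image2D(stack.data[idx, lo:hi].mean(axis=0), provenance="average", channel=channel)
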