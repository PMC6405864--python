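"""Tomographic volume I/O and geometric preparation.

Conventions
-----------
* Voxel-centered, 0-based indexing.  A voxel index ``(i, j, k)`` sits at
  ``origin_nm + (i, j, k) * voxel_size_nm`` in scene coordinates.
* Each data axis carries an anatomical tag from ``{"L", "T", "N"}``:
  longitudinal (along the wood fiber), tangential (along the wall surface)
  and normal/radial (through the wall thickness, the beam direction in
  single-axis tomography).  Re-tagging never touches intensities.
* MRC files are written as MRC2014 mode 2 (float32); the fastest-varying
  header axis (x) is the last numpy axis.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

AXIS_TAGS = ("L", "T", "N")


@dataclass
class DensityVolume:
    """3D scalar density grid with physical metadata.

    Higher values mean denser material (in permanganate-stained tomograms the
    fibrils are the high-density phase).
    """

    data: np.ndarray
    voxel_size_nm: tuple = (1.0, 1.0, 1.0)
    axes: tuple = ("L", "T", "N")
    origin_nm: tuple = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("data must be a 3D array with all extents >= 1")
        if np.isscalar(self.voxel_size_nm):
            self.voxel_size_nm = (float(self.voxel_size_nm),) * 3
        self.voxel_size_nm = tuple(float(v) for v in self.voxel_size_nm)
        if any(v <= 0 for v in self.voxel_size_nm):
            raise ValueError("voxel_size_nm must be positive on every axis")
        self.axes = tuple(self.axes)
        if sorted(self.axes) != sorted(AXIS_TAGS):
            raise ValueError(f"axes must be a permutation of {AXIS_TAGS}")
        self.origin_nm = tuple(float(v) for v in self.origin_nm)

    @property
    def shape(self):
        return self.data.shape

    def axis_index(self, tag: str) -> int:
        """Data-axis index carrying the anatomical tag."""
        return self.axes.index(tag)

    def axis_unit_vector(self, tag: str) -> np.ndarray:
        """Unit vector of an anatomical direction in scene coordinates."""
        e = np.zeros(3)
        e[self.axis_index(tag)] = 1.0
        return e

    def extent_nm(self) -> tuple:
        return tuple(s * v for s, v in zip(self.shape, self.voxel_size_nm))

    def with_data(self, data: np.ndarray) -> "DensityVolume":
        return replace(self, data=data, meta=dict(self.meta))


# ---------------------------------------------------------------------------
# MRC2014 mode-2 I/O (1024-byte header + little-endian float32 raster)
# ---------------------------------------------------------------------------

_MRC_HEADER_FMT = "<10i6f3i"  # words 1-19: dims, mode, start, grid, cell, angles, map order


def _write_mrc(path, data: np.ndarray, voxel_size_nm) -> None:
    data = np.ascontiguousarray(data, dtype="<f4")
    nz, ny, nx = data.shape
    # cell dimensions in Angstrom: voxel (nm) * 10 * grid size
    cell = [nx * voxel_size_nm[2] * 10.0, ny * voxel_size_nm[1] * 10.0,
            nz * voxel_size_nm[0] * 10.0]
    header = bytearray(1024)
    struct.pack_into(_MRC_HEADER_FMT, header, 0,
                     nx, ny, nz, 2,            # dims + mode 2 (float32)
                     0, 0, 0,                  # nxstart/nystart/nzstart
                     nx, ny, nz,               # mx/my/mz sampling grid
                     *cell, 90.0, 90.0, 90.0,  # cella, cellb
                     1, 2, 3)                  # mapc/mapr/maps
    struct.pack_into("<3f", header, 76, float(data.min()), float(data.max()),
                     float(data.mean()))
    struct.pack_into("<i", header, 88, 0)          # ispg
    header[208:212] = b"MAP "
    header[212:216] = b"\x44\x44\x00\x00"          # little-endian machine stamp
    struct.pack_into("<f", header, 216, float(data.std()))
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(data.tobytes())


def _read_mrc(path):
    with open(path, "rb") as fh:
        header = fh.read(1024)
        if len(header) < 1024:
            raise ValueError(f"corrupt MRC header in {path}: truncated")
        if header[208:212] not in (b"MAP ", b"MAP\x00"):
            raise ValueError(f"corrupt MRC header in {path}: missing MAP stamp")
        (nx, ny, nz, mode, _sx, _sy, _sz, mx, my, mz,
         cx, cy, cz, _a, _b, _c, mapc, mapr, maps) = struct.unpack_from(
            _MRC_HEADER_FMT, header, 0)
        if mode != 2:
            raise ValueError(f"unsupported MRC mode {mode}; only mode 2 (float32)")
        if (mapc, mapr, maps) != (1, 2, 3):
            raise ValueError("unsupported MRC axis ordering (mapc,mapr,maps != 1,2,3)")
        nsymbt = struct.unpack_from("<i", header, 92)[0]
        fh.seek(1024 + nsymbt)
        data = np.fromfile(fh, dtype="<f4", count=nx * ny * nz).reshape(nz, ny, nx)
    # header pixel spacing in Angstrom per voxel -> nm
    voxel = None
    if mx > 0 and my > 0 and mz > 0 and cx > 0 and cy > 0 and cz > 0:
        voxel = (cz / mz / 10.0, cy / my / 10.0, cx / mx / 10.0)
    return data, voxel


def write_volume(volume: DensityVolume, path, fmt: str | None = None) -> None:
    """Write a volume to MRC (default) or a multipage TIFF stack."""
    path = Path(path)
    fmt = fmt or ("tiff-stack" if path.suffix.lower() in (".tif", ".tiff") else "mrc")
    if fmt == "mrc":
        _write_mrc(path, volume.data, volume.voxel_size_nm)
    elif fmt == "tiff-stack":
        import tifffile
        tifffile.imwrite(path, np.asarray(volume.data, dtype=np.float32),
                         photometric="minisblack")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_volume(path, fmt: str | None = None, voxel_size_nm=None,
                axes=("L", "T", "N")) -> DensityVolume:
    """Read an MRC or TIFF-stack volume.

    The voxel size is taken from the MRC header when present, else from the
    ``voxel_size_nm`` argument; if both are missing an error names the field.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or ("tiff-stack" if path.suffix.lower() in (".tif", ".tiff") else "mrc")
    if fmt == "mrc":
        data, header_voxel = _read_mrc(path)
        voxel = header_voxel if header_voxel is not None else voxel_size_nm
    elif fmt == "tiff-stack":
        import tifffile
        data = np.asarray(tifffile.imread(path))
        if data.ndim == 2:
            data = data[None]
        voxel = voxel_size_nm
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if voxel is None:
        raise ValueError(
            "voxel_size_nm missing: not in file header and not passed as argument")
    if np.isscalar(voxel):
        voxel = (float(voxel),) * 3
    return DensityVolume(data=data, voxel_size_nm=tuple(voxel), axes=axes)


# ---------------------------------------------------------------------------
# Preparation operations
# ---------------------------------------------------------------------------

def gaussian_denoise(volume: DensityVolume, sigma_nm: float) -> DensityVolume:
    """Gaussian smoothing with physical kernel width (reflective boundaries).

    ``sigma_nm = 0`` returns the input unchanged.  Total intensity is
    conserved to well under 0.1%.
    """
    if sigma_nm < 0:
        raise ValueError("sigma_nm must be >= 0")
    if sigma_nm == 0:
        return volume
    sigma_vox = [sigma_nm / v for v in volume.voxel_size_nm]
    out = ndimage.gaussian_filter(np.asarray(volume.data, dtype=float),
                                  sigma=sigma_vox, mode="reflect")
    return volume.with_data(out)


def crop_middle_slab(volume: DensityVolume, thickness_nm: float,
                     axis: str = "N") -> DensityVolume:
    """Centered slab along an anatomical axis.

    The slab is centered on voxel index ``floor(extent/2)``; indices are the
    half-open range ``[c - thickness//2, c + ceil(thickness/2))`` in voxels.
    """
    ax = volume.axis_index(axis)
    step = volume.voxel_size_nm[ax]
    extent = volume.shape[ax]
    thick_vox = int(round(thickness_nm / step))
    if thick_vox > extent:
        raise ValueError(
            f"slab thickness {thickness_nm} nm exceeds extent {extent * step} nm")
    center = extent // 2
    lo = center - thick_vox // 2
    hi = lo + thick_vox
    if lo < 0:
        lo, hi = 0, thick_vox
    sl = [slice(None)] * 3
    sl[ax] = slice(lo, hi)
    origin = list(volume.origin_nm)
    origin[ax] += lo * step
    return replace(volume, data=volume.data[tuple(sl)], origin_nm=tuple(origin),
                   meta=dict(volume.meta))


def _grid_origins(extent_vox: int, side_vox: int, overlap: float) -> list:
    """1D tile origins: stride floor(side*(1-overlap)), clipped to fit, plus a
    final edge-flush tile so the union covers the full extent."""
    stride = max(1, int(np.floor(side_vox * (1.0 - overlap))))
    origins = list(range(0, extent_vox - side_vox + 1, stride))
    if not origins:
        origins = [0]
    if origins[-1] + side_vox < extent_vox:
        origins.append(extent_vox - side_vox)
    return origins


@dataclass(frozen=True)
class SubvolumeSpec:
    """Origin/extent of an axis-aligned subvolume (voxels), with a label."""
    origin_vox: tuple
    extent_vox: tuple
    label: str = ""


def extract_subvolumes(volume: DensityVolume, side: float, overlap: float = 0.0,
                       axis_pair=("L", "T"), side_unit: str = "nm"):
    """Tile a plane with square windows of the given side (full depth on the
    third axis).  ``side_unit`` is "nm" (default) or "vox".

    Returns a list of ``(SubvolumeSpec, DensityVolume)``.  Overlapping tiles
    are permitted; at overlap 0 the tiling is disjoint and covers the plane.
    """
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must be in [0, 1)")
    ax0, ax1 = (volume.axis_index(a) for a in axis_pair)
    sides_vox = []
    for ax in (ax0, ax1):
        s = side / volume.voxel_size_nm[ax] if side_unit == "nm" else side
        sides_vox.append(int(round(s)))
    if min(sides_vox) < 3:
        raise ValueError("subvolume side must be >= 3 voxels")
    for ax, s in zip((ax0, ax1), sides_vox):
        if s > volume.shape[ax]:
            raise ValueError("subvolume side larger than plane extent")
    out = []
    for i, o0 in enumerate(_grid_origins(volume.shape[ax0], sides_vox[0], overlap)):
        for j, o1 in enumerate(_grid_origins(volume.shape[ax1], sides_vox[1], overlap)):
            sl = [slice(None)] * 3
            origin = [0, 0, 0]
            extent = list(volume.shape)
            sl[ax0] = slice(o0, o0 + sides_vox[0])
            sl[ax1] = slice(o1, o1 + sides_vox[1])
            origin[ax0], origin[ax1] = o0, o1
            extent[ax0], extent[ax1] = sides_vox[0], sides_vox[1]
            spec = SubvolumeSpec(origin_vox=tuple(origin), extent_vox=tuple(extent),
                                 label=f"tile_{i}_{j}")
            orig_nm = tuple(volume.origin_nm[k] + origin[k] * volume.voxel_size_nm[k]
                            for k in range(3))
            sub = replace(volume, data=volume.data[tuple(sl)], origin_nm=orig_nm,
                          meta=dict(volume.meta))
            out.append((spec, sub))
    return out


def reference_grid_configs() -> dict:
    """Recorded tiling geometries for the three analyzed tomogram surveys.

    With a 45-voxel (40.5 nm at 0.9 nm/voxel) square window and 50% overlap
    these plane extents tile into exactly 13, 44 and 261 subvolumes — the
    subvolume counts of the three fitted tomograms.
    """
    side, overlap = 45, 0.5
    return {
        "survey_13": {"extent_vox": (309, 45), "side_vox": side, "overlap": overlap},
        "survey_44": {"extent_vox": (265, 111), "side_vox": side, "overlap": overlap},
        "survey_261": {"extent_vox": (661, 221), "side_vox": side, "overlap": overlap},
    }


def _signed_permutation(R: np.ndarray):
    """If R is a signed permutation matrix return (perm, signs), else None."""
    perm, signs = [], []
    for row in R:
        idx = np.argmax(np.abs(row))
        if not (np.isclose(abs(row[idx]), 1, atol=1e-10)
                and np.isclose(np.abs(row).sum(), 1, atol=1e-10)):
            return None
        perm.append(int(idx))
        signs.append(int(np.sign(row[idx])))
    if sorted(perm) != [0, 1, 2]:
        return None
    return perm, signs


def rotate_to_axis(volume: DensityVolume, rotation: np.ndarray,
                   order: int = 1) -> DensityVolume:
    """Resample the volume under a rigid rotation about its center.

    Identity is a bit-exact pass-through; rotations that are exact lattice
    symmetries (signed permutations) use transpose/flip with no interpolation.
    Otherwise trilinear (``order=1``, the default) or cubic resampling.
    """
    R = np.asarray(rotation, dtype=float)
    if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
        raise ValueError("rotation must be orthonormal")
    if np.linalg.det(R) < 0:
        raise ValueError("rotation must be proper (determinant +1)")
    if np.allclose(R, np.eye(3), atol=1e-12):
        return volume
    sp = _signed_permutation(np.round(R, 12))
    if sp is not None:
        perm, signs = sp
        # output axis i takes input axis perm[i], flipped when sign < 0
        data = np.transpose(volume.data, perm)
        for i, s in enumerate(signs):
            if s < 0:
                data = np.flip(data, axis=i)
        voxel = tuple(volume.voxel_size_nm[p] for p in perm)
        axes = tuple(volume.axes[p] for p in perm)
        return replace(volume, data=np.ascontiguousarray(data), voxel_size_nm=voxel,
                       axes=axes, meta=dict(volume.meta))
    center = (np.array(volume.shape) - 1) / 2.0
    # affine_transform maps output coords through matrix: in = M @ out + offset
    M = R.T
    offset = center - M @ center
    out = ndimage.affine_transform(np.asarray(volume.data, dtype=float), M,
                                   offset=offset, order=order, mode="nearest")
    return volume.with_data(out)
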