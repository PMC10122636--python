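"""Voxel image container and MetaImage / NRRD file I/O.

Images are stored with array index order (i, j, k) mapping to spatial axes
(1, 2, 3); voxel (0, 0, 0) has its lower corner at ``origin`` and spacing is
isotropic.  Only uncompressed little-endian files are produced, which keeps
the formats readable by ITK-based tools without any binary dependencies.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelImage", "read_image", "write_image"]

_MHD_TYPE = {
    "MET_UCHAR": np.uint8,
    "MET_CHAR": np.int8,
    "MET_USHORT": np.uint16,
    "MET_SHORT": np.int16,
    "MET_UINT": np.uint32,
    "MET_INT": np.int32,
    "MET_FLOAT": np.float32,
    "MET_DOUBLE": np.float64,
}
_MHD_TYPE_INV = {np.dtype(v): k for k, v in _MHD_TYPE.items()}

_NRRD_TYPE = {
    "uchar": np.uint8,
    "uint8": np.uint8,
    "short": np.int16,
    "ushort": np.uint16,
    "int": np.int32,
    "uint": np.uint32,
    "float": np.float32,
    "double": np.float64,
}


@dataclass
class VoxelImage:
    """3D scalar voxel grid with isotropic spacing.

    Parameters
    ----------
    values : ndarray, shape (n1, n2, n3)
        Voxel values; {0, 1} for segmented bone, [0, 1] for density fields.
    spacing : float
        Voxel edge length in mm.
    origin : ndarray, shape (3,)
        Position of the (0, 0, 0) voxel corner in mm.
    """

    values: np.ndarray
    spacing: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("image must be a 3D grid with all dimensions >= 1")
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def is_binary(self) -> bool:
        return bool(np.isin(self.values, (0, 1)).all())

    def bone_volume_fraction(self) -> float:
        """BV/TV: mean voxel value over the whole grid."""
        return float(np.mean(self.values))

    def physical_extent(self) -> np.ndarray:
        return np.array(self.shape, dtype=float) * self.spacing


def write_image(image: VoxelImage, path: str | os.PathLike) -> None:
    """Write an image as MetaImage (``.mhd`` + ``.raw``) or NRRD (``.nrrd``)."""
    path = os.fspath(path)
    if path.endswith(".mhd"):
        _write_mhd(image, path)
    elif path.endswith(".nrrd"):
        _write_nrrd(image, path)
    else:
        raise ValueError(f"unsupported image format: {path!r} (use .mhd or .nrrd)")


def read_image(path: str | os.PathLike) -> VoxelImage:
    """Read a MetaImage (``.mhd``) or NRRD (``.nrrd``) file."""
    path = os.fspath(path)
    if path.endswith(".mhd"):
        return _read_mhd(path)
    if path.endswith(".nrrd"):
        return _read_nrrd(path)
    raise ValueError(f"unsupported image format: {path!r} (use .mhd or .nrrd)")


def _cast_for_io(values: np.ndarray) -> np.ndarray:
    if np.isin(values, (0, 1)).all():
        return values.astype(np.uint8)
    return np.asarray(values, dtype=np.float64)


def _write_mhd(image: VoxelImage, path: str) -> None:
    data = _cast_for_io(image.values)
    raw_path = path[:-4] + ".raw"
    header = [
        "ObjectType = Image",
        "NDims = 3",
        "BinaryData = True",
        "BinaryDataByteOrderMSB = False",
        "CompressedData = False",
        "TransformMatrix = 1 0 0 0 1 0 0 0 1",
        f"Offset = {image.origin[0]:g} {image.origin[1]:g} {image.origin[2]:g}",
        "CenterOfRotation = 0 0 0",
        f"ElementSpacing = {image.spacing:g} {image.spacing:g} {image.spacing:g}",
        f"DimSize = {data.shape[0]} {data.shape[1]} {data.shape[2]}",
        f"ElementType = {_MHD_TYPE_INV[data.dtype]}",
        f"ElementDataFile = {os.path.basename(raw_path)}",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
    # MetaImage raw layout is x-fastest: write in Fortran order so that
    # axis 0 of the array is the fastest-varying (x) axis on disk.
    with open(raw_path, "wb") as fh:
        fh.write(np.asfortranarray(data).tobytes(order="F"))


def _read_mhd(path: str) -> VoxelImage:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if "=" in line:
                key, _, value = line.partition("=")
                meta[key.strip()] = value.strip()
    shape = tuple(int(v) for v in meta["DimSize"].split())
    dtype = _MHD_TYPE[meta["ElementType"]]
    spacing = float(meta["ElementSpacing"].split()[0])
    origin = np.array([float(v) for v in meta.get("Offset", "0 0 0").split()])
    raw_path = os.path.join(os.path.dirname(path), meta["ElementDataFile"])
    data = np.fromfile(raw_path, dtype=dtype)
    values = data.reshape(shape, order="F")
    return VoxelImage(values=values, spacing=spacing, origin=origin)


def _write_nrrd(image: VoxelImage, path: str) -> None:
    data = _cast_for_io(image.values)
    type_name = {np.dtype(np.uint8): "uchar", np.dtype(np.float64): "double"}[data.dtype]
    sp = image.spacing
    header = [
        "NRRD0004",
        f"type: {type_name}",
        "dimension: 3",
        "space: left-posterior-superior",
        f"sizes: {data.shape[0]} {data.shape[1]} {data.shape[2]}",
        f"space directions: ({sp:g},0,0) (0,{sp:g},0) (0,0,{sp:g})",
        "kinds: domain domain domain",
        "endian: little",
        "encoding: raw",
        f"space origin: ({image.origin[0]:g},{image.origin[1]:g},{image.origin[2]:g})",
    ]
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n\n").encode())
        fh.write(np.asfortranarray(data).tobytes(order="F"))


def _read_nrrd(path: str) -> VoxelImage:
    with open(path, "rb") as fh:
        raw = fh.read()
    head, _, body = raw.partition(b"\n\n")
    meta: dict[str, str] = {}
    for line in head.decode().splitlines()[1:]:
        if ":" in line:
            key, _, value = line.partition(":")
            meta[key.strip()] = value.strip()
    if meta.get("encoding", "raw") != "raw":
        raise ValueError("only raw-encoded NRRD is supported")
    shape = tuple(int(v) for v in meta["sizes"].split())
    dtype = _NRRD_TYPE[meta["type"]]
    spacing = 1.0
    if "space directions" in meta:
        first = meta["space directions"].split(")")[0].strip("( ")
        spacing = max(abs(float(v)) for v in first.split(","))
    origin = np.zeros(3)
    if "space origin" in meta:
        origin = np.array(
            [float(v) for v in meta["space origin"].strip("()").split(",")]
        )
    values = np.frombuffer(body, dtype=dtype, count=int(np.prod(shape)))
    return VoxelImage(
        values=values.reshape(shape, order="F").copy(), spacing=spacing, origin=origin
    )
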