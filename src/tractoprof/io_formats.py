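"""Readers/writers for tractograms and volumes, and the spatial frame contract.

All geometry in this package lives in world-space RAS millimetres.  A
:class:`VolumeGrid` (integer shape + invertible 4x4 voxel-to-world affine) is
the shared frame of every volume and ROI; voxel indices are 0-based and a
world point belongs to the voxel obtained by rounding its continuous voxel
coordinate to the nearest integer (voxel-centre convention).

Tractograms use the MRtrix ``.tck`` container: a text header opened by the
``mrtrix tracks`` magic line, ``key: value`` fields (``datatype``, ``count``,
``file: . <offset>``) terminated by ``END``, then a flat stream of 32-bit
float coordinate triples in which ``(NaN, NaN, NaN)`` closes a streamline and
``(Inf, Inf, Inf)`` closes the file.  We write little-endian only and accept
either byte order on read.

NIfTI volumes go through nibabel; the grid affine is taken from the sform
when its code is positive, else the qform, else a scaled identity built from
the header zooms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np

from .errors import (
    DimensionalityError,
    FormatError,
    TruncationError,
    UnsupportedDialectError,
    ValidationError,
)

__all__ = [
    "VolumeGrid",
    "ScalarMap",
    "BinaryROI",
    "Tractogram",
    "grids_equal",
    "world_to_voxel",
    "voxel_to_world",
    "read_tck",
    "write_tck",
    "read_volume",
    "read_volume_4d",
    "read_roi",
    "write_volume",
    "read_bvals_bvecs",
]

TCK_MAGIC = "mrtrix tracks"


# ---------------------------------------------------------------------------
# Spatial frame
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VolumeGrid:
    """A 3D voxel lattice embedded in world space.

    Parameters
    ----------
    shape
        Number of voxels along each axis; all components >= 1.
    affine
        4x4 matrix mapping homogeneous 0-based voxel indices to world RAS
        millimetres.  Must be invertible with bottom row (0, 0, 0, 1).
    """

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValidationError(f"grid shape must be 3 positive ints, got {self.shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValidationError("affine must be 4x4")
        if not np.allclose(affine[3], [0.0, 0.0, 0.0, 1.0]):
            raise ValidationError("affine bottom row must be (0, 0, 0, 1)")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValidationError("affine is singular")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)

    @property
    def voxel_size(self) -> np.ndarray:
        """Physical voxel dimensions in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def inverse_affine(self) -> np.ndarray:
        return np.linalg.inv(self.affine)

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        return world_to_voxel(self, points)

    def voxel_to_world(self, indices: np.ndarray) -> np.ndarray:
        return voxel_to_world(self, indices)

    def contains_index(self, idx: np.ndarray) -> np.ndarray:
        """Boolean test whether integer indices fall inside the lattice."""
        idx = np.atleast_2d(np.asarray(idx))
        inside = np.ones(len(idx), dtype=bool)
        for axis in range(3):
            inside &= (idx[:, axis] >= 0) & (idx[:, axis] < self.shape[axis])
        return inside


def grids_equal(a: VolumeGrid, b: VolumeGrid, atol: float = 1e-5) -> bool:
    """True when two grids share shape and affine (within ``atol`` mm)."""
    return a.shape == b.shape and np.allclose(a.affine, b.affine, atol=atol)


def world_to_voxel(grid: VolumeGrid, points: np.ndarray) -> np.ndarray:
    """Map world-mm points to continuous 0-based voxel coordinates."""
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    vox = pts @ grid.inverse_affine[:3, :3].T + grid.inverse_affine[:3, 3]
    return vox[0] if single else vox


def voxel_to_world(grid: VolumeGrid, indices: np.ndarray) -> np.ndarray:
    """Map continuous voxel coordinates to world mm."""
    idx = np.asarray(indices, dtype=float)
    single = idx.ndim == 1
    idx = np.atleast_2d(idx)
    pts = idx @ grid.affine[:3, :3].T + grid.affine[:3, 3]
    return pts[0] if single else pts


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------

@dataclass
class ScalarMap:
    """A scalar value per voxel on a :class:`VolumeGrid`.

    FA-labelled maps are expected to carry finite values in [0, 1]; NaN marks
    voxels excluded from fitting or outside a mask.
    """

    grid: VolumeGrid
    values: np.ndarray
    metric_name: str = "scalar"
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValidationError(
                f"value array shape {self.values.shape} != grid shape {self.grid.shape}"
            )


@dataclass
class BinaryROI:
    """A named boolean region of interest on a :class:`VolumeGrid`."""

    grid: VolumeGrid
    mask: np.ndarray
    name: str = "roi"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.shape != self.grid.shape:
            raise ValidationError(
                f"mask shape {self.mask.shape} != grid shape {self.grid.shape}"
            )

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


# ---------------------------------------------------------------------------
# Streamlines / tractograms
# ---------------------------------------------------------------------------

def as_streamline(points: np.ndarray) -> np.ndarray:
    """Validate and coerce an (n, 3) world-mm point array to a streamline."""
    pts = np.asarray(points, dtype=np.float32)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
        raise ValidationError("streamline needs >= 2 points of 3 coordinates")
    if not np.all(np.isfinite(pts)):
        raise ValidationError("streamline coordinates must be finite")
    return pts


@dataclass
class Tractogram:
    """An ordered collection of streamlines in world-mm space.

    May be empty — whole-brain tractograms are filtered down to tracts, and
    a selection can legitimately return nothing.
    """

    streamlines: list[np.ndarray] = field(default_factory=list)
    space: str = "world-mm"

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)

    def __getitem__(self, i):
        return self.streamlines[i]


# ---------------------------------------------------------------------------
# tck reader/writer
# ---------------------------------------------------------------------------

_DELIM = np.array([np.nan, np.nan, np.nan], dtype=np.float32)
_EOF = np.array([np.inf, np.inf, np.inf], dtype=np.float32)


def _parse_tck_header(raw: bytes) -> tuple[dict, int]:
    """Parse the text header; return (fields, data offset from file start)."""
    try:
        end = raw.index(b"END")
    except ValueError as exc:
        raise FormatError("tck header has no END marker") from exc
    text = raw[:end].decode("ascii", errors="replace")
    lines = text.splitlines()
    if not lines or lines[0].strip() != TCK_MAGIC:
        raise FormatError("missing 'mrtrix tracks' magic line")
    fields: dict[str, str] = {}
    for line in lines[1:]:
        if not line.strip():
            continue
        if ":" not in line:
            raise FormatError(f"malformed header line: {line!r}")
        key, _, value = line.partition(":")
        fields[key.strip()] = value.strip()
    if "file" not in fields:
        raise FormatError("tck header lacks the 'file' field")
    file_field = fields["file"].split()
    if len(file_field) != 2 or file_field[0] != ".":
        raise UnsupportedDialectError("only single-file tck ('file: . <offset>') supported")
    return fields, int(file_field[1])


def read_tck(path: str | Path) -> Tractogram:
    """Read an MRtrix ``.tck`` tractogram.

    Raises
    ------
    FormatError
        Missing magic line, malformed header, or count mismatch.
    UnsupportedDialectError
        A datatype other than 32-bit float.
    TruncationError
        Binary section ends before the Inf terminator triple.
    """
    raw = Path(path).read_bytes()
    fields, offset = _parse_tck_header(raw)
    datatype = fields.get("datatype", "Float32LE")
    if datatype == "Float32LE":
        dtype = np.dtype("<f4")
    elif datatype == "Float32BE":
        dtype = np.dtype(">f4")
    else:
        raise UnsupportedDialectError(f"unsupported tck datatype {datatype!r}")
    body = raw[offset:]
    n_floats = len(body) // 4
    if n_floats % 3 != 0:
        raise TruncationError("tck binary section is not a whole number of triples")
    triples = np.frombuffer(body[: n_floats * 4], dtype=dtype).reshape(-1, 3)

    streamlines: list[np.ndarray] = []
    current: list[np.ndarray] = []
    terminated = False
    for triple in triples:
        if np.all(np.isinf(triple)):
            terminated = True
            break
        if np.all(np.isnan(triple)):
            if current:
                streamlines.append(np.array(current, dtype=np.float32))
                current = []
            continue
        current.append(np.asarray(triple, dtype=np.float32))
    if not terminated:
        raise TruncationError("tck binary section lacks the Inf terminator")
    if current:  # tolerated on read: last streamline without a NaN delimiter
        streamlines.append(np.array(current, dtype=np.float32))

    if "count" in fields and int(fields["count"]) != len(streamlines):
        raise FormatError(
            f"header count {fields['count']} != streamlines read {len(streamlines)}"
        )
    return Tractogram(streamlines=streamlines)


def write_tck(tractogram: Tractogram | Iterable[np.ndarray], path: str | Path) -> None:
    """Write a tractogram as little-endian Float32 ``.tck``.

    Streamlines are stored back-to-back, each closed by a NaN triple, with a
    final Inf triple terminating the file; a round trip through
    :func:`read_tck` is bitwise lossless at float32 precision.
    """
    streamlines = list(tractogram)
    for s in streamlines:
        if not np.all(np.isfinite(np.asarray(s, dtype=np.float32))):
            raise ValidationError("non-finite coordinates (NaN/Inf are reserved delimiters)")

    chunks: list[np.ndarray] = []
    for s in streamlines:
        chunks.append(np.asarray(s, dtype="<f4").reshape(-1, 3))
        chunks.append(_DELIM.reshape(1, 3).astype("<f4"))
    chunks.append(_EOF.reshape(1, 3).astype("<f4"))
    body = np.concatenate(chunks).tobytes()

    # The offset appears inside the header, so fix it by iteration.
    def header(offset: int) -> bytes:
        return (
            f"{TCK_MAGIC}\n"
            f"datatype: Float32LE\n"
            f"count: {len(streamlines)}\n"
            f"file: . {offset}\n"
            "END\n"
        ).encode("ascii")

    offset = len(header(0))
    while len(header(offset)) != offset:
        offset = len(header(offset))
    Path(path).write_bytes(header(offset) + body)


# ---------------------------------------------------------------------------
# NIfTI volumes
# ---------------------------------------------------------------------------

def _grid_from_nifti(img) -> VolumeGrid:
    hdr = img.header
    sform, scode = hdr.get_sform(coded=True)
    qform, qcode = hdr.get_qform(coded=True)
    if scode > 0:
        affine = sform
    elif qcode > 0:
        affine = qform
    else:
        zooms = np.asarray(hdr.get_zooms()[:3], dtype=float)
        if np.any(zooms <= 0):
            raise FormatError("NIfTI file has neither sform/qform nor usable zooms")
        affine = np.diag(list(zooms) + [1.0])
    return VolumeGrid(shape=tuple(int(s) for s in img.shape[:3]), affine=affine)


def read_volume(path: str | Path, metric_name: str | None = None) -> ScalarMap:
    """Read a 3D NIfTI volume as a :class:`ScalarMap`."""
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise DimensionalityError(f"expected 3D volume, got shape {img.shape}")
    grid = _grid_from_nifti(img)
    values = np.asarray(img.get_fdata(), dtype=float)
    name = metric_name if metric_name is not None else Path(path).name.split(".")[0]
    return ScalarMap(grid=grid, values=values, metric_name=name)


def read_volume_4d(path: str | Path) -> tuple[np.ndarray, VolumeGrid]:
    """Read a 4D NIfTI stack (e.g. DWI); returns (data, spatial grid)."""
    img = nib.load(str(path))
    if len(img.shape) != 4:
        raise DimensionalityError(f"expected 4D volume, got shape {img.shape}")
    return np.asarray(img.get_fdata(), dtype=float), _grid_from_nifti(img)


def read_roi(path: str | Path, name: str | None = None) -> BinaryROI:
    """Read a NIfTI mask as a :class:`BinaryROI` (any nonzero voxel is True)."""
    vol = read_volume(path)
    roi_name = name if name is not None else Path(path).name.split(".")[0]
    return BinaryROI(grid=vol.grid, mask=vol.values != 0, name=roi_name)


def write_volume(volume: ScalarMap | BinaryROI, path: str | Path) -> None:
    """Write a scalar map (float32) or ROI (uint8) as NIfTI-1."""
    if isinstance(volume, BinaryROI):
        data = volume.mask.astype(np.uint8)
    else:
        data = volume.values.astype(np.float32)
    img = nib.Nifti1Image(data, volume.grid.affine)
    img.header.set_sform(volume.grid.affine, code=1)
    img.header.set_qform(volume.grid.affine, code=1)
    nib.save(img, str(path))


def write_volume_4d(data: np.ndarray, grid: VolumeGrid, path: str | Path) -> None:
    """Write a 4D stack sharing a spatial grid as NIfTI-1."""
    data = np.asarray(data)
    if data.ndim != 4:
        raise DimensionalityError(f"expected 4D data, got shape {data.shape}")
    img = nib.Nifti1Image(data.astype(np.float32), grid.affine)
    img.header.set_sform(grid.affine, code=1)
    img.header.set_qform(grid.affine, code=1)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# FSL gradient tables
# ---------------------------------------------------------------------------

def read_bvals_bvecs(bval_path: str | Path, bvec_path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read FSL-format b-value (1xN) and b-vector (3xN) text tables.

    Returns b-values as shape (N,) and b-vectors as shape (N, 3); a transposed
    (Nx3) b-vector file is accepted.
    """
    bvals = np.loadtxt(str(bval_path)).ravel()
    bvecs = np.loadtxt(str(bvec_path))
    if bvecs.ndim != 2:
        raise FormatError("bvec table must be 2D")
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape[1] != 3:
        raise FormatError(f"bvec table must be 3xN or Nx3, got {bvecs.shape}")
    if len(bvals) != len(bvecs):
        raise FormatError(f"{len(bvals)} b-values but {len(bvecs)} b-vectors")
    return bvals, bvecs


def write_bvals_bvecs(
    bvals: Sequence[float], bvecs: np.ndarray, bval_path: str | Path, bvec_path: str | Path
) -> None:
    """Write FSL-format gradient tables (bvals 1xN, bvecs 3xN)."""
    bvals = np.asarray(bvals, dtype=float).ravel()
    bvecs = np.asarray(bvecs, dtype=float)
    np.savetxt(str(bval_path), bvals[None, :], fmt="%.6g")
    np.savetxt(str(bvec_path), bvecs.T, fmt="%.8f")
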