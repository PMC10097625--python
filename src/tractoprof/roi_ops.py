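"""ROI validation, dilation and combination.

ROIs arrive from an anatomical pipeline already resampled into the subject's
native diffusion frame; nothing here resamples, and a grid mismatch is an
error rather than a silent interpolation (a mismatch usually means a
registration bug upstream).

Dilation uses a full 3x3x3 (26-connected) structuring element per iteration,
the common choice for making gray-matter ROIs reach into adjacent white
matter so that streamlines terminate inside them.

Combination defaults to voxelwise union — the operation that "generates
bigger ROIs from existing ones" — with an intersection mode available.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import EmptyROIError, FrameMismatchError, ValidationError
from .io_formats import BinaryROI, VolumeGrid, grids_equal

__all__ = ["validate_roi", "dilate_roi", "combine_rois"]

_CUBE = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity


def validate_roi(roi: BinaryROI, grid: VolumeGrid) -> BinaryROI:
    """Check an ROI is nonempty and lives on ``grid``; returns it unchanged.

    Raises :class:`EmptyROIError` for an all-false mask and
    :class:`FrameMismatchError` when shape or affine (within 1e-5) differ.
    """
    if not grids_equal(roi.grid, grid):
        raise FrameMismatchError(
            f"ROI {roi.name!r} grid does not match the reference grid (no silent resampling)"
        )
    if roi.n_voxels == 0:
        raise EmptyROIError(f"ROI {roi.name!r} has no voxels")
    return roi


def dilate_roi(roi: BinaryROI, iterations: int) -> BinaryROI:
    """Morphologically dilate ``iterations`` times with the 3x3x3 element.

    ``iterations=0`` is the identity; the result is always a superset of the
    input and dilations compose additively.
    """
    iterations = int(iterations)
    if iterations < 0:
        raise ValidationError(f"dilation iterations must be >= 0, got {iterations}")
    if iterations == 0:
        mask = roi.mask.copy()
    else:
        mask = ndimage.binary_dilation(roi.mask, structure=_CUBE, iterations=iterations)
    return BinaryROI(grid=roi.grid, mask=mask, name=roi.name)


def combine_rois(rois: list[BinaryROI], mode: str = "union") -> BinaryROI:
    """Combine >= 2 ROIs on identical grids by union (default) or intersection.

    The result's name concatenates the inputs' names with ``+`` (union) or
    ``&`` (intersection).
    """
    if len(rois) < 2:
        raise ValidationError("combine_rois needs at least 2 ROIs")
    if mode not in ("union", "intersect"):
        raise ValidationError(f"mode must be 'union' or 'intersect', got {mode!r}")
    ref = rois[0]
    for other in rois[1:]:
        if not grids_equal(ref.grid, other.grid):
            raise FrameMismatchError(
                f"ROIs {ref.name!r} and {other.name!r} are on different grids"
            )
    stack = np.stack([r.mask for r in rois])
    if mode == "union":
        mask = stack.any(axis=0)
        name = "+".join(r.name for r in rois)
    else:
        mask = stack.all(axis=0)
        name = "&".join(r.name for r in rois)
    return BinaryROI(grid=ref.grid, mask=mask, name=name)
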