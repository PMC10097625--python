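"""Seeded ground-truth phantoms: bundles, scalar fields, ROIs, DWI signals.

The phantom emulates the geometry the pipeline sees in practice — a dispersed
streamline bundle around a smooth centerline inside a small native-space
grid — with every quantity known analytically, so selection, cleaning,
profiling and tensor fitting can all be verified without any acquired data.

Defaults describe the reference phantom used throughout the test suite and
the reproducibility analysis: a circular-arc centerline (radius 30 mm,
~80 degrees of arc) inside a 40x40x40 voxel grid at 1 mm isotropic, a bundle
of 200 streamlines with 1 mm smooth Gaussian jitter (correlation length
10 mm along arc), and a two-shell DWI scheme (1 b=0 plus two shells at
b = 1000 and 2000 s/mm^2).

Streamline jitter is correlated along arc: white Gaussian noise per node is
smoothed with a Gaussian kernel (circular boundary) and rescaled so the
per-node offset SD equals ``jitter_sd`` exactly in expectation, keeping the
offsets streamline-like rather than jagged.  Each streamline is reversed
with probability 1/2 to exercise orientation alignment downstream.  All
generators are deterministic functions of their seed.

Noise on DWI signals is additive Gaussian (no Rician floor).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from typing import Callable

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .bundle_ops import Tract
from .dti_metrics import DWIScheme, TensorField
from .errors import ValidationError
from .io_formats import BinaryROI, ScalarMap, VolumeGrid

__all__ = [
    "PhantomSpec",
    "default_grid",
    "make_centerline",
    "make_bundle",
    "make_scalar_field",
    "make_roi_pair",
    "make_dwi_signals",
    "uniform_tensor_field",
    "fibonacci_directions",
    "two_shell_scheme",
]


def default_grid(n: int = 40, voxel_mm: float = 1.0) -> VolumeGrid:
    """The phantom's native frame: an n^3 grid at ``voxel_mm`` isotropic."""
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    return VolumeGrid(shape=(n, n, n), affine=affine)


@dataclass(frozen=True)
class PhantomSpec:
    """Everything needed to regenerate a bundle phantom bit-for-bit.

    ``kind`` selects the centerline family: ``line`` (straight segment),
    ``arc`` (circular arc of ``radius`` mm spanning ``angular_extent`` rad)
    or ``helix`` (arc plus a linear axial drift of ``helix_pitch`` mm per
    turn).
    """

    kind: str = "arc"
    n_streamlines: int = 200
    jitter_sd: float = 1.0
    jitter_smoothness: float = 10.0  # correlation length along arc, mm
    seed: int = 0
    n_points: int = 61
    radius: float = 30.0
    angular_extent: float = 1.4  # radians (~80 degrees)
    helix_pitch: float = 10.0
    line_start: tuple[float, float, float] = (5.0, 20.0, 20.0)
    line_end: tuple[float, float, float] = (35.0, 20.0, 20.0)
    grid: VolumeGrid = dataclass_field(default_factory=default_grid)

    def __post_init__(self) -> None:
        if self.kind not in ("line", "arc", "helix"):
            raise ValidationError(f"unknown centerline kind {self.kind!r}")
        if self.n_streamlines < 1:
            raise ValidationError("n_streamlines must be >= 1")
        if self.jitter_sd < 0:
            raise ValidationError("jitter_sd must be >= 0")


def make_centerline(spec: PhantomSpec, n_points: int | None = None) -> np.ndarray:
    """Ground-truth centerline polyline, shape (n_points, 3), world mm."""
    n = n_points if n_points is not None else spec.n_points
    grid_center = np.asarray(spec.grid.shape, dtype=float) * spec.grid.voxel_size / 2.0
    if spec.kind == "line":
        t = np.linspace(0.0, 1.0, n)[:, None]
        start = np.asarray(spec.line_start, dtype=float)
        end = np.asarray(spec.line_end, dtype=float)
        return start + t * (end - start)
    theta = np.linspace(-spec.angular_extent / 2.0, spec.angular_extent / 2.0, n)
    # circle centre sits `radius` below the grid centre so the arc apex
    # passes through the grid centre and bows gently in +y
    arc_center = grid_center - np.array([0.0, spec.radius, 0.0])
    x = arc_center[0] + spec.radius * np.sin(theta)
    y = arc_center[1] + spec.radius * np.cos(theta)
    z = np.full(n, grid_center[2])
    if spec.kind == "helix":
        z = grid_center[2] + spec.helix_pitch * theta / (2.0 * np.pi)
    return np.column_stack([x, y, z])


def _arc_coordinates(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _smooth_unit_noise(rng: np.random.Generator, n: int, sigma_samples: float) -> np.ndarray:
    """White noise smoothed along axis 0 (circular), rescaled to unit SD."""
    white = rng.standard_normal((n, 3))
    if sigma_samples <= 0:
        return white
    smooth = ndimage.gaussian_filter1d(white, sigma_samples, axis=0, mode="wrap")
    delta = np.zeros(n)
    delta[n // 2] = 1.0
    kernel = ndimage.gaussian_filter1d(delta, sigma_samples, mode="wrap")
    return smooth / np.sqrt(np.sum(kernel**2))


def make_bundle(spec: PhantomSpec) -> tuple[Tract, np.ndarray]:
    """Generate a jittered bundle around the spec's centerline.

    Returns ``(tract, centerline)``.  Offsets are zero-mean smooth Gaussian
    displacements with per-node SD ``jitter_sd``; each streamline is
    independently reversed with probability 1/2.
    """
    rng = np.random.default_rng(spec.seed)
    centerline = make_centerline(spec)
    arcs = _arc_coordinates(centerline)
    ds = float(np.mean(np.diff(arcs)))
    sigma_samples = spec.jitter_smoothness / ds if ds > 0 else 0.0

    streamlines: list[np.ndarray] = []
    for _ in range(spec.n_streamlines):
        offsets = spec.jitter_sd * _smooth_unit_noise(rng, spec.n_points, sigma_samples)
        pts = centerline + offsets
        if rng.random() < 0.5:
            pts = pts[::-1]
        streamlines.append(pts.astype(np.float32))
    tract = Tract(
        name="phantom",
        streamlines=streamlines,
        params={
            "kind": spec.kind,
            "n_streamlines": spec.n_streamlines,
            "jitter_sd": spec.jitter_sd,
            "jitter_smoothness": spec.jitter_smoothness,
            "seed": spec.seed,
        },
    )
    return tract, centerline


def make_scalar_field(
    grid: VolumeGrid,
    f: Callable[[np.ndarray], np.ndarray],
    centerline: np.ndarray,
    background: float = 0.0,
    tube_radius: float = 5.0,
    metric_name: str = "FA",
) -> ScalarMap:
    """Scalar map equal to ``f(arc position of nearest centerline point)``
    inside a tube of ``tube_radius`` mm around the centerline, ``background``
    outside."""
    fine = _densify_polyline(centerline, 0.25)
    arcs = _arc_coordinates(fine)
    tree = cKDTree(fine)
    idx = np.indices(grid.shape).reshape(3, -1).T
    centers = grid.voxel_to_world(idx)
    dist, nearest = tree.query(centers)
    values = np.full(len(centers), float(background))
    inside = dist <= tube_radius
    values[inside] = np.asarray(f(arcs[nearest[inside]]), dtype=float)
    return ScalarMap(grid=grid, values=values.reshape(grid.shape), metric_name=metric_name)


def _densify_polyline(points: np.ndarray, step: float) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    out = [pts[:1]]
    for i in range(len(pts) - 1):
        seg = pts[i + 1] - pts[i]
        n = max(int(np.ceil(np.linalg.norm(seg) / step)), 1)
        t = np.arange(1, n + 1) / n
        out.append(pts[i] + t[:, None] * seg)
    return np.concatenate(out)


def make_roi_pair(
    centerline: np.ndarray,
    arc_positions: tuple[float, float],
    radius: float,
    grid: VolumeGrid,
    names: tuple[str, str] = ("roi1", "roi2"),
) -> tuple[BinaryROI, BinaryROI]:
    """Two spherical ROIs centred on the centerline at the given arc positions."""
    arcs = _arc_coordinates(centerline)
    if not all(0.0 <= a <= arcs[-1] for a in arc_positions):
        raise ValidationError(
            f"arc positions {arc_positions} outside centerline span [0, {arcs[-1]:.1f}]"
        )
    idx = np.indices(grid.shape).reshape(3, -1).T
    centers = grid.voxel_to_world(idx)
    rois = []
    for arc, name in zip(arc_positions, names):
        point = np.column_stack(
            [np.interp(arc, arcs, centerline[:, k]) for k in range(3)]
        )[0]
        mask = (np.linalg.norm(centers - point, axis=1) <= radius).reshape(grid.shape)
        rois.append(BinaryROI(grid=grid, mask=mask, name=name))
    return rois[0], rois[1]


# ---------------------------------------------------------------------------
# DWI simulation
# ---------------------------------------------------------------------------

def fibonacci_directions(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors on the sphere (deterministic)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    golden = np.pi * (1 + np.sqrt(5))
    theta = golden * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def two_shell_scheme(n_b0: int = 1, n_per_shell: int = 10) -> DWIScheme:
    """A b = 0 / 1000 / 2000 s/mm^2 two-shell acquisition scheme."""
    dirs = fibonacci_directions(n_per_shell)
    bvals = np.concatenate(
        [np.zeros(n_b0), np.full(n_per_shell, 1000.0), np.full(n_per_shell, 2000.0)]
    )
    bvecs = np.concatenate([np.zeros((n_b0, 3)), dirs, dirs])
    return DWIScheme(bvals, bvecs)


def uniform_tensor_field(grid: VolumeGrid, tensor: np.ndarray, s0: float = 1000.0) -> TensorField:
    """A TensorField with the same symmetric tensor planted in every voxel."""
    t = np.asarray(tensor, dtype=float)
    coeffs = np.array([t[0, 0], t[1, 1], t[2, 2], t[0, 1], t[0, 2], t[1, 2]])
    return TensorField(
        grid=grid,
        coefficients=np.broadcast_to(coeffs, grid.shape + (6,)).copy(),
        s0=np.full(grid.shape, float(s0)),
    )


def make_dwi_signals(
    tensor_field: TensorField,
    scheme: DWIScheme,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Simulate S = S0 exp(-b g^T D g) (+ Gaussian noise) per voxel.

    Returns a 4D stack shaped ``grid.shape + (len(scheme),)``; noiseless when
    ``noise_sd`` is 0.
    """
    coeffs = tensor_field.coefficients.reshape(-1, 6)
    g = scheme.bvectors
    b = scheme.bvalues
    # g^T D g expanded over the 6 unique coefficients
    quad = (
        np.outer(coeffs[:, 0], g[:, 0] ** 2)
        + np.outer(coeffs[:, 1], g[:, 1] ** 2)
        + np.outer(coeffs[:, 2], g[:, 2] ** 2)
        + 2 * np.outer(coeffs[:, 3], g[:, 0] * g[:, 1])
        + 2 * np.outer(coeffs[:, 4], g[:, 0] * g[:, 2])
        + 2 * np.outer(coeffs[:, 5], g[:, 1] * g[:, 2])
    )
    s0 = tensor_field.s0.reshape(-1, 1)
    signals = s0 * np.exp(-b[None, :] * quad)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signals = signals + rng.normal(0.0, noise_sd, size=signals.shape)
    return signals.reshape(tensor_field.grid.shape + (len(scheme),))
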