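"""Voxelwise diffusion tensor fitting and scalar metric maps (FA, MD, RD, AD).

The diffusion tensor model predicts the DWI signal as

    S(b, g) = S0 * exp(-b * g^T D g)

with D a symmetric positive 3x3 tensor in mm^2/s.  Fitting is two-pass
weighted least squares on log-signals: an ordinary least-squares pass on
ln S, then one reweighted pass using the squared predicted signals as
weights (log-transform noise propagation makes the log-signal variance
proportional to 1/S^2).  On noiseless model signals both passes recover the
planted tensor exactly (to numerical precision).

Scalar metrics from the (descending) eigenvalues l1 >= l2 >= l3:

    MD = (l1 + l2 + l3) / 3          AD = l1        RD = (l2 + l3) / 2
    FA = sqrt(3/2) * ||l - MD|| / ||l||,   FA(0, 0, 0) := 0

Negative eigenvalues are clamped to zero for metric computation only; raw
fitted tensors are retained for diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, ValidationError
from .io_formats import ScalarMap, VolumeGrid

__all__ = [
    "DWIScheme",
    "TensorField",
    "design_matrix",
    "fit_tensor_wls",
    "eigendecompose",
    "scalar_metrics",
    "tensor_metric_maps",
    "METRIC_NAMES",
]

METRIC_NAMES = ("FA", "MD", "RD", "AD")


@dataclass(frozen=True)
class DWIScheme:
    """A diffusion acquisition scheme: b-values (s/mm^2) and unit b-vectors.

    b=0 rows may carry zero vectors.  Tensor fitting requires at least one
    baseline (b=0) measurement and at least six non-collinear diffusion
    directions.
    """

    bvalues: np.ndarray
    bvectors: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvalues, dtype=float).ravel()
        bvecs = np.asarray(self.bvectors, dtype=float)
        if bvecs.shape != (len(bvals), 3):
            raise ValidationError(f"bvectors must be (N, 3) matching {len(bvals)} b-values")
        if np.any(bvals < 0):
            raise ValidationError("b-values must be non-negative")
        dw = bvals > 0
        norms = np.linalg.norm(bvecs[dw], axis=1)
        if dw.any() and not np.allclose(norms, 1.0, atol=1e-3):
            raise ValidationError("b>0 vectors must be unit length")
        object.__setattr__(self, "bvalues", bvals)
        object.__setattr__(self, "bvectors", bvecs)

    def __len__(self) -> int:
        return len(self.bvalues)

    def restricted(self, max_b: float) -> "DWIScheme":
        """Scheme restricted to measurements with b <= max_b (keeps b=0)."""
        keep = self.bvalues <= max_b
        return DWIScheme(self.bvalues[keep], self.bvectors[keep])

    @property
    def selection(self) -> np.ndarray:
        return np.arange(len(self.bvalues))


@dataclass
class TensorField:
    """Per-voxel symmetric tensors (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) plus S0.

    Fitted eigenvalues may be negative; clamping is deferred to the metric
    level so the raw fit remains inspectable.
    """

    grid: VolumeGrid
    coefficients: np.ndarray  # shape grid.shape + (6,)
    s0: np.ndarray  # shape grid.shape

    def tensor_at(self, idx: tuple[int, int, int]) -> np.ndarray:
        return tensor_from_coefficients(self.coefficients[idx])


def tensor_from_coefficients(coeffs: np.ndarray) -> np.ndarray:
    """(Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) -> symmetric 3x3 matrix."""
    dxx, dyy, dzz, dxy, dxz, dyz = np.asarray(coeffs, dtype=float)
    return np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])


def coefficients_from_tensor(tensor: np.ndarray) -> np.ndarray:
    """Symmetric 3x3 matrix -> (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)."""
    t = np.asarray(tensor, dtype=float)
    return np.array([t[0, 0], t[1, 1], t[2, 2], t[0, 1], t[0, 2], t[1, 2]])


def design_matrix(scheme: DWIScheme) -> np.ndarray:
    """Log-linear design matrix X with ln S = X @ (Dxx..Dyz, ln S0).

    Row i is (-b gx^2, -b gy^2, -b gz^2, -2b gx gy, -2b gx gz, -2b gy gz, 1).
    """
    b = scheme.bvalues
    g = scheme.bvectors
    return np.column_stack(
        [
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
            np.ones_like(b),
        ]
    )


def _check_scheme_fittable(scheme: DWIScheme) -> np.ndarray:
    if len(scheme) < 7:
        raise InsufficientDataError(f"tensor fit needs >= 7 measurements, got {len(scheme)}")
    if not np.any(scheme.bvalues == 0):
        raise InsufficientDataError("tensor fit needs at least one b=0 baseline")
    X = design_matrix(scheme)
    if np.linalg.matrix_rank(X) < 7:
        raise InsufficientDataError("design matrix is rank deficient (need >= 6 non-collinear directions)")
    return X


def fit_tensor_wls(
    signals: np.ndarray, scheme: DWIScheme
) -> tuple[np.ndarray, np.ndarray]:
    """Fit the diffusion tensor to signals of shape (..., N) by two-pass WLS.

    Returns ``(coefficients, s0)`` with coefficients shaped ``(..., 6)``.
    Voxels containing any non-positive signal are flagged by NaN coefficients
    rather than aborting the batch.
    """
    X = _check_scheme_fittable(scheme)
    sig = np.asarray(signals, dtype=float)
    if sig.shape[-1] != len(scheme):
        raise ValidationError(
            f"signal vector length {sig.shape[-1]} != scheme length {len(scheme)}"
        )
    lead_shape = sig.shape[:-1]
    flat = sig.reshape(-1, len(scheme))

    coeffs = np.full((flat.shape[0], 6), np.nan)
    s0 = np.full(flat.shape[0], np.nan)
    usable = np.all(flat > 0, axis=1) & np.all(np.isfinite(flat), axis=1)
    if usable.any():
        y = np.log(flat[usable])
        # pass 1: OLS on log-signals
        beta_ols, *_ = np.linalg.lstsq(X, y.T, rcond=None)
        # pass 2: WLS with squared predicted signals as weights
        pred = np.exp(X @ beta_ols)  # (N, n_voxels)
        out = np.empty((usable.sum(), 7))
        for i in range(usable.sum()):
            w = pred[:, i] ** 2
            Xw = X * w[:, None]
            out[i] = np.linalg.solve(X.T @ Xw, Xw.T @ y[i])
        coeffs[usable] = out[:, :6]
        s0[usable] = np.exp(out[:, 6])
    return coeffs.reshape(lead_shape + (6,)), s0.reshape(lead_shape)


def eigendecompose(tensor: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Descending eigenvalues and matching orthonormal eigenvectors.

    Returns ``(eigenvalues, eigenvectors)`` with ``eigenvectors[:, k]`` the
    unit eigenvector of ``eigenvalues[k]``.
    """
    t = np.asarray(tensor, dtype=float)
    if not np.allclose(t, t.T, atol=1e-10):
        raise ValidationError("tensor must be symmetric")
    vals, vecs = np.linalg.eigh(t)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]


def scalar_metrics(eigenvalues: np.ndarray) -> tuple[float, float, float, float]:
    """(FA, MD, RD, AD) from eigenvalues; negatives clamped to 0 first.

    FA of the all-zero tensor is defined as 0 (removes the 0/0 ambiguity).
    """
    lam = np.sort(np.clip(np.asarray(eigenvalues, dtype=float), 0.0, None))[::-1]
    md = lam.mean()
    ad = lam[0]
    rd = (lam[1] + lam[2]) / 2.0
    norm = np.linalg.norm(lam)
    if norm == 0.0:
        fa = 0.0
    else:
        fa = float(np.sqrt(1.5) * np.linalg.norm(lam - md) / norm)
    return fa, float(md), float(rd), float(ad)


def _metrics_from_coefficients(coeffs_flat: np.ndarray) -> np.ndarray:
    """Vectorised (FA, MD, RD, AD) for an (M, 6) coefficient block."""
    m = coeffs_flat.shape[0]
    tensors = np.empty((m, 3, 3))
    dxx, dyy, dzz, dxy, dxz, dyz = coeffs_flat.T
    tensors[:, 0, 0] = dxx
    tensors[:, 1, 1] = dyy
    tensors[:, 2, 2] = dzz
    tensors[:, 0, 1] = tensors[:, 1, 0] = dxy
    tensors[:, 0, 2] = tensors[:, 2, 0] = dxz
    tensors[:, 1, 2] = tensors[:, 2, 1] = dyz
    lam = np.linalg.eigvalsh(tensors)[:, ::-1]  # descending
    lam = np.clip(lam, 0.0, None)
    md = lam.mean(axis=1)
    ad = lam[:, 0]
    rd = (lam[:, 1] + lam[:, 2]) / 2.0
    norm = np.linalg.norm(lam, axis=1)
    dev = np.linalg.norm(lam - md[:, None], axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.where(norm > 0, np.sqrt(1.5) * dev / np.maximum(norm, 1e-300), 0.0)
    return np.column_stack([fa, md, rd, ad])


def tensor_metric_maps(
    dwi: np.ndarray,
    grid: VolumeGrid,
    scheme: DWIScheme,
    mask: np.ndarray | None = None,
    max_b: float | None = None,
) -> dict[str, ScalarMap]:
    """Fit tensors voxelwise and return {FA, MD, RD, AD} scalar maps.

    Parameters
    ----------
    dwi
        4D array, last axis matching the scheme length.
    mask
        Optional boolean brain mask; voxels outside are NaN in every map.
    max_b
        If given, restrict the fit to measurements with b <= max_b (e.g.
        1000 to exclude a high-b shell from the tensor model).
    """
    dwi = np.asarray(dwi, dtype=float)
    if dwi.ndim != 4:
        raise ValidationError(f"expected 4D DWI stack, got shape {dwi.shape}")
    if dwi.shape[:3] != grid.shape:
        raise ValidationError(f"DWI spatial shape {dwi.shape[:3]} != grid shape {grid.shape}")
    if dwi.shape[3] != len(scheme):
        raise ValidationError(f"DWI has {dwi.shape[3]} volumes but scheme has {len(scheme)}")
    if max_b is not None:
        keep = scheme.bvalues <= max_b
        scheme = DWIScheme(scheme.bvalues[keep], scheme.bvectors[keep])
        dwi = dwi[..., keep]
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != grid.shape:
            raise ValidationError("mask shape must equal grid shape")

    flat = dwi.reshape(-1, dwi.shape[3])
    flat_mask = np.ones(flat.shape[0], dtype=bool) if mask is None else mask.ravel()
    metrics = np.full((flat.shape[0], 4), np.nan)
    if flat_mask.any():
        coeffs, _ = fit_tensor_wls(flat[flat_mask], scheme)
        ok = np.all(np.isfinite(coeffs), axis=1)
        vals = np.full((coeffs.shape[0], 4), np.nan)
        if ok.any():
            vals[ok] = _metrics_from_coefficients(coeffs[ok])
        metrics[flat_mask] = vals

    units = {"FA": "", "MD": "mm^2/s", "RD": "mm^2/s", "AD": "mm^2/s"}
    return {
        name: ScalarMap(
            grid=grid,
            values=metrics[:, k].reshape(grid.shape),
            metric_name=name,
            units=units[name],
        )
        for k, name in enumerate(METRIC_NAMES)
    }
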