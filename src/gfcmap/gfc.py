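"""Voxel-wise global-brain functional connectivity (GFC).

The GFC of a voxel is the mean Pearson correlation between its time series
and the time series of every *other* voxel inside a gray-matter mask,
Fisher r-to-z transformed.  Correlations enter the average in signed form
(negative values are not rectified).

Two conventions are supported for where the Fisher transform is applied:

``z_of_mean_r``
    z = arctanh(mean_j r_ij) — transform the averaged correlation
    (default; admits an exact O(V*T) reformulation).
``mean_of_z``
    z = mean_j arctanh(r_ij) — average the transformed correlations
    (computed in voxel blocks to bound memory).

The O(V*T) fast path standardises each masked series to zero mean and unit
L2 norm (u_i), so that sum_j r_ij = u_i . S with S = sum_j u_j, and the
self-correlation (always exactly 1) is removed by subtraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: correlations are clamped to +/- (1 - CLAMP_EPS) before arctanh so that
#: degenerate perfect correlations stay finite (and storable in NIfTI).
CLAMP_EPS = 1e-7

#: voxels whose temporal variance falls below this are treated as constant.
CONSTANT_VARIANCE_TOL = 1e-12


@dataclass
class VolumeSeries:
    """One subject's 4D BOLD series on a voxel grid.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz, n_frames)
        BOLD intensities, arbitrary units.
    affine : ndarray, shape (4, 4)
        Voxel-to-world (MNI mm) transform.
    tr : float
        Repetition time in seconds.
    subject_id : str
    """

    data: np.ndarray
    affine: np.ndarray
    tr: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D data, got shape {self.data.shape}")
        if self.data.shape[3] < 2:
            raise ValueError("need at least 2 frames")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"non-finite values in volume {self.subject_id!r}")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]


@dataclass
class GrayMask:
    """Ordered set of gray-matter voxels (row-major by x, then y, then z)."""

    member_voxels: np.ndarray  # (V, 3) int
    source_threshold: float
    grid_shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.member_voxels = np.asarray(self.member_voxels, dtype=np.intp)
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.member_voxels.ndim != 2 or self.member_voxels.shape[1] != 3:
            raise ValueError("member_voxels must have shape (V, 3)")
        if len(self.member_voxels) == 0:
            raise ValueError("mask is empty")
        if np.any(self.member_voxels < 0) or np.any(
            self.member_voxels >= np.asarray(self.grid_shape)
        ):
            raise ValueError("mask voxels outside grid")

    def __len__(self) -> int:
        return len(self.member_voxels)

    @property
    def flat_indices(self) -> np.ndarray:
        """Row-major (C-order) flat index of each member voxel."""
        return np.ravel_multi_index(self.member_voxels.T, self.grid_shape)

    def to_volume(self, values: np.ndarray, background: float = 0.0) -> np.ndarray:
        """Scatter per-mask-voxel values into a full 3D volume."""
        values = np.asarray(values)
        if values.shape != (len(self),):
            raise ValueError("values length does not match mask size")
        vol = np.full(self.grid_shape, background, dtype=float)
        vol.flat[self.flat_indices] = values
        return vol

    def boolean_volume(self) -> np.ndarray:
        vol = np.zeros(self.grid_shape, dtype=bool)
        vol.flat[self.flat_indices] = True
        return vol


@dataclass
class GFCMap:
    """Per-subject Fisher-z global connectivity values over a mask."""

    values: np.ndarray  # (V,) one z value per mask voxel
    subject_id: str
    z_order: str  # {"z_of_mean_r", "mean_of_z"}
    mask: GrayMask = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.mask),):
            raise ValueError("values length does not match mask size")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("GFC values must be finite (clamp before arctanh)")
        if self.z_order not in ("z_of_mean_r", "mean_of_z"):
            raise ValueError(f"unknown z_order {self.z_order!r}")

    def to_volume(self) -> np.ndarray:
        """3D volume with background encoded as 0 (mask is the sidecar)."""
        return self.mask.to_volume(self.values, background=0.0)


def build_gray_mask(
    probability_map: np.ndarray,
    threshold: float = 0.2,
    affine: np.ndarray | None = None,
) -> GrayMask:
    """Threshold a gray-matter probability map into an analysis mask.

    Voxels with probability *strictly greater* than ``threshold`` are kept,
    in a deterministic row-major order (x fastest-varying last).
    """
    prob = np.asarray(probability_map, dtype=float)
    if prob.ndim != 3:
        raise ValueError("probability map must be 3D")
    if np.any(prob < 0) or np.any(prob > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if not (0 <= threshold < 1):
        raise ValueError("threshold must lie in [0, 1)")
    coords = np.argwhere(prob > threshold)  # C-order scan -> row-major ordering
    if len(coords) == 0:
        raise ValueError(
            f"empty gray-matter mask: no voxel has probability > {threshold}"
        )
    if affine is None:
        affine = np.eye(4)
    return GrayMask(
        member_voxels=coords,
        source_threshold=float(threshold),
        grid_shape=prob.shape,
        affine=affine,
    )


def fisher_z(r):
    """Fisher r-to-z transform, arctanh(r), with clamping at 1 - 1e-7.

    Strictly increasing and odd; |r| may exceed 1 by at most 1e-9
    (numerical tolerance), anything beyond is an error.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1 + 1e-9):
        raise ValueError("correlation magnitude exceeds 1 beyond tolerance")
    out = np.arctanh(np.clip(r, -1 + CLAMP_EPS, 1 - CLAMP_EPS))
    return out if out.ndim else float(out)


def _masked_matrix(vs: VolumeSeries, mask: GrayMask) -> np.ndarray:
    """Extract the (V, T) matrix of masked time series."""
    if vs.grid_shape != mask.grid_shape:
        raise ValueError(
            f"grid mismatch: volume {vs.grid_shape} vs mask {mask.grid_shape}"
        )
    flat = vs.data.reshape(-1, vs.n_frames)
    return flat[mask.flat_indices].astype(float)


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-L2-norm rows; raises listing any constant voxel."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    T = X.shape[1]
    bad = np.flatnonzero(norms**2 / T < CONSTANT_VARIANCE_TOL)
    if bad.size:
        raise ValueError(
            f"{bad.size} masked voxel(s) have (near-)zero temporal variance "
            f"at mask positions {bad[:20].tolist()}"
            + ("..." if bad.size > 20 else "")
            + "; use drop_constant_voxels to shrink the mask"
        )
    return Xc / norms[:, None]


def compute_gfc(
    vs: VolumeSeries,
    mask: GrayMask,
    z_order: str = "z_of_mean_r",
    block_size: int = 512,
) -> GFCMap:
    """Compute one subject's GFC map over a gray-matter mask.

    For ``z_of_mean_r`` the O(V*T) identity
    ``mean_{j != i} r_ij = (u_i . S - 1) / (V - 1)`` with ``S = sum_j u_j``
    is used; for ``mean_of_z`` the pairwise correlations are formed in
    blocks of ``block_size`` voxels and arctanh-averaged with the self term
    subtracted.  Self-correlation is always excluded.
    """
    if z_order not in ("z_of_mean_r", "mean_of_z"):
        raise ValueError(f"unknown z_order {z_order!r}")
    X = _masked_matrix(vs, mask)
    V = X.shape[0]
    if V < 2:
        raise ValueError("GFC needs at least 2 mask voxels")
    U = _standardize_rows(X)

    if z_order == "z_of_mean_r":
        S = U.sum(axis=0)
        mean_r = (U @ S - 1.0) / (V - 1)
        values = fisher_z(np.clip(mean_r, -1.0, 1.0))
    else:
        self_z = np.arctanh(1.0 - CLAMP_EPS)  # the clamped r_ii = 1 term
        values = np.empty(V)
        for start in range(0, V, block_size):
            block = slice(start, min(start + block_size, V))
            R = np.clip(U[block] @ U.T, -1 + CLAMP_EPS, 1 - CLAMP_EPS)
            values[block] = (np.arctanh(R).sum(axis=1) - self_z) / (V - 1)

    return GFCMap(values=values, subject_id=vs.subject_id, z_order=z_order, mask=mask)


def drop_constant_voxels(vs: VolumeSeries, mask: GrayMask) -> GrayMask:
    """Return the mask minus voxels with temporal variance < 1e-12."""
    X = _masked_matrix(vs, mask)
    keep = X.var(axis=1) >= CONSTANT_VARIANCE_TOL
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info(
            "drop_constant_voxels: removed %d constant voxel(s) for subject %r",
            n_removed,
            vs.subject_id,
        )
    if not keep.any():
        raise ValueError("all mask voxels are constant; resulting mask empty")
    if not n_removed:
        return mask
    return GrayMask(
        member_voxels=mask.member_voxels[keep],
        source_threshold=mask.source_threshold,
        grid_shape=mask.grid_shape,
        affine=mask.affine,
    )


def preprocess_minimal(
    vs: VolumeSeries,
    motion: "np.ndarray | None" = None,
    detrend: bool = False,
    bandpass: tuple[float, float] | None = None,
    regress_motion: bool = False,
) -> VolumeSeries:
    """Optional convenience preprocessing: detrend -> motion regression -> band-pass.

    The canonical input to this package is already-preprocessed data; this
    stand-in applies, in a fixed order, (1) per-voxel linear detrend,
    (2) least-squares removal of the 6 rigid-body motion regressors, and
    (3) an ideal (discrete-Fourier-mask) band-pass.  Frame count is
    unchanged.

    Parameters
    ----------
    motion : ndarray, shape (n_frames, 6), required when ``regress_motion``.
    bandpass : (low_hz, high_hz) with 0 <= low < high < Nyquist = 1/(2 TR).
    """
    from scipy.signal import detrend as _detrend

    data = vs.data.astype(float)
    T = vs.n_frames
    flat = data.reshape(-1, T)

    if detrend:
        flat = _detrend(flat, axis=1, type="linear")

    if regress_motion:
        if motion is None:
            raise ValueError("regress_motion requires a motion trace")
        M = np.asarray(motion, dtype=float)
        if M.shape != (T, 6):
            raise ValueError(f"motion trace must be ({T}, 6), got {M.shape}")
        design = np.column_stack([np.ones(T), M])
        beta, *_ = np.linalg.lstsq(design, flat.T, rcond=None)
        flat = flat - (design @ beta).T

    if bandpass is not None:
        low, high = bandpass
        nyquist = 1.0 / (2.0 * vs.tr)
        if not (0 <= low < high):
            raise ValueError("bandpass requires 0 <= low < high")
        if high >= nyquist:
            raise ValueError(
                f"bandpass high {high} Hz must be below Nyquist {nyquist} Hz"
            )
        freqs = np.fft.rfftfreq(T, d=vs.tr)
        keep = (freqs >= low) & (freqs <= high)
        spec = np.fft.rfft(flat, axis=1)
        spec[:, ~keep] = 0
        flat = np.fft.irfft(spec, n=T, axis=1)

    return VolumeSeries(
        data=flat.reshape(vs.data.shape),
        affine=vs.affine,
        tr=vs.tr,
        subject_id=vs.subject_id,
    )


class GlobalConnectivity:
    """Transformer turning per-subject 4D series into a subjects x voxels GFC matrix.

    Scikit-learn style: construct with parameters, ``fit`` validates,
    ``transform`` maps a sequence of :class:`VolumeSeries` to an
    ``(n_subjects, n_mask_voxels)`` array of Fisher-z GFC values, one row
    per subject, columns in mask order.  Composes with downstream
    estimators that treat subjects as samples and voxels as features.
    """

    def __init__(self, mask: GrayMask | None = None, z_order: str = "z_of_mean_r"):
        self.mask = mask
        self.z_order = z_order

    def get_params(self, deep: bool = True) -> dict:
        return {"mask": self.mask, "z_order": self.z_order}

    def set_params(self, **params) -> "GlobalConnectivity":
        for key, value in params.items():
            if key not in ("mask", "z_order"):
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X, y=None) -> "GlobalConnectivity":
        if self.mask is None:
            raise ValueError("GlobalConnectivity requires a mask")
        if self.z_order not in ("z_of_mean_r", "mean_of_z"):
            raise ValueError(f"unknown z_order {self.z_order!r}")
        self.n_features_out_ = len(self.mask)
        return self

    def transform(self, X) -> np.ndarray:
        self.fit(X)
        maps = [compute_gfc(vs, self.mask, z_order=self.z_order) for vs in X]
        return np.vstack([m.values for m in maps])

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform(X)
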