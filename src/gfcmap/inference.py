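"""Voxel-wise group inference on GFC maps.

Per voxel, GFC is regressed on a design of [intercept, group, nuisance
covariates] by ordinary least squares and the group contrast (patients
minus controls) is tested with a t statistic.  Family-wise error over the
mask is controlled either by a Freedman-Lane maxT permutation scheme
(default) or by Bonferroni.  Supra-threshold voxels are grouped into
26-connected clusters, reported with their peak t and MNI coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as _sla
from scipy import ndimage
from scipy import stats

from .gfc import GrayMask

DEFAULT_COVARIATES = ("age", "sex", "education", "mean_fd")

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class StatMap:
    """Per-mask-voxel t statistics with two-sided uncorrected p values."""

    t: np.ndarray
    p: np.ndarray
    dof: int
    contrast: str = "patients - controls"


@dataclass
class FweResult:
    """Family-wise-error correction outcome over the mask."""

    method: str  # {"permutation_maxT", "bonferroni"}
    alpha: float
    threshold: float  # corrected threshold on |t|
    significant: np.ndarray  # boolean, one per mask voxel
    n_permutations: int = 0
    seed: int | None = None
    max_t_null: np.ndarray | None = field(default=None, repr=False)


@dataclass
class ClusterResult:
    """A supra-threshold 26-connected component."""

    cluster_id: str
    peak_mni: tuple[float, float, float]
    peak_t: float
    n_voxels: int
    member_voxels: np.ndarray  # (k, 3) voxel coordinates
    direction: str  # {"patients>controls", "patients<controls"}


def build_design(
    subjects: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    group_col: str = "group",
    patient_label: str = "patient",
) -> tuple[np.ndarray, list[str]]:
    """Assemble [intercept, group, covariates...] from a subject table.

    Continuous covariates are mean-centered (the intercept then estimates
    the control mean at average covariate values); ``sex`` is passed
    through as a 0/1 indicator.  Returns (matrix, column names).
    """
    n = len(subjects)
    group = (subjects[group_col] == patient_label).to_numpy(dtype=float)
    if group.min() == group.max():
        raise ValueError("group column must contain both patients and controls")
    cols = [np.ones(n), group]
    names = ["intercept", "group"]
    for cov in covariates:
        if cov not in subjects.columns:
            raise ValueError(f"covariate {cov!r} missing from subject table")
        x = subjects[cov].to_numpy(dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError(f"covariate {cov!r} contains non-finite values")
        if cov != "sex":
            x = x - x.mean()
        cols.append(x)
        names.append(cov)
    X = np.column_stack(cols)
    _check_full_rank(X, names)
    return X, names


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify offending columns via rank-revealing QR pivots
        _, R, piv = _sla.qr(X, pivoting=True, mode="economic")
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [names[piv[i]] for i in range(len(names)) if diag[i] <= tol]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def _glm_t(Y: np.ndarray, X: np.ndarray, pinv: np.ndarray, cvar: float, col: int,
           dof: int) -> np.ndarray:
    """t statistics for one design column, vectorised over voxels (columns of Y)."""
    beta = pinv @ Y
    resid = Y - X @ beta
    sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
    est = beta[col]
    # zero residual variance (relative to the data's scale) with a zero
    # contrast estimate is defined as t = 0, not 0/0
    scale = np.einsum("ij,ij->j", Y, Y) / Y.shape[0] + 1e-300
    zero_var = sigma2 <= scale * 1e-24
    zero_est = est**2 <= scale * 1e-24
    se = np.sqrt(cvar * sigma2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(
            zero_var,
            np.where(zero_est, 0.0, np.inf * np.sign(est)),
            est / np.where(se > 0, se, 1.0),
        )
    return t


def fit_voxelwise_glm(
    Y: np.ndarray,
    X: np.ndarray,
    group_col: int = 1,
    column_names: list[str] | None = None,
) -> StatMap:
    """OLS fit of GFC on the design at every voxel; t test on the group column.

    ``Y`` is (n_subjects, n_voxels) with rows aligned to the design rows.
    With a design of intercept + group only, the t statistic equals the
    classical pooled-variance two-sample t test.  Voxels with zero residual
    variance and zero contrast estimate get t = 0 (no 0/0).
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    if Y.shape[0] != X.shape[0]:
        raise ValueError("design rows do not align with the map stack")
    n, p = X.shape
    if n <= p:
        raise ValueError("need more subjects than design columns")
    _check_full_rank(X, column_names or [f"col{i}" for i in range(p)])
    dof = n - p
    pinv = np.linalg.pinv(X)
    cvar = np.linalg.inv(X.T @ X)[group_col, group_col]
    t = _glm_t(Y, X, pinv, cvar, group_col, dof)
    with np.errstate(invalid="ignore"):
        pvals = 2.0 * stats.t.sf(np.abs(t), dof)
    pvals = np.where(np.isfinite(t), pvals, 0.0)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    return StatMap(t=t, p=pvals, dof=dof)


def fwe_correct(
    stat: StatMap,
    Y: np.ndarray,
    X: np.ndarray,
    method: str = "permutation_maxT",
    alpha: float = 0.05,
    n_permutations: int = 1000,
    seed: int = 0,
    group_col: int = 1,
) -> FweResult:
    """Family-wise error control over the mask.

    ``permutation_maxT`` uses the Freedman-Lane scheme: the nuisance part
    of the design is regressed out of Y, the residuals are row-permuted
    (the identity permutation is always included), the full model is refit
    and the maximum |t| over the mask recorded; the corrected threshold is
    the (1 - alpha) empirical quantile (order statistic
    ``ceil((1 - alpha) * n_permutations)``) of that null.  ``bonferroni``
    thresholds the per-voxel p at alpha / V.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    V = Y.shape[1]

    if method == "bonferroni":
        per_voxel = alpha / V
        threshold = float(stats.t.isf(per_voxel / 2.0, stat.dof))
        significant = stat.p < per_voxel
        return FweResult(
            method=method, alpha=alpha, threshold=threshold, significant=significant
        )
    if method != "permutation_maxT":
        raise ValueError(f"unknown FWE method {method!r}")
    if n_permutations < 100:
        raise ValueError("permutation_maxT requires n_permutations >= 100")

    nuisance = np.delete(X, group_col, axis=1)
    # Freedman-Lane: fitted nuisance part + permuted nuisance residuals
    coef, *_ = np.linalg.lstsq(nuisance, Y, rcond=None)
    fitted = nuisance @ coef
    resid = Y - fitted

    dof = n - p
    pinv = np.linalg.pinv(X)
    cvar = np.linalg.inv(X.T @ X)[group_col, group_col]
    rng = np.random.default_rng(seed)
    max_t = np.empty(n_permutations)
    for k in range(n_permutations):
        order = np.arange(n) if k == 0 else rng.permutation(n)
        t_k = _glm_t(fitted + resid[order], X, pinv, cvar, group_col, dof)
        max_t[k] = np.abs(t_k).max()

    k_idx = int(np.ceil((1 - alpha) * n_permutations)) - 1
    threshold = float(np.sort(max_t)[k_idx])
    significant = np.abs(stat.t) > threshold
    return FweResult(
        method=method,
        alpha=alpha,
        threshold=threshold,
        significant=significant,
        n_permutations=n_permutations,
        seed=seed,
        max_t_null=max_t,
    )


def extract_clusters(
    stat: StatMap,
    fwe: FweResult,
    mask: GrayMask,
    affine: np.ndarray | None = None,
    connectivity: int = 26,
) -> list[ClusterResult]:
    """Group significant voxels into connected components, split by sign of t.

    Components are labelled with 26-connectivity by default (6/18
    available).  The peak is the member voxel maximising |t| (row-major
    tie-break); its MNI mm coordinate comes through the affine.  Clusters
    are returned sorted by descending peak |t|.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be one of 6, 18, 26")
    affine = mask.affine if affine is None else np.asarray(affine, dtype=float)
    t_vol = mask.to_volume(stat.t)
    sig_vol = mask.boolean_volume() & mask.to_volume(
        fwe.significant.astype(float)
    ).astype(bool)

    clusters: list[ClusterResult] = []
    for sign, direction in ((1, "patients>controls"), (-1, "patients<controls")):
        labelled, n_comp = ndimage.label(
            sig_vol & (sign * t_vol > 0), structure=_STRUCTURES[connectivity]
        )
        for comp in range(1, n_comp + 1):
            members = np.argwhere(labelled == comp)  # row-major order
            t_members = t_vol[tuple(members.T)]
            peak_local = int(np.argmax(np.abs(t_members)))  # first max: row-major tie-break
            peak_vox = members[peak_local]
            peak_mni = tuple((affine @ np.append(peak_vox, 1.0))[:3])
            clusters.append(
                ClusterResult(
                    cluster_id="",
                    peak_mni=peak_mni,
                    peak_t=float(t_members[peak_local]),
                    n_voxels=len(members),
                    member_voxels=members,
                    direction=direction,
                )
            )
    clusters.sort(key=lambda c: -abs(c.peak_t))
    for i, c in enumerate(clusters, start=1):
        c.cluster_id = f"cluster{i}"
    return clusters


def clusters_to_frame(clusters: list[ClusterResult]) -> pd.DataFrame:
    """Tabulate clusters (peak MNI, size, peak t, direction)."""
    return pd.DataFrame(
        [
            {
                "cluster_id": c.cluster_id,
                "peak_x": c.peak_mni[0],
                "peak_y": c.peak_mni[1],
                "peak_z": c.peak_mni[2],
                "n_voxels": c.n_voxels,
                "peak_t": c.peak_t,
                "direction": c.direction,
            }
            for c in clusters
        ],
        columns=[
            "cluster_id", "peak_x", "peak_y", "peak_z", "n_voxels", "peak_t", "direction",
        ],
    )


class VoxelwiseGroupGLM:
    """Estimator wrapping the voxel-wise GLM + FWE + clustering stage.

    Parameters mirror :func:`fit_voxelwise_glm` / :func:`fwe_correct`;
    ``fit(X, y, covariates=..., mask=...)`` takes the subjects x voxels GFC
    matrix ``X`` and 0/1 group labels ``y`` (1 = patient) and exposes
    fitted attributes ``t_``, ``p_``, ``dof_``, ``threshold_``,
    ``significant_`` and (when a mask is supplied) ``clusters_``.
    """

    def __init__(
        self,
        fwe: str = "permutation_maxT",
        alpha: float = 0.05,
        n_permutations: int = 1000,
        connectivity: int = 26,
        random_state: int = 0,
    ):
        self.fwe = fwe
        self.alpha = alpha
        self.n_permutations = n_permutations
        self.connectivity = connectivity
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "fwe": self.fwe,
            "alpha": self.alpha,
            "n_permutations": self.n_permutations,
            "connectivity": self.connectivity,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "VoxelwiseGroupGLM":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X, y, covariates: np.ndarray | None = None,
            mask: GrayMask | None = None) -> "VoxelwiseGroupGLM":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n = X.shape[0]
        cols = [np.ones(n), y]
        names = ["intercept", "group"]
        if covariates is not None:
            cov = np.atleast_2d(np.asarray(covariates, dtype=float))
            if cov.shape[0] != n:
                cov = cov.T
            cov = cov - cov.mean(axis=0)
            cols.extend(cov.T)
            names.extend(f"cov{i}" for i in range(cov.shape[1]))
        design = np.column_stack(cols)
        stat = fit_voxelwise_glm(X, design, group_col=1, column_names=names)
        fwe = fwe_correct(
            stat, X, design,
            method=self.fwe, alpha=self.alpha,
            n_permutations=self.n_permutations, seed=self.random_state,
        )
        self.t_, self.p_, self.dof_ = stat.t, stat.p, stat.dof
        self.threshold_, self.significant_ = fwe.threshold, fwe.significant
        self.stat_map_, self.fwe_result_ = stat, fwe
        if mask is not None:
            self.clusters_ = extract_clusters(
                stat, fwe, mask, connectivity=self.connectivity
            )
        return self
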