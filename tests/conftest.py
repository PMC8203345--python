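"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from gfcmap import (
    CohortSpec,
    VolumeSeries,
    build_gray_mask,
    compute_fd,
    compute_gfc,
    generate_cohort,
)
from gfcmap.cohort import DEFAULT_AFFINE
from gfcmap.inference import build_design, extract_clusters, fit_voxelwise_glm, fwe_correct


def random_volume(shape=(4, 4, 4), n_frames=50, seed=0, tr=2.0, subject_id="sub"):
    rng = np.random.default_rng(seed)
    return VolumeSeries(
        data=rng.normal(size=(*shape, n_frames)),
        affine=np.eye(4),
        tr=tr,
        subject_id=subject_id,
    )


def full_mask(shape=(4, 4, 4)):
    return build_gray_mask(np.full(shape, 0.9), 0.2)


def pairwise_gfc_oracle(vs: VolumeSeries, mask, z_order: str) -> np.ndarray:
    """Brute-force O(V^2 * T) GFC by explicit all-pairs Pearson correlation.

    Independent of the package's fast path: correlations via np.corrcoef
    per pair, clamping and averaging done longhand.
    """
    X = vs.data.reshape(-1, vs.n_frames)[mask.flat_indices].astype(float)
    V = X.shape[0]

    def clamp(r):
        return min(max(r, -1 + 1e-7), 1 - 1e-7)

    out = np.empty(V)
    for i in range(V):
        rs = [
            np.corrcoef(X[i], X[j])[0, 1] for j in range(V) if j != i
        ]
        if z_order == "z_of_mean_r":
            out[i] = np.arctanh(clamp(sum(rs) / (V - 1)))
        else:
            out[i] = sum(np.arctanh(clamp(r)) for r in rs) / (V - 1)
    return out


def run_group_stage(spec: CohortSpec, n_permutations: int = 1000, alpha: float = 0.05):
    """Simulate a cohort and run QC -> GFC -> GLM -> FWE -> clusters.

    Returns (stat, fwe, clusters, truth, mask, Y, subjects).
    """
    vols, gm, traces, subjects, truth = generate_cohort(spec)
    mask = build_gray_mask(gm, 0.2, affine=DEFAULT_AFFINE)
    Y = np.vstack([compute_gfc(v, mask).values for v in vols])
    fds = [compute_fd(t) for t in traces]
    subjects = subjects.copy()
    subjects["mean_fd"] = [f.mean_fd for f in fds]
    X, names = build_design(subjects)
    stat = fit_voxelwise_glm(Y, X, group_col=1, column_names=names)
    fwe = fwe_correct(
        stat, Y, X, method="permutation_maxT", alpha=alpha,
        n_permutations=n_permutations, seed=spec.seed,
    )
    clusters = extract_clusters(stat, fwe, mask)
    return stat, fwe, clusters, truth, mask, Y, subjects


def dice(a: set, b: set) -> float:
    return 2 * len(a & b) / (len(a) + len(b)) if (a or b) else 0.0


@pytest.fixture(scope="session")
def small_cohort():
    """A small but powered cohort shared across tests (12 + 12 subjects)."""
    spec = CohortSpec(n_patients=12, n_controls=12, seed=7)
    return spec, generate_cohort(spec)
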