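"""Cluster-mean GFC extraction and clinical correlation screening.

After group inference identifies clusters with abnormal global
connectivity, each subject's mean Fisher-z GFC over every cluster is
extracted and screened against clinical variables (serum lipids, symptom
scales, neuropsychological scores) with Pearson correlation, Bonferroni
corrected over the declared family of tests.  Missing values are dropped
pairwise, never imputed; correlations are computed among patients by
default (the clinical variables exist only for them).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .inference import ClusterResult

logger = logging.getLogger(__name__)


@dataclass
class CorrelationResult:
    cluster_id: str
    variable: str
    n: int
    r: float
    p_uncorrected: float
    p_threshold_bonferroni: float
    significant: bool
    shapiro_w: float = float("nan")
    shapiro_p: float = float("nan")


def extract_cluster_means(
    gfc_matrix: np.ndarray,
    subject_ids: list[str],
    clusters: list[ClusterResult],
    mask,
) -> pd.DataFrame:
    """Mean GFC z value per subject per cluster.

    ``gfc_matrix`` is (n_subjects, n_mask_voxels) in mask order; cluster
    member voxels must all lie inside the mask.
    """
    flat_to_col = {int(f): i for i, f in enumerate(mask.flat_indices)}
    out = pd.DataFrame({"subject": subject_ids})
    for c in clusters:
        if c.n_voxels == 0:
            raise ValueError(f"cluster {c.cluster_id!r} is empty")
        flat = np.ravel_multi_index(np.asarray(c.member_voxels).T, mask.grid_shape)
        try:
            cols = [flat_to_col[int(f)] for f in flat]
        except KeyError as exc:
            raise ValueError(
                f"cluster {c.cluster_id!r} has voxels outside the mask"
            ) from exc
        out[c.cluster_id] = gfc_matrix[:, cols].mean(axis=1)
    return out


def correlate_clinical(
    means: pd.DataFrame,
    subjects: pd.DataFrame,
    variables: list[str],
    group_filter: str = "patient",
    family: str = "all",
    alpha: float = 0.05,
) -> list[CorrelationResult]:
    """Pearson screen of cluster means against clinical variables.

    ``family`` declares the Bonferroni correction family: ``"all"`` divides
    alpha by the total number of performed (cluster, variable) tests,
    ``"per_cluster"`` by the number of variables tested within each
    cluster.  Pairs with fewer than 3 complete observations are skipped
    with a warning and do not count toward the family.  Normality of each
    cluster's means (Shapiro-Wilk) is reported, not gating.
    """
    if family not in ("all", "per_cluster"):
        raise ValueError("family must be 'all' or 'per_cluster'")
    for v in variables:
        if v not in subjects.columns:
            raise ValueError(f"variable {v!r} absent from subject table")

    merged = means.merge(subjects, on="subject", how="inner")
    if group_filter != "all":
        merged = merged[merged["group"] == group_filter]
    cluster_ids = [c for c in means.columns if c != "subject"]

    # first pass: which pairs have enough complete observations
    tested: list[tuple[str, str, np.ndarray, np.ndarray]] = []
    skipped_per_cluster = {cid: 0 for cid in cluster_ids}
    for cid in cluster_ids:
        for var in variables:
            pair = merged[[cid, var]].dropna()
            if len(pair) < 3:
                logger.warning(
                    "skipping %s x %s: only %d complete pairs", cid, var, len(pair)
                )
                skipped_per_cluster[cid] += 1
                continue
            tested.append((cid, var, pair[cid].to_numpy(), pair[var].to_numpy()))

    n_total = len(tested)
    shapiro_by_cluster = {}
    for cid in cluster_ids:
        vals = merged[cid].dropna().to_numpy()
        if len(vals) >= 3:
            w, p = stats.shapiro(vals)
        else:
            w, p = np.nan, np.nan
        shapiro_by_cluster[cid] = (float(w), float(p))

    results = []
    for cid, var, x, y in tested:
        if family == "all":
            n_family = n_total
        else:
            n_family = len(variables) - skipped_per_cluster[cid]
        threshold = alpha / n_family if n_family else np.nan
        if np.std(x) < 1e-15 or np.std(y) < 1e-15:
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(x, y)
        w, sp = shapiro_by_cluster[cid]
        results.append(
            CorrelationResult(
                cluster_id=cid,
                variable=var,
                n=len(x),
                r=float(r),
                p_uncorrected=float(p),
                p_threshold_bonferroni=float(threshold),
                significant=bool(p < threshold),
                shapiro_w=w,
                shapiro_p=sp,
            )
        )
    return results


def correlations_to_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cluster_id": r.cluster_id,
                "variable": r.variable,
                "n": r.n,
                "r": r.r,
                "p": r.p_uncorrected,
                "threshold": r.p_threshold_bonferroni,
                "significant": r.significant,
                "shapiro_w": r.shapiro_w,
                "shapiro_p": r.shapiro_p,
            }
            for r in results
        ]
    )
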