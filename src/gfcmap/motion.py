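"""Head-motion quality control: framewise displacement and subject exclusion.

Framewise displacement (FD) summarises rigid-body motion per frame as the
sum of absolute frame-to-frame changes in the three translations (mm) plus
the three rotations converted to arc length on a sphere (default radius
50 mm).  The first frame's FD is defined as 0.  Per-subject mean FD enters
the group model as a nuisance covariate; subjects exceeding configurable
limits are excluded outright (whole-subject exclusion, no frame censoring).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_SPHERE_RADIUS_MM = 50.0
DEFAULT_MEAN_FD_LIMIT_MM = 0.2
DEFAULT_MAX_ABS_TRANSLATION_MM = 2.0
DEFAULT_MAX_ABS_ROTATION_DEG = 2.0


@dataclass
class MotionTrace:
    """Per-frame rigid-body parameters: 3 translations (mm), 3 rotations (rad).

    SPM ``rp_*.txt`` column convention.  Rotations are radians unless the
    file was read with ``degrees=True`` (no silent unit guessing).
    """

    params: np.ndarray  # (n_frames, 6)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError(f"motion trace must be (n_frames, 6), got {self.params.shape}")
        if not np.all(np.isfinite(self.params)):
            raise ValueError(f"non-finite motion parameters for {self.subject_id!r}")

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]

    @property
    def translations(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def rotations(self) -> np.ndarray:
        return self.params[:, 3:]


@dataclass
class FDSeries:
    """Per-frame framewise displacement (mm) and its mean."""

    fd: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.fd = np.asarray(self.fd, dtype=float)
        if np.any(self.fd < 0):
            raise ValueError("FD values must be non-negative")

    @property
    def mean_fd(self) -> float:
        return float(self.fd.mean())


def read_motion_file(path, subject_id: str = "", degrees: bool = False) -> MotionTrace:
    """Read a 6-column whitespace-delimited motion file (SPM rp convention).

    ``degrees=True`` converts rotation columns to radians on load.
    """
    params = np.loadtxt(path, ndmin=2)
    if params.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 columns, got {params.shape[1]}")
    if degrees:
        params = params.copy()
        params[:, 3:] = np.deg2rad(params[:, 3:])
    sid = subject_id or Path(path).stem
    return MotionTrace(params=params, subject_id=sid)


def compute_fd(trace: MotionTrace, sphere_radius: float = DEFAULT_SPHERE_RADIUS_MM) -> FDSeries:
    """Power-style framewise displacement.

    FD_t = sum |Delta translations| + radius * sum |Delta rotations| for
    t >= 2, FD_1 = 0; rotations (radians) become arc length on a sphere of
    ``sphere_radius`` mm.
    """
    if trace.n_frames < 2:
        raise ValueError("FD needs at least 2 frames")
    diff = np.abs(np.diff(trace.params, axis=0))
    fd = diff[:, :3].sum(axis=1) + sphere_radius * diff[:, 3:].sum(axis=1)
    return FDSeries(fd=np.concatenate([[0.0], fd]), subject_id=trace.subject_id)


def apply_exclusion(
    fds: list[FDSeries],
    traces: list[MotionTrace],
    mean_fd_limit: float = DEFAULT_MEAN_FD_LIMIT_MM,
    max_abs_translation: float = DEFAULT_MAX_ABS_TRANSLATION_MM,
    max_abs_rotation: float = DEFAULT_MAX_ABS_ROTATION_DEG,
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Partition subjects into kept/excluded on motion criteria.

    A subject is excluded if mean FD > ``mean_fd_limit`` (mm), OR any
    absolute translation > ``max_abs_translation`` (mm), OR any absolute
    rotation > ``max_abs_rotation`` (degrees).  Returns
    ``(kept_ids, excluded_ids, report)`` where the report records per
    subject the mean FD, the verdict and every violated criterion.
    """
    if not (mean_fd_limit > 0 and max_abs_translation > 0 and max_abs_rotation > 0):
        raise ValueError("exclusion limits must be positive")
    by_id = {t.subject_id: t for t in traces}
    kept, excluded, rows = [], [], []
    for fd in fds:
        trace = by_id[fd.subject_id]
        reasons = []
        if fd.mean_fd > mean_fd_limit:
            reasons.append(f"mean_fd {fd.mean_fd:.3f} > {mean_fd_limit}")
        if np.abs(trace.translations).max() > max_abs_translation:
            reasons.append(
                f"max |translation| {np.abs(trace.translations).max():.3f} mm"
                f" > {max_abs_translation}"
            )
        max_rot_deg = np.rad2deg(np.abs(trace.rotations)).max()
        if max_rot_deg > max_abs_rotation:
            reasons.append(f"max |rotation| {max_rot_deg:.3f} deg > {max_abs_rotation}")
        (excluded if reasons else kept).append(fd.subject_id)
        rows.append(
            {
                "subject": fd.subject_id,
                "mean_fd": fd.mean_fd,
                "excluded": bool(reasons),
                "reason": "; ".join(reasons),
            }
        )
    return kept, excluded, pd.DataFrame(rows)
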