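"""Synthetic resting-state cohort generator.

Emulates a two-group study (patients vs. matched controls) with exactly the
statistical structure the downstream analysis assumes: spatially smoothed
Gaussian BOLD noise on a common grid, a single shared latent "global"
signal injected into a spherical hub cluster with a group-dependent
coupling weight, a gray-matter probability map, rigid-body motion traces
(a configurable number of high-motion subjects per group), and a clinical
table whose variables carry planted Pearson correlations with the
subjects' true hub coupling.

Every draw flows from one integer seed through a ``numpy`` SeedSequence
fan-out, so identical specs produce bit-identical cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.stats import truncnorm

from .gfc import VolumeSeries
from .motion import MotionTrace

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: plausible clinical means/sds used purely to put synthetic variables on a
#: realistic scale (serum lipids in mmol/L, symptom scales, RBANS and Stroop
#: scores); the values themselves are synthetic, not claims about any cohort.
CLINICAL_SCALE = {
    "TG": (1.06, 0.92),
    "CHOL": (3.88, 1.11),
    "HDL_C": (1.27, 0.40),
    "LDL_C": (2.41, 0.81),
    "glucose": (4.09, 1.04),
    "HAMD17": (22.14, 6.95),
    "HAMA14": (25.54, 8.20),
    "YMRS": (9.26, 6.84),
    "RBANS_coding": (56.97, 10.52),
    "RBANS_immediate_memory": (40.76, 10.69),
    "RBANS_delayed_memory": (48.21, 10.27),
    "stroop_word": (96.30, 20.84),
    "stroop_color": (68.42, 18.24),
    "stroop_color_word": (41.42, 8.81),
    "illness_duration": (1.8, 1.2),
}

DEFAULT_CLINICAL_EFFECTS = (
    ("TG", 0.45),
    ("LDL_C", 0.42),
    ("RBANS_coding", -0.40),
    ("stroop_color", -0.47),
)

#: 3 mm isotropic grid with an MNI-like origin.
DEFAULT_AFFINE = np.array(
    [
        [3.0, 0.0, 0.0, -24.0],
        [0.0, 3.0, 0.0, -30.0],
        [0.0, 0.0, 3.0, -18.0],
        [0.0, 0.0, 0.0, 1.0],
    ]
)


@dataclass(frozen=True)
class CohortSpec:
    """Full parameterisation of a synthetic study.

    ``coupling_patient`` / ``coupling_control`` are the group means of the
    unitless weight with which the shared latent signal enters hub voxels;
    per-subject weights are Normal(group mean, ``coupling_sd``) truncated
    at 0.  ``n_high_motion`` is the number of subjects *per group* whose
    motion trace exceeds the default exclusion limits.
    ``clinical_effects`` lists (variable, target Pearson r with the true
    coupling, among patients).
    """

    n_patients: int = 35
    n_controls: int = 37
    grid_shape: tuple[int, int, int] = (16, 16, 16)
    n_frames: int = 150
    tr: float = 2.0
    gm_fraction: float = 0.55
    hub_center: tuple[int, int, int] = (8, 8, 8)
    hub_radius: float = 3.5
    coupling_patient: float = 0.25
    coupling_control: float = 0.05
    coupling_sd: float = 0.10
    noise_sd: float = 1.0
    smooth_fwhm: float = 2.0
    n_high_motion: int = 0
    clinical_effects: tuple[tuple[str, float], ...] = DEFAULT_CLINICAL_EFFECTS
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_patients", "n_controls", "n_frames"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_high_motion < 0:
            raise ValueError("n_high_motion must be non-negative")
        if self.n_high_motion >= min(self.n_patients, self.n_controls):
            raise ValueError("n_high_motion must be smaller than each group")
        if not (0 < self.gm_fraction <= 1):
            raise ValueError("gm_fraction must lie in (0, 1]")
        if self.coupling_patient < 0 or self.coupling_control < 0:
            raise ValueError("coupling weights must be >= 0")
        if self.coupling_sd < 0 or self.noise_sd <= 0:
            raise ValueError("coupling_sd must be >= 0 and noise_sd > 0")
        center = np.asarray(self.hub_center, dtype=float)
        shape = np.asarray(self.grid_shape, dtype=float)
        if np.any(center - self.hub_radius < 0) or np.any(
            center + self.hub_radius > shape - 1
        ):
            raise ValueError("hub sphere must lie fully inside the grid")
        for name, r in self.clinical_effects:
            if not abs(r) < 1:
                raise ValueError(f"|target r| for {name!r} must be < 1")
            if name not in CLINICAL_SCALE:
                raise ValueError(f"unknown clinical variable {name!r}")


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery tests."""

    hub_voxels: np.ndarray  # (k, 3)
    coupling: dict[str, float]  # subject id -> true coupling weight
    planted_r: dict[str, float]  # clinical variable -> target r
    high_motion_ids: list[str] = field(default_factory=list)

    def hub_voxel_set(self) -> set[tuple[int, int, int]]:
        return {tuple(int(c) for c in v) for v in self.hub_voxels}


def _hub_voxels(spec: CohortSpec) -> np.ndarray:
    grid = np.indices(spec.grid_shape).reshape(3, -1).T
    d2 = ((grid - np.asarray(spec.hub_center)) ** 2).sum(axis=1)
    return grid[d2 <= spec.hub_radius**2]


def _gm_probability_map(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Centered ball of gray matter covering ``gm_fraction`` of the grid.

    Member voxels get probabilities in (0.25, 0.95] (> 0.2), the rest in
    [0, 0.2]; the membership ordering (distance from grid center, row-major
    tie-break) is deterministic.
    """
    shape = np.asarray(spec.grid_shape)
    n_total = int(np.prod(shape))
    n_gm = max(1, int(round(spec.gm_fraction * n_total)))
    grid = np.indices(spec.grid_shape).reshape(3, -1).T
    center = (shape - 1) / 2.0
    d2 = ((grid - center) ** 2).sum(axis=1)
    order = np.lexsort((np.arange(n_total), d2))  # distance, then row-major
    prob = np.empty(n_total)
    inside = order[:n_gm]
    outside = order[n_gm:]
    prob[inside] = 0.25 + 0.70 * rng.random(n_gm)
    prob[outside] = 0.20 * rng.random(len(outside))
    prob_vol = prob.reshape(spec.grid_shape)
    hub = _hub_voxels(spec)
    if np.any(prob_vol[tuple(hub.T)] <= 0.2):
        raise ValueError(
            "hub sphere is not fully inside the gray-matter region; "
            "increase gm_fraction or move hub_center toward the grid center"
        )
    return prob_vol


def _subject_series(
    spec: CohortSpec,
    coupling: float,
    hub: np.ndarray,
    rng: np.random.Generator,
    subject_id: str,
) -> VolumeSeries:
    noise = rng.normal(0.0, spec.noise_sd, size=(*spec.grid_shape, spec.n_frames))
    sigma = spec.smooth_fwhm * FWHM_TO_SIGMA
    data = gaussian_filter(noise, sigma=(sigma, sigma, sigma, 0.0))
    latent = rng.normal(0.0, 1.0, size=spec.n_frames)
    # unit *sample* variance so `coupling` is the exact realized amplitude
    latent = (latent - latent.mean()) / latent.std()
    data[tuple(hub.T)] += coupling * latent
    return VolumeSeries(
        data=data.astype(np.float32),
        affine=DEFAULT_AFFINE,
        tr=spec.tr,
        subject_id=subject_id,
    )


def _draw_coupling(mean: float, sd: float, rng: np.random.Generator) -> float:
    if sd == 0:
        return mean
    a = (0.0 - mean) / sd  # truncation at zero
    return float(truncnorm.rvs(a, np.inf, loc=mean, scale=sd, random_state=rng))


def _motion_trace(
    spec: CohortSpec, high_motion: bool, rng: np.random.Generator, subject_id: str
) -> MotionTrace:
    T = spec.n_frames
    steps = np.column_stack(
        [
            rng.normal(0.0, 0.008, size=(T, 3)),  # translation steps, mm
            rng.normal(0.0, 5e-5, size=(T, 3)),  # rotation steps, rad
        ]
    )
    steps[0] = 0.0
    if high_motion:
        steps[:, :3] *= 25.0  # mean FD well beyond 0.2 mm
        spike = rng.integers(T // 4, 3 * T // 4)
        steps[spike, 0] += 3.0  # unambiguous > 2 mm translation excursion
    return MotionTrace(params=np.cumsum(steps, axis=0), subject_id=subject_id)


def _planted_variable(
    target_r: float, coupling_z: np.ndarray, scale: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """x = r * z + sqrt(1 - r^2) * noise, affinely rescaled to (mean, sd)."""
    n = len(coupling_z)
    raw = target_r * coupling_z + np.sqrt(1.0 - target_r**2) * rng.normal(size=n)
    mean, sd = scale
    sd_raw = raw.std()
    if sd_raw < 1e-12:
        return np.full(n, mean)
    return mean + sd * (raw - raw.mean()) / sd_raw


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[VolumeSeries], np.ndarray, list[MotionTrace], pd.DataFrame, GroundTruth]:
    """Generate a full synthetic study.

    Returns ``(volumes, gm_probability_map, motion_traces, subjects, truth)``
    with one volume/trace per subject (patients first, ids ``patient01``...,
    ``control01``...), the gray-matter probability volume, the subject
    table (clinical variables for patients only), and the ground truth.
    """
    ss = np.random.SeedSequence(spec.seed)
    (
        rng_gm, rng_couple, rng_clin, rng_motion_pick, rng_demo,
    ) = [np.random.default_rng(s) for s in ss.spawn(5)]
    subj_streams = ss.spawn(spec.n_patients + spec.n_controls)

    hub = _hub_voxels(spec)
    gm_prob = _gm_probability_map(spec, rng_gm)

    ids = [f"patient{i + 1:02d}" for i in range(spec.n_patients)] + [
        f"control{i + 1:02d}" for i in range(spec.n_controls)
    ]
    groups = ["patient"] * spec.n_patients + ["control"] * spec.n_controls
    coupling_mean = {
        "patient": spec.coupling_patient, "control": spec.coupling_control,
    }
    coupling = {
        sid: _draw_coupling(coupling_mean[grp], spec.coupling_sd, rng_couple)
        for sid, grp in zip(ids, groups)
    }

    high_motion_ids: list[str] = []
    for grp_ids in (ids[: spec.n_patients], ids[spec.n_patients:]):
        pick = rng_motion_pick.choice(
            len(grp_ids), size=spec.n_high_motion, replace=False
        )
        high_motion_ids.extend(grp_ids[i] for i in sorted(pick))

    volumes, traces = [], []
    for sid, stream in zip(ids, subj_streams):
        rng_s = np.random.default_rng(stream)
        volumes.append(_subject_series(spec, coupling[sid], hub, rng_s, sid))
        traces.append(_motion_trace(spec, sid in high_motion_ids, rng_s, sid))

    subjects = _subject_table(spec, ids, groups, coupling, rng_demo, rng_clin)
    truth = GroundTruth(
        hub_voxels=hub,
        coupling=coupling,
        planted_r=dict(spec.clinical_effects),
        high_motion_ids=high_motion_ids,
    )
    return volumes, gm_prob, traces, subjects, truth


def _subject_table(
    spec: CohortSpec,
    ids: list[str],
    groups: list[str],
    coupling: dict[str, float],
    rng_demo: np.random.Generator,
    rng_clin: np.random.Generator,
) -> pd.DataFrame:
    n_pat, n_con = spec.n_patients, spec.n_controls
    is_patient = np.array([g == "patient" for g in groups])

    age = np.where(
        is_patient,
        rng_demo.normal(20.7, 2.5, size=len(ids)),
        rng_demo.normal(21.3, 3.2, size=len(ids)),
    ).round(1)
    education = np.where(
        is_patient,
        rng_demo.normal(13.9, 2.0, size=len(ids)),
        rng_demo.normal(15.0, 2.1, size=len(ids)),
    ).round(1)
    sex = np.where(
        is_patient,
        rng_demo.random(len(ids)) < 11 / 35,  # male fraction, patients
        rng_demo.random(len(ids)) < 17 / 37,  # male fraction, controls
    ).astype(int)

    table = pd.DataFrame(
        {"subject": ids, "group": groups, "age": age, "sex": sex,
         "education": education}
    )

    effects = dict(spec.clinical_effects)
    pat_coupling = np.array([coupling[s] for s, p in zip(ids, is_patient) if p])
    sd = pat_coupling.std()
    coupling_z = (
        (pat_coupling - pat_coupling.mean()) / sd if sd > 1e-12
        else np.zeros(n_pat)
    )
    for name, scale in CLINICAL_SCALE.items():
        # Gaussian on the (mean, sd) scale; no truncation/folding, which
        # would distort the planted correlation for low-mean variables
        vals = _planted_variable(effects.get(name, 0.0), coupling_z, scale, rng_clin)
        col = np.full(len(ids), np.nan)
        col[is_patient] = np.round(vals, 2)
        table[name] = col
    return table


# ---------------------------------------------------------------------------
# writers

def write_cohort(
    out_dir,
    volumes: list[VolumeSeries],
    gm_prob: np.ndarray,
    traces: list[MotionTrace],
    subjects: pd.DataFrame,
    truth: GroundTruth,
) -> dict[str, object]:
    """Persist a generated cohort: NIfTI volumes, gm map, rp_*.txt traces,
    subjects.tsv and ground_truth.json.  Returns the path manifest."""
    import nibabel as nib

    out = Path(out_dir)
    bold_dir = out / "bold"
    motion_dir = out / "motion"
    bold_dir.mkdir(parents=True, exist_ok=True)
    motion_dir.mkdir(parents=True, exist_ok=True)

    paths: dict[str, object] = {"bold": {}, "motion": {}}
    for vs in volumes:
        p = bold_dir / f"{vs.subject_id}.nii.gz"
        img = nib.Nifti1Image(vs.data, vs.affine)
        img.header.set_zooms((*np.abs(np.diag(vs.affine)[:3]), vs.tr))
        nib.save(img, p)
        paths["bold"][vs.subject_id] = str(p)
    gm_path = out / "gm_probability.nii.gz"
    nib.save(nib.Nifti1Image(gm_prob.astype(np.float32), volumes[0].affine), gm_path)
    paths["gm_probability"] = str(gm_path)

    for tr in traces:
        p = motion_dir / f"rp_{tr.subject_id}.txt"
        np.savetxt(p, tr.params, fmt="%.8f")
        paths["motion"][tr.subject_id] = str(p)

    subj_path = out / "subjects.tsv"
    subjects.to_csv(subj_path, sep="\t", index=False)
    paths["subjects"] = str(subj_path)

    truth_path = out / "ground_truth.json"
    truth_path.write_text(
        json.dumps(
            {
                "hub_voxels": truth.hub_voxels.tolist(),
                "coupling": truth.coupling,
                "planted_r": truth.planted_r,
                "high_motion_ids": truth.high_motion_ids,
            },
            indent=2,
        )
    )
    paths["ground_truth"] = str(truth_path)
    return paths


def spec_from_dict(d: dict) -> CohortSpec:
    """Build a CohortSpec from a (YAML-loaded) mapping."""
    d = dict(d)
    for key in ("grid_shape", "hub_center"):
        if key in d:
            d[key] = tuple(d[key])
    if "clinical_effects" in d:
        d["clinical_effects"] = tuple(
            (str(name), float(r)) for name, r in d["clinical_effects"]
        )
    return CohortSpec(**d)


def spec_to_dict(spec: CohortSpec) -> dict:
    d = asdict(spec)
    d["grid_shape"] = list(spec.grid_shape)
    d["hub_center"] = list(spec.hub_center)
    d["clinical_effects"] = [[n, r] for n, r in spec.clinical_effects]
    return d
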