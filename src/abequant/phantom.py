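"""Synthetic T1-like phantom cohorts for the neonatal hyperbilirubinemia study design.

The generator emulates a two-group cohort of neonates with hyperbilirubinemia:
an acute bilirubin encephalopathy (ABE) group and a non-ABE group.  Each
subject carries clinical covariates drawn from group-specific normals and a
pair of ground-truth normalized intensity ratios (globus pallidus / white
matter and subthalamic nucleus / white matter).  Subjects are rendered as
multi-slice 2D axial "T1-weighted" stacks: a brain modeled as an ellipse of
white-matter-level tissue, with bilateral GP and STN ellipses and an anterior
subcortical WM reference region drawn on the three central slices.

Two sources of variation are kept deliberately separate:

* between-subject (biological) variation lives in :func:`sample_cohort`
  (normal draws of the true ratios), and
* voxelwise measurement noise lives in :func:`render_subject`
  (additive Gaussian, SD proportional to the regional mean).

This separation makes parameter-recovery experiments well-posed: extracted
ratios converge to the configured subject-level distribution as the voxel
noise goes to zero.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from skimage.draw import ellipse

from .errors import ConfigurationError, IntegrityError, RenderingError

ABE = "ABE"
NON_ABE = "non-ABE"
GROUPS = (ABE, NON_ABE)

#: mask code book (fixed)
BACKGROUND, WM, GP, STN = 0, 1, 2, 3
MASK_CODES = (BACKGROUND, WM, GP, STN)

#: minimum pixels any ROI code must occupy on an ROI-bearing slice
MIN_ROI_PIXELS = 20

# Default per-group covariate distributions: mean, SD (or proportion for sex).
# Units: age in days, weight in kg, gestational age in weeks, total serum
# bilirubin in umol/L, albumin in g/L.
_DEFAULT_COVARIATES = {
    ABE: {
        "age_days": (9.83, 3.05),
        "weight_kg": (3.21, 0.48),
        "gestational_age_weeks": (38.47, 1.58),
        "tsb_umol_per_l": (369.11, 114.78),
        "albumin_g_per_l": (38.34, 2.98),
        "male_proportion": 29 / 47,
    },
    NON_ABE: {
        "age_days": (12.15, 5.28),
        "weight_kg": (3.36, 0.43),
        "gestational_age_weeks": (38.38, 1.47),
        "tsb_umol_per_l": (326.13, 79.20),
        "albumin_g_per_l": (38.45, 3.21),
        "male_proportion": 23 / 32,
    },
}

# Physiologic clamps applied after each normal draw; the study design admits
# chronological ages of 1-18 days only.
_COVARIATE_CLAMPS = {
    "age_days": (1.0, 18.0),
    "weight_kg": (1.5, 6.0),
    "gestational_age_weeks": (28.0, 44.0),
    "tsb_umol_per_l": (50.0, 800.0),
    "albumin_g_per_l": (20.0, 60.0),
}

_DEFAULT_RATIOS = {
    ABE: {"GP": (1.39, 0.06), "STN": (1.47, 0.09)},
    NON_ABE: {"GP": (1.33, 0.06), "STN": (1.42, 0.07)},
}


def _check_mean_sd(name: str, mean: float, sd: float) -> None:
    if not (math.isfinite(mean) and math.isfinite(sd)):
        raise ConfigurationError(f"{name}: non-finite parameter ({mean}, {sd})")
    if sd < 0:
        raise ConfigurationError(f"{name}: negative SD {sd}")


@dataclass
class PhantomConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the study conditions: 47 ABE vs 32 non-ABE subjects,
    GP ratios 1.39±0.06 vs 1.33±0.06, STN ratios 1.47±0.09 vs 1.42±0.07,
    covariates per the cohort summary table, and 18 axial slices per stack.
    """

    n_pos: int = 47
    n_neg: int = 32
    ratio_params: dict = field(default_factory=lambda: json.loads(json.dumps(_DEFAULT_RATIOS)))
    wm_mean: float = 100.0
    noise_cv: float = 0.02
    n_slices: int = 18
    slice_shape: tuple[int, int] = (128, 128)
    covariate_params: dict = field(
        default_factory=lambda: json.loads(json.dumps(_DEFAULT_COVARIATES))
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ConfigurationError(
                f"both groups need at least one subject (got {self.n_pos}/{self.n_neg})"
            )
        if not math.isfinite(self.wm_mean) or self.wm_mean <= 0:
            raise ConfigurationError(f"wm_mean must be positive, got {self.wm_mean}")
        if not math.isfinite(self.noise_cv) or self.noise_cv < 0:
            raise ConfigurationError(f"noise_cv must be >= 0, got {self.noise_cv}")
        if self.n_slices < 1:
            raise ConfigurationError(f"n_slices must be >= 1, got {self.n_slices}")
        self.slice_shape = tuple(int(s) for s in self.slice_shape)
        if len(self.slice_shape) != 2 or any(s < 8 for s in self.slice_shape):
            raise ConfigurationError(f"slice_shape must be 2D and >= 8, got {self.slice_shape}")
        for group in GROUPS:
            for region in ("GP", "STN"):
                mean, sd = self.ratio_params[group][region]
                _check_mean_sd(f"ratio_params[{group}][{region}]", mean, sd)
                if mean <= 0:
                    raise ConfigurationError(f"ratio mean must be > 0, got {mean}")
            cov = self.covariate_params[group]
            for key, val in cov.items():
                if key == "male_proportion":
                    if not 0.0 <= val <= 1.0:
                        raise ConfigurationError(f"male_proportion out of [0,1]: {val}")
                else:
                    _check_mean_sd(f"covariate_params[{group}][{key}]", *val)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["slice_shape"] = list(self.slice_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        d = dict(d)
        if "slice_shape" in d:
            d["slice_shape"] = tuple(d["slice_shape"])
        return cls(**d)


@dataclass
class SubjectRecord:
    """One synthetic neonate: group label, clinical covariates, true ratios."""

    subject_id: str
    group: str
    sex: str
    age_days: float
    weight_kg: float
    gestational_age_weeks: float
    tsb_umol_per_l: float
    albumin_g_per_l: float
    bind_score: int  # 0-9 clinical severity score; metadata only
    true_gp_ratio: float
    true_stn_ratio: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ConfigurationError(f"unknown group {self.group!r}")
        if self.true_gp_ratio <= 0 or self.true_stn_ratio <= 0:
            raise ConfigurationError("true ratios must be positive")


@dataclass
class LabeledSlice:
    """A 2D intensity grid plus an integer ROI mask (0 bg, 1 WM, 2 GP, 3 STN)."""

    subject_id: str
    slice_index: int
    intensity: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.mask = np.asarray(self.mask, dtype=np.int16)
        if self.intensity.shape != self.mask.shape:
            raise IntegrityError(
                f"intensity {self.intensity.shape} and mask {self.mask.shape} shapes differ"
            )
        codes = np.unique(self.mask)
        if not np.isin(codes, MASK_CODES).all():
            raise IntegrityError(f"mask contains codes outside {MASK_CODES}: {codes}")


def _clamp(value: float, key: str) -> float:
    lo, hi = _COVARIATE_CLAMPS[key]
    return float(min(max(value, lo), hi))


def sample_cohort(config: PhantomConfig, rng: np.random.Generator | None = None) -> list[SubjectRecord]:
    """Draw ``n_pos + n_neg`` subject records from the configured distributions.

    True GP/STN ratios are drawn independently from the group's normal
    distributions; covariates from their group normals (sex from a Bernoulli
    on the male proportion) and clamped to physiologic ranges.  Reproducible
    under a fixed ``config.seed`` (or an explicit ``rng``).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    records: list[SubjectRecord] = []
    counts = {ABE: config.n_pos, NON_ABE: config.n_neg}
    idx = 0
    # BIND severity metadata: mild scores more common than advanced ones.
    bind_scores = np.arange(1, 10)
    bind_weights = np.array([3, 3, 3, 2, 2, 2, 1, 1, 1], dtype=float)
    bind_weights /= bind_weights.sum()
    for group in GROUPS:
        ratio = config.ratio_params[group]
        cov = config.covariate_params[group]
        for _ in range(counts[group]):
            idx += 1
            gp = max(rng.normal(*ratio["GP"]), 0.05)
            stn = max(rng.normal(*ratio["STN"]), 0.05)
            sex = "M" if rng.random() < cov["male_proportion"] else "F"
            bind = int(rng.choice(bind_scores, p=bind_weights)) if group == ABE else 0
            records.append(
                SubjectRecord(
                    subject_id=f"S{idx:04d}",
                    group=group,
                    sex=sex,
                    age_days=_clamp(rng.normal(*cov["age_days"]), "age_days"),
                    weight_kg=_clamp(rng.normal(*cov["weight_kg"]), "weight_kg"),
                    gestational_age_weeks=_clamp(
                        rng.normal(*cov["gestational_age_weeks"]), "gestational_age_weeks"
                    ),
                    tsb_umol_per_l=_clamp(rng.normal(*cov["tsb_umol_per_l"]), "tsb_umol_per_l"),
                    albumin_g_per_l=_clamp(rng.normal(*cov["albumin_g_per_l"]), "albumin_g_per_l"),
                    bind_score=bind,
                    true_gp_ratio=float(gp),
                    true_stn_ratio=float(stn),
                )
            )
    return records


# --- slice geometry -------------------------------------------------------
# ROI placement is expressed in fractions of the grid so the phantom scales
# with slice_shape.  Anterior = low row index.  Bilateral structures are
# pooled into a single mask code per region.

_BRAIN = ((0.50, 0.50), (0.42, 0.36))
_WM_ROI = ((0.27, 0.50), (0.06, 0.10))  # anterior subcortical WM reference
_GP_ROIS = (((0.52, 0.36), (0.055, 0.050)), ((0.52, 0.64), (0.055, 0.050)))
_STN_ROIS = (((0.67, 0.40), (0.040, 0.035)), ((0.67, 0.60), (0.040, 0.035)))


def _ellipse_mask(shape: tuple[int, int], center_frac, semi_frac) -> np.ndarray:
    h, w = shape
    rr, cc = ellipse(center_frac[0] * h, center_frac[1] * w, semi_frac[0] * h, semi_frac[1] * w, shape=shape)
    m = np.zeros(shape, dtype=bool)
    m[rr, cc] = True
    return m


def slice_geometry(shape: tuple[int, int]) -> dict[str, np.ndarray]:
    """Boolean masks (brain, wm_roi, gp, stn) for an ROI-bearing slice.

    Raises :class:`RenderingError` if the grid is too small for every ROI
    code to occupy at least ``MIN_ROI_PIXELS`` pixels, or if ROIs collide.
    """
    brain = _ellipse_mask(shape, *_BRAIN)
    wm_roi = _ellipse_mask(shape, *_WM_ROI)
    gp = np.zeros(shape, dtype=bool)
    for c, s in _GP_ROIS:
        gp |= _ellipse_mask(shape, c, s)
    stn = np.zeros(shape, dtype=bool)
    for c, s in _STN_ROIS:
        stn |= _ellipse_mask(shape, c, s)
    for name, m in (("WM", wm_roi), ("GP", gp), ("STN", stn)):
        if m.sum() < MIN_ROI_PIXELS:
            raise RenderingError(
                f"slice_shape {shape} too small: {name} ROI has {int(m.sum())} px "
                f"(need >= {MIN_ROI_PIXELS})"
            )
        if not (m <= brain).all():
            raise RenderingError(f"{name} ROI exceeds the brain ellipse at shape {shape}")
    if (wm_roi & gp).any() or (wm_roi & stn).any() or (gp & stn).any():
        raise RenderingError(f"ROIs overlap at shape {shape}")
    return {"brain": brain, "wm_roi": wm_roi, "gp": gp, "stn": stn}


def roi_slice_indices(n_slices: int) -> list[int]:
    """Indices of the (up to 3) central slices that carry the ROIs."""
    center = n_slices // 2
    lo = max(0, center - 1)
    return list(range(lo, min(n_slices, lo + 3)))


def render_subject(
    record: SubjectRecord,
    config: PhantomConfig,
    rng: np.random.Generator | None = None,
) -> list[LabeledSlice]:
    """Render a subject's multi-slice stack.

    Regional mean intensity before noise is ``wm_mean * true ratio`` in
    GP/STN and ``wm_mean`` in brain tissue; independent zero-mean Gaussian
    noise with SD ``noise_cv * regional mean`` is added voxelwise, and
    intensities are clipped at 0.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    geom = slice_geometry(config.slice_shape)
    roi_slices = set(roi_slice_indices(config.n_slices))
    slices: list[LabeledSlice] = []
    for k in range(config.n_slices):
        clean = np.zeros(config.slice_shape, dtype=float)
        clean[geom["brain"]] = config.wm_mean
        mask = np.zeros(config.slice_shape, dtype=np.int16)
        if k in roi_slices:
            clean[geom["gp"]] = config.wm_mean * record.true_gp_ratio
            clean[geom["stn"]] = config.wm_mean * record.true_stn_ratio
            mask[geom["wm_roi"]] = WM
            mask[geom["gp"]] = GP
            mask[geom["stn"]] = STN
        if config.noise_cv > 0:
            noisy = clean + rng.normal(size=clean.shape) * (config.noise_cv * clean)
            intensity = np.clip(noisy, 0.0, None)
        else:
            intensity = clean
        slices.append(LabeledSlice(record.subject_id, k, intensity, mask))
    return slices


def generate_cohort(
    config: PhantomConfig,
) -> tuple[list[SubjectRecord], dict[str, list[LabeledSlice]]]:
    """Sample a cohort and render every subject; fully seeded by ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    records = sample_cohort(config, rng)
    stacks = {r.subject_id: render_subject(r, config, rng) for r in records}
    return records, stacks


def records_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    # post-menstrual age in weeks: gestational age + chronological age
    df["pma_weeks"] = df["gestational_age_weeks"] + df["age_days"] / 7.0
    return df


def write_dataset(
    stacks: dict[str, list[LabeledSlice]],
    records: list[SubjectRecord],
    directory: str | Path,
    config: PhantomConfig | None = None,
) -> dict:
    """Write one NIfTI image + mask volume per subject, a cohort CSV, a manifest.

    Returns the manifest dict (also written as ``manifest.json``).
    """
    directory = Path(directory)
    record_ids = {r.subject_id for r in records}
    if record_ids != set(stacks):
        raise IntegrityError(
            f"subject ids mismatch between records and stacks: "
            f"{sorted(record_ids ^ set(stacks))[:5]}..."
        )
    directory.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    files = {}
    for r in records:
        stack = sorted(stacks[r.subject_id], key=lambda s: s.slice_index)
        vol = np.stack([s.intensity for s in stack], axis=-1).astype(np.float32)
        msk = np.stack([s.mask for s in stack], axis=-1).astype(np.int16)
        img_path = directory / f"{r.subject_id}_t1.nii.gz"
        msk_path = directory / f"{r.subject_id}_mask.nii.gz"
        nib.save(nib.Nifti1Image(vol, affine), img_path)
        nib.save(nib.Nifti1Image(msk, affine), msk_path)
        files[r.subject_id] = {"image": img_path.name, "mask": msk_path.name}
    table_path = directory / "cohort.csv"
    records_to_frame(records).to_csv(table_path, index=False)
    manifest = {
        "cohort_table": table_path.name,
        "files": files,
        "seed": None if config is None else config.seed,
        "config": None if config is None else config.to_dict(),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def read_subject_stack(directory: str | Path, subject_id: str) -> list[LabeledSlice]:
    """Load one subject's image+mask volumes back into :class:`LabeledSlice` objects."""
    directory = Path(directory)
    img_path = directory / f"{subject_id}_t1.nii.gz"
    msk_path = directory / f"{subject_id}_mask.nii.gz"
    if not img_path.exists() or not msk_path.exists():
        raise IntegrityError(f"missing image or mask volume for {subject_id}")
    vol = np.asarray(nib.load(img_path).dataobj, dtype=np.float32)
    msk = np.asarray(nib.load(msk_path).dataobj, dtype=np.int16)
    if vol.shape != msk.shape:
        raise IntegrityError(f"{subject_id}: image/mask shape mismatch")
    return [
        LabeledSlice(subject_id, k, vol[..., k].astype(float), msk[..., k])
        for k in range(vol.shape[-1])
    ]


def read_cohort_table(directory: str | Path) -> pd.DataFrame:
    path = Path(directory) / "cohort.csv"
    if not path.exists():
        raise IntegrityError(f"no cohort.csv under {directory}")
    return pd.read_csv(path)
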