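"""ROI intensity extraction and the normalized T1 scores.

The semi-quantitative scores are intensity ratios referenced to anterior
subcortical white matter, computed on the single slice covering the largest
combined GP+STN area:

    GP_norm  = mean(GP)  / mean(WM)
    STN_norm = mean(STN) / mean(WM)

Being ratios, they are invariant to any global rescaling of the image, which
is what makes them comparable across scanners and acquisitions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyRegionError, IntegrityError, SelectionError
from .phantom import GP, STN, WM, LabeledSlice, read_cohort_table, read_subject_stack

_REGION_NAMES = {WM: "WM", GP: "GP", STN: "STN"}


@dataclass
class FeatureRow:
    """Per-subject normalized intensities with the true group label."""

    subject_id: str
    gp_norm: float
    stn_norm: float
    label: str
    selected_slice_index: int


def roi_mean(slc: LabeledSlice, region_code: int) -> float:
    """Arithmetic mean intensity over pixels whose mask equals ``region_code``.

    An absent region is a hard :class:`EmptyRegionError`, never a silent zero.
    """
    if region_code not in _REGION_NAMES:
        raise ValueError(f"region_code must be one of {sorted(_REGION_NAMES)}")
    sel = slc.mask == region_code
    if not sel.any():
        raise EmptyRegionError(
            f"region {_REGION_NAMES[region_code]} absent from mask "
            f"(subject {slc.subject_id}, slice {slc.slice_index})"
        )
    return float(slc.intensity[sel].mean())


def select_slice(stack: list[LabeledSlice]) -> LabeledSlice:
    """The slice with the largest combined GP+STN pixel count.

    Ties break to the lowest slice index; a stack with no GP/STN pixels at
    all raises :class:`SelectionError`.
    """
    if not stack:
        raise SelectionError("empty stack")
    best: LabeledSlice | None = None
    best_area = 0
    for slc in sorted(stack, key=lambda s: s.slice_index):
        area = int(((slc.mask == GP) | (slc.mask == STN)).sum())
        if area > best_area:
            best, best_area = slc, area
    if best is None:
        raise SelectionError("no slice contains GP or STN pixels")
    return best


def normalized_intensities(slc: LabeledSlice) -> tuple[float, float]:
    """(GP_norm, STN_norm) for one labeled slice.

    Scale-invariant: multiplying the whole intensity grid by a positive
    constant leaves both ratios unchanged.
    """
    wm = roi_mean(slc, WM)
    if wm == 0:
        raise ZeroDivisionError(
            f"WM reference mean is zero (subject {slc.subject_id}, slice {slc.slice_index})"
        )
    return roi_mean(slc, GP) / wm, roi_mean(slc, STN) / wm


def feature_row(stack: list[LabeledSlice], label: str) -> FeatureRow:
    slc = select_slice(stack)
    gp_norm, stn_norm = normalized_intensities(slc)
    return FeatureRow(slc.subject_id, gp_norm, stn_norm, label, slc.slice_index)


def build_feature_table(directory: str | Path) -> pd.DataFrame:
    """One row per subject from a written phantom dataset, in cohort-table order."""
    df = read_cohort_table(directory)
    if "subject_id" not in df.columns or "group" not in df.columns:
        raise IntegrityError("cohort table lacks subject_id/group columns")
    rows = []
    for _, rec in df.iterrows():
        stack = read_subject_stack(directory, rec["subject_id"])
        rows.append(feature_row(stack, rec["group"]))
    return pd.DataFrame([dataclasses.asdict(r) for r in rows])


def feature_table_from_stacks(
    stacks: dict[str, list[LabeledSlice]], labels: dict[str, str]
) -> pd.DataFrame:
    """In-memory variant of :func:`build_feature_table` (same row contract)."""
    missing = set(stacks) - set(labels)
    if missing:
        raise IntegrityError(f"labels missing for subjects {sorted(missing)[:5]}")
    rows = [feature_row(stacks[sid], labels[sid]) for sid in stacks]
    return pd.DataFrame([dataclasses.asdict(r) for r in rows])
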