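"""ROI-level measurements: parameter means, lesion size, delta parameters.

Mirrors a radiology reading workflow: mean D, D* and f over a lesion ROI
(averaged over triplicate re-measurements), maximum transverse diameter,
slice-by-slice lesion volume, pre-minus-mid parameter changes and size
shrinkage percentages, and cutoff-based response classification.

Sign convention, used everywhere: ``delta_x = x_pre - x_mid``, so a
parameter that rises under therapy has a negative delta; shrinkage is
``100 * (pre - mid) / pre`` percent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .fitting import ParameterMaps
from .model import ValidationError

__all__ = [
    "PatientRecord",
    "TimepointMeasures",
    "DeltaRecord",
    "roi_summary",
    "max_diameter",
    "lesion_volume",
    "compute_deltas",
    "classify_by_cutoff",
    "records_to_cohort",
    "COHORT_COLUMNS",
]

logger = logging.getLogger(__name__)

#: CohortTable CSV schema; D/Dstar written in 1e-3 mm^2/s, f in percent.
COHORT_COLUMNS = ["id", "timepoint", "D", "Dstar", "f", "MD_mm", "V_mm3", "miller_payne", "pcr"]


@dataclass(frozen=True)
class TimepointMeasures:
    """ROI means and size at one scan timepoint (internal units)."""

    D: float          # mm^2/s
    D_star: float     # mm^2/s; NaN when unidentifiable
    f: float          # fraction
    MD: float         # maximum transverse diameter, mm
    V: float          # lesion volume, mm^3


@dataclass(frozen=True)
class PatientRecord:
    """One patient's pre-/mid-treatment measurements and pathology label.

    ``pcr`` marks a pathologic complete response, i.e. Miller-Payne grade 5
    (no residual invasive tumor); ``mid`` is None for patients who lacked
    the second scan.
    """

    id: str
    pre: TimepointMeasures
    mid: TimepointMeasures | None = None
    miller_payne: int | None = None
    pcr: bool | None = None

    def __post_init__(self) -> None:
        if self.miller_payne is not None:
            if not 1 <= self.miller_payne <= 5:
                raise ValidationError("miller_payne must be in 1..5")
            expected = self.miller_payne == 5
            if self.pcr is None:
                object.__setattr__(self, "pcr", expected)
            elif self.pcr != expected:
                raise ValidationError("pcr label inconsistent with Miller-Payne grade")


@dataclass(frozen=True)
class DeltaRecord:
    """Pre-minus-mid parameter changes and size shrinkage."""

    delta_D: float          # mm^2/s
    delta_Dstar: float      # mm^2/s
    delta_f: float          # percentage points
    shrink_MD_pct: float    # percent, <= 100
    shrink_V_pct: float     # percent, <= 100


def _jitter_roi(roi: np.ndarray, rng: np.random.Generator, p: float = 0.2) -> np.ndarray:
    """Randomly toggle boundary voxels to emulate a manual ROI re-draw."""
    inner = roi & ~ndimage.binary_erosion(roi)
    outer = ndimage.binary_dilation(roi) & ~roi
    out = roi.copy()
    out[inner] ^= rng.random(int(inner.sum())) < p
    out[outer] ^= rng.random(int(outer.sum())) < p
    return out if out.any() else roi


def roi_summary(
    maps: ParameterMaps,
    roi: np.ndarray,
    n_repeats: int = 3,
    rng: np.random.Generator | int | None = 0,
) -> tuple[float, float, float]:
    """Mean (D, D*, f) over an ROI, averaged over triplicate re-draws.

    Each repeat jitters the ROI boundary (seeded) before averaging,
    emulating a reader's independent re-measurements; ``n_repeats=1``
    disables the jitter.  D and f average over converged voxels; D* only
    over voxels where it was identifiable.  An ROI with no identifiable
    D* yields a NaN D* mean with a log notice.
    """
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != maps.shape:
        raise ValidationError("roi shape must match maps")
    if not (roi & maps.fit_mask).any():
        raise ValidationError("roi is empty within fitted voxels")
    rng = np.random.default_rng(rng)

    d_means, f_means, ds_means = [], [], []
    for rep in range(int(n_repeats)):
        r = roi if (rep == 0 or n_repeats == 1) else _jitter_roi(roi, rng)
        sel = r & maps.fit_mask
        if not sel.any():
            sel = roi & maps.fit_mask
        d_means.append(float(np.nanmean(maps.D[sel])))
        f_means.append(float(np.nanmean(maps.f[sel])))
        ds = maps.D_star[sel]
        ds = ds[np.isfinite(ds)]
        ds_means.append(float(ds.mean()) if ds.size else np.nan)
    ds_arr = np.asarray(ds_means)
    if np.all(np.isnan(ds_arr)):
        logger.warning("roi_summary: D* unidentifiable in every repeat; mean is NaN")
        ds_mean = float("nan")
    else:
        ds_mean = float(np.nanmean(ds_arr))
    return float(np.mean(d_means)), ds_mean, float(np.mean(f_means))


def max_diameter(mask: np.ndarray, voxel_size: tuple[float, float, float]) -> float:
    """Maximum transverse diameter in mm.

    Takes the largest pairwise distance between in-slice voxel centers,
    maximized over transverse (constant-z) slices.  A single-voxel mask is
    0 mm by the center-to-center convention.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValidationError("empty mask")
    dx, dy, _ = voxel_size
    best = 0.0
    for z in range(mask.shape[2]):
        pts = np.argwhere(mask[:, :, z]).astype(float)
        if len(pts) < 2:
            continue
        pts *= np.array([dx, dy])
        if len(pts) > 10:
            try:
                pts = pts[ConvexHull(pts).vertices]
            except QhullError:
                pass  # collinear points: brute force below
        best = max(best, float(pdist(pts).max()))
    return best


def lesion_volume(mask: np.ndarray, voxel_size: tuple[float, float, float]) -> float:
    """Lesion volume in mm^3: voxel count x in-plane area x slice spacing.

    An empty mask returns 0 with a warning (a vanished lesion, not an
    error).
    """
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        warnings.warn("lesion_volume: empty mask, volume is 0", stacklevel=2)
        return 0.0
    dx, dy, dz = voxel_size
    return n * dx * dy * dz


def compute_deltas(record: PatientRecord) -> DeltaRecord | None:
    """Pre-minus-mid deltas for one patient; None if the mid scan is missing.

    Patients without the second scan drop out of all mid-treatment
    analyses, mirroring cohort attrition.
    """
    if record.mid is None:
        return None
    pre, mid = record.pre, record.mid
    return DeltaRecord(
        delta_D=pre.D - mid.D,
        delta_Dstar=pre.D_star - mid.D_star,
        delta_f=100.0 * (pre.f - mid.f),
        shrink_MD_pct=100.0 * (pre.MD - mid.MD) / pre.MD,
        shrink_V_pct=100.0 * (pre.V - mid.V) / pre.V,
    )


def classify_by_cutoff(value: float, cutoff: float, direction: str = "le") -> bool:
    """Predict the positive class from a scalar score and a cutoff.

    ``direction='le'`` calls values at or below the cutoff positive,
    ``'ge'`` values at or above it.  Ties fall on the positive side.
    """
    if direction == "le":
        return value <= cutoff
    if direction == "ge":
        return value >= cutoff
    raise ValidationError(f"direction must be 'le' or 'ge', got {direction!r}")


def records_to_cohort(records: list[PatientRecord]) -> pd.DataFrame:
    """Serialize patient records to the long CohortTable layout.

    One row per patient and timepoint; D and D* are written in
    1e-3 mm^2/s and f in percent (the conventional reporting scales).
    """
    rows = []
    for rec in records:
        for tp_name, tp in (("pre", rec.pre), ("mid", rec.mid)):
            if tp is None:
                continue
            rows.append(
                {
                    "id": rec.id,
                    "timepoint": tp_name,
                    "D": tp.D * 1e3,
                    "Dstar": tp.D_star * 1e3,
                    "f": tp.f * 100.0,
                    "MD_mm": tp.MD,
                    "V_mm3": tp.V,
                    "miller_payne": rec.miller_payne,
                    "pcr": rec.pcr,
                }
            )
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)
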