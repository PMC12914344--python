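"""Dose-volume metrics, fractionation correction and dose-prediction error.

All doses are handled internally in cGy. The fractionation correction maps a
physical dose delivered in ``n`` fractions to its 2-Gy-per-fraction
equivalent (EQD2) under the linear-quadratic model,

    EQD2 = D * (d + alpha/beta) / (2 + alpha/beta),    d = D / n  [Gy],

with alpha/beta = 3 Gy by default (the standard late-rectal value). The
rectum-wall V6300cGy evaluated on the EQD2 map is the single dosimetric
covariate of the logistic complication model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .phantoms import Phantom

__all__ = [
    "DVHCurve",
    "FractionationParams",
    "compute_dvh",
    "v_at_dose",
    "d_max",
    "eqd2_transform",
    "v6300_rectum_wall",
    "mae",
]


@dataclass(frozen=True)
class FractionationParams:
    """Linear-quadratic fractionation parameters.

    alpha_beta is in Gy; reference dose per fraction is fixed at 2 Gy.
    """

    n_fractions: int = 25
    alpha_beta: float = 3.0
    reference_dose_per_fraction: float = 2.0

    def __post_init__(self) -> None:
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")
        if self.alpha_beta <= 0 or self.reference_dose_per_fraction <= 0:
            raise ValueError("alpha_beta and reference dose per fraction must be > 0")


@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram: % of ROI volume receiving >= dose."""

    dose_grid: np.ndarray  # cGy, ascending
    cumulative_relative_volume: np.ndarray  # percent

    def to_csv(self, path) -> None:
        arr = np.column_stack([self.dose_grid, self.cumulative_relative_volume])
        np.savetxt(path, arr, delimiter=",", header="dose_cGy,volume_percent",
                   comments="", fmt="%.6f")


def _grid_of(dose) -> np.ndarray:
    # accept either a DoseMap-like object or a bare array
    return np.asarray(getattr(dose, "grid", dose), dtype=float)


def _roi_doses(dose, mask, roi: str = "ROI") -> np.ndarray:
    grid = _grid_of(dose)
    mask = np.asarray(mask).astype(bool)
    if grid.shape != mask.shape:
        raise ValueError(f"dose grid {grid.shape} and mask {mask.shape} are not aligned")
    if not mask.any():
        raise ValueError(f"ROI {roi!r} is empty")
    return grid[mask]


def compute_dvh(dose, mask, bin_width: float = 10.0, roi: str = "ROI") -> DVHCurve:
    """Cumulative DVH by exact voxel counting at each bin edge."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    doses = _roi_doses(dose, mask, roi)
    top = float(doses.max())
    n_bins = int(np.ceil(top / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    volume = np.array([100.0 * np.count_nonzero(doses >= e) / doses.size for e in edges])
    return DVHCurve(dose_grid=edges, cumulative_relative_volume=volume)


def v_at_dose(dose, mask, threshold: float, roi: str = "ROI") -> float:
    """V_D: percent of ROI volume receiving at least ``threshold`` cGy."""
    doses = _roi_doses(dose, mask, roi)
    return 100.0 * np.count_nonzero(doses >= threshold) / doses.size


def d_max(dose, mask, roi: str = "ROI") -> float:
    """Maximum voxel dose (cGy) within the ROI."""
    return float(_roi_doses(dose, mask, roi).max())


def eqd2_transform(dose, params: FractionationParams = FractionationParams()):
    """Voxelwise 2-Gy-equivalent dose (cGy) of a physical dose map (cGy)."""
    grid = _grid_of(dose)
    ab = params.alpha_beta
    d_gy = grid / 100.0 / params.n_fractions  # per-fraction dose in Gy
    out = grid * (d_gy + ab) / (params.reference_dose_per_fraction + ab)
    if hasattr(dose, "grid"):
        from dataclasses import replace
        return replace(dose, grid=out)
    return out


def v6300_rectum_wall(dose, phantom: Phantom,
                      params: FractionationParams = FractionationParams(),
                      threshold: float = 6300.0) -> float:
    """Rectum-wall V6300cGy on the EQD2 map — the complication-model input."""
    if "rectum_wall" not in phantom.masks:
        raise ValueError("phantom has no 'rectum_wall' mask")
    eqd2 = eqd2_transform(dose, params)
    return v_at_dose(eqd2, phantom.masks["rectum_wall"], threshold, roi="rectum_wall")


def mae(pred, gt, mask, prescription_dose: float,
        case_ids: Sequence[str] | None = None) -> float:
    """Prescription-normalised mean absolute dose error, in percent.

    For a single case: mean over ROI voxels of |pred - gt| / prescription
    dose, times 100. For sequences of cases the per-case values are averaged
    with equal weight (two-level average), which is how cohort prediction
    error is reported.
    """
    if prescription_dose <= 0:
        raise ValueError("prescription_dose must be > 0")
    single = not isinstance(mask, (list, tuple))
    preds = [pred] if single else list(pred)
    gts = [gt] if single else list(gt)
    masks = [mask] if single else list(mask)
    if not (len(preds) == len(gts) == len(masks)):
        raise ValueError("pred, gt and mask sequences must have equal length")
    ids = case_ids if case_ids is not None else [f"case {i}" for i in range(len(preds))]
    per_case = []
    for p, g, m, cid in zip(preds, gts, masks, ids):
        pg, gg = _grid_of(p), _grid_of(g)
        mm = np.asarray(m).astype(bool)
        if not mm.any():
            raise ValueError(f"ROI is empty for {cid}")
        per_case.append(100.0 * np.mean(np.abs(pg[mm] - gg[mm])) / prescription_dose)
    return float(np.mean(per_case))
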