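"""False-positive calibration by leave-one-out control analysis.

Detection parameters (p-value mode and level, minimum cluster extent) are
chosen so that running the full single-subject detection chain on each
healthy control — compared against the remaining controls — flags at most a
target fraction of them (default 10%).  Among admissible parameter sets the
one with the lowest cluster-extent threshold is preferred, i.e. the most
sensitive setting that still respects the false-positive budget.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import Atlas, VolumetricImage
from .stats import (ControlCohort, DetectionParams, parenchyma_filter,
                    threshold_map)

__all__ = ["CalibrationResult", "loo_flag_count", "calibrate_fp",
           "default_grid"]


@dataclass
class CalibrationResult:
    """Outcome of a grid calibration."""

    chosen_params: DetectionParams
    flagged_controls: list[int]
    fp_rate: float
    grid_evaluated: list[tuple[DetectionParams, float]]
    admissible: bool
    n: int

    def to_dict(self) -> dict:
        return {
            "chosen_params": self.chosen_params.label(),
            "flagged_controls": list(self.flagged_controls),
            "fp_rate": self.fp_rate,
            "admissible": self.admissible,
            "n": self.n,
            "grid": [{"params": p.label(), "fp_rate": r}
                     for p, r in self.grid_evaluated],
        }


def _loo_zmaps(smoothed: ControlCohort) -> np.ndarray:
    """Leave-one-out z-maps for every cohort member, vectorized.

    For control i the mean/SD are recomputed from the other n-1 maps
    (SD with ddof=1, hence n >= 3).  Voxels with zero leave-one-out SD are
    NaN (undefined, never tested).
    """
    x = np.stack([m.data for m in smoothed.maps])  # (n, ...)
    n = x.shape[0]
    if n < 3:
        raise ValueError("leave-one-out calibration needs n >= 3 controls")
    s = x.sum(axis=0)
    q = (x ** 2).sum(axis=0)
    mean = (s - x) / (n - 1)
    # sum of squared deviations within the n-1 remaining maps
    ssd = (q - x ** 2) - (n - 1) * mean ** 2
    var = np.clip(ssd, 0.0, None) / (n - 2)
    sd = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (x - mean) / sd
    z[sd == 0] = np.nan
    return z


def loo_flag_count(cohort: ControlCohort, params: DetectionParams,
                   atlas: Atlas | None, test_mask: VolumetricImage,
                   cortex_distance_mm: float = 5.0,
                   _smoothed: ControlCohort | None = None,
                   ) -> tuple[int, list[int]]:
    """Count controls flagged when each is detected against the rest.

    Returns ``(count, flagged_indices)``.  A control is flagged when at least
    one cluster survives thresholding and the parenchyma filter.
    """
    smoothed = _smoothed if _smoothed is not None else cohort.smoothed(
        params.smoothing_fwhm_mm, test_mask)
    z = _loo_zmaps(smoothed)
    flagged = []
    for i in range(z.shape[0]):
        if not np.isfinite(z[i][test_mask.data > 0]).any():
            continue  # z undefined everywhere (e.g. zero-variance cohort)
        zi = VolumetricImage(z[i], test_mask.affine)
        cs = threshold_map(zi, params, test_mask)
        if atlas is not None and len(cs):
            cs = parenchyma_filter(cs, atlas, cortex_distance_mm)
        if len(cs):
            flagged.append(i)
    return len(flagged), flagged


def default_grid(fwhm_mm: float = 6.0,
                 cluster_ks: tuple[int, ...] = (10, 30, 55),
                 ) -> list[DetectionParams]:
    """The default calibration grid: the two p-value modes used in practice
    (uncorrected <=0.001 and familywise-error <=0.05) crossed with a range of
    cluster-extent thresholds."""
    grid = []
    for mode, p in (("uncorrected", 0.001), ("fwe", 0.05)):
        for k in cluster_ks:
            grid.append(DetectionParams(
                smoothing_fwhm_mm=fwhm_mm, p_mode=mode, p_value=p,
                cluster_k=k))
    return grid


_MODE_RESTRICTIVENESS = {"uncorrected": 0, "fdr": 1, "fwe": 2}


def calibrate_fp(cohort: ControlCohort, target_rate: float,
                 search_grid: list[DetectionParams],
                 atlas: Atlas | None, test_mask: VolumetricImage,
                 cortex_distance_mm: float = 5.0) -> CalibrationResult:
    """Choose detection parameters meeting a subject-level FP budget.

    Every grid point is evaluated by leave-one-out flagging.  Among points
    with ``fp_rate <= target_rate`` the one with the smallest ``cluster_k``
    wins, ties broken by the less restrictive p-setting (mode order
    uncorrected < FDR < FWE, then larger p), then by grid order.  If no point
    is admissible the minimum-FP point is returned with
    ``admissible=False``.
    """
    if not search_grid:
        raise ValueError("search_grid must be nonempty")
    if not (0.0 < target_rate < 1.0):
        raise ValueError("target_rate must be in (0, 1)")

    # smooth the cohort once per distinct FWHM
    smoothed_cache: dict[float, ControlCohort] = {}
    evaluated: list[tuple[DetectionParams, float]] = []
    flagged_by_point: list[list[int]] = []
    for p in search_grid:
        fw = p.smoothing_fwhm_mm
        if fw not in smoothed_cache:
            smoothed_cache[fw] = cohort.smoothed(fw, test_mask)
        count, idx = loo_flag_count(cohort, p, atlas, test_mask,
                                    cortex_distance_mm,
                                    _smoothed=smoothed_cache[fw])
        evaluated.append((p, count / cohort.n))
        flagged_by_point.append(idx)

    admissible = [k for k, (_, r) in enumerate(evaluated)
                  if r <= target_rate]
    if admissible:
        best = min(admissible, key=lambda k: (
            evaluated[k][0].cluster_k,
            _MODE_RESTRICTIVENESS[evaluated[k][0].p_mode],
            -evaluated[k][0].p_value,
            k,
        ))
        ok = True
    else:
        best = min(range(len(evaluated)), key=lambda k: (evaluated[k][1], k))
        ok = False
    params, rate = evaluated[best]
    return CalibrationResult(
        chosen_params=params,
        flagged_controls=flagged_by_point[best],
        fp_rate=rate,
        grid_evaluated=evaluated,
        admissible=ok,
        n=cohort.n,
    )
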