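"""Mapping from raw subject channels to the five quantitative measures.

Each measure is a single scalar map per subject, ready for the shared
single-subject detection engine:

* ``T2`` — log-linear relaxometry fit of the multi-echo series;
* ``MTR`` — magnetization transfer ratio of the MT-off/MT-on pair;
* ``MD`` — mean diffusivity, validated pass-through;
* ``CThk`` — cortical thickness, validated pass-through;
* ``WGJS`` — convolved gray-white junction map from the T1-weighted volume.

Voxels where a measure is undefined (failed T2 fit, nonpositive MT-off) are
set to NaN so cohort statistics exclude them automatically.
"""

from __future__ import annotations

import numpy as np

from . import maps as qmaps
from .image import VolumetricImage
from .phantom import SubjectDataset

__all__ = ["MEASURES", "MEASURE_CHANNELS", "compute_measure_map"]

MEASURES = ("CThk", "WGJS", "T2", "MTR", "MD")

# raw phantom/acquisition channels each measure consumes
MEASURE_CHANNELS = {
    "T2": ("T2",),
    "MTR": ("MTR",),
    "MD": ("MD",),
    "CThk": ("thickness",),
    "WGJS": ("T1w",),
}


def compute_measure_map(subject: SubjectDataset, measure: str,
                        prob_threshold: float = 0.9,
                        kernel_size: int = 5) -> VolumetricImage:
    """Compute one quantitative measure map for a subject."""
    if measure == "T2":
        if subject.echo_series is None:
            raise ValueError(f"{subject.subject_id}: no echo series")
        fit = qmaps.fit_t2_map(subject.echo_series, subject.te_ms,
                               subject.brain_mask)
        out = fit.t2_map.data.copy()
        out[fit.valid_mask.data == 0] = np.nan
        return fit.t2_map.with_data(out)
    if measure == "MTR":
        if subject.mt_off is None or subject.mt_on is None:
            raise ValueError(f"{subject.subject_id}: no MT pair")
        mtr, valid = qmaps.compute_mtr(subject.mt_off, subject.mt_on,
                                       subject.brain_mask)
        out = mtr.data.copy()
        out[valid.data == 0] = np.nan
        return mtr.with_data(out)
    if measure == "MD":
        if subject.md_map is None:
            raise ValueError(f"{subject.subject_id}: no MD map")
        return qmaps.validate_passthrough(subject.md_map, "MD",
                                          subject.brain_mask)
    if measure == "CThk":
        if subject.thickness_map is None:
            raise ValueError(f"{subject.subject_id}: no thickness map")
        return qmaps.validate_passthrough(subject.thickness_map, "thickness",
                                          subject.brain_mask)
    if measure == "WGJS":
        if subject.t1w is None or not subject.tpm:
            raise ValueError(f"{subject.subject_id}: no T1w/TPM inputs")
        art = qmaps.junction_mask(subject.t1w, subject.tpm, prob_threshold,
                                  subject.brain_mask)
        return qmaps.junction_map(art.junction_mask, kernel_size)
    raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")
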