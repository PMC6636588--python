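"""Quantitative map computation: T2 relaxometry, MTR, gray-white junction.

T2 maps come from a log-linear fit of the mono-exponential decay model,
``ln S = -TE/T2 + ln S0``, by ordinary least squares of log-signal on echo
time per voxel.  The magnetization transfer ratio is the percent signal drop
between the MT-off and MT-on acquisitions,
``MTR = (MT_off - MT_on) / MT_off * 100``.  The gray-white junction signal
(WGJS) map highlights blurring of the cortical gray/white interface: voxels
whose T1-weighted intensity falls between ``mean_GM - SD_GM`` and
``mean_WM + SD_WM`` (statistics taken over high-probability GM/WM masks) form
a binary junction mask, which is then convolved with a unitary box kernel
(default 5x5x5) so each voxel counts the junction voxels in its neighborhood.

Mean diffusivity and cortical thickness are consumed as precomputed scalar
maps and only validated here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve

from .image import VolumetricImage

__all__ = [
    "T2FitResult",
    "JunctionArtifacts",
    "fit_t2_map",
    "compute_mtr",
    "junction_mask",
    "junction_map",
    "validate_passthrough",
]

T2_SENTINEL = -1.0
MTR_SENTINEL = -1.0


@dataclass
class T2FitResult:
    """Per-voxel T2 (ms) and S0 with a validity mask.

    Voxels with any nonpositive echo signal, or a non-decaying (slope >= 0)
    fit, are cleared from ``valid_mask`` and set to the sentinel value -1
    rather than clamped, so fit failures stay visible.
    """

    t2_map: VolumetricImage
    s0_map: VolumetricImage
    valid_mask: VolumetricImage


@dataclass
class JunctionArtifacts:
    """Intermediates and output of the junction-map pipeline."""

    gm_mask: VolumetricImage
    wm_mask: VolumetricImage
    interval_low: float
    interval_high: float
    junction_mask: VolumetricImage
    junction_map: VolumetricImage | None = None


def fit_t2_map(echo_series: VolumetricImage, te_ms, mask: VolumetricImage,
               ) -> T2FitResult:
    """Log-linear T2 fit over masked voxels.

    Parameters
    ----------
    echo_series:
        4D volume, last axis indexing echoes.
    te_ms:
        strictly increasing echo times (ms), one per echo.
    mask:
        binary volume restricting the fit.
    """
    te = np.asarray(te_ms, dtype=float)
    if te.ndim != 1 or te.size < 2:
        raise ValueError("need at least 2 echo times")
    if np.any(np.diff(te) <= 0):
        raise ValueError("echo times must be strictly increasing")
    data = echo_series.data
    if data.ndim != 4 or data.shape[-1] != te.size:
        raise ValueError(
            f"echo series must be 4D with {te.size} echoes, got {data.shape}")
    mask.check_grid(VolumetricImage(data[..., 0], echo_series.affine), "mask")
    m = mask.data > 0

    sig = data[m]  # (n_vox, n_echo)
    positive = np.all(sig > 0, axis=1)
    logs = np.full_like(sig, np.nan)
    logs[positive] = np.log(sig[positive])

    # closed-form OLS of ln(S) on TE
    te_c = te - te.mean()
    denom = (te_c ** 2).sum()
    slope = (logs * te_c).sum(axis=1) / denom
    intercept = logs.mean(axis=1) - slope * te.mean()

    # slope >= 0 means non-decaying; the -1e-12 tolerance absorbs float
    # round-off on constant signals (T2 beyond 1e12 ms is unphysical anyway)
    ok = positive & (slope < -1e-12)
    t2 = np.full(sig.shape[0], T2_SENTINEL)
    s0 = np.full(sig.shape[0], T2_SENTINEL)
    t2[ok] = -1.0 / slope[ok]
    s0[ok] = np.exp(intercept[ok])

    shape = data.shape[:3]
    t2_map = np.full(shape, T2_SENTINEL)
    s0_map = np.full(shape, T2_SENTINEL)
    valid = np.zeros(shape, dtype=np.uint8)
    t2_map[m] = t2
    s0_map[m] = s0
    valid[m] = ok.astype(np.uint8)
    aff = echo_series.affine
    return T2FitResult(
        VolumetricImage(t2_map, aff),
        VolumetricImage(s0_map, aff),
        VolumetricImage(valid, aff),
    )


def compute_mtr(mt_off: VolumetricImage, mt_on: VolumetricImage,
                mask: VolumetricImage) -> tuple[VolumetricImage, VolumetricImage]:
    """MTR = (MT_off - MT_on) / MT_off * 100 per masked voxel.

    Voxels with ``mt_off <= 0`` cannot be normalized; they are set to the
    sentinel -1 and dropped from the returned validity mask.
    """
    mt_off.check_grid(mt_on, "mt_on")
    mt_off.check_grid(mask, "mask")
    m = mask.data > 0
    ok = m & (mt_off.data > 0)
    mtr = np.full(mt_off.shape, MTR_SENTINEL)
    mtr[ok] = (mt_off.data[ok] - mt_on.data[ok]) / mt_off.data[ok] * 100.0
    return (VolumetricImage(mtr, mt_off.affine),
            VolumetricImage(ok.astype(np.uint8), mt_off.affine))


def junction_mask(t1w: VolumetricImage, tpm: dict[str, VolumetricImage],
                  prob_threshold: float = 0.9,
                  brain_mask: VolumetricImage | None = None,
                  ) -> JunctionArtifacts:
    """Binary gray-white junction mask from T1-weighted intensities.

    High-probability GM and WM masks (tissue probability > ``prob_threshold``)
    define per-subject intensity statistics; brain voxels whose intensity lies
    in ``[mean_GM - SD_GM, mean_WM + SD_WM]`` form the junction mask.  The
    interval uses the subject's own raw intensities, which makes the rule
    invariant to global intensity scaling.
    """
    if not (0.0 < prob_threshold < 1.0):
        raise ValueError("prob_threshold must be in (0, 1)")
    for t in ("gm", "wm", "csf"):
        if t not in tpm:
            raise ValueError(f"tpm missing class '{t}'")
        t1w.check_grid(tpm[t], f"tpm[{t}]")
    gm = tpm["gm"].data > prob_threshold
    wm = tpm["wm"].data > prob_threshold
    if not gm.any():
        raise ValueError("empty GM mask: cannot estimate junction interval")
    if not wm.any():
        raise ValueError("empty WM mask: cannot estimate junction interval")
    x = t1w.data
    lo = float(x[gm].mean() - x[gm].std())
    hi = float(x[wm].mean() + x[wm].std())
    if brain_mask is None:
        brain = (tpm["gm"].data + tpm["wm"].data + tpm["csf"].data) > 0.5
    else:
        t1w.check_grid(brain_mask, "brain_mask")
        brain = brain_mask.data > 0
    jm = brain & (x >= lo) & (x <= hi)
    aff = t1w.affine
    return JunctionArtifacts(
        gm_mask=VolumetricImage(gm.astype(np.uint8), aff),
        wm_mask=VolumetricImage(wm.astype(np.uint8), aff),
        interval_low=lo,
        interval_high=hi,
        junction_mask=VolumetricImage(jm.astype(np.uint8), aff),
    )


def junction_map(jmask: VolumetricImage, kernel_size: int = 5,
                 ) -> VolumetricImage:
    """Convolve the binary junction mask with a unitary box kernel.

    Each voxel's value is the count of junction voxels within its
    ``kernel_size``^3 neighborhood (zero-padded at the borders), so values lie
    in ``[0, kernel_size^3]``.
    """
    if kernel_size < 1 or kernel_size % 2 == 0:
        raise ValueError(f"kernel_size must be odd and positive, got {kernel_size}")
    kernel = np.ones((kernel_size,) * 3)
    counts = convolve(jmask.data.astype(np.float64), kernel, mode="constant")
    return VolumetricImage(np.rint(counts), jmask.affine)


def validate_passthrough(vol: VolumetricImage, modality: str,
                         brain_mask: VolumetricImage) -> VolumetricImage:
    """Validate a scanner/surface-derived scalar map and return it unchanged.

    ``modality`` must be ``"MD"`` or ``"thickness"``; both are physically
    nonnegative quantities.
    """
    if modality not in ("MD", "thickness"):
        raise ValueError(f"modality must be 'MD' or 'thickness', got {modality!r}")
    brain_mask.check_grid(vol, f"{modality} map")
    inside = brain_mask.data > 0
    neg = inside & (vol.data < 0)
    if neg.any():
        where = tuple(int(i) for i in np.argwhere(neg)[0])
        raise ValueError(
            f"{modality} map has negative value at voxel {where} inside mask")
    return vol
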