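"""Single-subject versus control-cohort voxelwise detection.

One subject's quantitative map is compared with a cohort of control maps on
the same grid: per-voxel z-scores against the cohort mean/SD, Gaussian
smoothing (masked, renormalized), significance thresholding (uncorrected,
Benjamini-Hochberg FDR, or Bonferroni FWE) and a minimum cluster extent, and
finally removal of non-parenchymal findings.  The same engine serves every
modality, including cortical-thickness scalar maps.

Conventions, all logged with results:

* the statistic is the plain z-score ``(x - mean)/sd``; a small-cohort
  variant inflating the SD by ``sqrt(1 + 1/n)`` is available via
  ``DetectionParams.crawford_howell``;
* testing is two-sided by default (abnormality may be an increase or a
  decrease);
* cluster connectivity defaults to 26 neighbors (configurable 6/18/26);
* the FWE mode is Bonferroni over the tested voxels — conservative and
  reproducible without random-field machinery;
* tested voxels are those inside the test mask with a defined z (cohort
  SD > 0), so undefined voxels never count as tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.stats import norm

from .image import Atlas, VolumetricImage

__all__ = [
    "ControlCohort",
    "DetectionParams",
    "Cluster",
    "ClusterSet",
    "smooth_map",
    "zscore_map",
    "threshold_map",
    "fdr_threshold",
    "parenchyma_filter",
    "detect",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
P_MODES = ("uncorrected", "fdr", "fwe")


@dataclass(frozen=True)
class DetectionParams:
    """The tunable surface of the detector."""

    smoothing_fwhm_mm: float = 6.0
    p_mode: str = "uncorrected"
    p_value: float = 0.001
    cluster_k: int = 30
    two_sided: bool = True
    connectivity: int = 26
    crawford_howell: bool = False

    def __post_init__(self) -> None:
        if self.smoothing_fwhm_mm < 0:
            raise ValueError("smoothing_fwhm_mm must be >= 0")
        if self.p_mode not in P_MODES:
            raise ValueError(f"p_mode must be one of {P_MODES}, got {self.p_mode!r}")
        if not (0.0 < self.p_value < 1.0):
            raise ValueError("p_value must be in (0, 1)")
        if self.cluster_k < 1:
            raise ValueError("cluster_k must be >= 1")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")

    def label(self) -> str:
        return (f"fwhm={self.smoothing_fwhm_mm:g}mm,{self.p_mode}"
                f"<={self.p_value:g},k={self.cluster_k}")


@dataclass
class ControlCohort:
    """Aligned control maps of one modality with voxelwise summaries."""

    maps: list[VolumetricImage]
    modality: str = ""
    mean_map: VolumetricImage = None
    sd_map: VolumetricImage = None

    def __post_init__(self) -> None:
        if len(self.maps) < 2:
            raise ValueError("a control cohort needs at least 2 maps")
        ref = self.maps[0]
        for m in self.maps[1:]:
            ref.check_grid(m, "cohort map")
        if self.mean_map is None or self.sd_map is None:
            stack = np.stack([m.data for m in self.maps])
            self.mean_map = ref.with_data(stack.mean(axis=0))
            self.sd_map = ref.with_data(stack.std(axis=0, ddof=1))

    @property
    def n(self) -> int:
        return len(self.maps)

    def smoothed(self, fwhm_mm: float, mask: VolumetricImage | None = None,
                 ) -> "ControlCohort":
        """Cohort of smoothed maps (summaries recomputed)."""
        if fwhm_mm == 0:
            return self
        return ControlCohort(
            [smooth_map(m, fwhm_mm, mask) for m in self.maps], self.modality)


@dataclass
class Cluster:
    """One suprathreshold connected component."""

    voxels: np.ndarray  # (size, 3) int array
    size: int
    peak_voxel: tuple[int, int, int]
    peak_z: float
    region: tuple[str, str] | None = None  # (lobe, side), set by concordance

    def to_dict(self) -> dict:
        return {
            "size": int(self.size),
            "peak_voxel": [int(v) for v in self.peak_voxel],
            "peak_z": float(self.peak_z),
            "region": list(self.region) if self.region else None,
        }


@dataclass
class ClusterSet:
    """Surviving clusters, largest first, with the parameters that made them."""

    clusters: list[Cluster]
    params_used: DetectionParams
    n_tests: int
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    shape: tuple[int, int, int] = (0, 0, 0)

    def __len__(self) -> int:
        return len(self.clusters)

    def label_volume(self) -> VolumetricImage:
        """Integer volume: voxels of cluster i carry label i+1."""
        lab = np.zeros(self.shape, dtype=np.int32)
        for i, c in enumerate(self.clusters):
            lab[tuple(c.voxels.T)] = i + 1
        return VolumetricImage(lab, self.affine)

    def to_dict(self) -> dict:
        return {
            "params": self.params_used.label(),
            "n_tests": int(self.n_tests),
            "clusters": [c.to_dict() for c in self.clusters],
        }


# ---------------------------------------------------------------------------

def smooth_map(vol: VolumetricImage, fwhm_mm: float,
               mask: VolumetricImage | None = None) -> VolumetricImage:
    """Gaussian smoothing with FWHM given in mm, optionally mask-renormalized.

    With a mask, the result is ``smooth(x * m) / smooth(m)`` inside the mask
    (zero outside), so zeros beyond the brain do not dilute edge voxels and a
    constant map stays constant.  Non-finite voxels (undefined measure
    values) are treated as missing: they are excluded from the weighting and
    receive a neighborhood-interpolated value, so a handful of failed-fit
    voxels cannot poison the map.  ``fwhm_mm = 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return vol.with_data(vol.data.copy())
    sigma = fwhm_mm * FWHM_TO_SIGMA / vol.voxel_size
    data = vol.data.astype(float)
    finite = np.isfinite(data)
    if mask is None and finite.all():
        return vol.with_data(ndimage.gaussian_filter(data, sigma))
    if mask is None:
        inside = np.ones(data.shape, dtype=bool)
    else:
        vol.check_grid(mask, "mask")
        inside = mask.data > 0
    w = (inside & finite).astype(float)
    num = ndimage.gaussian_filter(np.where(w > 0, data, 0.0), sigma)
    den = ndimage.gaussian_filter(w, sigma)
    out = np.zeros_like(num)
    ok = inside & (den > 0)
    out[ok] = num[ok] / den[ok]
    out[inside & ~ok] = np.nan
    return vol.with_data(out)


def zscore_map(subject_map: VolumetricImage, cohort: ControlCohort,
               crawford_howell: bool = False) -> VolumetricImage:
    """Voxelwise z of a subject against the cohort mean/SD.

    Voxels with zero cohort SD are undefined and returned as NaN; downstream
    thresholding never tests them.  ``crawford_howell`` inflates the SD by
    ``sqrt(1 + 1/n)`` to account for the estimated mean in small cohorts.
    """
    subject_map.check_grid(cohort.mean_map, "cohort")
    sd = cohort.sd_map.data
    if crawford_howell:
        sd = sd * np.sqrt(1.0 + 1.0 / cohort.n)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (subject_map.data - cohort.mean_map.data) / sd
    z[cohort.sd_map.data == 0] = np.nan
    return subject_map.with_data(z)


def fdr_threshold(p_values, q: float) -> float:
    """Benjamini-Hochberg p-value cutoff.

    Returns the largest ``p_(i)`` with ``p_(i) <= i*q/m`` over the sorted
    p-values, or 0.0 when nothing passes (a threshold no p can meet, since
    valid p-values are positive).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("p_values must be nonempty")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p_values must lie in [0, 1]")
    if not (0.0 < q < 1.0):
        raise ValueError("q must be in (0, 1)")
    ps = np.sort(p)
    thresh = np.arange(1, ps.size + 1) * q / ps.size
    passing = np.nonzero(ps <= thresh)[0]
    return float(ps[passing[-1]]) if passing.size else 0.0


def _connectivity_structure(connectivity: int) -> np.ndarray:
    order = {6: 1, 18: 2, 26: 3}[connectivity]
    return ndimage.generate_binary_structure(3, order)


def threshold_map(zmap: VolumetricImage, params: DetectionParams,
                  test_mask: VolumetricImage) -> ClusterSet:
    """Significance thresholding plus cluster-extent filtering.

    Per-voxel p-values come from the standard normal (two-sided when
    ``params.two_sided``); the significance rule depends on ``p_mode``:
    ``uncorrected`` compares each p to ``p_value``, ``fdr`` applies
    Benjamini-Hochberg over the tested voxels, ``fwe`` applies Bonferroni
    (``p <= p_value / n_tests``).  Surviving voxels are grouped by
    ``params.connectivity``; components smaller than ``cluster_k`` are
    dropped.  Clusters are returned largest first with their |z| peak.
    """
    zmap.check_grid(test_mask, "test_mask")
    z = zmap.data
    tested = (test_mask.data > 0) & np.isfinite(z)
    n_tests = int(tested.sum())
    if n_tests == 0:
        raise ValueError("empty test mask (no defined voxels to test)")

    if params.two_sided:
        p = np.full(z.shape, np.nan)
        p[tested] = 2.0 * norm.sf(np.abs(z[tested]))
    else:
        p = np.full(z.shape, np.nan)
        p[tested] = norm.sf(z[tested])

    if params.p_mode == "uncorrected":
        cutoff = params.p_value
    elif params.p_mode == "fwe":
        cutoff = params.p_value / n_tests
    else:  # fdr
        cutoff = fdr_threshold(p[tested], params.p_value)

    sig = tested & (p <= cutoff)
    labels, n_comp = ndimage.label(
        sig, structure=_connectivity_structure(params.connectivity))

    clusters: list[Cluster] = []
    if n_comp:
        sizes = np.bincount(labels.ravel())[1:]
        keep = np.nonzero(sizes >= params.cluster_k)[0] + 1
        for lab in keep:
            vox = np.argwhere(labels == lab)
            zv = z[tuple(vox.T)]
            k = int(np.argmax(np.abs(zv)))
            clusters.append(Cluster(
                voxels=vox, size=int(vox.shape[0]),
                peak_voxel=tuple(int(v) for v in vox[k]),
                peak_z=float(zv[k]),
            ))
    clusters.sort(key=lambda c: c.size, reverse=True)
    return ClusterSet(clusters, params, n_tests, zmap.affine, zmap.shape)


def parenchyma_filter(clusters: ClusterSet, atlas: Atlas,
                      cortex_distance_mm: float = 5.0) -> ClusterSet:
    """Drop findings outside the cerebral parenchyma or far from cortex.

    A cluster is removed when its peak voxel carries an excluded atlas label
    (background, CSF, ventricles, brainstem, cerebellum) or — when the atlas
    provides a cortical GM mask — lies farther than ``cortex_distance_mm``
    from any GM voxel.
    """
    if clusters.shape != atlas.labels.shape:
        raise ValueError("atlas grid does not match cluster grid")
    lobes = set(atlas.table["lobe"])
    if not lobes & {"frontal", "parietal", "temporal", "occipital"}:
        raise ValueError("atlas table lacks cortical lobe labels")

    dist = None
    if atlas.gm_mask is not None:
        gm = atlas.gm_mask.data > 0
        dist = ndimage.distance_transform_edt(
            ~gm, sampling=atlas.labels.voxel_size)

    kept = []
    for c in clusters.clusters:
        lab = int(atlas.labels.data[c.peak_voxel])
        if atlas.is_excluded(lab):
            continue
        if dist is not None and dist[c.peak_voxel] > cortex_distance_mm:
            continue
        kept.append(c)
    return replace(clusters, clusters=kept)


def detect(subject_map: VolumetricImage, cohort: ControlCohort,
           params: DetectionParams, test_mask: VolumetricImage,
           atlas: Atlas | None = None,
           cortex_distance_mm: float = 5.0) -> ClusterSet:
    """Full single-subject chain: smooth, z-score, threshold, filter.

    The subject map and every cohort map are smoothed identically (masked by
    ``test_mask``) before the comparison.  When ``atlas`` is given the
    parenchyma filter is applied to the surviving clusters.
    """
    sm_subject = smooth_map(subject_map, params.smoothing_fwhm_mm, test_mask)
    sm_cohort = cohort.smoothed(params.smoothing_fwhm_mm, test_mask)
    z = zscore_map(sm_subject, sm_cohort, params.crawford_howell)
    cs = threshold_map(z, params, test_mask)
    if atlas is not None:
        cs = parenchyma_filter(cs, atlas, cortex_distance_mm)
    return cs
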