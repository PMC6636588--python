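"""Synthetic brain phantoms and control cohorts.

The detection pipeline compares one subject against a cohort of controls
voxel by voxel, so the phantom generator has to reproduce the statistical
structure that comparison assumes: per-tissue intensity distributions,
spatially smooth between-subject variability, and measurement noise on each
acquisition channel.  Geometry is a set of concentric smoothed ellipsoids
(CSF rim and ventricles, a gray-matter ribbon, a white-matter interior, plus
a brainstem/cerebellum block) — deliberately simple, but carrying every
feature downstream code consumes: tissue probability maps, a brain mask, a
lobe/side label atlas, and a cortical ribbon for thickness maps.

Acquisition channels per subject:

``T2``
    multi-echo series following mono-exponential decay
    ``S(TE) = S0 * exp(-TE / T2)`` at echo times 20..100 ms, plus noise;
``MTR``
    a proton-density pair without/with a saturation pulse,
    ``MT_on = MT_off * (1 - saturation_fraction)`` before noise;
``MD``
    a mean-diffusivity map (10^-3 mm^2/s), consumed as scanner output;
``thickness``
    a cortical-thickness scalar map supported on the GM ribbon;
``T1w``
    a T1-weighted intensity volume feeding the gray-white junction maps.

Between-subject variability is one unit-variance Gaussian random field per
subject per channel, scaled by the tissue-wise SD; focal lesions are inserted
as additive offsets (in multiples of that local SD) inside a sphere, touching
exactly one channel.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from .image import Atlas, VolumetricImage, load_json, save_json

__all__ = [
    "TissueParams",
    "PhantomSpec",
    "LesionSpec",
    "SubjectDataset",
    "generate_phantom",
    "insert_lesion",
    "save_subject",
    "load_subject",
    "LESION_CHANNELS",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

# Lesionable channels and the pre-noise parameter map each one perturbs.
LESION_CHANNELS = {
    "T2": "t2",
    "MTR": "mt_sat",
    "MD": "md",
    "thickness": "thickness",
    "junction": "t1w",
}

# Parameter maps drawn per channel; index keys the per-channel RNG stream so
# generating a subset of channels reproduces the full-generation values.
_CHANNEL_FIELDS = {
    "T2": ("t2", "s0"),
    "MTR": ("mt_sat", "pd"),
    "MD": ("md",),
    "thickness": ("thickness",),
    "T1w": ("t1w",),
}
_CHANNEL_INDEX = {c: k for k, c in enumerate(sorted(_CHANNEL_FIELDS))}


@dataclass(frozen=True)
class TissueParams:
    """Mean/SD of each quantitative property for one tissue class.

    SDs are *between-subject* standard deviations; measurement noise is a
    separate, channel-level setting on :class:`PhantomSpec`.
    """

    t2_ms: tuple[float, float]
    s0: tuple[float, float]
    mt_sat: tuple[float, float]  # saturation fraction in [0, 1)
    md: tuple[float, float]  # 10^-3 mm^2/s
    t1w: tuple[float, float]
    thickness_mm: tuple[float, float] = (0.0, 0.0)

    def validate(self, name: str) -> None:
        for fld in ("t2_ms", "s0", "mt_sat", "md", "t1w", "thickness_mm"):
            mean, sd = getattr(self, fld)
            if sd < 0:
                raise ValueError(f"tissue {name}: {fld} SD must be >= 0, got {sd}")
        if self.t2_ms[0] <= 0:
            raise ValueError(f"tissue {name}: T2 mean must be > 0")
        if not (0.0 <= self.mt_sat[0] < 1.0):
            raise ValueError(f"tissue {name}: mt_sat mean must be in [0, 1)")


def _default_tissues() -> dict[str, TissueParams]:
    # Literature-typical 3T values; see docs/methods.md for the rationale.
    return {
        "gm": TissueParams(
            t2_ms=(100.0, 5.0), s0=(1000.0, 40.0), mt_sat=(0.30, 0.015),
            md=(0.85, 0.04), t1w=(400.0, 15.0), thickness_mm=(2.5, 0.25),
        ),
        "wm": TissueParams(
            t2_ms=(80.0, 4.0), s0=(950.0, 40.0), mt_sat=(0.45, 0.02),
            md=(0.75, 0.035), t1w=(600.0, 20.0),
        ),
        "csf": TissueParams(
            t2_ms=(500.0, 25.0), s0=(1050.0, 40.0), mt_sat=(0.05, 0.01),
            md=(3.0, 0.10), t1w=(150.0, 15.0),
        ),
    }


@dataclass
class PhantomSpec:
    """Everything needed to generate a deterministic cohort of phantoms."""

    grid_shape: tuple[int, int, int] = (48, 56, 48)
    voxel_size_mm: float = 3.0
    tissue_params: dict[str, TissueParams] = field(default_factory=_default_tissues)
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {
            "echo": 4.0, "mt": 4.0, "md": 0.01, "t1w": 4.0, "thickness": 0.05,
        }
    )
    between_subject_smoothness_mm: float = 18.0
    te_ms: tuple[float, ...] = (20.0, 40.0, 60.0, 80.0, 100.0)
    rician_noise: bool = False
    seed: int = 0

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(n <= 0 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 positive ints, got {self.grid_shape}")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be > 0")
        if len(self.te_ms) < 2 or np.any(np.diff(self.te_ms) <= 0):
            raise ValueError("te_ms must be >= 2 strictly increasing echo times")
        for name in ("gm", "wm", "csf"):
            if name not in self.tissue_params:
                raise ValueError(f"tissue_params missing class '{name}'")
            self.tissue_params[name].validate(name)
        for ch, sd in self.noise_sd.items():
            if sd < 0:
                raise ValueError(f"noise_sd[{ch}] must be >= 0")
        if self.between_subject_smoothness_mm < 0:
            raise ValueError("between_subject_smoothness_mm must be >= 0")

    # -- (de)serialization for the CLI ------------------------------------
    def to_dict(self) -> dict:
        d = {
            "grid_shape": list(self.grid_shape),
            "voxel_size_mm": self.voxel_size_mm,
            "between_subject_smoothness_mm": self.between_subject_smoothness_mm,
            "te_ms": list(self.te_ms),
            "noise_sd": dict(self.noise_sd),
            "rician_noise": self.rician_noise,
            "seed": self.seed,
            "tissue_params": {
                t: {f: list(getattr(p, f)) for f in (
                    "t2_ms", "s0", "mt_sat", "md", "t1w", "thickness_mm")}
                for t, p in self.tissue_params.items()
            },
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        kwargs = dict(d)
        if "grid_shape" in kwargs:
            kwargs["grid_shape"] = tuple(kwargs["grid_shape"])
        if "te_ms" in kwargs:
            kwargs["te_ms"] = tuple(kwargs["te_ms"])
        if "tissue_params" in kwargs:
            kwargs["tissue_params"] = {
                t: TissueParams(**{f: tuple(v) for f, v in p.items()})
                for t, p in kwargs["tissue_params"].items()
            }
        spec = cls(**kwargs)
        spec.validate()
        return spec

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


@dataclass(frozen=True)
class LesionSpec:
    """A spherical focal offset applied to one channel's pre-noise map.

    ``delta`` is expressed in multiples of the between-subject SD at each
    voxel, so a ``delta=5`` lesion sits five cohort-SDs away from the control
    mean before measurement noise.
    """

    center_voxel: tuple[int, int, int]
    radius_mm: float
    channel: str
    delta: float

    def validate(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be > 0")
        if self.channel not in LESION_CHANNELS:
            raise ValueError(
                f"channel must be one of {sorted(LESION_CHANNELS)}, got {self.channel!r}"
            )


@dataclass
class SubjectDataset:
    """One subject's raw inputs, all on a shared grid.

    Besides the observed channels, the dataset keeps the pre-noise parameter
    maps (``truth``), the frozen noise realizations (``noise``) and the
    between-subject SD maps (``sd_maps``) so that lesion insertion can offset
    a single channel and re-derive it with the identical noise.
    """

    subject_id: str
    affine: np.ndarray
    brain_mask: VolumetricImage
    tpm: dict[str, VolumetricImage]
    atlas: Atlas
    te_ms: tuple[float, ...] = ()
    echo_series: VolumetricImage | None = None
    mt_on: VolumetricImage | None = None
    mt_off: VolumetricImage | None = None
    md_map: VolumetricImage | None = None
    thickness_map: VolumetricImage | None = None
    t1w: VolumetricImage | None = None
    truth: dict[str, np.ndarray] = field(default_factory=dict)
    noise: dict[str, np.ndarray] = field(default_factory=dict)
    sd_maps: dict[str, np.ndarray] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _normalized_coords(shape: tuple[int, int, int]):
    axes = [
        (np.arange(n) - (n - 1) / 2.0) / ((n - 1) / 2.0) for n in shape
    ]
    return np.meshgrid(*axes, indexing="ij")


def build_geometry(spec: PhantomSpec) -> dict:
    """Deterministic head geometry shared by every subject of a cohort.

    Returns tissue-class labels, the brain mask, smoothed tissue probability
    maps, the GM ribbon, and the lobe/side atlas.
    """
    ux, uy, uz = _normalized_coords(spec.grid_shape)
    r2 = (ux / 0.92) ** 2 + (uy / 0.95) ** 2 + (uz / 0.88) ** 2
    brain = r2 <= 1.0

    # tissue classes: 0 bg, 1 csf rim, 2 gm ribbon, 3 wm core,
    #                 4 ventricle (csf), 5 brainstem (wm), 6 cerebellum (gm)
    seg = np.zeros(spec.grid_shape, dtype=np.int16)
    seg[brain & (r2 > 0.82)] = 1
    seg[brain & (r2 <= 0.82)] = 2
    seg[brain & (r2 <= 0.50)] = 3
    vent = ((ux / 0.16) ** 2 + (uy / 0.30) ** 2 + (uz / 0.13) ** 2) <= 1.0
    seg[brain & vent] = 4
    stem = brain & (np.abs(ux) < 0.14) & (uy > -0.55) & (uy < -0.05) & (uz < -0.62)
    seg[stem] = 5
    cereb = brain & (uy < -0.55) & (uz < -0.50) & ~stem
    seg[cereb] = 6

    tissue_of = {0: "bg", 1: "csf", 2: "gm", 3: "wm", 4: "csf", 5: "wm", 6: "gm"}
    tclass = np.zeros(spec.grid_shape, dtype="U3")
    for lab, t in tissue_of.items():
        tclass[seg == lab] = t

    # tissue probability maps: lightly smoothed class indicators
    tpm = {}
    for t in ("gm", "wm", "csf"):
        ind = (tclass == t).astype(np.float64)
        tpm[t] = gaussian_filter(ind, sigma=0.4)
    total = tpm["gm"] + tpm["wm"] + tpm["csf"]
    over = total > 1.0
    for t in tpm:
        tpm[t][over] /= total[over]
        tpm[t][~brain] = 0.0

    gm_ribbon = seg == 2

    # lobe/side atlas over the cerebral parenchyma (gm ribbon + wm core)
    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    side_right = ux >= 0
    frontal = uy >= 0.15
    occipital = uy < -0.50
    temporal = (~frontal) & (~occipital) & (uz < -0.10)
    parietal = (~frontal) & (~occipital) & (uz >= -0.10)
    rows = []
    lab = 1
    cerebral = (seg == 2) | (seg == 3)
    for lobe, region in (
        ("frontal", frontal), ("parietal", parietal),
        ("temporal", temporal), ("occipital", occipital),
    ):
        for side, smask in (("left", ~side_right), ("right", side_right)):
            labels[cerebral & region & smask] = lab
            rows.append({"label": lab, "lobe": lobe, "side": side})
            lab += 1
    for lobe, region in (
        ("ventricle", seg == 4), ("brainstem", seg == 5),
        ("cerebellum", seg == 6), ("csf", seg == 1),
    ):
        labels[region] = lab
        rows.append({"label": lab, "lobe": lobe, "side": "none"})
        lab += 1
    rows.insert(0, {"label": 0, "lobe": "background", "side": "none"})

    aff = np.diag([spec.voxel_size_mm] * 3 + [1.0])
    atlas = Atlas(
        VolumetricImage(labels, aff),
        pd.DataFrame(rows),
        gm_mask=VolumetricImage(gm_ribbon.astype(np.uint8), aff),
    )
    return {
        "brain_mask": brain,
        "seg": seg,
        "tclass": tclass,
        "tpm": tpm,
        "gm_ribbon": gm_ribbon,
        "atlas": atlas,
        "affine": aff,
    }


# ---------------------------------------------------------------------------
# Subject generation
# ---------------------------------------------------------------------------

_FIELD_TISSUE_ATTR = {
    "t2": "t2_ms", "s0": "s0", "pd": "s0", "mt_sat": "mt_sat",
    "md": "md", "t1w": "t1w", "thickness": "thickness_mm",
}
# background values per parameter map (mean, sd)
_BG = {"t2": (1.0, 0.0), "s0": (0.0, 0.0), "pd": (0.0, 0.0),
       "mt_sat": (0.0, 0.0), "md": (0.0, 0.0), "t1w": (0.0, 0.0),
       "thickness": (0.0, 0.0)}


def _tissue_maps(spec: PhantomSpec, tclass: np.ndarray, fld: str):
    attr = _FIELD_TISSUE_ATTR[fld]
    mean = np.full(tclass.shape, _BG[fld][0])
    sd = np.full(tclass.shape, _BG[fld][1])
    for t, p in spec.tissue_params.items():
        m, s = getattr(p, attr)
        sel = tclass == t
        mean[sel] = m
        sd[sel] = s
    if fld == "thickness":
        # thickness lives on the cortical ribbon only
        off = tclass != "gm"
        mean[off] = 0.0
        sd[off] = 0.0
    return mean, sd


def _smooth_unit_field(rng: np.random.Generator, shape, sigma_vox: float):
    white = rng.standard_normal(shape)
    if sigma_vox <= 0:
        return white
    f = gaussian_filter(white, sigma=sigma_vox)
    s = f.std()
    return f / s if s > 0 else f


def _clip_field(fld: str, arr: np.ndarray) -> np.ndarray:
    if fld == "t2":
        return np.clip(arr, 1.0, None)
    if fld == "mt_sat":
        return np.clip(arr, 0.0, 0.99)
    if fld in ("md", "thickness", "s0", "pd", "t1w"):
        return np.clip(arr, 0.0, None)
    return arr


def _derive_channel(subj: SubjectDataset, spec: PhantomSpec, geo: dict,
                    channel: str) -> None:
    """(Re)compute one observed channel from truth + frozen noise."""
    aff = subj.affine
    tr, nz = subj.truth, subj.noise
    if channel == "T2":
        te = np.asarray(spec.te_ms)
        sig = tr["s0"][..., None] * np.exp(-te / tr["t2"][..., None])
        subj.echo_series = VolumetricImage(sig + nz["echo"], aff)
        subj.te_ms = tuple(spec.te_ms)
    elif channel == "MTR":
        subj.mt_off = VolumetricImage(tr["pd"] + nz["mt_off"], aff)
        subj.mt_on = VolumetricImage(
            tr["pd"] * (1.0 - tr["mt_sat"]) + nz["mt_on"], aff)
    elif channel == "MD":
        subj.md_map = VolumetricImage(
            np.clip(tr["md"] + nz["md"], 0.0, None), aff)
    elif channel == "thickness":
        ribbon = geo["gm_ribbon"]
        thick = np.clip(tr["thickness"] + nz["thickness"], 0.0, None)
        subj.thickness_map = VolumetricImage(np.where(ribbon, thick, 0.0), aff)
    elif channel == "T1w":
        subj.t1w = VolumetricImage(tr["t1w"] + nz["t1w"], aff)
    else:  # pragma: no cover
        raise ValueError(f"unknown channel {channel!r}")


def _generate_subject(spec: PhantomSpec, geo: dict, index: int,
                      channels: tuple[str, ...]) -> SubjectDataset:
    aff = geo["affine"]
    subj = SubjectDataset(
        subject_id=f"sub-{index:03d}",
        affine=aff,
        brain_mask=VolumetricImage(geo["brain_mask"].astype(np.uint8), aff),
        tpm={t: VolumetricImage(geo["tpm"][t], aff) for t in ("gm", "wm", "csf")},
        atlas=geo["atlas"],
        te_ms=tuple(spec.te_ms),
    )
    sigma_vox = (spec.between_subject_smoothness_mm * FWHM_TO_SIGMA
                 / spec.voxel_size_mm)
    shape = spec.grid_shape
    for ch in channels:
        rng = np.random.default_rng([spec.seed + index, _CHANNEL_INDEX[ch]])
        for fld in _CHANNEL_FIELDS[ch]:
            mean, sd = _tissue_maps(spec, geo["tclass"], fld)
            g = _smooth_unit_field(rng, shape, sigma_vox)
            subj.truth[fld] = _clip_field(fld, mean + g * sd)
            subj.sd_maps[fld] = sd
        # frozen measurement-noise realizations, one stream per channel
        if ch == "T2":
            subj.noise["echo"] = (
                spec.noise_sd.get("echo", 0.0)
                * rng.standard_normal(shape + (len(spec.te_ms),)))
        elif ch == "MTR":
            s = spec.noise_sd.get("mt", 0.0)
            subj.noise["mt_off"] = s * rng.standard_normal(shape)
            subj.noise["mt_on"] = s * rng.standard_normal(shape)
        elif ch == "MD":
            subj.noise["md"] = (
                spec.noise_sd.get("md", 0.0) * rng.standard_normal(shape))
        elif ch == "thickness":
            subj.noise["thickness"] = (
                spec.noise_sd.get("thickness", 0.0) * rng.standard_normal(shape))
        elif ch == "T1w":
            subj.noise["t1w"] = (
                spec.noise_sd.get("t1w", 0.0) * rng.standard_normal(shape))
        _derive_channel(subj, spec, geo, ch)
    return subj


def generate_phantom(spec: PhantomSpec, n_subjects: int,
                     channels: tuple[str, ...] | None = None,
                     ) -> list[SubjectDataset]:
    """Generate ``n_subjects`` phantom datasets.

    Deterministic given ``(spec, n_subjects)``; subject ``i`` depends only on
    ``spec.seed + i``, so growing a cohort keeps existing subjects identical.
    ``channels`` restricts generation to a subset of
    ``{"T2", "MTR", "MD", "thickness", "T1w"}`` (all by default); each channel
    uses its own substream, so a subset reproduces the full run's values.
    """
    spec.validate()
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if channels is None:
        channels = tuple(sorted(_CHANNEL_FIELDS))
    unknown = set(channels) - set(_CHANNEL_FIELDS)
    if unknown:
        raise ValueError(f"unknown channels {sorted(unknown)}")
    geo = build_geometry(spec)
    return [_generate_subject(spec, geo, i, tuple(channels))
            for i in range(n_subjects)]


# ---------------------------------------------------------------------------
# Lesion insertion
# ---------------------------------------------------------------------------

def _sphere_mask(shape, voxel_size_mm: float, center, radius_mm: float):
    idx = np.indices(shape)
    d2 = sum((idx[k] - center[k]) ** 2 for k in range(3)) * voxel_size_mm ** 2
    return d2 <= radius_mm ** 2


def insert_lesion(subject: SubjectDataset, lesion: LesionSpec,
                  spec: PhantomSpec) -> SubjectDataset:
    """Return a copy of ``subject`` with a focal offset on one channel.

    Only the targeted channel's pre-noise parameter map is shifted (by
    ``delta`` local between-subject SDs inside the sphere) and re-derived with
    the subject's frozen noise; every other channel is bit-identical.
    """
    lesion.validate()
    shape = subject.brain_mask.shape
    center = tuple(int(c) for c in lesion.center_voxel)
    if not all(0 <= center[k] < shape[k] for k in range(3)):
        raise ValueError(f"lesion center {center} outside grid {shape}")
    sphere = _sphere_mask(shape, spec.voxel_size_mm, center, lesion.radius_mm)
    if not np.any(sphere & (subject.brain_mask.data > 0)):
        raise ValueError("lesion sphere does not intersect the brain mask")

    fld = LESION_CHANNELS[lesion.channel]
    if fld not in subject.truth:
        raise ValueError(
            f"subject has no generated channel for {lesion.channel!r}")
    out = copy.copy(subject)
    out.truth = dict(subject.truth)
    new = subject.truth[fld].copy()
    new[sphere] += lesion.delta * subject.sd_maps[fld][sphere]
    out.truth[fld] = _clip_field(fld, new)

    geo_like = {
        "gm_ribbon": subject.atlas.gm_mask.data.astype(bool)
        if subject.atlas.gm_mask is not None else np.zeros(shape, bool),
    }
    derive_ch = "T1w" if lesion.channel == "junction" else lesion.channel
    _derive_channel(out, spec, geo_like, derive_ch)
    return out


# ---------------------------------------------------------------------------
# File I/O (NIfTI-1 + JSON sidecar)
# ---------------------------------------------------------------------------

_VOLUME_FILES = {
    "echo_series": "echo.nii.gz", "mt_on": "mt_on.nii.gz",
    "mt_off": "mt_off.nii.gz", "md_map": "md.nii.gz",
    "thickness_map": "thickness.nii.gz", "t1w": "t1w.nii.gz",
    "brain_mask": "brain_mask.nii.gz",
}


def save_subject(subject: SubjectDataset, out_dir: str | Path) -> Path:
    """Write a subject as NIfTI-1 volumes plus a JSON sidecar."""
    out = Path(out_dir) / subject.subject_id
    out.mkdir(parents=True, exist_ok=True)
    for attr, fname in _VOLUME_FILES.items():
        vol = getattr(subject, attr)
        if vol is not None:
            vol.save(out / fname)
    for t, vol in subject.tpm.items():
        vol.save(out / f"tpm_{t}.nii.gz")
    save_json(
        {"subject_id": subject.subject_id, "te_ms": list(subject.te_ms)},
        out / "sidecar.json",
    )
    return out


def load_subject(sub_dir: str | Path, atlas: Atlas) -> SubjectDataset:
    sub_dir = Path(sub_dir)
    meta = load_json(sub_dir / "sidecar.json")
    vols = {}
    for attr, fname in _VOLUME_FILES.items():
        p = sub_dir / fname
        vols[attr] = VolumetricImage.load(p) if p.exists() else None
    tpm = {}
    for t in ("gm", "wm", "csf"):
        p = sub_dir / f"tpm_{t}.nii.gz"
        if p.exists():
            tpm[t] = VolumetricImage.load(p)
    if vols["brain_mask"] is None:
        raise FileNotFoundError(f"{sub_dir}: brain_mask.nii.gz missing")
    return SubjectDataset(
        subject_id=str(meta.get("subject_id", sub_dir.name)),
        affine=vols["brain_mask"].affine,
        brain_mask=vols["brain_mask"],
        tpm=tpm,
        atlas=atlas,
        te_ms=tuple(meta.get("te_ms", ())),
        echo_series=vols["echo_series"],
        mt_on=vols["mt_on"],
        mt_off=vols["mt_off"],
        md_map=vols["md_map"],
        thickness_map=vols["thickness_map"],
        t1w=vols["t1w"],
    )
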