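"""End-to-end orchestration: simulate -> maps -> calibrate -> detect -> score.

The pipeline takes a directory layout of NIfTI subjects (patients and
controls), an atlas, and a run configuration; it computes each requested
quantitative measure, calibrates or applies detection parameters, runs the
single-subject detector for every patient, scores lobe-level concordance
against each patient's EZ hypothesis, and writes a cohort report (TSV) plus
a structured run manifest (JSON) so every number is traceable to its inputs
and parameters.  Per-subject failures are recorded as postprocessing
failures without aborting the cohort, and they are excluded from the
denominators of per-measure percentages.
"""

from __future__ import annotations

import traceback
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .calibration import calibrate_fp, default_grid
from .concordance import EZHypothesis, score_concordance
from .image import Atlas, VolumetricImage, load_json, save_json
from .measures import MEASURES, compute_measure_map
from .phantom import SubjectDataset, load_subject
from .stats import ControlCohort, DetectionParams, detect

__all__ = ["RunConfig", "CohortReport", "run_pipeline", "analyze_cohort"]

FAILURE = "failure"


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    controls_dir: str
    patients_dir: str
    atlas_stem: str
    out_dir: str
    measures: tuple[str, ...] = MEASURES
    detection: dict[str, DetectionParams] = field(default_factory=dict)
    target_fp_rate: float = 0.10
    cortex_distance_mm: float = 5.0
    calibration_cluster_ks: tuple[int, ...] = (10, 30, 55)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.measures:
            raise ValueError("measure list must be nonempty")
        unknown = set(self.measures) - set(MEASURES)
        if unknown:
            raise ValueError(f"unknown measures {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        det = {}
        for m, p in (d.pop("detection", None) or {}).items():
            det[m] = DetectionParams(**p)
        if "measures" in d:
            d["measures"] = tuple(d["measures"])
        if "calibration_cluster_ks" in d:
            d["calibration_cluster_ks"] = tuple(d["calibration_cluster_ks"])
        return cls(detection=det, **d)


@dataclass
class CohortReport:
    """Per measure x subject findings plus marginal percentages."""

    table: pd.DataFrame  # rows: subjects; columns: measures + overall
    marginals: dict
    manifest: dict

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out / "report.tsv", sep="\t")
        save_json(self.marginals, out / "marginals.json")
        save_json(self.manifest, out / "manifest.json")


def _subject_dirs(root: str | Path) -> list[Path]:
    return sorted(p for p in Path(root).iterdir() if p.is_dir())


def analyze_cohort(patients: list[tuple[SubjectDataset, EZHypothesis]],
                   controls: list[SubjectDataset],
                   atlas: Atlas,
                   config: RunConfig) -> CohortReport:
    """Run the configured measures over in-memory subjects.

    Measures without explicit :class:`DetectionParams` in ``config.detection``
    are calibrated on the control cohort at ``config.target_fp_rate`` over the
    default grid first.
    """
    test_mask = controls[0].brain_mask if controls else patients[0][0].brain_mask
    manifest: dict = {
        "software": {"name": "qmlm", "version": __version__},
        "seed": config.seed,
        "n_controls": len(controls),
        "n_patients": len(patients),
        "measures": {},
    }
    rows: dict[str, dict] = {}
    positives: dict[str, dict[str, str]] = {}

    for measure in config.measures:
        mrec: dict = {}
        # control maps; a control failure is fatal for the measure
        cohort_maps = [compute_measure_map(c, measure) for c in controls]
        cohort = ControlCohort(cohort_maps, modality=measure)

        params = config.detection.get(measure)
        if params is None:
            calib = calibrate_fp(
                cohort, config.target_fp_rate,
                default_grid(cluster_ks=config.calibration_cluster_ks),
                atlas, test_mask, config.cortex_distance_mm)
            params = calib.chosen_params
            mrec["calibration"] = calib.to_dict()
        mrec["params"] = params.label()

        per_subject = {}
        for subject, ez in patients:
            sid = subject.subject_id
            try:
                smap = compute_measure_map(subject, measure)
                clusters = detect(smap, cohort, params, test_mask, atlas,
                                  config.cortex_distance_mm)
                conc = score_concordance(clusters, ez, atlas)
                if not len(clusters):
                    status = "negative"
                elif conc.subject_call == "concordant":
                    status = "concordant"
                elif conc.subject_call == "discordant_only":
                    status = "discordant"
                else:  # NA_NSLF with findings
                    status = "positive_NA"
                per_subject[sid] = {
                    "status": status,
                    "n_clusters": len(clusters),
                    "clusters": clusters.to_dict(),
                    "concordance": conc.to_dict(),
                }
            except Exception as exc:  # postprocessing failure, isolated
                per_subject[sid] = {
                    "status": FAILURE,
                    "error": f"{type(exc).__name__}: {exc}",
                    "trace": traceback.format_exc(limit=2),
                }
            rows.setdefault(sid, {})[measure] = per_subject[sid]["status"]
            positives.setdefault(measure, {})[sid] = per_subject[sid]["status"]
        mrec["subjects"] = per_subject
        manifest["measures"][measure] = mrec

    # overall column: union of per-measure findings over non-failed measures
    for sid, row in rows.items():
        statuses = [s for s in row.values() if s != FAILURE]
        if any(s == "concordant" for s in statuses):
            row["overall"] = "concordant"
        elif any(s in ("discordant", "positive_NA") for s in statuses):
            row["overall"] = "positive"
        elif statuses:
            row["overall"] = "negative"
        else:
            row["overall"] = FAILURE

    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table.index.name = "subject"

    marginals: dict = {}
    for measure in config.measures:
        col = {sid: s for sid, s in positives.get(measure, {}).items()}
        avail = [s for s in col.values() if s != FAILURE]
        pos = [s for s in avail if s in ("concordant", "discordant",
                                         "positive_NA")]
        conc = [s for s in avail if s == "concordant"]
        marginals[measure] = {
            "n_available": len(avail),
            "n_failures": len(col) - len(avail),
            "n_positive": len(pos),
            "n_concordant": len(conc),
            "pct_positive": (100.0 * len(pos) / len(avail)) if avail else None,
            "pct_concordant": (100.0 * len(conc) / len(avail)) if avail else None,
        }
    return CohortReport(table, marginals, manifest)


def run_pipeline(config: RunConfig) -> CohortReport:
    """File-based front end to :func:`analyze_cohort`."""
    atlas = Atlas.load(config.atlas_stem)
    controls = [load_subject(d, atlas) for d in _subject_dirs(config.controls_dir)]
    patients = []
    for d in _subject_dirs(config.patients_dir):
        ez_path = d / "ez.json"
        ez = (EZHypothesis.from_dict(load_json(ez_path)) if ez_path.exists()
              else EZHypothesis("NSLF"))
        try:
            patients.append((load_subject(d, atlas), ez))
        except Exception as exc:
            # unreadable subject: carried through as an all-failure row
            stub = SubjectDataset(
                subject_id=d.name, affine=atlas.labels.affine,
                brain_mask=VolumetricImage(
                    atlas.labels.data * 0, atlas.labels.affine),
                tpm={}, atlas=atlas)
            stub._load_error = f"{type(exc).__name__}: {exc}"  # type: ignore
            patients.append((stub, ez))
    report = analyze_cohort(patients, controls, atlas, config)
    report.save(config.out_dir)
    return report
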