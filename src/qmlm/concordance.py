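"""Lobe-level concordance between detected clusters and the EZ hypothesis.

The electroclinical work-up summarizes the suspected epileptogenic zone (EZ)
as one or more (lobe, side) regions — or declares no suspected location
("NSLF").  Each detected cluster is assigned a (lobe, side) from the atlas
label of its |z|-peak voxel (falling back to the majority label over the
cluster when the peak lies in excluded tissue), and a cluster is concordant
when its region matches any hypothesized EZ region; an unlateralized EZ
region matches either side.  The subject-level call is ``concordant`` as
soon as one cluster agrees, ``discordant_only`` when clusters exist but none
agree, ``no_findings`` without clusters, and ``NA_NSLF`` when there is no
electroclinical hypothesis to compare against.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .image import Atlas
from .stats import Cluster, ClusterSet

__all__ = ["EZHypothesis", "ConcordanceResult", "assign_cluster_region",
           "score_concordance"]

UNLATERALIZED = "unlateralized"


@dataclass(frozen=True)
class EZHypothesis:
    """Electroclinical localization: SLF with regions, or NSLF."""

    status: str  # "SLF" | "NSLF"
    regions: frozenset = frozenset()  # {(lobe, side)}

    def __post_init__(self) -> None:
        if self.status not in ("SLF", "NSLF"):
            raise ValueError("status must be 'SLF' or 'NSLF'")
        object.__setattr__(self, "regions",
                           frozenset((str(l), str(s)) for l, s in self.regions))
        if self.status == "SLF" and not self.regions:
            raise ValueError("SLF hypothesis requires at least one region")
        if self.status == "NSLF" and self.regions:
            raise ValueError("NSLF hypothesis must have no regions")

    @classmethod
    def from_dict(cls, d: dict) -> "EZHypothesis":
        return cls(d["status"], frozenset(map(tuple, d.get("regions", []))))

    def to_dict(self) -> dict:
        return {"status": self.status,
                "regions": sorted(map(list, self.regions))}

    def matches(self, region: tuple[str, str]) -> bool:
        lobe, side = region
        for ez_lobe, ez_side in self.regions:
            if ez_lobe == lobe and ez_side in (side, UNLATERALIZED):
                return True
        return False


@dataclass
class ConcordanceResult:
    """Per-cluster verdicts and the subject-level call."""

    per_cluster: list[dict]
    subject_call: str  # concordant | discordant_only | no_findings | NA_NSLF
    counts: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"per_cluster": self.per_cluster,
                "subject_call": self.subject_call,
                "counts": dict(self.counts)}


def assign_cluster_region(cluster: Cluster, atlas: Atlas) -> tuple[str, str]:
    """(lobe, side) of a cluster: peak-voxel label, majority fallback.

    When the peak voxel carries an excluded label (the cluster straddles a
    tissue boundary), the most frequent non-excluded label over the cluster's
    voxels decides; ties break toward the more frequent, then smaller label.
    """
    lab = int(atlas.labels.data[cluster.peak_voxel])
    if not atlas.is_excluded(lab):
        return atlas.region_of(lab)
    votes = Counter(
        int(v) for v in atlas.labels.data[tuple(cluster.voxels.T)]
        if not atlas.is_excluded(int(v))
    )
    if not votes:
        raise ValueError(
            f"cluster at {cluster.peak_voxel} has no labeled parenchymal voxels")
    best = min(votes.items(), key=lambda kv: (-kv[1], kv[0]))[0]
    return atlas.region_of(best)


def score_concordance(clusters: ClusterSet, ez: EZHypothesis,
                      atlas: Atlas) -> ConcordanceResult:
    """Score every cluster against the EZ hypothesis and call the subject."""
    per_cluster = []
    any_concordant = False
    counts = Counter()
    for i, c in enumerate(clusters.clusters):
        region = assign_cluster_region(c, atlas)
        c.region = region
        if ez.status == "NSLF":
            verdict = "NA"
        else:
            verdict = "yes" if ez.matches(region) else "no"
            any_concordant = any_concordant or verdict == "yes"
        counts[verdict] += 1
        per_cluster.append({"cluster": i, "region": list(region),
                            "concordant": verdict})
    if ez.status == "NSLF":
        call = "NA_NSLF"
    elif not per_cluster:
        call = "no_findings"
    elif any_concordant:
        call = "concordant"
    else:
        call = "discordant_only"
    return ConcordanceResult(per_cluster, call, dict(counts))
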