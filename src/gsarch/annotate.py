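"""Functional annotation of markers, grouping models, and marker panels.

Every marker is assigned to exactly one group under a named grouping model:

* ``FAN1`` - eight functional groups.  When a marker qualifies for several
  categories the most impactful one wins, in the order: coding variants,
  eQTLs, regulatory elements (split into those supported by both open
  chromatin and epigenetic evidence, epigenetic only, open chromatin only),
  exon-associated elements, intronic, intergenic.
* ``FAN2`` - as FAN1 but eQTLs and regulatory elements are split into
  muscle vs other-tissue categories instead of by detection technique.
* ``LDMS`` - 12 groups crossing three MAF bins ((0.01, 0.05], (0.05, 0.10],
  (0.10, 0.50]) with LD-score quartiles.
* ``LDMSxFAN1`` - the 96-cell Cartesian product of the two.

Panels (``FUN1``-``FUN3``, ``LD99``-``LD80``, ``ARRAY``) are marker subsets
used to pre-select variants for models that cannot use annotation directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genomatrix import GenotypeMatrix, LdProfile, ld_prune

__all__ = [
    "GenomicIntervals",
    "FeatureTracks",
    "AnnotationMap",
    "PanelSpec",
    "FAN1_LABELS",
    "FAN2_LABELS",
    "assign_fan1",
    "assign_fan2",
    "build_annotation",
    "build_ldms",
    "cross_groups",
    "build_panel",
    "PANEL_NAMES",
]

FAN1_LABELS = [
    "coding", "eqtl", "reg_atac", "reg_epigenetic", "reg_both",
    "exon_assoc", "intronic", "intergenic",
]
FAN2_LABELS = [
    "coding", "eqtl_muscle", "eqtl_other", "reg_muscle", "reg_other",
    "exon_assoc", "intronic", "intergenic",
]
PANEL_NAMES = ("WGS", "FUN1", "FUN2", "FUN3",
               "LD99", "LD98", "LD95", "LD90", "LD80", "ARRAY")
_LD_PANEL_THRESHOLDS = {"LD99": 0.99, "LD98": 0.98, "LD95": 0.95,
                        "LD90": 0.90, "LD80": 0.80}


class GenomicIntervals:
    """Per-chromosome interval set with optional muscle flags.

    Stored 1-based inclusive; a variant overlaps when its position lies
    inside an interval (indels are judged by start position only).
    """

    def __init__(self, records: Iterable[tuple] = ()):  # (chrom, start, end[, muscle])
        self._trees: dict[str, IntervalTree] = {}
        for rec in records:
            chrom, start, end = rec[0], int(rec[1]), int(rec[2])
            muscle = bool(rec[3]) if len(rec) > 3 else False
            self.add(chrom, start, end, muscle)

    def add(self, chrom, start: int, end: int, muscle: bool = False) -> None:
        if end < start:
            raise ValueError("interval end before start")
        tree = self._trees.setdefault(str(chrom), IntervalTree())
        tree.addi(start, end + 1, muscle)

    @classmethod
    def from_bed(cls, path, muscle: bool | None = None) -> "GenomicIntervals":
        """Load a BED file (0-based half-open), converting to 1-based.

        If the file has a fourth column equal to ``muscle`` the interval is
        muscle-flagged; an explicit ``muscle`` argument overrides.
        """
        out = cls()
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                parts = line.split()
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                flag = muscle if muscle is not None else (
                    len(parts) > 3 and parts[3].lower() == "muscle")
                out.add(chrom, start + 1, end, flag)
        return out

    def overlaps(self, chrom, pos: int) -> bool:
        tree = self._trees.get(str(chrom))
        return bool(tree is not None and tree.overlaps(pos))

    def muscle_overlaps(self, chrom, pos: int) -> bool:
        tree = self._trees.get(str(chrom))
        if tree is None:
            return False
        return any(iv.data for iv in tree.at(pos))

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())


@dataclass
class FeatureTracks:
    """Evidence tracks from which functional groups are derived."""

    coding_ids: set = field(default_factory=set)
    eqtl_ids: set = field(default_factory=set)
    eqtl_muscle_ids: set = field(default_factory=set)
    atac_intervals: GenomicIntervals = field(default_factory=GenomicIntervals)
    epigenetic_intervals: GenomicIntervals = field(default_factory=GenomicIntervals)
    exon_assoc_intervals: GenomicIntervals = field(default_factory=GenomicIntervals)
    intron_intervals: GenomicIntervals = field(default_factory=GenomicIntervals)
    mmd_ids: set = field(default_factory=set)
    array_ids: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.eqtl_muscle_ids <= self.eqtl_ids:
            self.eqtl_ids = self.eqtl_ids | self.eqtl_muscle_ids


@dataclass
class AnnotationMap:
    """Assignment of every marker to exactly one group."""

    model_name: str
    marker_ids: np.ndarray
    group_of: np.ndarray
    group_labels: list[str]

    def __post_init__(self) -> None:
        self.group_of = np.asarray(self.group_of, dtype=np.int64)
        if self.group_of.min(initial=0) < 0 or (
            self.group_of.size and self.group_of.max() >= len(self.group_labels)
        ):
            raise ValueError("group index out of range")

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)

    @property
    def group_sizes(self) -> np.ndarray:
        return np.bincount(self.group_of, minlength=self.n_groups)

    def to_frame(self) -> pd.DataFrame:
        labels = np.asarray(self.group_labels, dtype=object)
        return pd.DataFrame(
            {"marker_id": self.marker_ids, "group_label": labels[self.group_of]}
        )


@dataclass
class PanelSpec:
    name: str
    rule: str = ""


def assign_fan1(marker, tracks: FeatureTracks) -> str:
    """FAN1 group of one marker (``marker`` needs id/chrom/pos attributes)."""
    mid, chrom, pos = marker.id, marker.chrom, int(marker.pos)
    if mid in tracks.coding_ids:
        return "coding"
    if mid in tracks.eqtl_ids:
        return "eqtl"
    in_atac = tracks.atac_intervals.overlaps(chrom, pos)
    in_epi = tracks.epigenetic_intervals.overlaps(chrom, pos)
    if in_atac and in_epi:
        return "reg_both"
    if in_epi:
        return "reg_epigenetic"
    if in_atac:
        return "reg_atac"
    if tracks.exon_assoc_intervals.overlaps(chrom, pos):
        return "exon_assoc"
    if tracks.intron_intervals.overlaps(chrom, pos):
        return "intronic"
    return "intergenic"


def assign_fan2(marker, tracks: FeatureTracks) -> str:
    """FAN2 group; muscle evidence takes precedence over other tissues."""
    mid, chrom, pos = marker.id, marker.chrom, int(marker.pos)
    if mid in tracks.coding_ids:
        return "coding"
    if mid in tracks.eqtl_ids:
        return "eqtl_muscle" if mid in tracks.eqtl_muscle_ids else "eqtl_other"
    in_atac = tracks.atac_intervals.overlaps(chrom, pos)
    in_epi = tracks.epigenetic_intervals.overlaps(chrom, pos)
    if in_atac or in_epi:
        muscle = (tracks.atac_intervals.muscle_overlaps(chrom, pos)
                  or tracks.epigenetic_intervals.muscle_overlaps(chrom, pos))
        return "reg_muscle" if muscle else "reg_other"
    if tracks.exon_assoc_intervals.overlaps(chrom, pos):
        return "exon_assoc"
    if tracks.intron_intervals.overlaps(chrom, pos):
        return "intronic"
    return "intergenic"


def build_annotation(
    geno: GenotypeMatrix, tracks: FeatureTracks, model: str = "FAN1"
) -> AnnotationMap:
    """Assign every marker of ``geno`` under FAN1 or FAN2."""
    if model == "FAN1":
        labels, assign = FAN1_LABELS, assign_fan1
    elif model == "FAN2":
        labels, assign = FAN2_LABELS, assign_fan2
    else:
        raise ValueError(f"unknown annotation model {model!r}")
    index = {lab: i for i, lab in enumerate(labels)}
    groups = np.array(
        [index[assign(row, tracks)] for row in geno.markers.itertuples()]
    )
    return AnnotationMap(model, geno.marker_ids.copy(), groups, list(labels))


_MAF_EDGES = (0.01, 0.05, 0.10, 0.50)


def build_ldms(geno: GenotypeMatrix, ld: LdProfile) -> AnnotationMap:
    """12-group LD-score-quartile x MAF-bin stratification.

    Quartile boundaries use the nearest-rank convention on the marker set
    being grouped; a score exactly on a boundary falls in the lower
    quartile.  MAF bins are right-closed.
    """
    scores = np.asarray(ld.ld_score, dtype=float)
    if scores.shape[0] != geno.n_markers:
        raise ValueError("LD profile length does not match marker count")
    if np.unique(scores).size < 4:
        raise ValueError("need at least four distinct LD scores for quartiles")
    order = np.sort(scores)
    n = order.size
    bounds = [order[int(np.ceil(k * n / 4)) - 1] for k in (1, 2, 3)]
    ld_bin = np.searchsorted(bounds, scores, side="left")  # boundary -> lower
    maf = geno.maf()
    maf_bin = np.searchsorted(_MAF_EDGES[1:-1], maf, side="left")
    labels = [f"MS{m + 1}_LD{q + 1}" for m in range(3) for q in range(4)]
    groups = maf_bin * 4 + ld_bin
    return AnnotationMap("LDMS", geno.marker_ids.copy(), groups, labels)


def cross_groups(fan: AnnotationMap, ldms: AnnotationMap) -> AnnotationMap:
    """Cartesian product of two groupings; empty cells are kept at size 0."""
    if not np.array_equal(fan.marker_ids, ldms.marker_ids):
        raise ValueError("groupings cover different marker sets")
    labels = [f"{a}x{b}" for a in fan.group_labels for b in ldms.group_labels]
    groups = fan.group_of * ldms.n_groups + ldms.group_of
    return AnnotationMap(
        f"{fan.model_name}x{ldms.model_name}", fan.marker_ids.copy(),
        groups, labels,
    )


def build_panel(
    geno: GenotypeMatrix,
    tracks: FeatureTracks | None,
    spec: PanelSpec | str,
    ld_threshold: float | None = None,
    window_bp: int = 1_000_000,
) -> list[str]:
    """Marker ids of a named panel, de-duplicated and position-sorted.

    ``FUN1`` unions coding variants, eQTLs, variants in regulatory elements
    from either evidence source, and medium-density-array markers; ``FUN2``
    keeps only open-chromatin regulatory evidence and ``FUN3`` only the
    epigenetic catalogue.  ``LD99``-``LD80`` prune on pairwise r2 and
    ``ARRAY`` keeps commercial-array markers.
    """
    name = spec.name if isinstance(spec, PanelSpec) else str(spec)
    if name == "WGS":
        return list(geno.marker_ids)
    if name in _LD_PANEL_THRESHOLDS or name == "LD":
        thr = ld_threshold if ld_threshold is not None else \
            _LD_PANEL_THRESHOLDS.get(name)
        if thr is None:
            raise ValueError("LD panel needs a pruning threshold")
        return ld_prune(geno, r2_threshold=thr, window_bp=window_bp)
    if tracks is None:
        raise ValueError(f"panel {name!r} needs feature tracks")
    if name == "ARRAY":
        chosen = tracks.array_ids
    elif name in ("FUN1", "FUN2", "FUN3"):
        chosen = set(tracks.coding_ids) | set(tracks.eqtl_ids) | set(tracks.mmd_ids)
        use_atac = name in ("FUN1", "FUN2")
        use_epi = name in ("FUN1", "FUN3")
        for row in geno.markers.itertuples():
            if row.id in chosen:
                continue
            pos = int(row.pos)
            if use_atac and tracks.atac_intervals.overlaps(row.chrom, pos):
                chosen.add(row.id)
            elif use_epi and tracks.epigenetic_intervals.overlaps(row.chrom, pos):
                chosen.add(row.id)
    else:
        raise ValueError(f"unknown panel name {name!r}")
    mask = geno.markers["id"].isin(chosen).to_numpy()
    return list(geno.marker_ids[mask])
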