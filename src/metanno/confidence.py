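"""Confidence grading and redundancy removal.

Peaks sharing a metabolite annotation are clustered by retention time into
*peak groups* (monoisotope, isotope and adduct peaks of one metabolite
co-elute).  Each group gets a confidence grade:

* grade 1 — contains a spectral-library (round-0) annotation,
* grade 2 — otherwise, contains isotope peaks,
* grade 3 — otherwise, contains a reliable adduct
  ([M+H]+/[M+Na]+/[M+NH4]+ positive, [M-H]-/[M+Cl]-/[M+CH3COO]- negative),
* grade 4 — none of the above.

Redundancy removal then alternates two pruning rules with regrouping until
the annotation redundancy stops changing: a metabolite spread over several
peak groups loses its grade-4 groups (unless all are grade 4), and a peak
with several metabolite annotations keeps only the best grade.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .models import Annotation, MS1Peak, ROLE_ADDUCT, ROLE_ISOTOPE, ROLE_MONO

log = logging.getLogger(__name__)

__all__ = [
    "PeakGroup",
    "RedundancyReport",
    "RELIABLE_ADDUCTS",
    "group_peaks",
    "assign_grades",
    "remove_redundancy",
]

RELIABLE_ADDUCTS = {
    "[M+H]+", "[M+Na]+", "[M+NH4]+",
    "[M-H]-", "[M+Cl]-", "[M+CH3COO]-",
}


@dataclass
class PeakGroup:
    """Co-eluting annotated peaks of one metabolite."""

    metabolite_id: str
    annotations: list[Annotation] = field(default_factory=list)
    rt_center: float = 0.0
    grade: int | None = None


@dataclass(frozen=True)
class RedundancyReport:
    """Annotations per peak / peak groups per metabolite, and their mean."""

    peak_redundancy: float
    metabolite_redundancy: float

    @property
    def combined(self) -> float:
        return 0.5 * (self.peak_redundancy + self.metabolite_redundancy)


def group_peaks(
    annotations: list[Annotation],
    peaks: list[MS1Peak],
    rt_window_s: float = 3.0,
) -> list[PeakGroup]:
    """Cluster each metabolite's annotated peaks by RT (single linkage).

    Two peaks join the same group when their RTs differ by at most the
    window (transitively).  A peak with annotations for several metabolites
    belongs to one group per metabolite.
    """
    rt = {p.peak_id: p.rt for p in peaks}
    by_met: dict[str, list[Annotation]] = {}
    for a in annotations:
        by_met.setdefault(a.metabolite_id, []).append(a)
    groups: list[PeakGroup] = []
    for met_id, anns in by_met.items():
        anns = sorted(anns, key=lambda a: rt[a.peak_id])
        current: list[Annotation] = []
        last_rt = None
        for a in anns:
            r = rt[a.peak_id]
            if last_rt is not None and r - last_rt > rt_window_s:
                groups.append(_finish_group(met_id, current, rt))
                current = []
            current.append(a)
            last_rt = r
        if current:
            groups.append(_finish_group(met_id, current, rt))
    return groups


def _finish_group(met_id: str, anns: list[Annotation], rt: dict[str, float]) -> PeakGroup:
    rts = [rt[a.peak_id] for a in anns]
    return PeakGroup(metabolite_id=met_id, annotations=list(anns), rt_center=sum(rts) / len(rts))


def assign_grades(groups: list[PeakGroup]) -> list[PeakGroup]:
    """Apply the grade ladder; the grade is stamped on groups and members."""
    for g in groups:
        if any(a.round == 0 and a.role == ROLE_MONO for a in g.annotations):
            grade = 1
        elif any(a.role == ROLE_ISOTOPE for a in g.annotations):
            grade = 2
        elif any(a.role == ROLE_ADDUCT and a.adduct in RELIABLE_ADDUCTS for a in g.annotations):
            grade = 3
        else:
            grade = 4
        g.grade = grade
        for a in g.annotations:
            a.grade = grade
    return groups


def _redundancy(groups: list[PeakGroup]) -> RedundancyReport:
    """Redundancy over monoisotope-role annotations (identifications)."""
    mono = [a for g in groups for a in g.annotations if a.role == ROLE_MONO]
    peaks_annotated = {a.peak_id for a in mono}
    mets = {a.metabolite_id for a in mono}
    mono_groups = [g for g in groups if any(a.role == ROLE_MONO for a in g.annotations)]
    if not mono or not peaks_annotated or not mets:
        return RedundancyReport(0.0, 0.0)
    return RedundancyReport(
        peak_redundancy=len(mono) / len(peaks_annotated),
        metabolite_redundancy=len(mono_groups) / len(mets),
    )


def remove_redundancy(
    annotations: list[Annotation],
    peaks: list[MS1Peak],
    rt_window_s: float = 3.0,
    max_iter: int = 20,
    trace: list[RedundancyReport] | None = None,
) -> tuple[list[Annotation], RedundancyReport, list[PeakGroup]]:
    """Prune redundant annotations until the redundancy is stable.

    Each iteration regroups and regrades, then applies, in order:

    1. a metabolite matched to several peak groups drops its grade-4
       groups — unless *all* of its groups are grade 4, in which case they
       all survive;
    2. a peak annotated as several metabolites keeps only the annotations
       with the best grade (ties all kept, ranked downstream by score).

    Returns the retained annotations, the final redundancy report and the
    final grouping.
    """
    current = list(annotations)
    prev_red: float | None = None
    for _ in range(max_iter):
        groups = assign_grades(group_peaks(current, peaks, rt_window_s))
        report = _redundancy(groups)
        if trace is not None:
            trace.append(report)

        # rule 1: per metabolite, drop grade-4 groups when better ones exist
        by_met: dict[str, list[PeakGroup]] = {}
        for g in groups:
            by_met.setdefault(g.metabolite_id, []).append(g)
        doomed: set[int] = set()
        for met_id, gs in by_met.items():
            if len(gs) > 1 and any(g.grade != 4 for g in gs):
                for g in gs:
                    if g.grade == 4:
                        doomed.update(id(a) for a in g.annotations)
        survivors = [a for a in current if id(a) not in doomed]

        # rule 2: per peak, keep only the best-grade annotations
        by_peak: dict[str, list[Annotation]] = {}
        for a in survivors:
            by_peak.setdefault(a.peak_id, []).append(a)
        kept: list[Annotation] = []
        for pid, anns in by_peak.items():
            mono = [a for a in anns if a.role == ROLE_MONO and a.grade is not None]
            if len({a.metabolite_id for a in mono}) > 1:
                best = min(a.grade for a in mono)
                keep_mets = {a.metabolite_id for a in mono if a.grade == best}
                for a in anns:
                    if a.role != ROLE_MONO or a.metabolite_id in keep_mets:
                        kept.append(a)
            else:
                kept.extend(anns)

        changed = len(kept) != len(current)
        current = kept
        if not changed and prev_red is not None and report.combined == prev_red:
            # drop support annotations orphaned by removed identifications
            mono_keys = {(a.metabolite_id) for a in current if a.role == ROLE_MONO}
            current = [
                a for a in current
                if a.role == ROLE_MONO or a.metabolite_id in mono_keys
            ]
            groups = assign_grades(group_peaks(current, peaks, rt_window_s))
            return current, _redundancy(groups), groups
        prev_red = report.combined
    raise RuntimeError(f"redundancy removal did not stabilize in {max_iter} iterations")
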