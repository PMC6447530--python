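"""Annotation of initial seed metabolites against the spectral library.

Experimental MS1/MS2 pairs are matched to standard-library records whose
precursor lies within the MS1 m/z tolerance.  The spectral similarity is
the dot product in both forward and reverse direction; an annotation is
kept when either exceeds the library threshold (default 0.8).  Surviving
annotations are filtered by predicted retention time (default ±30%) and
those present in the reaction network become the round-0 seeds of the
recursive annotation.
"""

from __future__ import annotations

import logging

from .models import Annotation, LibraryRecord, MS1Peak, Seed
from .mrn import ReactionPairNetwork
from .spectra import (
    DEFAULT_SCORING,
    SpectralScoringConfig,
    Spectrum,
    dot_product,
    normalize,
)

log = logging.getLogger(__name__)

__all__ = ["match_library", "filter_by_predicted_rt", "init_seeds"]


def match_library(
    pairs: dict[str, Spectrum],
    peaks: list[MS1Peak],
    library: list[LibraryRecord],
    mz_tol_ppm: float = 25.0,
    dp_keep: float = 0.8,
    ce: str | None = None,
    cfg: SpectralScoringConfig = DEFAULT_SCORING,
) -> list[Annotation]:
    """Match MS1/MS2 pairs against the standard spectral library.

    Keeps an annotation when the forward OR the reverse dot product exceeds
    ``dp_keep`` (strictly).  When one peak matches several records of the
    same metabolite (e.g. different collision energies) only the
    highest-scoring record survives.  ``ce`` restricts the library to one
    collision-energy label before matching.
    """
    if not library:
        log.warning("spectral library is empty; no seed annotations possible")
        return []
    if ce is not None:
        library = [r for r in library if r.collision_energy == ce]
    peak_by_id = {p.peak_id: p for p in peaks}
    annotations: list[Annotation] = []
    for peak_id, spec in pairs.items():
        peak = peak_by_id.get(peak_id)
        if peak is None:
            continue
        exp = normalize(spec)
        tol = peak.mz * mz_tol_ppm * 1e-6
        best_per_met: dict[str, Annotation] = {}
        for rec in library:
            if abs(rec.precursor_mz - peak.mz) > tol:
                continue
            ref = normalize(rec.spectrum)
            fwd = dot_product(exp, ref, cfg, mode="forward")
            rev = dot_product(exp, ref, cfg, mode="reverse")
            if not (fwd > dp_keep or rev > dp_keep):
                continue
            dp = max(fwd, rev)
            ann = Annotation(
                peak_id=peak_id,
                metabolite_id=rec.metabolite_id,
                adduct=rec.adduct,
                score_spec=dp,
                total_score=dp,
                round=0,
            )
            prev = best_per_met.get(rec.metabolite_id)
            if prev is None or ann.score_spec > prev.score_spec:
                best_per_met[rec.metabolite_id] = ann
        annotations.extend(best_per_met.values())
    return annotations


def filter_by_predicted_rt(
    annotations: list[Annotation],
    peaks: list[MS1Peak],
    predicted_rt: dict[str, float],
    rt_tol_frac: float = 0.30,
) -> list[Annotation]:
    """Keep annotations whose peak RT agrees with the predicted RT (±30%).

    Metabolites without a predicted RT cannot be checked; their annotations
    are kept but flagged ``rt_checked=False`` and logged.
    """
    rt_by_peak = {p.peak_id: p.rt for p in peaks}
    kept: list[Annotation] = []
    n_unchecked = 0
    for a in annotations:
        rt_t = predicted_rt.get(a.metabolite_id)
        rt_e = rt_by_peak[a.peak_id]
        if rt_t is None or rt_t <= 0:
            a.rt_checked = False
            n_unchecked += 1
            kept.append(a)
            continue
        if abs(rt_e - rt_t) / rt_t <= rt_tol_frac:
            rel = abs(rt_e - rt_t) / rt_t
            a.score_rt = 1.0 - rel / rt_tol_frac
            kept.append(a)
    if n_unchecked:
        log.warning("%d annotations kept without an RT check (no predicted RT)", n_unchecked)
    return kept


def init_seeds(
    annotations: list[Annotation],
    net: ReactionPairNetwork,
    pairs: dict[str, Spectrum],
) -> list[Seed]:
    """Turn round-0 annotations into seeds: one per (metabolite, peak).

    Only metabolites that exist as network nodes can propagate; the others
    remain valid identifications but are logged as non-propagating.  A
    metabolite annotated on several peaks yields one seed record per peak,
    each carrying its own experimental spectrum.
    """
    seeds: list[Seed] = []
    n_outside = 0
    for a in annotations:
        if a.round != 0:
            continue
        if a.metabolite_id not in net:
            n_outside += 1
            continue
        spec = pairs.get(a.peak_id)
        if spec is None:
            continue
        seeds.append(
            Seed(
                metabolite_id=a.metabolite_id,
                peak_id=a.peak_id,
                spectrum=normalize(spec),
                score=a.total_score,
                round=0,
            )
        )
    if n_outside:
        log.info("%d library identifications are outside the reaction network", n_outside)
    if not seeds:
        raise RuntimeError(
            "no seed metabolites: the spectral library matched nothing inside the "
            "reaction network; consider a larger library or looser thresholds"
        )
    return seeds
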