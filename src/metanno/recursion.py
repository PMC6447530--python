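"""MRN-based recursive annotation.

Each seed metabolite lends its experimental MS2 spectrum to its
reaction-paired neighbors as a *surrogate* spectrum — the working
assumption being that metabolites one enzymatic reaction apart tend to
share fragmentation behavior.  A neighbor is annotated on an MS1 peak when

* the peak m/z matches the neighbor's theoretical adduct m/z (±25 ppm),
* the peak RT matches the neighbor's predicted RT (±30%), and
* the peak's own MS2 spectrum resembles the precursor-trimmed surrogate
  (dot product >= 0.5).

Matches are scored  Score_iden = 0.25*Score_mz + 0.25*Score_rt + 0.5*Score_spec.
Newly annotated metabolites become next-round seeds; the loop ends when a
round produces no new seeds.  Because the cumulative seed set grows
strictly while bounded by the network's node count, termination is
guaranteed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .isotopes import (
    DEFAULT_ISO_CFG,
    IsoAdductScoringConfig,
    PeakIndex,
    annotate_isotopes,
    score_mz,
)
from .models import Annotation, MS1Peak, RoundLog, Seed, ROLE_MONO
from .mrn import ReactionPairNetwork
from .spectra import (
    DEFAULT_SCORING,
    SpectralScoringConfig,
    Spectrum,
    dot_product,
    normalize,
    trim_to_precursor,
)

log = logging.getLogger(__name__)

__all__ = [
    "NeighborScoringConfig",
    "score_rt_pct",
    "annotate_neighbors",
    "select_new_seeds",
    "run_recursion",
]


@dataclass(frozen=True)
class NeighborScoringConfig:
    """Tolerances and weights of the neighbor-annotation score."""

    mz_tol_ppm: float = 25.0
    rt_tol_frac: float = 0.30
    spec_min: float = 0.5
    w_mz: float = 0.25
    w_rt: float = 0.25
    w_spec: float = 0.50
    max_reaction_step: int = 3
    score_cutoff: float = 0.4
    top_k: int = 5
    max_rounds: int = 50
    spec_mode: str = "forward"  # dot-product direction on trimmed spectra

    def __post_init__(self):
        if abs(self.w_mz + self.w_rt + self.w_spec - 1.0) > 1e-9:
            raise ValueError("score weights must sum to 1")
        if not (0 < self.spec_min <= 1):
            raise ValueError("spec_min must be in (0, 1]")
        if self.max_reaction_step < 1:
            raise ValueError("max_reaction_step must be >= 1")


DEFAULT_NEIGHBOR_CFG = NeighborScoringConfig()


def score_rt_pct(rt_e: float, rt_t: float, tol_frac: float = 0.30) -> float:
    """Relative-RT match score: 1 at equality, 0 at the percent tolerance."""
    if rt_t <= 0:
        raise ValueError("theoretical RT must be > 0")
    return 1.0 - abs((rt_e - rt_t) * 100.0 / rt_t) / (tol_frac * 100.0)


def annotate_neighbors(
    seed: Seed,
    net: ReactionPairNetwork,
    index: PeakIndex,
    peak_spectra: dict[str, Spectrum],
    predicted_rt: dict[str, float],
    adducts,
    cfg: NeighborScoringConfig = DEFAULT_NEIGHBOR_CFG,
    round_index: int = 1,
    spec_cfg: SpectralScoringConfig = DEFAULT_SCORING,
) -> tuple[list[Annotation], int]:
    """Annotate one seed's reaction-paired neighbors with surrogate spectra.

    Neighbors are first retrieved at one reaction step; if the seed yields
    no annotation there, the search widens to two and then three steps
    (``cfg.max_reaction_step``).  Only network nodes flagged eligible (an
    organic structure) are considered, and only candidate peaks carrying
    their own MS2 spectrum can be scored.

    Returns the annotations plus the number of neighbor metabolites
    retrieved at the widest step used.
    """
    if seed.metabolite_id not in net:
        raise KeyError(f"seed metabolite {seed.metabolite_id!r} not in network")
    surrogate = normalize(seed.spectrum)
    eligible = net.eligible_ids()
    annotations: list[Annotation] = []
    n_retrieved = 0
    for step in range(1, cfg.max_reaction_step + 1):
        neighbor_ids = [
            m for m in net.neighbors_within(seed.metabolite_id, step) if m in eligible
        ]
        n_retrieved = len(neighbor_ids)
        for met_id in neighbor_ids:
            node = net.node(met_id)
            if node.monoisotopic_mass <= 0:
                continue
            rt_t = predicted_rt.get(met_id)
            if rt_t is not None and rt_t <= 0:
                rt_t = None
            for rule in adducts:
                mz_t = rule.mz_from_mass(node.monoisotopic_mass)
                for cand in index.query(mz_t, cfg.mz_tol_ppm):
                    if rt_t is not None and abs(cand.rt - rt_t) / rt_t > cfg.rt_tol_frac:
                        continue
                    exp = peak_spectra.get(cand.peak_id)
                    if exp is None:
                        continue
                    surr_t, exp_t = trim_to_precursor(
                        surrogate, seed.spectrum.precursor_mz, mz_t, normalize(exp)
                    )
                    s_spec = dot_product(exp_t, surr_t, spec_cfg, mode=cfg.spec_mode)
                    if s_spec < cfg.spec_min:
                        continue
                    s_mz = score_mz(cand.mz, mz_t, cfg.mz_tol_ppm)
                    # without a usable predicted RT the candidate is matched
                    # on m/z and spectrum alone; the RT component scores 0
                    s_rt = score_rt_pct(cand.rt, rt_t, cfg.rt_tol_frac) if rt_t is not None else 0.0
                    total = cfg.w_mz * s_mz + cfg.w_rt * s_rt + cfg.w_spec * s_spec
                    annotations.append(
                        Annotation(
                            peak_id=cand.peak_id,
                            metabolite_id=met_id,
                            adduct=rule.name,
                            role=ROLE_MONO,
                            score_mz=s_mz,
                            score_rt=s_rt,
                            score_spec=s_spec,
                            total_score=total,
                            round=round_index,
                            seed_parent=seed.metabolite_id,
                            rt_checked=rt_t is not None,
                        )
                    )
        if annotations:
            break
    return annotations, n_retrieved


def select_new_seeds(
    annotations: list[Annotation],
    prior_seed_metabolites: set[str],
    peak_spectra: dict[str, Spectrum],
    round_index: int,
) -> list[Seed]:
    """Promote newly annotated metabolites to seeds for the next round.

    A metabolite that has already served as a seed is not re-seeded (this
    caps redundancy and guarantees termination).  A metabolite annotated on
    several new peaks contributes one seed carrying the spectrum of its
    best-scoring peak.
    """
    best: dict[str, Annotation] = {}
    for a in annotations:
        if a.role != ROLE_MONO or a.metabolite_id in prior_seed_metabolites:
            continue
        if a.peak_id not in peak_spectra:
            continue  # no MS2 -> cannot serve a surrogate spectrum
        prev = best.get(a.metabolite_id)
        if prev is None or a.total_score > prev.total_score:
            best[a.metabolite_id] = a
    return [
        Seed(
            metabolite_id=a.metabolite_id,
            peak_id=a.peak_id,
            spectrum=normalize(peak_spectra[a.peak_id]),
            score=a.total_score,
            round=round_index,
        )
        for a in best.values()
    ]


def run_recursion(
    seeds0: list[Seed],
    net: ReactionPairNetwork,
    peaks: list[MS1Peak],
    peak_spectra: dict[str, Spectrum],
    predicted_rt: dict[str, float],
    adducts,
    cfg: NeighborScoringConfig = DEFAULT_NEIGHBOR_CFG,
    iso_cfg: IsoAdductScoringConfig = DEFAULT_ISO_CFG,
    round0_annotations: list[Annotation] | None = None,
    annotate_isotope_peaks: bool = True,
) -> tuple[list[Annotation], list[RoundLog]]:
    """Run seed -> neighbor-annotation -> seed-selection to convergence.

    When one (peak, metabolite) pair is derived repeatedly — from different
    seeds or in different rounds — the single highest-scoring instance is
    kept, and round-0 library annotations are never overwritten.  Isotope
    annotation runs for every new monoisotope annotation.

    Returns all annotations (round 0 included) and the per-round log.
    """
    if not seeds0:
        raise ValueError("at least one initial seed is required")
    index = PeakIndex(peaks)
    peak_by_id = {p.peak_id: p for p in peaks}
    store: dict[tuple[str, str], Annotation] = {}
    support: dict[tuple[str, str, str, int], Annotation] = {}
    for a in round0_annotations or []:
        key = a.key
        prev = store.get(key)
        if prev is None or a.total_score > prev.total_score:
            store[key] = a

    def add_isotopes(ann: Annotation) -> None:
        node = net.node(ann.metabolite_id) if ann.metabolite_id in net.compounds else None
        if node is None or not node.formula:
            return
        peak = peak_by_id.get(ann.peak_id)
        if peak is None:
            return
        for iso in annotate_isotopes(
            ann, peak, node.formula, index, iso_cfg,
            monoisotopic_mass=node.monoisotopic_mass or None,
        ):
            skey = (iso.peak_id, iso.metabolite_id, iso.role, iso.isotope_k)
            prev = support.get(skey)
            if prev is None or iso.total_score > prev.total_score:
                support[skey] = iso

    if annotate_isotope_peaks:
        for a in list(store.values()):
            add_isotopes(a)

    seeded: set[str] = {s.metabolite_id for s in seeds0}
    current = list(seeds0)
    logs: list[RoundLog] = []
    round_index = 0
    while current:
        round_index += 1
        if round_index > cfg.max_rounds:
            raise RuntimeError(
                f"recursion exceeded {cfg.max_rounds} rounds without converging"
            )
        new_this_round: list[Annotation] = []
        n_retrieved = 0
        for seed in current:
            anns, n_r = annotate_neighbors(
                seed, net, index, peak_spectra, predicted_rt, adducts,
                cfg, round_index=round_index,
            )
            n_retrieved += n_r
            for a in anns:
                prev = store.get(a.key)
                if prev is None:
                    store[a.key] = a
                    new_this_round.append(a)
                    if annotate_isotope_peaks:
                        add_isotopes(a)
                elif prev.round != 0 and a.total_score > prev.total_score:
                    # better re-derivation: keep the improved scores but
                    # stamp the round of first appearance
                    a.round = prev.round
                    store[a.key] = a
        new_seeds = select_new_seeds(new_this_round, seeded, peak_spectra, round_index)
        seeded.update(s.metabolite_id for s in new_seeds)
        logs.append(
            RoundLog(
                round=round_index,
                n_seeds_in=len(current),
                n_neighbors_retrieved=n_retrieved,
                n_annotated=len(new_this_round),
                n_new_seeds=len(new_seeds),
            )
        )
        current = new_seeds
    annotations = list(store.values()) + list(support.values())
    return annotations, logs
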