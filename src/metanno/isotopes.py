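"""Isotope envelopes and adduct peaks: generation and scoring.

For every annotated metabolite the engine predicts the isotopologue
envelope [M] .. [M+4] from the molecular formula and searches the MS1 peak
table for the corresponding peaks, then does the same for alternative
adduct forms ([M+Na]+ etc.).  Matched support peaks receive weighted
component scores:

    Score_iso    = W_mz * Score_mz + W_rt * Score_rt + W_int * Score_int
    Score_adduct = W_mz * Score_mz + W_rt * Score_rt

with each component a linear ramp from 1 (exact match) to 0 (at the match
tolerance).  Matches outside tolerance are rejected before scoring, so all
scores lie in [0, 1] by construction.

Isotopologue intensities are computed by exact polynomial expansion of the
natural isotope abundances, aggregated by nominal mass shift (isotopic fine
structure is merged, which is what the [M+k] notation implies) and reported
as percentages of the monoisotopic peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import Annotation, AdductRule, MS1Peak, ROLE_ADDUCT, ROLE_ISOTOPE
from .mrn import parse_formula

__all__ = [
    "IsotopePattern",
    "IsoAdductScoringConfig",
    "ISOTOPE_ABUNDANCES",
    "POSITIVE_ADDUCTS",
    "NEGATIVE_ADDUCTS",
    "adduct_rules",
    "isotope_pattern",
    "score_mz",
    "score_rt_abs",
    "score_rel_int",
    "annotate_isotopes",
    "annotate_adducts",
]

# Natural isotope abundances, NIST compilation: per element, a list of
# (nominal mass shift from the lightest isotope, fractional abundance).
# Pinned here so envelope predictions are bit-identical across platforms.
ISOTOPE_ABUNDANCES: dict[str, list[tuple[int, float]]] = {
    "H": [(0, 0.999885), (1, 0.000115)],
    "C": [(0, 0.9893), (1, 0.0107)],
    "N": [(0, 0.99636), (1, 0.00364)],
    "O": [(0, 0.99757), (1, 0.00038), (2, 0.00205)],
    "P": [(0, 1.0)],
    "S": [(0, 0.9499), (1, 0.0075), (2, 0.0425), (4, 0.0001)],
    "Cl": [(0, 0.7576), (2, 0.2424)],
    "Br": [(0, 0.5069), (2, 0.4931)],
    "Na": [(0, 1.0)],
    "K": [(0, 0.932581), (1, 0.000117), (2, 0.067302)],
    "F": [(0, 1.0)],
    "I": [(0, 1.0)],
}

#: average isotopologue m/z spacing (the 13C mass difference dominates
#: organic envelopes)
ISOTOPE_SPACING = 1.0033548378

N_ISOTOPE_PEAKS = 5  # [M] .. [M+4]


@dataclass(frozen=True)
class IsotopePattern:
    """Theoretical envelope: m/z and relative intensity (% of [M]) for [M+k]."""

    mz: tuple[float, ...]
    relative_intensity: tuple[float, ...]  # percent, entry 0 == 100

    def __len__(self) -> int:
        return len(self.mz)


@dataclass(frozen=True)
class IsoAdductScoringConfig:
    mz_tol_ppm: float = 25.0
    rt_tol_s: float = 3.0
    int_tol_pct: float = 500.0
    iso_w_mz: float = 0.45
    iso_w_rt: float = 0.45
    iso_w_int: float = 0.10
    adduct_w_mz: float = 0.8
    adduct_w_rt: float = 0.2

    def __post_init__(self):
        if not np.isclose(self.iso_w_mz + self.iso_w_rt + self.iso_w_int, 1.0):
            raise ValueError("isotope score weights must sum to 1")
        if not np.isclose(self.adduct_w_mz + self.adduct_w_rt, 1.0):
            raise ValueError("adduct score weights must sum to 1")
        if min(self.mz_tol_ppm, self.rt_tol_s, self.int_tol_pct) <= 0:
            raise ValueError("tolerances must be > 0")


DEFAULT_ISO_CFG = IsoAdductScoringConfig()

# Default adduct tables for singly charged species.  Mass shifts include the
# electron, e.g. [M+H]+ = M + 1.007276.  Overridable via a CSV adduct table.
POSITIVE_ADDUCTS = [
    AdductRule("[M+H]+", 1.0072765, +1, "both", "positive"),
    AdductRule("[M+Na]+", 22.9892213, +1, "both", "positive"),
    AdductRule("[M+NH4]+", 18.0338254, +1, "both", "positive"),
    AdductRule("[M+K]+", 38.9631585, +1, "both", "positive"),
    AdductRule("[M+H-H2O]+", -17.0032882, +1, "both", "positive"),
]
NEGATIVE_ADDUCTS = [
    AdductRule("[M-H]-", -1.0072765, -1, "both", "negative"),
    AdductRule("[M+Cl]-", 34.9694013, -1, "both", "negative"),
    AdductRule("[M+CH3COO]-", 59.0138536, -1, "both", "negative"),
    AdductRule("[M-H-H2O]-", -19.0178410, -1, "both", "negative"),
]


def adduct_rules(polarity: str = "positive", lc: str = "HILIC") -> list[AdductRule]:
    table = POSITIVE_ADDUCTS if polarity == "positive" else NEGATIVE_ADDUCTS
    return [r for r in table if r.lc in ("both", lc)]


def _truncated_power(p: np.ndarray, n: int, length: int) -> np.ndarray:
    """(p convolved with itself n times), truncated to ``length`` terms."""
    result = np.zeros(length)
    result[0] = 1.0
    base = p[:length].copy()
    while n > 0:
        if n & 1:
            result = np.convolve(result, base)[:length]
        base = np.convolve(base, base)[:length]
        n >>= 1
    return result


def isotope_pattern(formula: str, adduct: AdductRule | None = None,
                    monoisotopic_mass: float | None = None) -> IsotopePattern:
    """Theoretical [M]..[M+4] envelope for a formula (and optional adduct).

    The abundance distribution over nominal mass shifts is the product of
    per-element multinomial distributions, computed exactly by truncated
    polynomial exponentiation.  Intensities are returned as % of [M]; m/z
    values step by the 13C spacing from the monoisotopic ion m/z.
    """
    counts = parse_formula(formula)
    unsupported = [el for el in counts if el not in ISOTOPE_ABUNDANCES]
    if unsupported:
        raise ValueError(f"unsupported element(s) {unsupported} in formula {formula!r}")
    dist = np.zeros(N_ISOTOPE_PEAKS)
    dist[0] = 1.0
    for el, n in counts.items():
        p = np.zeros(N_ISOTOPE_PEAKS)
        for shift, ab in ISOTOPE_ABUNDANCES[el]:
            if shift < N_ISOTOPE_PEAKS:
                p[shift] = ab
        dist = np.convolve(dist, _truncated_power(p, n, N_ISOTOPE_PEAKS))[:N_ISOTOPE_PEAKS]
    rel = (dist / dist[0]) * 100.0

    if monoisotopic_mass is None:
        from pyteomics import mass as _pytmass

        monoisotopic_mass = float(_pytmass.calculate_mass(formula=formula))
    mono_mz = adduct.mz_from_mass(monoisotopic_mass) if adduct is not None else monoisotopic_mass
    mzs = tuple(mono_mz + k * ISOTOPE_SPACING for k in range(N_ISOTOPE_PEAKS))
    return IsotopePattern(mz=mzs, relative_intensity=tuple(rel))


# ---------------------------------------------------------------------------
# Component scores (linear ramps on the match error)


def score_mz(mz_e: float, mz_t: float, tol_ppm: float = 25.0) -> float:
    """1 at exact m/z match, 0 at the ppm tolerance."""
    return 1.0 - abs((mz_e - mz_t) * 1e6 / mz_t) / tol_ppm


def score_rt_abs(rt_e: float, rt_t: float, tol_s: float = 3.0) -> float:
    """1 at exact co-elution, 0 at the absolute RT tolerance (seconds)."""
    return 1.0 - abs(rt_e - rt_t) / tol_s


def score_rel_int(int_e_pct: float, int_t_pct: float, tol_pct: float = 500.0) -> float:
    """1 at exact relative-intensity match, 0 at the tolerance.

    The deviation is normalized by the theoretical intensity, so the
    tolerance is not symmetric in ratio space (a 6-fold excess scores 0, a
    6-fold deficit does not); this is deliberate.
    """
    return 1.0 - abs((int_e_pct - int_t_pct) * 100.0 / int_t_pct) / tol_pct


# ---------------------------------------------------------------------------
# Support-peak annotation


class PeakIndex:
    """m/z-sorted index over MS1 peaks for tolerance window queries."""

    def __init__(self, peaks: list[MS1Peak]):
        self.peaks = sorted(peaks, key=lambda p: p.mz)
        self._mz = np.array([p.mz for p in self.peaks])

    def query(self, mz: float, tol_ppm: float) -> list[MS1Peak]:
        tol = mz * tol_ppm * 1e-6
        lo = np.searchsorted(self._mz, mz - tol, side="left")
        hi = np.searchsorted(self._mz, mz + tol, side="right")
        return self.peaks[lo:hi]


def annotate_isotopes(
    parent: Annotation,
    parent_peak: MS1Peak,
    formula: str,
    index: PeakIndex,
    cfg: IsoAdductScoringConfig = DEFAULT_ISO_CFG,
    adduct: AdductRule | None = None,
    monoisotopic_mass: float | None = None,
) -> list[Annotation]:
    """Search and score the [M+1]..[M+4] peaks of an annotated peak.

    A candidate must lie within the m/z tolerance of the theoretical
    isotopologue, co-elute with the parent within the RT tolerance, and have
    a relative abundance (summed over samples, % of the parent) within the
    intensity tolerance.  Absent isotope peaks are simply not annotated.
    The best-scoring candidate per k is kept.
    """
    pattern = isotope_pattern(formula, adduct=adduct, monoisotopic_mass=monoisotopic_mass)
    out: list[Annotation] = []
    parent_ab = parent_peak.abundance
    if parent_ab <= 0:
        return out
    for k in range(1, N_ISOTOPE_PEAKS):
        # anchor the expected m/z on the observed parent peak so a calibration
        # offset shared by the whole envelope does not eat into the tolerance
        mz_t = parent_peak.mz + k * ISOTOPE_SPACING
        int_t = pattern.relative_intensity[k]
        if int_t <= 0:
            continue
        best: Annotation | None = None
        for cand in index.query(mz_t, cfg.mz_tol_ppm):
            if cand.peak_id == parent_peak.peak_id:
                continue
            if abs(cand.rt - parent_peak.rt) > cfg.rt_tol_s:
                continue
            int_e = 100.0 * cand.abundance / parent_ab
            if abs((int_e - int_t) * 100.0 / int_t) > cfg.int_tol_pct:
                continue
            s_mz = score_mz(cand.mz, mz_t, cfg.mz_tol_ppm)
            s_rt = score_rt_abs(cand.rt, parent_peak.rt, cfg.rt_tol_s)
            s_int = score_rel_int(int_e, int_t, cfg.int_tol_pct)
            total = cfg.iso_w_mz * s_mz + cfg.iso_w_rt * s_rt + cfg.iso_w_int * s_int
            ann = Annotation(
                peak_id=cand.peak_id,
                metabolite_id=parent.metabolite_id,
                adduct=parent.adduct,
                role=ROLE_ISOTOPE,
                isotope_k=k,
                score_mz=s_mz,
                score_rt=s_rt,
                score_int=s_int,
                total_score=total,
                round=parent.round,
                seed_parent=parent.seed_parent,
                parent_peak_id=parent_peak.peak_id,
            )
            if best is None or ann.total_score > best.total_score:
                best = ann
        if best is not None:
            out.append(best)
    return out


def annotate_adducts(
    parent: Annotation,
    parent_peak: MS1Peak,
    monoisotopic_mass: float,
    index: PeakIndex,
    rules: list[AdductRule],
    cfg: IsoAdductScoringConfig = DEFAULT_ISO_CFG,
    formula: str | None = None,
) -> list[Annotation]:
    """Search and score alternative adduct peaks of an annotated metabolite.

    Every rule other than the parent's own adduct is tried; matches within
    the m/z and RT tolerances are scored with the adduct weights.  Each
    matched adduct peak then receives its own isotope-annotation pass when a
    formula is supplied; those isotopes carry role ``isotope`` and inherit
    the parent's seed lineage.
    """
    out: list[Annotation] = []
    for rule in rules:
        if rule.name == parent.adduct:
            continue
        mz_t = rule.mz_from_mass(monoisotopic_mass)
        best: tuple[Annotation, MS1Peak] | None = None
        for cand in index.query(mz_t, cfg.mz_tol_ppm):
            if cand.peak_id == parent_peak.peak_id:
                continue
            if abs(cand.rt - parent_peak.rt) > cfg.rt_tol_s:
                continue
            s_mz = score_mz(cand.mz, mz_t, cfg.mz_tol_ppm)
            s_rt = score_rt_abs(cand.rt, parent_peak.rt, cfg.rt_tol_s)
            total = cfg.adduct_w_mz * s_mz + cfg.adduct_w_rt * s_rt
            ann = Annotation(
                peak_id=cand.peak_id,
                metabolite_id=parent.metabolite_id,
                adduct=rule.name,
                role=ROLE_ADDUCT,
                score_mz=s_mz,
                score_rt=s_rt,
                total_score=total,
                round=parent.round,
                seed_parent=parent.seed_parent,
                parent_peak_id=parent_peak.peak_id,
            )
            if best is None or ann.total_score > best[0].total_score:
                best = (ann, cand)
        if best is not None:
            ann, cand = best
            out.append(ann)
            if formula:
                out.extend(
                    annotate_isotopes(
                        ann, cand, formula, index, cfg,
                        adduct=rule, monoisotopic_mass=monoisotopic_mass,
                    )
                )
    return out
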