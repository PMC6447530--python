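"""Isotope envelopes, component scores, and support-peak annotation."""

import numpy as np
import pytest

from metanno.isotopes import (
    ISOTOPE_SPACING,
    IsoAdductScoringConfig,
    PeakIndex,
    POSITIVE_ADDUCTS,
    annotate_adducts,
    annotate_isotopes,
    isotope_pattern,
    score_mz,
    score_rel_int,
    score_rt_abs,
)
from metanno.models import Annotation, MS1Peak


def oracle_pattern(formula, n_peaks=5, threshold=1e-10):
    """Independent envelope: exhaustive isotopologue enumeration (pyteomics)."""
    from pyteomics import mass

    mono = mass.calculate_mass(formula=formula)
    agg = np.zeros(n_peaks)
    for comp, ab in mass.isotopologues(
        formula, report_abundance=True, overall_threshold=threshold,
        isotope_threshold=1e-6,
    ):
        m = mass.calculate_mass(composition=comp)
        k = int(round(m - mono))
        if 0 <= k < n_peaks:
            agg[k] += ab
    return 100.0 * agg / agg[0]


def random_formula(rng):
    c = int(rng.integers(1, 12))
    h = int(rng.integers(1, 2 * c + 3))
    parts = [f"C{c}", f"H{h}"]
    if rng.random() < 0.5:
        parts.append(f"N{int(rng.integers(1, 4))}")
    if rng.random() < 0.7:
        parts.append(f"O{int(rng.integers(1, 6))}")
    if rng.random() < 0.2:
        parts.append("S")
    return "".join(parts)


class TestIsotopePattern:
    def test_five_entries_first_hundred(self):
        pat = isotope_pattern("C6H12O6")
        assert len(pat) == 5
        assert pat.relative_intensity[0] == 100.0

    def test_molecular_hydrogen_deuterium(self):
        pat = isotope_pattern("H2", monoisotopic_mass=2.0157)
        assert pat.relative_intensity[1] == pytest.approx(0.023, rel=2e-3)

    def test_glucose_m1_dominated_by_carbon(self):
        pat = isotope_pattern("C6H12O6")
        # six carbons at ~1.08% plus H/O contributions
        assert pat.relative_intensity[1] == pytest.approx(oracle_pattern("C6H12O6")[1], rel=1e-6)
        assert 6.0 < pat.relative_intensity[1] < 7.5

    def test_chlorine_two_dalton_signature(self):
        pat = isotope_pattern("C2H5Cl")
        assert pat.relative_intensity[2] > 30  # 37Cl ~ 32% of 35Cl

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(12):
            f = random_formula(rng)
            mine = np.array(isotope_pattern(f).relative_intensity)
            ora = oracle_pattern(f)
            mask = ora > 1e-3
            assert np.allclose(mine[mask], ora[mask], rtol=1e-4), f

    def test_mz_spacing(self):
        pat = isotope_pattern("C6H12O6", monoisotopic_mass=180.0634)
        diffs = np.diff(pat.mz)
        assert np.allclose(diffs, ISOTOPE_SPACING)

    def test_unsupported_element_named(self):
        with pytest.raises(ValueError, match="Se"):
            isotope_pattern("C2H6Se")


class TestComponentScores:
    def test_mz_score_ramp(self):
        assert score_mz(200.0, 200.0) == 1.0
        assert score_mz(200.0 * (1 + 25e-6), 200.0) == pytest.approx(0.0, abs=1e-9)
        assert score_mz(200.0 * (1 + 12.5e-6), 200.0) == pytest.approx(0.5, abs=1e-9)

    def test_rt_score_ramp(self):
        assert score_rt_abs(100.0, 100.0) == 1.0
        assert score_rt_abs(103.0, 100.0) == pytest.approx(0.0)
        assert score_rt_abs(101.5, 100.0) == pytest.approx(0.5)

    def test_relative_intensity_ramp(self):
        assert score_rel_int(6.9, 6.9) == 1.0
        assert score_rel_int(6.0 * 6.9, 6.9) == pytest.approx(0.0)
        assert score_rel_int(3.5 * 6.9, 6.9) == pytest.approx(0.5)

    def test_intensity_tolerance_asymmetric_in_ratio(self):
        # deviation is normalized by the theoretical value: a 6-fold excess
        # hits the 500% tolerance, a 6-fold deficit does not
        assert score_rel_int(6.0, 1.0) == pytest.approx(0.0)
        assert score_rel_int(1.0 / 6.0, 1.0) > 0.8


GLUCOSE = "C6H12O6"
GLUCOSE_MASS = 180.06339


def peak(pid, mz, rt, abundance):
    return MS1Peak(pid, mz, rt, {"S1": abundance})


def parent_annotation():
    return Annotation(peak_id="P0", metabolite_id="glc", adduct="[M+H]+", round=0)


class TestAnnotateIsotopes:
    def test_perfect_m1_scores_one(self):
        pat = isotope_pattern(GLUCOSE, monoisotopic_mass=GLUCOSE_MASS)
        p0 = peak("P0", GLUCOSE_MASS + 1.0073, 100.0, 1e6)
        p1 = peak("P1", p0.mz + ISOTOPE_SPACING, 100.0, 1e6 * pat.relative_intensity[1] / 100)
        (ann,) = annotate_isotopes(parent_annotation(), p0, GLUCOSE, PeakIndex([p0, p1]))
        assert ann.isotope_k == 1
        assert ann.total_score == pytest.approx(1.0, abs=1e-9)
        assert ann.role == "isotope"

    def test_half_deviations_score_half(self):
        pat = isotope_pattern(GLUCOSE, monoisotopic_mass=GLUCOSE_MASS)
        p0 = peak("P0", GLUCOSE_MASS + 1.0073, 100.0, 1e6)
        mz_t = p0.mz + ISOTOPE_SPACING
        p1 = peak("P1", mz_t * (1 + 12.5e-6), 101.5, 1e6 * 3.5 * pat.relative_intensity[1] / 100)
        (ann,) = annotate_isotopes(parent_annotation(), p0, GLUCOSE, PeakIndex([p0, p1]))
        assert ann.total_score == pytest.approx(0.5, abs=1e-6)

    def test_coelution_window_enforced(self):
        pat = isotope_pattern(GLUCOSE, monoisotopic_mass=GLUCOSE_MASS)
        p0 = peak("P0", GLUCOSE_MASS + 1.0073, 100.0, 1e6)
        p1 = peak("P1", p0.mz + ISOTOPE_SPACING, 105.0, 1e6 * pat.relative_intensity[1] / 100)
        assert annotate_isotopes(parent_annotation(), p0, GLUCOSE, PeakIndex([p0, p1])) == []

    def test_intensity_window_enforced(self):
        p0 = peak("P0", GLUCOSE_MASS + 1.0073, 100.0, 1e6)
        p1 = peak("P1", p0.mz + ISOTOPE_SPACING, 100.0, 1e6)  # ~14x theoretical
        assert annotate_isotopes(parent_annotation(), p0, GLUCOSE, PeakIndex([p0, p1])) == []

    def test_scores_within_unit_interval(self):
        rng = np.random.default_rng(3)
        pat = isotope_pattern(GLUCOSE, monoisotopic_mass=GLUCOSE_MASS)
        p0 = peak("P0", GLUCOSE_MASS + 1.0073, 100.0, 1e6)
        for _ in range(30):
            k = int(rng.integers(1, 5))
            mz = (p0.mz + k * ISOTOPE_SPACING) * (1 + rng.uniform(-25e-6, 25e-6))
            rt = 100.0 + rng.uniform(-3, 3)
            ab = 1e6 * pat.relative_intensity[k] / 100 * rng.uniform(0.2, 5.9)
            pk = peak("P1", mz, rt, ab)
            for ann in annotate_isotopes(parent_annotation(), p0, GLUCOSE, PeakIndex([p0, pk])):
                assert 0.0 <= ann.total_score <= 1.0 + 1e-9


class TestAnnotateAdducts:
    def test_perfect_sodium_adduct(self):
        p0 = peak("P0", GLUCOSE_MASS + 1.0073, 100.0, 1e6)
        pna = peak("P1", GLUCOSE_MASS + 22.9892213, 100.0, 3e5)
        anns = annotate_adducts(
            parent_annotation(), p0, GLUCOSE_MASS, PeakIndex([p0, pna]), POSITIVE_ADDUCTS
        )
        (ann,) = [a for a in anns if a.role == "adduct-of"]
        assert ann.adduct == "[M+Na]+"
        assert ann.total_score == pytest.approx(1.0, abs=1e-9)

    def test_half_deviations_score_half(self):
        p0 = peak("P0", GLUCOSE_MASS + 1.0073, 100.0, 1e6)
        mz_t = GLUCOSE_MASS + 22.9892213
        pna = peak("P1", mz_t * (1 + 12.5e-6), 101.5, 3e5)
        anns = annotate_adducts(
            parent_annotation(), p0, GLUCOSE_MASS, PeakIndex([p0, pna]), POSITIVE_ADDUCTS
        )
        (ann,) = [a for a in anns if a.role == "adduct-of"]
        assert ann.total_score == pytest.approx(0.5, abs=1e-6)

    def test_adduct_gets_its_own_isotopes(self):
        pat = isotope_pattern(GLUCOSE, monoisotopic_mass=GLUCOSE_MASS)
        p0 = peak("P0", GLUCOSE_MASS + 1.0073, 100.0, 1e6)
        pna = peak("P1", GLUCOSE_MASS + 22.9892213, 100.0, 3e5)
        pna1 = peak("P2", pna.mz + ISOTOPE_SPACING, 100.0, 3e5 * pat.relative_intensity[1] / 100)
        parent = Annotation(
            peak_id="P0", metabolite_id="glc", adduct="[M+H]+", round=0, seed_parent="seedX"
        )
        anns = annotate_adducts(
            parent, p0, GLUCOSE_MASS, PeakIndex([p0, pna, pna1]),
            POSITIVE_ADDUCTS, formula=GLUCOSE,
        )
        iso = [a for a in anns if a.role == "isotope"]
        assert iso and iso[0].peak_id == "P2"
        assert iso[0].seed_parent == "seedX"


class TestConfigValidation:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            IsoAdductScoringConfig(iso_w_mz=0.5, iso_w_rt=0.5, iso_w_int=0.5)
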