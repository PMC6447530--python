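"""Recursive neighbor annotation: scoring, seed selection, convergence."""

import numpy as np
import pandas as pd
import pytest

from metanno.isotopes import PeakIndex, adduct_rules
from metanno.models import Annotation, MS1Peak, Seed
from metanno.mrn import build_mrn
from metanno.msio import annotation_table
from metanno.recursion import (
    NeighborScoringConfig,
    annotate_neighbors,
    run_recursion,
    score_rt_pct,
    select_new_seeds,
)
from metanno.spectra import Spectrum

PROTON = 1.0072765
RULES = adduct_rules("positive")


def spectrum(*frags, pre=200.0, rt=None):
    return Spectrum(precursor_mz=pre, precursor_rt=rt, fragments=np.array(frags, dtype=float))


def net_with_masses(masses: dict[str, float], edges):
    pairs = pd.DataFrame([{"rp_id": f"r{i}", "from": a, "to": b} for i, (a, b) in enumerate(edges)])
    compounds = pd.DataFrame(
        {
            "id": list(masses), "name": list(masses),
            "formula": ["C6H12O6"] * len(masses),
            "monoisotopic_mass": list(masses.values()),
            "smiles": ["CCC"] * len(masses),
        }
    )
    return build_mrn(pairs, compounds)


class TestScoreRtPct:
    def test_ramp(self):
        assert score_rt_pct(100.0, 100.0) == 1.0
        assert score_rt_pct(130.0, 100.0) == pytest.approx(0.0)
        assert score_rt_pct(115.0, 100.0) == pytest.approx(0.5)

    def test_requires_positive_theoretical_rt(self):
        with pytest.raises(ValueError):
            score_rt_pct(100.0, 0.0)


class TestAnnotateNeighbors:
    def setup_pair(self, shared=True):
        """Seed A and neighbor B; B's peak carries A's spectrum (or not)."""
        net = net_with_masses({"A": 180.0, "B": 240.0}, [("A", "B")])
        frags_a = [(80, 1.0), (95, 0.8), (120, 0.5)]
        frags_b = frags_a if shared else [(61, 1.0), (77, 0.8), (131, 0.5)]
        peak_b = MS1Peak("PB", 240.0 + PROTON, 150.0, {"S1": 1e5})
        seed = Seed("A", "PA", spectrum(*frags_a, pre=180.0 + PROTON))
        peak_spectra = {"PB": spectrum(*frags_b, pre=peak_b.mz)}
        return seed, net, peak_b, peak_spectra

    def test_perfect_neighbor_scores_one(self):
        seed, net, peak_b, spectra = self.setup_pair()
        anns, n = annotate_neighbors(
            seed, net, PeakIndex([peak_b]), spectra, {"B": 150.0}, RULES
        )
        (a,) = anns
        assert a.metabolite_id == "B"
        assert a.total_score == pytest.approx(1.0, abs=1e-9)
        assert n == 1

    def test_weighted_sum_of_half_components(self):
        seed, net, _, spectra = self.setup_pair()
        # m/z off by 12.5 ppm, RT off by 15%, spectrum sharing ~half weight
        mz_t = 240.0 + PROTON
        peak_b = MS1Peak("PB", mz_t * (1 + 12.5e-6), 150.0 * 1.15, {"S1": 1e5})
        half = spectrum((80, 1.0), (95, 0.8), (61, 1.0), (77, 0.8), pre=peak_b.mz)
        anns, _ = annotate_neighbors(
            seed, net, PeakIndex([peak_b]), {"PB": half}, {"B": 150.0}, RULES
        )
        (a,) = anns
        assert a.score_mz == pytest.approx(0.5, abs=1e-6)
        assert a.score_rt == pytest.approx(0.5, abs=1e-6)
        expected = 0.25 * a.score_mz + 0.25 * a.score_rt + 0.5 * a.score_spec
        assert a.total_score == pytest.approx(expected, abs=1e-12)

    def test_spectral_gate_blocks_dissimilar_candidates(self):
        seed, net, peak_b, _ = self.setup_pair(shared=False)
        spectra = {"PB": spectrum((61, 1.0), (77, 0.8), (131, 0.5), pre=peak_b.mz)}
        anns, _ = annotate_neighbors(
            seed, net, PeakIndex([peak_b]), spectra, {"B": 150.0}, RULES
        )
        assert anns == []

    def test_rt_window_blocks_late_candidates(self):
        seed, net, _, spectra = self.setup_pair()
        peak_b = MS1Peak("PB", 240.0 + PROTON, 150.0 * 1.4, {"S1": 1e5})
        anns, _ = annotate_neighbors(
            seed, net, PeakIndex([peak_b]), spectra, {"B": 150.0}, RULES
        )
        assert anns == []

    def test_step_widening_on_empty_first_shell(self):
        # chain A-B-C where B has no peak: the seed reaches C at step 2
        net = net_with_masses({"A": 180.0, "B": 500.0, "C": 240.0}, [("A", "B"), ("B", "C")])
        frags = [(80, 1.0), (95, 0.8)]
        peak_c = MS1Peak("PC", 240.0 + PROTON, 150.0, {"S1": 1e5})
        seed = Seed("A", "PA", spectrum(*frags, pre=180.0 + PROTON))
        anns, _ = annotate_neighbors(
            seed, net, PeakIndex([peak_c]), {"PC": spectrum(*frags, pre=peak_c.mz)},
            {"C": 150.0}, RULES,
        )
        assert [a.metabolite_id for a in anns] == ["C"]

    def test_seed_outside_network_rejected(self):
        _, net, peak_b, spectra = self.setup_pair()
        stranger = Seed("Z", "PZ", spectrum((80, 1.0)))
        with pytest.raises(KeyError):
            annotate_neighbors(stranger, net, PeakIndex([peak_b]), spectra, {}, RULES)


class TestSelectNewSeeds:
    def ann(self, pid, met, score):
        return Annotation(peak_id=pid, metabolite_id=met, adduct="[M+H]+",
                          total_score=score, round=1)

    def test_previously_seeded_metabolites_excluded(self):
        anns = [self.ann(f"P{i}", f"M{i}", 0.8) for i in range(5)]
        spectra = {f"P{i}": spectrum((80, 1.0)) for i in range(5)}
        seeds = select_new_seeds(anns, {"M0", "M1"}, spectra, 1)
        assert {s.metabolite_id for s in seeds} == {"M2", "M3", "M4"}

    def test_all_seeded_means_none(self):
        anns = [self.ann("P1", "M1", 0.8)]
        assert select_new_seeds(anns, {"M1"}, {"P1": spectrum((80, 1.0))}, 1) == []

    def test_best_peak_supplies_the_spectrum(self):
        anns = [self.ann("P1", "M1", 0.6), self.ann("P2", "M1", 0.9)]
        spectra = {"P1": spectrum((80, 1.0)), "P2": spectrum((90, 1.0))}
        (seed,) = select_new_seeds(anns, set(), spectra, 1)
        assert seed.peak_id == "P2"

    def test_peaks_without_ms2_cannot_seed(self):
        anns = [self.ann("P1", "M1", 0.8)]
        assert select_new_seeds(anns, set(), {}, 1) == []


def make_chain_world(n=3, base_mass=180.0, rt=150.0):
    """Chain M0-M1-...; every metabolite has a peak carrying its spectrum.

    Adjacent metabolites share most of their fragments so that propagation
    can walk the chain one step per round.
    """
    ids = [f"M{i}" for i in range(n)]
    masses = {m: base_mass + 60.0 * i for i, m in enumerate(ids)}
    net = net_with_masses(masses, list(zip(ids, ids[1:])))
    # uniform intensities keep pairwise dot products symmetric, so a
    # re-derivation can never beat the first annotation and round stamps
    # follow the hand trace
    pool = [(60 + 5 * j, 0.8) for j in range(20)]
    peaks, spectra = [], {}
    for i, m in enumerate(ids):
        frags = pool[2 * i : 2 * i + 8]  # 6 of 8 shared with each neighbor
        pk = MS1Peak(f"P{i}", masses[m] + PROTON, rt, {"S1": 1e5})
        peaks.append(pk)
        spectra[f"P{i}"] = spectrum(*frags, pre=pk.mz, rt=rt)
    predicted = {m: rt for m in ids}
    return ids, net, peaks, spectra, predicted


class TestRunRecursion:
    def test_chain_annotated_round_by_round(self):
        ids, net, peaks, spectra, predicted = make_chain_world(4)
        seeds0 = [Seed(ids[0], "P0", spectra["P0"])]
        r0 = [Annotation(peak_id="P0", metabolite_id=ids[0], adduct="[M+H]+",
                         total_score=0.95, round=0)]
        anns, logs = run_recursion(
            seeds0, net, peaks, spectra, predicted, RULES,
            round0_annotations=r0, annotate_isotope_peaks=False,
        )
        rounds = {a.metabolite_id: a.round for a in anns}
        assert rounds == {"M0": 0, "M1": 1, "M2": 2, "M3": 3}
        assert logs[-1].n_new_seeds == 0

    def test_no_matching_neighbors_single_round(self):
        ids, net, peaks, spectra, predicted = make_chain_world(3)
        lonely = {m: 9999.0 for m in ids}  # predicted RTs exclude every peak
        seeds0 = [Seed(ids[0], "P0", spectra["P0"])]
        anns, logs = run_recursion(
            seeds0, net, peaks, spectra, lonely, RULES, annotate_isotope_peaks=False
        )
        assert anns == []
        assert len(logs) == 1

    def test_cycle_terminates_without_reseeding(self):
        ids = ["A", "B", "C"]
        masses = {"A": 180.0, "B": 240.0, "C": 300.0}
        net = net_with_masses(masses, [("A", "B"), ("B", "C"), ("C", "A")])
        frags = [(80, 1.0), (95, 0.8), (120, 0.5)]
        peaks = [MS1Peak(f"P{m}", masses[m] + PROTON, 150.0, {"S1": 1e5}) for m in ids]
        spectra = {f"P{m}": spectrum(*frags, pre=masses[m] + PROTON) for m in ids}
        predicted = {m: 150.0 for m in ids}
        seeds0 = [Seed("A", "PA", spectra["PA"])]
        anns, logs = run_recursion(
            seeds0, net, peaks, spectra, predicted, RULES, annotate_isotope_peaks=False
        )
        assert logs[-1].n_new_seeds == 0
        assert len(logs) <= 3

    def test_round0_never_overwritten(self):
        ids, net, peaks, spectra, predicted = make_chain_world(2)
        r0 = [Annotation(peak_id="P1", metabolite_id="M1", adduct="[M+H]+",
                         total_score=0.5, round=0)]
        seeds0 = [Seed("M0", "P0", spectra["P0"])]
        anns, _ = run_recursion(
            seeds0, net, peaks, spectra, predicted, RULES,
            round0_annotations=r0, annotate_isotope_peaks=False,
        )
        (m1,) = [a for a in anns if a.metabolite_id == "M1"]
        assert m1.round == 0 and m1.total_score == 0.5

    def test_duplicate_derivations_keep_best(self):
        # A and C both neighbor B; the higher-scoring derivation survives
        masses = {"A": 180.0, "B": 240.0, "C": 300.0}
        net = net_with_masses(masses, [("A", "B"), ("C", "B")])
        frags = [(80, 1.0), (95, 0.8)]
        peak_b = MS1Peak("PB", 240.0 + PROTON, 150.0, {"S1": 1e5})
        spectra = {"PB": spectrum(*frags, pre=peak_b.mz)}
        seeds0 = [
            Seed("A", "PA", spectrum(*frags, pre=180.0 + PROTON)),
            Seed("C", "PC", spectrum(*frags, (110, 0.5), pre=300.0 + PROTON)),
        ]
        anns, _ = run_recursion(
            seeds0, net, [peak_b], spectra, {"B": 150.0}, RULES, annotate_isotope_peaks=False
        )
        assert len([a for a in anns if a.metabolite_id == "B"]) == 1

    def test_requires_initial_seed(self):
        ids, net, peaks, spectra, predicted = make_chain_world(2)
        with pytest.raises(ValueError):
            run_recursion([], net, peaks, spectra, predicted, RULES)


class TestCutoffMonotonicity:
    def test_raising_cutoff_never_adds_annotations(self):
        rng = np.random.default_rng(0)
        anns = [
            Annotation(peak_id=f"P{i % 7}", metabolite_id=f"M{i}", adduct="[M+H]+",
                       total_score=float(rng.uniform(0, 1)), round=1)
            for i in range(80)
        ]
        counts = [
            len(annotation_table(anns, score_cutoff=c)) for c in np.linspace(0.0, 1.0, 11)
        ]
        assert counts == sorted(counts, reverse=True)


class TestConfigValidation:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            NeighborScoringConfig(w_mz=0.4, w_rt=0.4, w_spec=0.4)

    def test_spec_gate_must_be_positive(self):
        with pytest.raises(ValueError):
            NeighborScoringConfig(spec_min=0.0)
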