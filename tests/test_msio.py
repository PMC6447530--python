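"""Readers, writers and MS1-MS2 pairing."""

import numpy as np
import pandas as pd
import pytest

from metanno import msio
from metanno.models import Annotation, MS1Peak, SampleSheet
from metanno.spectra import Spectrum


SHEET = SampleSheet(samples=("S1", "S2"), groups=("control", "case"))


def write_csv(tmp_path, text, name="table.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestPeakTable:
    def test_basic_parse(self, tmp_path):
        p = write_csv(tmp_path, "name,mz,rt,S1,S2\nP1,100.5,60,1,2\nP2,200.5,70,3,4\nP3,300.5,80,5,6\n")
        peaks = msio.read_peak_table(p, SHEET)
        assert len(peaks) == 3
        assert peaks[0].intensities == {"S1": 1.0, "S2": 2.0}

    def test_unrenamed_xcms_columns_rejected(self, tmp_path):
        p = write_csv(tmp_path, "name,mzmed,rtmed,S1,S2\nP1,100.5,60,1,2\n")
        with pytest.raises(msio.FormatError, match="mz"):
            msio.read_peak_table(p, SHEET)

    def test_empty_intensity_cell_identified(self, tmp_path):
        p = write_csv(tmp_path, "name,mz,rt,S1,S2\nP1,100.5,60,1,\n")
        with pytest.raises(msio.FormatError, match="S2"):
            msio.read_peak_table(p, SHEET)

    def test_duplicate_peak_ids_listed(self, tmp_path):
        p = write_csv(tmp_path, "name,mz,rt,S1,S2\nP1,100.5,60,1,2\nP1,200.5,70,3,4\n")
        with pytest.raises(msio.FormatError, match="P1"):
            msio.read_peak_table(p, SHEET)

    def test_intensity_column_missing_from_sheet(self, tmp_path):
        p = write_csv(tmp_path, "name,mz,rt,S1,S2,S3\nP1,100.5,60,1,2,3\n")
        with pytest.raises(msio.FormatError, match="S3"):
            msio.read_peak_table(p, SHEET)


class TestSampleSheet:
    def test_read(self, tmp_path):
        p = write_csv(tmp_path, "sample.name,group\nS1,control\nS2,case\n")
        sheet = msio.read_sample_sheet(p)
        assert sheet.samples == ("S1", "S2")
        assert sheet.group_names == ("control", "case")

    def test_wrong_header_rejected(self, tmp_path):
        p = write_csv(tmp_path, "sample,grp\nS1,a\n")
        with pytest.raises(msio.FormatError):
            msio.read_sample_sheet(p)


def make_spectra(n=2):
    return [
        Spectrum(
            precursor_mz=200.0 + i,
            precursor_rt=100.0 + i,
            fragments=np.array([[100.123456, 1.0], [150.654321, 0.5]]),
            metadata={"title": f"s{i}"},
        )
        for i in range(n)
    ]


class TestMs2IO:
    def test_mgf_read(self, tmp_path):
        p = tmp_path / "two.mgf"
        msio.write_ms2(p, make_spectra(2))
        assert len(msio.read_ms2(p)) == 2

    @pytest.mark.parametrize("dialect", ["mgf", "msp"])
    def test_round_trip_preserves_fragments(self, tmp_path, dialect):
        p = tmp_path / f"rt.{dialect}"
        original = make_spectra(3)
        msio.write_ms2(p, original, dialect=dialect)
        back = msio.read_ms2(p, dialect=dialect)
        for o, b in zip(original, back):
            assert np.allclose(o.fragments, b.fragments, atol=5e-7)
            assert b.precursor_mz == pytest.approx(o.precursor_mz, abs=5e-7)

    def test_msp_num_peaks_mismatch_skipped(self, tmp_path, caplog):
        p = tmp_path / "bad.msp"
        p.write_text(
            "Name: ok\nPrecursorMZ: 200.0\nNum Peaks: 2\n100.0 1.0\n150.0 0.5\n\n"
            "Name: truncated\nPrecursorMZ: 300.0\nNum Peaks: 3\n100.0 1.0\n150.0 0.5\n\n"
        )
        with caplog.at_level("WARNING"):
            spectra = msio.read_ms2(p, dialect="msp")
        assert len(spectra) == 1
        assert "truncated" in caplog.text

    def test_record_without_precursor_skipped(self, tmp_path, caplog):
        p = tmp_path / "nopre.mgf"
        p.write_text(
            "BEGIN IONS\nTITLE=a\nRTINSECONDS=10\n100.0 1.0\nEND IONS\n\n"
            "BEGIN IONS\nTITLE=b\nPEPMASS=200.0\n100.0 1.0\nEND IONS\n"
        )
        with caplog.at_level("WARNING"):
            spectra = msio.read_ms2(p)
        assert len(spectra) == 1

    def test_msp_rt_minutes_converted_to_seconds(self, tmp_path):
        p = tmp_path / "rt.msp"
        p.write_text("Name: x\nPrecursorMZ: 200.0\nRetentionTime: 2.0\nNum Peaks: 1\n100.0 1.0\n\n")
        (s,) = msio.read_ms2(p, dialect="msp")
        assert s.precursor_rt == pytest.approx(120.0)

    def test_library_round_trip(self, tmp_path):
        from metanno.models import LibraryRecord

        rec = LibraryRecord(
            metabolite_id="C00001", name="water-ish", adduct="[M+H]+",
            precursor_mz=123.456789,
            spectrum=Spectrum(precursor_mz=123.456789, fragments=np.array([[60.0, 1.0]])),
            collision_energy="30",
        )
        p = tmp_path / "lib.msp"
        msio.write_library(p, [rec])
        (back,) = msio.read_library(p)
        assert back.metabolite_id == "C00001"
        assert back.adduct == "[M+H]+"
        assert back.collision_energy == "30"


def peak(pid, mz, rt):
    return MS1Peak(pid, mz, rt, {"S1": 10.0})


class TestPairing:
    def test_within_tolerance_paired(self):
        p = peak("P1", 200.0000, 100.0)
        s = Spectrum(precursor_mz=200.0030, precursor_rt=105.0, fragments=np.array([[100.0, 1.0]]))
        assert msio.pair_ms1_ms2([p], [s])["P1"] is s

    def test_outside_mz_tolerance_unpaired(self):
        p = peak("P1", 200.0000, 100.0)
        s = Spectrum(precursor_mz=200.0060, precursor_rt=100.0, fragments=np.array([[100.0, 1.0]]))
        assert msio.pair_ms1_ms2([p], [s]) == {}

    def test_most_abundant_spectrum_wins(self):
        p = peak("P1", 200.0, 100.0)
        weak = Spectrum(
            precursor_mz=200.0, precursor_rt=100.0,
            fragments=np.column_stack([np.arange(100, 110, 1.0), np.full(10, 90.0)]),
        )  # top-10 sum 900
        strong = Spectrum(
            precursor_mz=200.0, precursor_rt=100.0,
            fragments=np.column_stack([np.arange(100, 110, 1.0), np.full(10, 120.0)]),
        )  # top-10 sum 1200
        assert msio.pair_ms1_ms2([p], [weak, strong])["P1"] is strong

    def test_abundance_uses_top_ten_fragments_only(self):
        p = peak("P1", 200.0, 100.0)
        # 10 big fragments beat 20 small ones even though the total is larger
        big10 = Spectrum(
            precursor_mz=200.0, precursor_rt=100.0,
            fragments=np.column_stack([np.arange(100, 110, 1.0), np.full(10, 100.0)]),
        )
        small20 = Spectrum(
            precursor_mz=200.0, precursor_rt=100.0,
            fragments=np.column_stack([np.arange(100, 120, 1.0), np.full(20, 60.0)]),
        )
        assert msio.pair_ms1_ms2([p], [small20, big10])["P1"] is big10

    def test_partial_map_and_tolerance_invariant(self):
        rng = np.random.default_rng(0)
        peaks = [peak(f"P{i}", float(rng.uniform(100, 900)), float(rng.uniform(0, 600))) for i in range(30)]
        spectra = [
            Spectrum(
                precursor_mz=float(rng.uniform(100, 900)),
                precursor_rt=float(rng.uniform(0, 600)),
                fragments=np.array([[80.0, 1.0]]),
            )
            for _ in range(30)
        ]
        mapping = msio.pair_ms1_ms2(peaks, spectra)
        assert len(mapping) <= len(peaks)
        by_id = {p.peak_id: p for p in peaks}
        for pid, s in mapping.items():
            pk = by_id[pid]
            assert abs(s.precursor_mz - pk.mz) <= pk.mz * 25e-6
            assert abs(s.precursor_rt - pk.rt) <= 10.0

    def test_preassigned_spectra_bypass_search(self):
        p = peak("P1", 200.0, 100.0)
        s = Spectrum(
            precursor_mz=500.0, precursor_rt=999.0,  # way off; assignment should win
            fragments=np.array([[100.0, 1.0]]), metadata={"peak_id": "P1"},
        )
        assert msio.pair_ms1_ms2([p], [s])["P1"] is s


class TestOutputs:
    def ann(self, pid, met, score, round_=1):
        return Annotation(peak_id=pid, metabolite_id=met, adduct="[M+H]+",
                          total_score=score, score_spec=score, round=round_)

    def test_empty_annotations_header_only(self, tmp_path):
        files = msio.write_outputs(tmp_path, [])
        tab = pd.read_csv(files["annotation"])
        assert len(tab) == 0
        assert list(tab.columns) == msio.ANNOT_COLUMNS
        assert files["enrichment"].exists()
        assert files["quant_metabolite"].exists()
        assert files["quant_pathway"].exists()

    def test_top_five_above_cutoff(self, tmp_path):
        anns = [self.ann("P1", f"M{i}", 0.3 + 0.08 * i) for i in range(8)]
        files = msio.write_outputs(tmp_path, anns)
        tab = pd.read_csv(files["annotation"])
        assert len(tab) == 5
        assert (tab["total_score"] > 0.4).all()

    def test_rows_sorted_by_peak_and_rank(self, tmp_path):
        anns = [self.ann("P2", "M1", 0.9), self.ann("P1", "M2", 0.5), self.ann("P1", "M3", 0.8)]
        tab = pd.read_csv(msio.write_outputs(tmp_path, anns)["annotation"])
        assert list(tab["peak_id"]) == ["P1", "P1", "P2"]
        assert list(tab["rank"]) == [1, 2, 1]
        assert tab.iloc[0]["metabolite_id"] == "M3"

    def test_output_files_named_as_published(self):
        assert msio.ANNOTATION_FILE == "Annotation.result.csv"
        assert msio.QUANT_METABOLITE_FILE == "Quantitative.pathway.metabolite.result.csv"
        assert msio.QUANT_PATHWAY_FILE == "Quantitative.pathway.result.csv"
        assert msio.ENRICHMENT_FILE == "Pathway.enrichment.analysis.csv"
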