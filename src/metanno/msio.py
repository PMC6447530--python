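"""I/O for every external format the pipeline touches.

Formats
-------
* MS1 peak table: CSV with columns ``name, mz, rt`` followed by one
  intensity column per sample (the naming convention of aligned peak tables
  exported from XCMS/MS-DIAL after renaming the first three columns).
* Sample sheet: CSV with columns ``sample.name, group``.
* MS2 data: MGF (via pyteomics) or MSP.  MSP is a loose text dialect; the
  reader here is deliberately strict about ``Num Peaks`` consistency so that
  truncated records are skipped with a warning instead of silently
  mis-parsed.
* Spectral library: MSP records extended with ``KEGGID``, ``Adduct`` and
  ``CE`` fields.
* Results: four CSV files (annotation table, pathway enrichment, and the
  two quantitative pathway files).

RT units are seconds everywhere in memory.  MGF ``RTINSECONDS`` is taken at
face value; MSP ``RetentionTime`` is assumed to be minutes (the common
dialect of DIA alignment software) and converted on read, with a log note.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .models import MS1Peak, LibraryRecord, SampleSheet
from .spectra import Spectrum

log = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "read_sample_sheet",
    "read_peak_table",
    "read_ms2",
    "write_ms2",
    "read_library",
    "write_library",
    "pair_ms1_ms2",
    "write_outputs",
    "ANNOTATION_FILE",
    "ENRICHMENT_FILE",
    "QUANT_METABOLITE_FILE",
    "QUANT_PATHWAY_FILE",
]

ANNOTATION_FILE = "Annotation.result.csv"
ENRICHMENT_FILE = "Pathway.enrichment.analysis.csv"
QUANT_METABOLITE_FILE = "Quantitative.pathway.metabolite.result.csv"
QUANT_PATHWAY_FILE = "Quantitative.pathway.result.csv"


class FormatError(ValueError):
    """An input file does not follow the expected layout."""


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path)
    cols = [c.strip() for c in df.columns]
    if "sample.name" not in cols or "group" not in cols:
        raise FormatError(
            f"{path}: sample sheet must have columns 'sample.name' and 'group', got {cols}"
        )
    df.columns = cols
    return SampleSheet(
        samples=tuple(str(s) for s in df["sample.name"]),
        groups=tuple(str(g) for g in df["group"]),
    )


def read_peak_table(path: str | Path, sheet: SampleSheet) -> list[MS1Peak]:
    """Parse the MS1 peak table and bind intensity columns to the sheet.

    Every column after ``rt`` is treated as a sample intensity column and
    must appear in the sample sheet; columns the sheet does not know are an
    error rather than silently dropped.
    """
    df = pd.read_csv(path, dtype={"name": str})
    for col in ("name", "mz", "rt"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column '{col}'")
    rt_pos = list(df.columns).index("rt")
    sample_cols = list(df.columns[rt_pos + 1 :])
    unknown = [c for c in sample_cols if c not in sheet.samples]
    if unknown:
        raise FormatError(
            f"{path}: intensity columns {unknown} not present in the sample sheet"
        )
    missing = [s for s in sheet.samples if s not in sample_cols]
    if missing:
        raise FormatError(f"{path}: sample sheet samples {missing} missing from table")
    dup = df["name"][df["name"].duplicated()].tolist()
    if dup:
        raise FormatError(f"{path}: duplicate peak ids: {sorted(set(dup))}")

    peaks: list[MS1Peak] = []
    for row_i, row in df.iterrows():
        intens: dict[str, float] = {}
        for s in sample_cols:
            v = row[s]
            if pd.isna(v):
                raise FormatError(
                    f"{path}: empty intensity in row {row_i} ('{row['name']}'), column '{s}'"
                )
            try:
                fv = float(v)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-numeric intensity {v!r} in row {row_i}, column '{s}'"
                ) from None
            intens[s] = fv
        peaks.append(
            MS1Peak(peak_id=str(row["name"]), mz=float(row["mz"]), rt=float(row["rt"]), intensities=intens)
        )
    return peaks


# ---------------------------------------------------------------------------
# MS2 readers / writers


def _spectrum_from_mgf(rec: dict) -> Spectrum | None:
    params = rec.get("params", {})
    pep = params.get("pepmass")
    if pep is None:
        return None
    pre_mz = float(pep[0] if isinstance(pep, (tuple, list)) else pep)
    rt = params.get("rtinseconds")
    rt = float(rt) if rt is not None else None
    frags = np.column_stack([rec["m/z array"], rec["intensity array"]])
    meta = {k: v for k, v in params.items() if k not in ("pepmass", "rtinseconds")}
    if "title" in params:
        meta["title"] = params["title"]
    return Spectrum(precursor_mz=pre_mz, precursor_rt=rt, fragments=frags, metadata=meta)


def _parse_msp_blocks(text: str):
    """Split MSP text into blocks of (header dict, fragment lines)."""
    block_lines: list[str] = []
    for line in text.splitlines() + [""]:
        if line.strip() == "":
            if block_lines:
                yield block_lines
                block_lines = []
        else:
            block_lines.append(line.rstrip())
    if block_lines:
        yield block_lines


def _read_msp(path: str | Path) -> list[tuple[dict, np.ndarray]]:
    records: list[tuple[dict, np.ndarray]] = []
    n_skipped = 0
    text = Path(path).read_text()
    for lines in _parse_msp_blocks(text):
        header: dict[str, str] = {}
        frags: list[tuple[float, float]] = []
        in_peaks = False
        declared = None
        bad = False
        for line in lines:
            if not in_peaks and ":" in line:
                key, _, val = line.partition(":")
                key_l = key.strip().lower()
                header[key_l] = val.strip()
                if key_l == "num peaks":
                    declared = int(val.strip())
                    in_peaks = True
            elif in_peaks:
                parts = line.replace(",", " ").split()
                if len(parts) < 2:
                    bad = True
                    break
                try:
                    frags.append((float(parts[0]), float(parts[1])))
                except ValueError:
                    bad = True
                    break
        if bad or (declared is not None and declared != len(frags)):
            n_skipped += 1
            log.warning(
                "skipping malformed MSP record %r (declared %s peaks, found %d)",
                header.get("name", "?"), declared, len(frags),
            )
            continue
        if "precursormz" not in header:
            n_skipped += 1
            log.warning("skipping MSP record %r without PrecursorMZ", header.get("name", "?"))
            continue
        records.append((header, np.array(frags, dtype=float).reshape(-1, 2)))
    if n_skipped:
        log.warning("%d malformed/incomplete MSP records skipped", n_skipped)
    return records


def read_ms2(path: str | Path, dialect: str | None = None) -> list[Spectrum]:
    """Read MS2 spectra from MGF or MSP.

    Records lacking a precursor m/z are skipped with a logged warning.
    Fragments come back sorted by m/z with zero-intensity entries dropped
    (a guarantee of the :class:`~metanno.spectra.Spectrum` container).
    """
    path = Path(path)
    if dialect is None:
        dialect = path.suffix.lstrip(".").lower()
    if dialect == "mgf":
        spectra = []
        n_skipped = 0
        with _mgf.MGF(str(path)) as reader:
            for rec in reader:
                spec = _spectrum_from_mgf(rec)
                if spec is None:
                    n_skipped += 1
                    continue
                spectra.append(spec)
        if n_skipped:
            log.warning("%d MGF records without precursor m/z skipped", n_skipped)
        return spectra
    if dialect == "msp":
        spectra = []
        for header, frags in _read_msp(path):
            rt = header.get("retentiontime")
            if rt is not None:
                rt = float(rt) * 60.0  # MSP convention: minutes
            meta = {k: v for k, v in header.items() if k not in ("precursormz", "retentiontime", "num peaks")}
            spectra.append(
                Spectrum(
                    precursor_mz=float(header["precursormz"]),
                    precursor_rt=rt,
                    fragments=frags,
                    metadata=meta,
                )
            )
        if any("retentiontime" in h for h, _ in _read_msp(path)):
            log.info("MSP retention times interpreted as minutes and converted to seconds")
        return spectra
    raise FormatError(f"unknown MS2 dialect {dialect!r} for {path}")


def write_ms2(path: str | Path, spectra: list[Spectrum], dialect: str | None = None) -> None:
    """Write spectra as MGF or MSP (fragment m/z and intensity to 6 decimals)."""
    path = Path(path)
    if dialect is None:
        dialect = path.suffix.lstrip(".").lower()
    if dialect == "mgf":
        with open(path, "w") as fh:
            for i, s in enumerate(spectra):
                fh.write("BEGIN IONS\n")
                fh.write(f"TITLE={s.metadata.get('title', f'spectrum_{i}')}\n")
                fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
                if s.precursor_rt is not None:
                    fh.write(f"RTINSECONDS={s.precursor_rt:.3f}\n")
                for mz, inten in s.fragments:
                    fh.write(f"{mz:.6f} {inten:.6f}\n")
                fh.write("END IONS\n\n")
        return
    if dialect == "msp":
        with open(path, "w") as fh:
            for i, s in enumerate(spectra):
                fh.write(f"Name: {s.metadata.get('name', f'spectrum_{i}')}\n")
                fh.write(f"PrecursorMZ: {s.precursor_mz:.6f}\n")
                if s.precursor_rt is not None:
                    fh.write(f"RetentionTime: {s.precursor_rt / 60.0:.6f}\n")
                for key, val in s.metadata.items():
                    if key not in ("name",):
                        fh.write(f"{key.upper()}: {val}\n")
                fh.write(f"Num Peaks: {len(s)}\n")
                for mz, inten in s.fragments:
                    fh.write(f"{mz:.6f} {inten:.6f}\n")
                fh.write("\n")
        return
    raise FormatError(f"unknown MS2 dialect {dialect!r}")


def read_library(path: str | Path) -> list[LibraryRecord]:
    """Read the standard spectral library (MSP with KEGGID/Adduct/CE fields)."""
    records = []
    for header, frags in _read_msp(path):
        records.append(
            LibraryRecord(
                metabolite_id=header.get("keggid", header.get("name", "?")),
                name=header.get("name", ""),
                adduct=header.get("adduct", "[M+H]+"),
                precursor_mz=float(header["precursormz"]),
                spectrum=Spectrum(precursor_mz=float(header["precursormz"]), fragments=frags),
                collision_energy=header.get("ce", ""),
            )
        )
    return records


def write_library(path: str | Path, records: list[LibraryRecord]) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"Name: {r.name or r.metabolite_id}\n")
            fh.write(f"KEGGID: {r.metabolite_id}\n")
            fh.write(f"Adduct: {r.adduct}\n")
            fh.write(f"PrecursorMZ: {r.precursor_mz:.6f}\n")
            if r.collision_energy:
                fh.write(f"CE: {r.collision_energy}\n")
            fh.write(f"Num Peaks: {len(r.spectrum)}\n")
            for mz, inten in r.spectrum.fragments:
                fh.write(f"{mz:.6f} {inten:.6f}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# MS1 <-> MS2 pairing


def _top10_abundance(spec: Spectrum) -> float:
    inten = np.sort(spec.intensity)[::-1]
    return float(inten[:10].sum())


def pair_ms1_ms2(
    peaks: list[MS1Peak],
    spectra: list[Spectrum],
    mz_tol_ppm: float = 25.0,
    rt_tol_s: float = 10.0,
) -> dict[str, Spectrum]:
    """Assign to each MS1 peak its most abundant matching MS2 spectrum.

    A spectrum matches a peak when its precursor lies within ``mz_tol_ppm``
    and ``rt_tol_s`` of the peak.  Among multiple matches the spectrum with
    the greatest abundance wins, abundance being the summed intensity of the
    10 largest fragments; ties break by smaller |ΔRT|, then smaller |Δm/z|.

    Spectra that already carry a peak assignment (``peak_id`` in metadata,
    as produced by upstream alignment software emitting MSP) bypass the
    tolerance search entirely.
    """
    if mz_tol_ppm <= 0 or rt_tol_s <= 0:
        raise ValueError("tolerances must be > 0")
    pre_assigned = [s for s in spectra if "peak_id" in s.metadata]
    if pre_assigned and len(pre_assigned) == len(spectra):
        by_peak: dict[str, Spectrum] = {}
        known = {p.peak_id for p in peaks}
        for s in pre_assigned:
            pid = str(s.metadata["peak_id"])
            if pid in known:
                by_peak[pid] = s
        return by_peak

    out: dict[str, Spectrum] = {}
    for peak in peaks:
        tol = peak.mz * mz_tol_ppm * 1e-6
        best = None
        for s in spectra:
            if abs(s.precursor_mz - peak.mz) > tol:
                continue
            if s.precursor_rt is None or abs(s.precursor_rt - peak.rt) > rt_tol_s:
                continue
            key = (
                -_top10_abundance(s),
                abs(s.precursor_rt - peak.rt),
                abs(s.precursor_mz - peak.mz),
            )
            if best is None or key < best[0]:
                best = (key, s)
        if best is not None:
            out[peak.peak_id] = best[1]
    return out


# ---------------------------------------------------------------------------
# Result files


ANNOT_COLUMNS = [
    "peak_id", "metabolite_id", "metabolite_name", "adduct", "role",
    "score_mz", "score_rt", "score_spec", "score_int",
    "total_score", "round", "grade", "rank",
]


def annotation_table(
    annotations,
    score_cutoff: float = 0.4,
    top_k: int = 5,
    names: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Tabulate annotations: per peak, top-``top_k`` by score above cutoff.

    Rows come back sorted by (peak_id, rank).  The defaults implement the
    output rule of keeping at most the five best-ranked candidates per peak
    with scores above 0.4.
    """
    names = names or {}
    rows = []
    by_peak: dict[str, list] = {}
    for a in annotations:
        by_peak.setdefault(a.peak_id, []).append(a)
    for pid in sorted(by_peak):
        cands = [a for a in by_peak[pid] if a.total_score > score_cutoff]
        cands.sort(key=lambda a: (-a.total_score, -a.score_spec))
        for rank, a in enumerate(cands[:top_k], start=1):
            rows.append({
                "peak_id": a.peak_id,
                "metabolite_id": a.metabolite_id,
                "metabolite_name": names.get(a.metabolite_id, ""),
                "adduct": a.adduct,
                "role": a.role,
                "score_mz": a.score_mz,
                "score_rt": a.score_rt,
                "score_spec": a.score_spec,
                "score_int": a.score_int,
                "total_score": a.total_score,
                "round": a.round,
                "grade": a.grade,
                "rank": rank,
            })
    return pd.DataFrame(rows, columns=ANNOT_COLUMNS)


def write_outputs(
    out_dir: str | Path,
    annotations,
    enrichment: pd.DataFrame | None = None,
    quant_metabolite: pd.DataFrame | None = None,
    quant_pathway: pd.DataFrame | None = None,
    score_cutoff: float = 0.4,
    top_k: int = 5,
    names: dict[str, str] | None = None,
) -> dict[str, Path]:
    """Write the annotation table and pathway result files.

    Empty inputs produce header-only files, so a run that annotates nothing
    still leaves a complete, parseable output directory.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    tab = annotation_table(annotations, score_cutoff=score_cutoff, top_k=top_k, names=names)
    p = out_dir / ANNOTATION_FILE
    tab.to_csv(p, index=False)
    written["annotation"] = p

    if enrichment is None:
        enrichment = pd.DataFrame(columns=["pathway_id", "name", "overlap", "pathway_size", "p_value", "significant"])
    p = out_dir / ENRICHMENT_FILE
    enrichment.to_csv(p, index=False)
    written["enrichment"] = p

    if quant_metabolite is None:
        quant_metabolite = pd.DataFrame()
    p = out_dir / QUANT_METABOLITE_FILE
    quant_metabolite.to_csv(p)
    written["quant_metabolite"] = p

    if quant_pathway is None:
        quant_pathway = pd.DataFrame()
    p = out_dir / QUANT_PATHWAY_FILE
    quant_pathway.to_csv(p)
    written["quant_pathway"] = p
    return written
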