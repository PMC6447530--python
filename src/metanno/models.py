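"""Shared domain types of the annotation engine."""

from __future__ import annotations

from dataclasses import dataclass

from .spectra import Spectrum

__all__ = [
    "MS1Peak",
    "SampleSheet",
    "MetaboliteNode",
    "LibraryRecord",
    "Annotation",
    "Seed",
    "AdductRule",
    "RoundLog",
]


@dataclass(frozen=True)
class MS1Peak:
    """One aligned chromatographic feature from the MS1 peak table."""

    peak_id: str
    mz: float  # Th
    rt: float  # seconds
    intensities: dict[str, float]

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError(f"peak {self.peak_id}: mz must be > 0")
        if self.rt < 0:
            raise ValueError(f"peak {self.peak_id}: rt must be >= 0")
        if not self.intensities:
            raise ValueError(f"peak {self.peak_id}: no sample intensities")

    @property
    def abundance(self) -> float:
        """Total abundance: intensity summed across samples."""
        return float(sum(self.intensities.values()))


@dataclass(frozen=True)
class SampleSheet:
    """Sample-to-group assignment; sample ids must match peak-table columns."""

    samples: tuple[str, ...]
    groups: tuple[str, ...]

    def __post_init__(self):
        if len(self.samples) != len(self.groups):
            raise ValueError("samples and groups must have equal length")
        if len(self.samples) == 0:
            raise ValueError("sample sheet is empty")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids in sample sheet")

    @property
    def group_names(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g, None)
        return tuple(seen)

    def samples_in(self, group: str) -> tuple[str, ...]:
        return tuple(s for s, g in zip(self.samples, self.groups) if g == group)


@dataclass
class MetaboliteNode:
    """One metabolite of the reaction-pair network."""

    metabolite_id: str
    name: str = ""
    formula: str = ""
    monoisotopic_mass: float = 0.0  # Da
    smiles: str = ""
    predicted_rt: float | None = None  # seconds


@dataclass(frozen=True)
class LibraryRecord:
    """One record of the standard MS2 spectral library."""

    metabolite_id: str
    name: str
    adduct: str
    precursor_mz: float
    spectrum: Spectrum
    collision_energy: str = ""


#: peak roles an annotation can carry
ROLE_MONO = "monoisotope"
ROLE_ISOTOPE = "isotope"
ROLE_ADDUCT = "adduct-of"


@dataclass
class Annotation:
    """One (peak, metabolite, adduct) hypothesis with its score components.

    ``round`` 0 marks a spectral-library (seed) match; higher rounds come
    from network propagation.  For isotope annotations ``isotope_k`` records
    the isotopologue index ([M+k]) and ``parent_peak_id`` the peak whose
    envelope the isotope belongs to.
    """

    peak_id: str
    metabolite_id: str
    adduct: str
    role: str = ROLE_MONO
    score_mz: float = 0.0
    score_rt: float = 0.0
    score_spec: float = 0.0  # DP for round 0 / Score_spec in propagation
    score_int: float = 0.0  # relative-intensity component (isotopes only)
    total_score: float = 0.0
    round: int = 0
    seed_parent: str | None = None  # metabolite id of the seed that proposed this
    parent_peak_id: str | None = None
    isotope_k: int = 0
    grade: int | None = None
    rt_checked: bool = True

    @property
    def key(self) -> tuple[str, str]:
        return (self.peak_id, self.metabolite_id)


@dataclass
class Seed:
    """An annotated metabolite whose spectrum serves as a surrogate."""

    metabolite_id: str
    peak_id: str
    spectrum: Spectrum
    score: float = 1.0
    round: int = 0


@dataclass(frozen=True)
class AdductRule:
    """Ion-type rule: expected m/z = (neutral mass + mass_shift) for |z| = 1."""

    name: str
    mass_shift: float  # Da, includes electron gain/loss
    charge: int  # +1 or -1
    lc: str = "both"  # HILIC / RP / both
    polarity: str = "positive"

    def __post_init__(self):
        if abs(self.charge) != 1:
            raise ValueError("only singly charged species are supported")

    def mz_from_mass(self, monoisotopic_mass: float) -> float:
        return monoisotopic_mass + self.mass_shift


@dataclass
class RoundLog:
    """Bookkeeping of one recursion round."""

    round: int
    n_seeds_in: int
    n_neighbors_retrieved: int
    n_annotated: int
    n_new_seeds: int
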