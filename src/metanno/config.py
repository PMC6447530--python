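"""Run configuration: one flat object carrying every tolerance and weight.

Defaults are the engine's published operating point: 25 ppm m/z match,
10 s MS1-MS2 pairing window, 3 s co-elution window, ±30% RT filter, ±500%
isotope-intensity tolerance, 0.8 library dot-product threshold, 0.5
surrogate-spectrum gate, 0.4 output score cutoff with top-5 candidates,
and a maximum reaction step of 3.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .isotopes import IsoAdductScoringConfig
from .recursion import NeighborScoringConfig
from .spectra import SpectralScoringConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    polarity: str = "positive"  # positive | negative | both
    lc: str = "HILIC"  # HILIC | RP
    instrument: str = ""
    ce: str | None = None  # collision-energy label filter for the library
    control_group: str | None = None
    case_group: str | None = None
    test: str = "t"  # t | wilcoxon
    adjust: str = "none"  # none | BH
    p_cutoff: float = 0.01
    enrichment_p_cutoff: float = 0.05
    species: str = ""
    seed: int = 42

    mz_tol_ppm: float = 25.0
    pair_rt_tol_s: float = 10.0
    coelution_rt_tol_s: float = 3.0
    rt_tol_frac: float = 0.30
    int_tol_pct: float = 500.0
    dp_keep: float = 0.8
    spec_min: float = 0.5
    score_cutoff: float = 0.4
    top_k: int = 5
    max_reaction_step: int = 3
    iso_weights: tuple[float, float, float] = (0.45, 0.45, 0.10)
    adduct_weights: tuple[float, float] = (0.8, 0.2)
    neighbor_weights: tuple[float, float, float] = (0.25, 0.25, 0.50)
    rt_n_repeats: int = 100
    rt_selection_ntree: int = 100
    rt_grid: list | None = None

    def spectral_cfg(self) -> SpectralScoringConfig:
        return SpectralScoringConfig(fragment_align_tol_ppm=self.mz_tol_ppm)

    def iso_cfg(self) -> IsoAdductScoringConfig:
        w = self.iso_weights
        a = self.adduct_weights
        return IsoAdductScoringConfig(
            mz_tol_ppm=self.mz_tol_ppm,
            rt_tol_s=self.coelution_rt_tol_s,
            int_tol_pct=self.int_tol_pct,
            iso_w_mz=w[0], iso_w_rt=w[1], iso_w_int=w[2],
            adduct_w_mz=a[0], adduct_w_rt=a[1],
        )

    def neighbor_cfg(self) -> NeighborScoringConfig:
        w = self.neighbor_weights
        return NeighborScoringConfig(
            mz_tol_ppm=self.mz_tol_ppm,
            rt_tol_frac=self.rt_tol_frac,
            spec_min=self.spec_min,
            w_mz=w[0], w_rt=w[1], w_spec=w[2],
            max_reaction_step=self.max_reaction_step,
            score_cutoff=self.score_cutoff,
            top_k=self.top_k,
        )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("iso_weights", "adduct_weights", "neighbor_weights"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)
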