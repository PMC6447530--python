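"""MS2 spectra: normalization, fragment alignment, and dot-product similarity.

The similarity score used throughout the annotation engine is the classic
weighted-cosine ("dot product") over fragment intensity vectors,

    DP = sum(W_S * W_E) / sqrt(sum(W_S^2) * sum(W_E^2)),   W = I^n * (m/z)^m

with n = 1 and m = 0 by default, so W is simply the relative fragment
intensity after rescaling the base peak to 1.  Scores lie in [0, 1].

Because two spectra never share exact fragment m/z values, the score is
computed over a fragment *alignment*: a greedy one-to-one matching of
fragments within a ppm tolerance.  The forward score is the cosine over the
union vector space (unmatched fragments of either spectrum contribute to
their own denominator only); the reverse score restricts both vectors to the
fragments of the reference spectrum, the convention of reverse library
search.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "Spectrum",
    "SpectralScoringConfig",
    "normalize",
    "align_fragments",
    "dot_product",
    "trim_to_precursor",
]


@dataclass(frozen=True)
class Spectrum:
    """A precursor-tagged fragment spectrum.

    Parameters
    ----------
    precursor_mz:
        Precursor mass-to-charge, Th.
    fragments:
        Array of shape (n, 2): columns are fragment m/z (Th) and intensity.
        Stored sorted by ascending m/z; zero-intensity fragments removed.
    precursor_rt:
        Retention time of the precursor, seconds (optional).
    """

    precursor_mz: float
    fragments: np.ndarray
    precursor_rt: float | None = None
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        frag = np.asarray(self.fragments, dtype=float).reshape(-1, 2)
        if np.any(frag[:, 1] < 0):
            raise ValueError("fragment intensities must be non-negative")
        frag = frag[frag[:, 1] > 0]
        frag = frag[np.argsort(frag[:, 0], kind="stable")]
        object.__setattr__(self, "fragments", frag)

    @property
    def mz(self) -> np.ndarray:
        return self.fragments[:, 0]

    @property
    def intensity(self) -> np.ndarray:
        return self.fragments[:, 1]

    def __len__(self) -> int:
        return len(self.fragments)

    @property
    def is_empty(self) -> bool:
        return len(self.fragments) == 0


@dataclass(frozen=True)
class SpectralScoringConfig:
    """Knobs of the dot-product score.

    ``intensity_exponent`` (n) and ``mz_exponent`` (m) define the fragment
    weight W = I^n * mz^m; defaults n=1, m=0.  Fragment alignment uses a ppm
    tolerance with an absolute floor in Th so that low-m/z fragments are not
    matched over-tightly.
    """

    intensity_exponent: float = 1.0
    mz_exponent: float = 0.0
    fragment_align_tol_ppm: float = 25.0
    fragment_align_tol_floor: float = 0.01  # Th
    min_fragments: int = 1

    def __post_init__(self):
        if self.intensity_exponent < 0 or self.mz_exponent < 0:
            raise ValueError("weight exponents must be >= 0")
        if self.fragment_align_tol_ppm <= 0 or self.fragment_align_tol_floor <= 0:
            raise ValueError("alignment tolerances must be > 0")


DEFAULT_SCORING = SpectralScoringConfig()


def normalize(spec: Spectrum) -> Spectrum:
    """Rescale intensities so the base peak equals 1.

    Empty spectra are returned unchanged.
    """
    if spec.is_empty:
        return spec
    frag = spec.fragments.copy()
    frag[:, 1] /= frag[:, 1].max()
    return replace(spec, fragments=frag)


def _weights(mz: np.ndarray, inten: np.ndarray, cfg: SpectralScoringConfig) -> np.ndarray:
    return inten ** cfg.intensity_exponent * mz ** cfg.mz_exponent


def align_fragments(
    a: Spectrum, b: Spectrum, cfg: SpectralScoringConfig = DEFAULT_SCORING
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Greedy one-to-one fragment matching by ascending m/z distance.

    Candidate pairs within tolerance (max of ppm tolerance and the absolute
    floor) are sorted by |delta m/z|; each fragment is used at most once.

    Returns
    -------
    (matched, unmatched_a, unmatched_b):
        ``matched`` is a list of (index in a, index in b) pairs; the
        unmatched lists hold the leftover fragment indices of each spectrum.
    """
    mza, mzb = a.mz, b.mz
    pairs = []
    for i, m in enumerate(mza):
        tol = max(m * cfg.fragment_align_tol_ppm * 1e-6, cfg.fragment_align_tol_floor)
        lo = np.searchsorted(mzb, m - tol, side="left")
        hi = np.searchsorted(mzb, m + tol, side="right")
        for j in range(lo, hi):
            pairs.append((abs(mzb[j] - m), i, j))
    pairs.sort(key=lambda t: t[0])
    used_a: set[int] = set()
    used_b: set[int] = set()
    matched: list[tuple[int, int]] = []
    for _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        matched.append((i, j))
        used_a.add(i)
        used_b.add(j)
    unmatched_a = [i for i in range(len(mza)) if i not in used_a]
    unmatched_b = [j for j in range(len(mzb)) if j not in used_b]
    return matched, unmatched_a, unmatched_b


def dot_product(
    a: Spectrum,
    b: Spectrum,
    cfg: SpectralScoringConfig = DEFAULT_SCORING,
    mode: str = "forward",
) -> float:
    """Weighted-cosine similarity between two normalized spectra, in [0, 1].

    ``mode='forward'`` scores over the union of fragments: unmatched
    fragments of either spectrum contribute zero to the numerator but full
    weight to their own denominator term, so spurious fragments are
    penalized.  ``mode='reverse'`` treats ``b`` as the reference spectrum and
    restricts both vectors to the reference's fragments: unmatched fragments
    of ``a`` are ignored entirely.

    Two empty spectra (or empty fragment overlap in a degenerate case) score 0.
    """
    if mode not in ("forward", "reverse"):
        raise ValueError(f"unknown mode {mode!r}")
    if a.is_empty and b.is_empty:
        warnings.warn("dot_product of two empty spectra; returning 0")
        return 0.0
    if a.is_empty or b.is_empty:
        return 0.0
    wa = _weights(a.mz, a.intensity, cfg)
    wb = _weights(b.mz, b.intensity, cfg)
    matched, _, _ = align_fragments(a, b, cfg)
    num = sum(wa[i] * wb[j] for i, j in matched)
    if num == 0.0:
        return 0.0
    if mode == "forward":
        den_a = float(np.sum(wa**2))
        den_b = float(np.sum(wb**2))
    else:
        den_a = sum(wa[i] ** 2 for i, _ in matched)
        den_b = float(np.sum(wb**2))
    if den_a == 0.0 or den_b == 0.0:
        return 0.0
    return float(num / np.sqrt(den_a * den_b))


def trim_to_precursor(
    surrogate: Spectrum, seed_mz: float, neighbor_mz: float, experimental: Spectrum
) -> tuple[Spectrum, Spectrum]:
    """Drop fragments that cannot exist for the lighter of seed/neighbor.

    A surrogate spectrum borrowed from a seed metabolite may contain
    fragments heavier than the neighbor's precursor; those are physically
    impossible for the neighbor and are removed before scoring.  When the
    neighbor is the heavier species the rule applies in the opposite
    direction and the experimental spectrum is trimmed instead.

    Returns the (surrogate, experimental) pair, each possibly trimmed.
    Trimming can yield an empty spectrum, in which case the downstream score
    is 0.
    """
    if seed_mz <= 0 or neighbor_mz <= 0:
        raise ValueError("precursor m/z values must be > 0")
    if seed_mz > neighbor_mz:
        frag = surrogate.fragments[surrogate.mz <= neighbor_mz]
        surrogate = replace(surrogate, fragments=frag)
    elif neighbor_mz > seed_mz:
        frag = experimental.fragments[experimental.mz <= seed_mz]
        experimental = replace(experimental, fragments=frag)
    return surrogate, experimental
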