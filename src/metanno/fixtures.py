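"""Synthetic ground-truthed datasets exercising every pipeline stage.

The generator plants the statistical structure the annotation engine
relies on:

* a reaction-pair network over randomly composed organic formulas (chain,
  star or small-world topology);
* fragment spectra that are *inherited* along network edges — reaction
  partners share a configurable fraction of fragments (default 0.7, giving
  an expected dot product above the 0.5 propagation gate), while unrelated
  metabolites share only a few percent by chance;
* an MS1 peak table with exact isotope envelopes, an extra adduct peak for
  part of the metabolites, per-sample log-normal abundances with a planted
  fold change for effect metabolites, and a handful of noise peaks;
* retention times generated as a fixed linear function of two planted
  molecular descriptors (plus decoy descriptors, missing values and a
  constant column to exercise matrix hygiene);
* a spectral library covering a configurable subset of metabolites (the
  prospective seeds) and a pathway table with the effect metabolites
  concentrated in one pathway.

Every generated peak is traceable to exactly one ground-truth record (or
labeled noise).  All randomness flows from the mandatory seed, and
``Fixture.write`` emits byte-identical files for identical specs.

Not emulated: chromatographic peak shapes, detector noise models, in-source
fragmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .isotopes import ISOTOPE_SPACING, isotope_pattern
from .models import LibraryRecord, MS1Peak, SampleSheet, Seed
from .mrn import ReactionPairNetwork, build_mrn
from .msio import write_library, write_ms2
from .pathway import PathwayDB
from .spectra import Spectrum

__all__ = [
    "FixtureSpec",
    "GroundTruth",
    "Fixture",
    "make_fixture",
    "corrupt_seeds",
    "StressResult",
    "seed_stress_experiment",
]

PROTON = 1.0072765
SODIUM = 22.9892213


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions of one synthetic dataset."""

    seed: int
    n_metabolites: int = 50
    topology: str = "smallworld"  # chain | star | smallworld
    inheritance: float = 0.7
    library_fraction: float = 0.2
    library_metabolites: tuple[str, ...] | None = None
    n_samples_per_group: int = 10
    n_effect: int = 5
    fold_change: float = 4.0
    noise_sd: float = 0.2  # log-scale per-sample intensity noise
    rt_noise_sd: float = 3.0  # seconds, on the descriptor-driven RT
    n_fragments: int = 12
    fragment_pool: int = 400
    n_decoy_descriptors: int = 20
    n_noise_peaks: int = 10
    adduct_fraction: float = 0.5  # metabolites that also show [M+Na]+
    n_isotope_peaks: int = 2  # [M+1], [M+2] planted per metabolite

    def __post_init__(self):
        if not (0.0 <= self.inheritance <= 1.0):
            raise ValueError("inheritance fraction must be in [0, 1]")
        if self.topology not in ("chain", "star", "smallworld"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.n_metabolites < 2:
            raise ValueError("need at least 2 metabolites")


@dataclass
class GroundTruth:
    """What each generated peak really is."""

    peak_truth: dict[str, tuple[str, str, str]]  # peak -> (metabolite | "", adduct, role)
    metabolite_rt: dict[str, float]
    metabolite_peak: dict[str, str]  # metabolite -> monoisotope peak id
    seed_metabolites: list[str]
    effect_metabolites: list[str]
    planted_descriptors: tuple[str, str] = ("d1", "d2")
    dysregulated_pathway: str = ""


@dataclass
class Fixture:
    """In-memory dataset plus writers for the on-disk formats."""

    spec: FixtureSpec
    compounds: pd.DataFrame
    pairs: pd.DataFrame
    net: ReactionPairNetwork
    peaks: list[MS1Peak]
    sheet: SampleSheet
    ms2: list[Spectrum]
    library: list[LibraryRecord]
    descriptors: pd.DataFrame
    pathways: PathwayDB
    truth: GroundTruth
    true_spectra: dict[str, Spectrum] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        files = {
            "peak_table": out / "peak_table.csv",
            "sample_sheet": out / "sample_sheet.csv",
            "ms2": out / "spectra.mgf",
            "library": out / "library.msp",
            "pairs": out / "reaction_pairs.csv",
            "compounds": out / "compounds.csv",
            "descriptors": out / "descriptors.csv",
            "pathways": out / "pathways.csv",
        }
        samples = list(self.sheet.samples)
        rows = []
        for p in self.peaks:
            row = {"name": p.peak_id, "mz": round(p.mz, 6), "rt": round(p.rt, 3)}
            row.update({s: round(p.intensities[s], 3) for s in samples})
            rows.append(row)
        pd.DataFrame(rows).to_csv(files["peak_table"], index=False)
        pd.DataFrame({"sample.name": samples, "group": list(self.sheet.groups)}).to_csv(
            files["sample_sheet"], index=False
        )
        write_ms2(files["ms2"], self.ms2, dialect="mgf")
        write_library(files["library"], self.library)
        self.pairs.to_csv(files["pairs"], index=False)
        self.compounds.round(6).to_csv(files["compounds"], index=False)
        self.descriptors.round(6).to_csv(files["descriptors"], index_label="metabolite_id")
        pd.DataFrame(
            {
                "pathway_id": list(self.pathways.members),
                "name": [self.pathways.names[p] for p in self.pathways.members],
                "members": [";".join(sorted(self.pathways.members[p])) for p in self.pathways.members],
            }
        ).to_csv(files["pathways"], index=False)
        return files


def _random_formula(rng: np.random.Generator) -> str:
    c = int(rng.integers(6, 22))
    h = int(rng.integers(c, 2 * c + 3))
    n = int(rng.integers(0, 4))
    o = int(rng.integers(1, 8))
    parts = [f"C{c}", f"H{h}"]
    if n:
        parts.append(f"N{n}")
    parts.append(f"O{o}")
    return "".join(parts)


def _graph(spec: FixtureSpec) -> nx.Graph:
    n = spec.n_metabolites
    if spec.topology == "chain":
        return nx.path_graph(n)
    if spec.topology == "star":
        return nx.star_graph(n - 1)
    return nx.connected_watts_strogatz_graph(n, k=4, p=0.1, seed=spec.seed)


def make_fixture(spec: FixtureSpec) -> Fixture:
    """Generate a complete dataset with planted ground truth."""
    from pyteomics import mass as pytmass

    rng = np.random.default_rng(spec.seed)
    n = spec.n_metabolites
    met_ids = [f"M{i:04d}" for i in range(n)]

    # --- compounds: formulas whose ion hypotheses never collide -----------
    # separation is enforced on every ion m/z the engine can hypothesize
    # (all positive adduct rules, with isotopologues), not just neutral
    # masses: one metabolite's [M+NH4]+ window landing on another's [M+H]+
    # peak would make peak identity ambiguous and the ground truth
    # ill-defined
    from .isotopes import POSITIVE_ADDUCTS

    shifts = [r.mass_shift for r in POSITIVE_ADDUCTS]

    def _ion_mzs(m: float) -> list[float]:
        return [
            m + shift + k * ISOTOPE_SPACING
            for shift in shifts
            for k in range(3)
        ]

    masses: list[float] = []
    formulas: list[str] = []
    used_mz: list[float] = []
    for _ in met_ids:
        for _attempt in range(500):
            f = _random_formula(rng)
            m = float(pytmass.calculate_mass(formula=f))
            ions = _ion_mzs(m)
            if all(
                abs(mz - u) / u > 6e-5 for mz in ions for u in used_mz
            ):
                break
        masses.append(m)
        formulas.append(f)
        used_mz.extend(_ion_mzs(m))
    compounds = pd.DataFrame(
        {
            "id": met_ids,
            "name": [f"metabolite {i}" for i in range(n)],
            "formula": formulas,
            "monoisotopic_mass": masses,
            "smiles": ["C" * parse_c(f) for f in formulas],
        }
    )

    # --- network ----------------------------------------------------------
    g = _graph(spec)
    pairs = pd.DataFrame(
        [
            {"rp_id": f"RP{k:04d}", "from": met_ids[a], "to": met_ids[b]}
            for k, (a, b) in enumerate(sorted(g.edges()))
        ]
    )
    net = build_mrn(pairs, compounds)

    # --- fragment spectra with graph-coherent inheritance -----------------
    # Fragment content follows a latent coordinate: each node's spectrum is
    # a sliding window over a permuted fragment pool, so the shared-fragment
    # proportion decays with lattice distance.  Every reaction-paired
    # neighbor then shares fragments (mean proportion = the configured
    # inheritance), two-step relatives share less, and distant metabolites
    # share essentially nothing — the similarity structure annotation
    # propagation relies on, with redundant paths into every node.
    spectra_frag = _inherited_spectra(spec, g, met_ids, rng)

    # --- descriptors and retention times ----------------------------------
    d1 = rng.uniform(0.0, 60.0, size=n)
    d2 = rng.uniform(0.0, 60.0, size=n)
    rt_signal = 100.0 + 2.0 * d1 + 3.0 * d2
    rt_true = rt_signal + rng.normal(0.0, spec.rt_noise_sd, size=n)
    rt_true = np.maximum(rt_true, 30.0)
    desc = pd.DataFrame({"d1": d1, "d2": d2}, index=pd.Index(met_ids, name="metabolite_id"))
    for j in range(spec.n_decoy_descriptors):
        col = rng.uniform(0.0, 60.0, size=n)
        if j < 3:  # some decoys carry missing values
            miss = rng.random(n) < 0.2
            col = np.where(miss, np.nan, col)
        desc[f"decoy{j:02d}"] = col
    desc["const"] = 1.0

    # --- samples and abundances -------------------------------------------
    n_s = spec.n_samples_per_group
    samples = [f"S{i + 1:02d}" for i in range(2 * n_s)]
    groups = ["control"] * n_s + ["case"] * n_s
    sheet = SampleSheet(samples=tuple(samples), groups=tuple(groups))
    effect = list(rng.choice(met_ids, size=min(spec.n_effect, n), replace=False))

    peaks: list[MS1Peak] = []
    ms2: list[Spectrum] = []
    truth: dict[str, tuple[str, str, str]] = {}
    met_peak: dict[str, str] = {}
    true_spectra: dict[str, Spectrum] = {}
    pk = 0

    def next_pid() -> str:
        nonlocal pk
        pk += 1
        return f"P{pk:05d}"

    for i, mid in enumerate(met_ids):
        mono_mz_t = masses[i] + PROTON
        mz_err = rng.uniform(-5, 5) * 1e-6
        mono_mz = mono_mz_t * (1.0 + mz_err)
        rt = float(rt_true[i])
        base = float(np.exp(rng.normal(np.log(1e5), 0.5)))
        inten = base * np.exp(rng.normal(0.0, spec.noise_sd, size=2 * n_s))
        if mid in effect:
            inten[n_s:] *= spec.fold_change
        mono_int = {s: float(v) for s, v in zip(samples, inten)}
        pid = next_pid()
        peaks.append(MS1Peak(pid, mono_mz, rt, mono_int))
        truth[pid] = (mid, "[M+H]+", "monoisotope")
        met_peak[mid] = pid

        pattern = isotope_pattern(formulas[i], monoisotopic_mass=masses[i])
        for k in range(1, spec.n_isotope_peaks + 1):
            rel = pattern.relative_intensity[k]
            if rel <= 0:
                continue
            ipid = next_pid()
            peaks.append(
                MS1Peak(
                    ipid,
                    mono_mz + k * ISOTOPE_SPACING,
                    rt + float(rng.uniform(-0.3, 0.3)),
                    {s: v * rel / 100.0 for s, v in mono_int.items()},
                )
            )
            truth[ipid] = (mid, "[M+H]+", f"isotope[M+{k}]")

        if rng.random() < spec.adduct_fraction:
            apid = next_pid()
            peaks.append(
                MS1Peak(
                    apid,
                    (masses[i] + SODIUM) * (1.0 + rng.uniform(-5, 5) * 1e-6),
                    rt + float(rng.uniform(-0.3, 0.3)),
                    {s: 0.3 * v for s, v in mono_int.items()},
                )
            )
            truth[apid] = (mid, "[M+Na]+", "adduct")

        frag = spectra_frag[mid]
        true_spectra[mid] = Spectrum(precursor_mz=mono_mz_t, fragments=frag.copy())
        exp_frag = frag.copy()
        exp_frag[:, 1] *= np.exp(rng.normal(0.0, 0.05, size=len(exp_frag)))
        ms2.append(
            Spectrum(
                precursor_mz=mono_mz,
                precursor_rt=rt,
                fragments=exp_frag,
                metadata={"title": f"{pid}_{mid}"},
            )
        )

    # noise peaks, kept clear of every true peak's match window
    true_mzs = np.array([p.mz for p in peaks])
    n_noise = 0
    while n_noise < spec.n_noise_peaks:
        mz = float(rng.uniform(150.0, 650.0))
        if np.min(np.abs(true_mzs - mz) / mz) < 5e-5:
            continue
        pid = next_pid()
        peaks.append(
            MS1Peak(
                pid,
                mz,
                float(rng.uniform(40.0, 400.0)),
                {s: float(np.exp(rng.normal(np.log(2e4), 0.5))) for s in samples},
            )
        )
        truth[pid] = ("", "", "noise")
        n_noise += 1

    # --- spectral library ---------------------------------------------------
    if spec.library_metabolites is not None:
        lib_ids = list(spec.library_metabolites)
    else:
        n_lib = max(1, int(round(spec.library_fraction * n)))
        lib_ids = sorted(rng.choice(met_ids, size=n_lib, replace=False))
    library = []
    for mid in lib_ids:
        i = met_ids.index(mid)
        frag = spectra_frag[mid].copy()
        frag[:, 1] *= np.exp(rng.normal(0.0, 0.03, size=len(frag)))
        library.append(
            LibraryRecord(
                metabolite_id=mid,
                name=f"metabolite {i}",
                adduct="[M+H]+",
                precursor_mz=masses[i] + PROTON,
                spectrum=Spectrum(precursor_mz=masses[i] + PROTON, fragments=frag),
                collision_energy="30",
            )
        )

    # --- pathways: effect metabolites concentrated in the first ------------
    non_effect = [m for m in met_ids if m not in effect]
    rng.shuffle(non_effect)
    n_path = 4
    members: dict[str, set[str]] = {f"path{j + 1}": set() for j in range(n_path)}
    members["path1"].update(effect)
    for j, m in enumerate(non_effect):
        members[f"path{(j % n_path) + 1}"].add(m)
    pathways = PathwayDB(
        names={p: f"pathway {p[-1]}" for p in members},
        members={p: mem for p, mem in members.items() if mem},
    )

    gt = GroundTruth(
        peak_truth=truth,
        metabolite_rt={m: float(r) for m, r in zip(met_ids, rt_true)},
        metabolite_peak=met_peak,
        seed_metabolites=list(lib_ids),
        effect_metabolites=effect,
        dysregulated_pathway="path1",
    )
    return Fixture(
        spec=spec,
        compounds=compounds,
        pairs=pairs,
        net=net,
        peaks=peaks,
        sheet=sheet,
        ms2=ms2,
        library=library,
        descriptors=desc,
        pathways=pathways,
        truth=gt,
        true_spectra=true_spectra,
    )


def parse_c(formula: str) -> int:
    from .mrn import parse_formula

    return parse_formula(formula).get("C", 1)


def _inherited_spectra(
    spec: FixtureSpec, g: nx.Graph, met_ids: list[str], rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Fragment sets as sliding windows over a permuted fragment pool.

    The window step is chosen so the mean shared-fragment proportion over
    the topology's neighbor edges equals the inheritance fraction; zero
    inheritance uses fully disjoint windows.  Fragment m/z values come from
    a spaced grid (well beyond the alignment tolerance apart) and each pool
    fragment carries an intrinsic intensity, jittered per node, so shared
    fragments look alike across neighboring spectra.
    """
    L = spec.n_fragments
    f = spec.inheritance
    if f == 0.0:
        step = float(L)
    elif spec.topology == "smallworld":
        # lattice edges reach one and two positions: mean overlap
        # ((L-s) + (L-2s)) / 2L = f
        step = 2.0 * L * (1.0 - f) / 3.0
    else:
        step = L * (1.0 - f)
    n = len(met_ids)
    if spec.topology == "star":
        # every spoke keeps a random inheritance-fraction of the hub's
        # fragments plus a private remainder
        n_keep = int(round(f * L))
        needed = L + (n - 1) * (L - n_keep)
        selections: dict[int, np.ndarray] = {}
        cursor = L
        hub_sel = np.arange(L)
        selections[0] = hub_sel
        for v in range(1, n):
            kept = rng.choice(hub_sel, size=n_keep, replace=False) if n_keep else np.empty(0, int)
            fresh = np.arange(cursor, cursor + L - n_keep)
            cursor += L - n_keep
            selections[v] = np.concatenate([kept, fresh])
    else:
        starts = {v: int(round(step * v)) for v in g.nodes}
        needed = max(starts.values()) + L
        selections = {v: np.arange(starts[v], starts[v] + L) for v in g.nodes}
    grid = np.arange(60.0, 140.0, 0.05)
    pool_size = max(spec.fragment_pool, needed)
    if pool_size > len(grid):
        raise ValueError("fragment pool exceeds the available m/z grid")
    pool_mz = np.sort(rng.choice(grid, size=pool_size, replace=False))
    perm = rng.permutation(pool_size)  # scatter windows across the m/z range
    pool_intensity = rng.uniform(0.2, 1.0, size=pool_size)
    spectra: dict[str, np.ndarray] = {}
    for v in g.nodes:
        sel = perm[selections[v]]
        mz = pool_mz[sel]
        inten = pool_intensity[sel] * np.exp(rng.normal(0.0, 0.08, size=len(sel)))
        order = np.argsort(mz)
        spectra[met_ids[v]] = np.column_stack([mz[order], inten[order]])
    return spectra


# ---------------------------------------------------------------------------
# Misannotated-seed stress test


@dataclass
class DecoyRecord:
    decoy_id: str
    true_metabolite: str
    peak_id: str
    mass_error_ppm: float
    rt_error_s: float
    dp_with_true: float


def corrupt_seeds(
    fixture: Fixture,
    corruption_type: int,
    rng: np.random.Generator | None = None,
) -> tuple[list[Seed], ReactionPairNetwork, list[DecoyRecord]]:
    """Replace the true seed assignments with decoy metabolites.

    Four decoy classes, defined by the decoy's theoretical mass and RT
    relative to the seed peak and by its spectral similarity to the true
    seed spectrum:

    1. mass error > 25 ppm and RT error > 60 s;
    2. mass error < 25 ppm, RT error > 60 s;
    3. mass error < 25 ppm, RT error < 60 s;
    4. as 2, but the decoy's spectrum has a dot product > 0.8 with the true
       seed spectrum (an isomer-like decoy).

    Each decoy is a new network node attached to a non-reaction-paired
    metabolite chosen by spectral similarity: decoys of types 1-2
    (chemically unrelated) attach where every spectrum reachable within the
    widened search is below the propagation gate, so their propagation is
    blocked; mass-matched decoys (types 3-4, isomer-like) attach where the
    similarity to the surrogate spectrum is marginal, producing a reduced
    number of low-scoring annotations.
    Returns the corrupted seeds, an augmented copy of the
    network, and the decoy bookkeeping (each record verifiably satisfies
    its class inequalities).
    """
    if corruption_type not in (1, 2, 3, 4):
        raise ValueError("corruption type must be 1..4")
    if rng is None:
        rng = np.random.default_rng(fixture.spec.seed + corruption_type)
    from .spectra import dot_product, normalize

    net = ReactionPairNetwork(fixture.net.graph.copy(), dict(fixture.net.compounds))
    _dp_cache: dict[tuple[str, str], float] = {}
    peak_by_id = {p.peak_id: p for p in fixture.peaks}
    ms2_by_title = {s.metadata.get("title", ""): s for s in fixture.ms2}
    seeds: list[Seed] = []
    records: list[DecoyRecord] = []
    grid = np.arange(60.0, 140.0, 0.05)
    for j, mid in enumerate(fixture.truth.seed_metabolites):
        pid = fixture.truth.metabolite_peak[mid]
        peak = peak_by_id[pid]
        exp_spec = ms2_by_title.get(f"{pid}_{mid}")
        if exp_spec is None:
            continue
        # attachment is chosen by the defining empirical property of
        # misannotated seeds: low spectral similarity between the surrogate
        # spectrum and the decoy's reachable neighborhood.  Unrelated
        # decoys (types 1-2) attach where every reachable spectrum is below
        # the propagation gate; mass-matched decoys (types 3-4) attach
        # where the similarity is marginal, so a reduced number of
        # low-scoring annotations can still arise.
        seed_spec_norm = normalize(fixture.true_spectra[mid])

        def _max_nbhd_dp(candidate: str, steps: int = 2) -> float:
            nbhd = nx.single_source_shortest_path_length(net.graph, candidate, cutoff=steps)
            vals = [
                _dp_cache.setdefault(
                    (mid, m),
                    dot_product(seed_spec_norm, normalize(fixture.true_spectra[m])),
                )
                for m in nbhd
                if m in fixture.true_spectra
            ]
            # the true metabolite scores 1.0 against itself, so attachment
            # within reach of it is rejected automatically
            return max(vals, default=0.0)

        candidates = [
            m for m in net.graph.nodes
            if m != mid and not net.graph.has_edge(m, mid) and not m.startswith("DECOY")
        ]
        rng.shuffle(candidates)
        if corruption_type in (1, 2):
            # margin below the 0.5 gate: experimental-spectrum jitter can
            # lift a borderline similarity across it
            pool = [m for m in candidates[:40] if _max_nbhd_dp(m) < 0.40]
        else:
            pool = [m for m in candidates[:40] if 0.45 <= _max_nbhd_dp(m) < 0.70]
        if not pool:
            continue  # no eligible attachment point for a decoy
        attach = str(rng.choice(pool))
        decoy_id = f"DECOY{corruption_type}{j:03d}"
        true_mass = float(
            fixture.compounds.set_index("id").loc[mid, "monoisotopic_mass"]
        )
        if corruption_type == 1:
            mass = true_mass * (1.0 + 80e-6)
            rt_shift = 90.0
        elif corruption_type == 2 or corruption_type == 4:
            mass = true_mass * (1.0 + 5e-6)
            rt_shift = 90.0
        else:
            mass = true_mass * (1.0 + 5e-6)
            rt_shift = 30.0
        true_frag = fixture.true_spectra[mid].fragments
        if corruption_type == 4:
            frag = true_frag.copy()
            frag[:, 1] *= np.exp(rng.normal(0.0, 0.03, size=len(frag)))
        else:
            mzs = np.sort(rng.choice(grid, size=len(true_frag), replace=False))
            frag = np.column_stack([mzs, rng.uniform(0.2, 1.0, size=len(mzs))])
        decoy_spec = Spectrum(precursor_mz=mass + PROTON, fragments=frag)
        dp = dot_product(normalize(decoy_spec), normalize(fixture.true_spectra[mid]))
        from .models import MetaboliteNode

        node = MetaboliteNode(
            metabolite_id=decoy_id,
            name=f"decoy for {mid}",
            formula="",
            monoisotopic_mass=mass,
            smiles="",
        )
        net.compounds[decoy_id] = node
        net.graph.add_edge(decoy_id, attach, rp_ids=[f"RPD{j:03d}"])
        net.graph.nodes[decoy_id]["eligible"] = False
        mz_t = mass + PROTON
        records.append(
            DecoyRecord(
                decoy_id=decoy_id,
                true_metabolite=mid,
                peak_id=pid,
                mass_error_ppm=abs(mz_t - peak.mz) / peak.mz * 1e6,
                rt_error_s=abs((peak.rt + rt_shift) - peak.rt),
                dp_with_true=dp,
            )
        )
        seeds.append(
            Seed(metabolite_id=decoy_id, peak_id=pid, spectrum=normalize(exp_spec), round=0)
        )
    return seeds, net, records


@dataclass
class StressResult:
    """Propagation outcome with true versus corrupted seeds."""

    n_control: int  # recursive annotations from the true seeds
    n_corrupted: int  # recursive annotations from the decoy seeds
    control_scores: list[float] = field(default_factory=list)
    corrupted_scores: list[float] = field(default_factory=list)

    def removal_fraction(self, scores: list[float], cutoff: float, base: float = 0.4) -> float:
        kept_base = [s for s in scores if s > base]
        if not kept_base:
            return 0.0
        return 1.0 - len([s for s in kept_base if s > cutoff]) / len(kept_base)


def seed_stress_experiment(
    fixture: Fixture,
    corruption_type: int = 1,
    config=None,
) -> StressResult:
    """Propagate from true seeds and from corrupted seeds, same inputs.

    Measures how badly misannotated seeds pollute the recursive output:
    the number of recursive (round > 0) monoisotope annotations from each
    seed set, and their score distributions (whose tails determine how
    much a higher score cutoff removes).
    """
    from .config import RunConfig
    from .msio import pair_ms1_ms2
    from .recursion import annotate_neighbors, run_recursion
    from .seeds import init_seeds, match_library
    from .isotopes import PeakIndex, adduct_rules
    from .models import ROLE_MONO
    from . import rtpred

    config = config or RunConfig()
    pairs_map = pair_ms1_ms2(
        fixture.peaks, fixture.ms2,
        mz_tol_ppm=config.mz_tol_ppm, rt_tol_s=config.pair_rt_tol_s,
    )
    round0 = match_library(
        pairs_map, fixture.peaks, fixture.library,
        mz_tol_ppm=config.mz_tol_ppm, dp_keep=config.dp_keep,
    )
    predicted_rt: dict[str, float] = {}
    try:
        model, predicted_rt = rtpred.train_rt_model(
            round0, fixture.peaks, fixture.descriptors,
            seed=config.seed, lc=config.lc,
            n_repeats=config.rt_n_repeats,
            selection_ntree=config.rt_selection_ntree,
            grid=config.rt_grid,
        )
        if not model.usable:
            predicted_rt = {}
    except ValueError:
        pass
    rules = adduct_rules("positive", config.lc)
    ncfg = config.neighbor_cfg()

    control_seeds = init_seeds(round0, fixture.net, pairs_map)
    control_ann, _ = run_recursion(
        control_seeds, fixture.net, fixture.peaks, pairs_map, predicted_rt,
        rules, cfg=ncfg, annotate_isotope_peaks=False,
    )
    corrupted_seeds, corrupted_net, _ = corrupt_seeds(fixture, corruption_type)
    if corrupted_seeds:
        corrupted_ann, _ = run_recursion(
            corrupted_seeds, corrupted_net, fixture.peaks, pairs_map,
            predicted_rt, rules, cfg=ncfg, annotate_isotope_peaks=False,
        )
    else:
        corrupted_ann = []
    control = [a for a in control_ann if a.round > 0 and a.role == ROLE_MONO]
    corrupted = [a for a in corrupted_ann if a.round > 0 and a.role == ROLE_MONO]

    # score distributions are compared on the annotations each seed set
    # derives *directly* (one neighbor-annotation pass per seed): the full
    # recursion re-seeds from real peak spectra, so later rounds no longer
    # carry the misannotated seeds' signature
    def _direct_scores(seed_list, network) -> list[float]:
        index = PeakIndex(fixture.peaks)
        scores: list[float] = []
        for sd in seed_list:
            anns, _ = annotate_neighbors(
                sd, network, index, pairs_map, predicted_rt, rules, ncfg
            )
            scores.extend(a.total_score for a in anns)
        return scores

    return StressResult(
        n_control=len(control),
        n_corrupted=len(corrupted),
        control_scores=_direct_scores(control_seeds, fixture.net),
        corrupted_scores=_direct_scores(corrupted_seeds, corrupted_net),
    )
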