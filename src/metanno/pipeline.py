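"""End-to-end pipeline: the six stages wired together.

1. import the MS1 peak table and MS2 data, pair them;
2. annotate initial seed metabolites against the spectral library
   (with RT-model training and predicted-RT filtering in between);
3-4. recursive network annotation of reaction-paired neighbors, with
   isotope/adduct support-peak annotation;
5. confidence assignment and redundancy removal;
6. dysregulated-pathway analysis and quantification.

Deterministic under a fixed seed; stage logs and the per-round trace are
written next to the result files.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import msio, rtpred
from .confidence import PeakGroup, RedundancyReport, remove_redundancy
from .config import RunConfig
from .fixtures import Fixture
from .isotopes import PeakIndex, adduct_rules, annotate_adducts
from .models import Annotation, MS1Peak, RoundLog, SampleSheet, ROLE_MONO
from .mrn import ReactionPairNetwork, build_mrn, read_compounds, read_reaction_pairs
from .pathway import (
    PathwayDB,
    dysregulated_peaks,
    enrich_pathways,
    quantify_pathways,
    read_pathway_db,
)
from .recursion import run_recursion
from .seeds import filter_by_predicted_rt, init_seeds, match_library

log = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline", "run_on_fixture"]


@dataclass
class PipelineResult:
    annotations: list[Annotation]
    groups: list[PeakGroup]
    redundancy: RedundancyReport
    round_logs: list[RoundLog]
    enrichment: pd.DataFrame
    quant_metabolite: pd.DataFrame
    quant_pathway: pd.DataFrame
    predicted_rt: dict[str, float] = field(default_factory=dict)
    rt_model: object | None = None
    n_seeds0: int = 0

    @property
    def mono_annotations(self) -> list[Annotation]:
        return [a for a in self.annotations if a.role == ROLE_MONO]


def _annotate_seed_adducts(annotations, peaks, net, rules, iso_cfg):
    """Adduct (and adduct-isotope) support peaks for library annotations."""
    index = PeakIndex(peaks)
    peak_by_id = {p.peak_id: p for p in peaks}
    support = []
    for a in annotations:
        if a.role != ROLE_MONO or a.metabolite_id not in net.compounds:
            continue
        node = net.node(a.metabolite_id)
        if node.monoisotopic_mass <= 0:
            continue
        peak = peak_by_id.get(a.peak_id)
        if peak is None:
            continue
        support.extend(
            annotate_adducts(
                a, peak, node.monoisotopic_mass, index, rules, iso_cfg,
                formula=node.formula or None,
            )
        )
    return support


def run_core(
    peaks: list[MS1Peak],
    sheet: SampleSheet,
    pairs_map,
    library,
    net: ReactionPairNetwork,
    descriptors: pd.DataFrame,
    pathways: PathwayDB | None,
    config: RunConfig,
) -> PipelineResult:
    """The analysis stages on already-loaded inputs."""
    t0 = time.time()
    rules = adduct_rules(config.polarity if config.polarity != "both" else "positive", config.lc)

    # stage 2: seed annotation
    round0 = match_library(
        pairs_map, peaks, library,
        mz_tol_ppm=config.mz_tol_ppm, dp_keep=config.dp_keep, ce=config.ce,
        cfg=config.spectral_cfg(),
    )
    log.info("library matching: %d round-0 annotations", len(round0))

    # RT model (trained on round-0 identifications), then the ±30% filter
    predicted_rt: dict[str, float] = {}
    rt_model = None
    if descriptors is not None and len(round0):
        try:
            rt_model, predicted_rt = rtpred.train_rt_model(
                round0, peaks, descriptors,
                seed=config.seed, lc=config.lc,
                n_repeats=config.rt_n_repeats,
                selection_ntree=config.rt_selection_ntree,
                grid=config.rt_grid,
            )
            log.info(
                "RT model: %d descriptors, ntree=%d mtry=%d, oob MSE %.1f",
                len(rt_model.selected_descriptors), rt_model.ntree, rt_model.mtry,
                rt_model.training_mse,
            )
        except ValueError as e:
            log.warning("RT model not trained (%s); RT filtering skipped", e)
    if rt_model is not None and not rt_model.usable:
        log.warning(
            "RT model out-of-bag R² = %.2f (no predictive value); RT filtering "
            "disabled, annotations will be RT-unchecked", rt_model.oob_r2,
        )
        predicted_rt = {}
    rt_tol_frac = config.rt_tol_frac
    if rt_model is not None and rt_model.recommended_rt_tol_frac is not None:
        rt_tol_frac = max(rt_tol_frac, rt_model.recommended_rt_tol_frac)
        log.warning(
            "RT model trained on only %d metabolites; widening the RT filter to ±%.0f%%",
            rt_model.n_training, 100 * rt_tol_frac,
        )
    round0 = filter_by_predicted_rt(round0, peaks, predicted_rt, rt_tol_frac)
    log.info("after predicted-RT filter: %d round-0 annotations", len(round0))

    # stage 3-4: recursion with isotope support peaks
    seeds0 = init_seeds(round0, net, pairs_map)
    neighbor_cfg = config.neighbor_cfg()
    if rt_tol_frac != neighbor_cfg.rt_tol_frac:
        from dataclasses import replace as _replace

        neighbor_cfg = _replace(neighbor_cfg, rt_tol_frac=rt_tol_frac)
    annotations, round_logs = run_recursion(
        seeds0, net, peaks, pairs_map, predicted_rt, rules,
        cfg=neighbor_cfg, iso_cfg=config.iso_cfg(),
        round0_annotations=round0,
    )
    annotations = annotations + _annotate_seed_adducts(
        [a for a in annotations if a.round == 0], peaks, net, rules, config.iso_cfg()
    )
    log.info(
        "recursion: %d rounds, %d annotations",
        len(round_logs), len(annotations),
    )

    # stage 5: confidence and redundancy
    retained, redundancy, groups = remove_redundancy(
        annotations, peaks, rt_window_s=config.coelution_rt_tol_s
    )
    log.info(
        "redundancy removal: %d annotations retained; peak %.2f / metabolite %.2f",
        len(retained), redundancy.peak_redundancy, redundancy.metabolite_redundancy,
    )

    # stage 6: pathway analysis
    enrichment = pd.DataFrame()
    quant_met = pd.DataFrame()
    quant_path = pd.DataFrame()
    if pathways is not None and len(sheet.group_names) == 2:
        stats_res = dysregulated_peaks(
            peaks, sheet, test=config.test, adjust=config.adjust, p_cutoff=config.p_cutoff
        )
        dys_peaks = {r.peak_id for r in stats_res if r.dysregulated}
        mono = [a for a in retained if a.role == ROLE_MONO]
        universe = {a.metabolite_id for a in mono}
        dys_mets = {a.metabolite_id for a in mono if a.peak_id in dys_peaks}
        enrichment = enrich_pathways(
            dys_mets, universe, pathways, p_cutoff=config.enrichment_p_cutoff
        )
        sig = enrichment[enrichment["significant"]]["pathway_id"].tolist() if len(enrichment) else []
        quant_met, quant_path = quantify_pathways(
            retained, groups, peaks, pathways, pathway_ids=sig or None
        )
    log.info("pipeline finished in %.1f s", time.time() - t0)
    return PipelineResult(
        annotations=retained,
        groups=groups,
        redundancy=redundancy,
        round_logs=round_logs,
        enrichment=enrichment,
        quant_metabolite=quant_met,
        quant_pathway=quant_path,
        predicted_rt=predicted_rt,
        rt_model=rt_model,
        n_seeds0=len(seeds0),
    )


def run_pipeline(
    config: RunConfig,
    peak_table: str | Path,
    sample_sheet: str | Path,
    ms2: str | Path,
    library: str | Path,
    reaction_pairs: str | Path,
    compounds: str | Path,
    descriptors: str | Path | None = None,
    pathways: str | Path | None = None,
    out_dir: str | Path = "metanno_out",
) -> PipelineResult:
    """Load inputs from files, run the pipeline, write the result files."""
    sheet = msio.read_sample_sheet(sample_sheet)
    peaks = msio.read_peak_table(peak_table, sheet)
    spectra = msio.read_ms2(ms2)
    pairs_map = msio.pair_ms1_ms2(
        peaks, spectra, mz_tol_ppm=config.mz_tol_ppm, rt_tol_s=config.pair_rt_tol_s
    )
    lib = msio.read_library(library)
    net = build_mrn(read_reaction_pairs(reaction_pairs), read_compounds(compounds))
    desc = (
        pd.read_csv(descriptors, index_col=0) if descriptors is not None else None
    )
    pdb = read_pathway_db(pathways) if pathways is not None else None

    result = run_core(peaks, sheet, pairs_map, lib, net, desc, pdb, config)
    write_result(result, out_dir, config, net)
    return result


def write_result(
    result: PipelineResult,
    out_dir: str | Path,
    config: RunConfig,
    net: ReactionPairNetwork | None = None,
) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = (
        {m: net.node(m).name for m in {a.metabolite_id for a in result.annotations} if m in net.compounds}
        if net is not None else None
    )
    msio.write_outputs(
        out_dir,
        result.annotations,
        enrichment=result.enrichment,
        quant_metabolite=result.quant_metabolite,
        quant_pathway=result.quant_pathway,
        score_cutoff=config.score_cutoff,
        top_k=config.top_k,
        names=names,
    )
    pd.DataFrame(
        [
            {
                "round": r.round,
                "n_seeds": r.n_seeds_in,
                "n_retrieved": r.n_neighbors_retrieved,
                "n_annotated": r.n_annotated,
                "n_new_seeds": r.n_new_seeds,
            }
            for r in result.round_logs
        ]
    ).to_csv(out_dir / "round_log.csv", index=False)
    with open(out_dir / "run.log", "a") as fh:
        fh.write(f"effective config: {config.to_dict()}\n")
        fh.write(
            f"redundancy: peak={result.redundancy.peak_redundancy:.3f} "
            f"metabolite={result.redundancy.metabolite_redundancy:.3f} "
            f"combined={result.redundancy.combined:.3f}\n"
        )


def run_on_fixture(fixture: Fixture, config: RunConfig | None = None) -> PipelineResult:
    """Run the analysis stages directly on an in-memory synthetic dataset."""
    config = config or RunConfig()
    pairs_map = msio.pair_ms1_ms2(
        fixture.peaks, fixture.ms2,
        mz_tol_ppm=config.mz_tol_ppm, rt_tol_s=config.pair_rt_tol_s,
    )
    return run_core(
        fixture.peaks, fixture.sheet, pairs_map, fixture.library,
        fixture.net, fixture.descriptors, fixture.pathways, config,
    )


def merge_polarities(results: list[PipelineResult]) -> set[str]:
    """Union of annotated metabolites across ionization modes.

    Positive- and negative-mode runs are merged by metabolite id only — the
    pathway stage then sees every metabolite annotated in either mode.
    """
    out: set[str] = set()
    for r in results:
        out.update(a.metabolite_id for a in r.mono_annotations)
    return out
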