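"""Dysregulated-pathway analysis.

* per-peak two-group univariate testing (Student's t or
  Mann-Whitney-Wilcoxon, optional Benjamini-Hochberg correction);
* hypergeometric enrichment of dysregulated metabolites in pathways;
* quantitative pathway expression from Pareto-scaled peak intensities;
* Pearson correlation networks for pathway-pathway and gene-metabolite
  integration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .confidence import PeakGroup
from .models import Annotation, MS1Peak, SampleSheet, ROLE_MONO

log = logging.getLogger(__name__)

__all__ = [
    "PathwayDB",
    "StatResult",
    "read_pathway_db",
    "dysregulated_peaks",
    "enrich_pathways",
    "pareto_scale",
    "quantify_pathways",
    "correlation_network",
]


@dataclass
class PathwayDB:
    """pathway id -> (name, metabolite members[, gene members])."""

    names: dict[str, str] = field(default_factory=dict)
    members: dict[str, set[str]] = field(default_factory=dict)
    gene_members: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self):
        for pid, mem in self.members.items():
            if not mem:
                raise ValueError(f"pathway {pid!r} has no members")

    def __iter__(self):
        return iter(self.members)


def read_pathway_db(path: str | Path) -> PathwayDB:
    """Read a pathway table: CSV ``pathway_id,name,members`` with members
    separated by ';'."""
    df = pd.read_csv(path)
    names, members = {}, {}
    for _, row in df.iterrows():
        pid = str(row["pathway_id"])
        names[pid] = str(row.get("name", pid))
        members[pid] = {m for m in str(row["members"]).split(";") if m}
    return PathwayDB(names=names, members=members)


@dataclass(frozen=True)
class StatResult:
    peak_id: str
    statistic: float
    p_value: float
    p_adjusted: float | None
    dysregulated: bool


def dysregulated_peaks(
    peaks: list[MS1Peak],
    sheet: SampleSheet,
    test: str = "t",
    adjust: str = "none",
    p_cutoff: float = 0.05,
    groups: tuple[str, str] | None = None,
) -> list[StatResult]:
    """Two-sided two-group test per peak; flag peaks below the cutoff.

    ``test`` is ``'t'`` (Welch is not used; classic two-sample t, matching
    the usual metabolomics default) or ``'wilcoxon'`` (Mann-Whitney U).
    ``adjust='BH'`` applies Benjamini-Hochberg and flags on the adjusted p.
    Peaks with zero variance in both groups get p = 1 with a warning.
    """
    if groups is None:
        gnames = sheet.group_names
        if len(gnames) != 2:
            raise ValueError(f"need exactly two groups, sample sheet has {gnames}")
        groups = (gnames[0], gnames[1])
    s1 = sheet.samples_in(groups[0])
    s2 = sheet.samples_in(groups[1])
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError("each group needs at least 2 samples")
    pvals, statv = [], []
    for p in peaks:
        x = np.array([p.intensities[s] for s in s1])
        y = np.array([p.intensities[s] for s in s2])
        if np.ptp(x) == 0 and np.ptp(y) == 0 and x[0] == y[0]:
            log.warning("peak %s has zero variance; p set to 1", p.peak_id)
            statv.append(0.0)
            pvals.append(1.0)
            continue
        if test == "t":
            t, pv = stats.ttest_ind(x, y, equal_var=True)
        elif test == "wilcoxon":
            t, pv = stats.mannwhitneyu(x, y, alternative="two-sided")
        else:
            raise ValueError(f"unknown test {test!r}")
        statv.append(float(t))
        pvals.append(float(pv) if np.isfinite(pv) else 1.0)
    if adjust == "BH":
        padj = multipletests(pvals, method="fdr_bh")[1]
    elif adjust == "none":
        padj = [None] * len(pvals)
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    results = []
    for p, t, pv, pa in zip(peaks, statv, pvals, padj):
        crit = pa if pa is not None else pv
        results.append(
            StatResult(
                peak_id=p.peak_id,
                statistic=t,
                p_value=pv,
                p_adjusted=None if pa is None else float(pa),
                dysregulated=bool(crit < p_cutoff),
            )
        )
    return results


def enrich_pathways(
    dysregulated: set[str],
    universe: set[str],
    db: PathwayDB,
    p_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment per pathway.

    For a pathway with ``K`` members in the universe and ``k`` of the ``n``
    dysregulated metabolites, p = P[X >= k] with X hypergeometric(N, K, n).
    Pathways with no universe members are skipped.
    """
    if not dysregulated <= universe:
        raise ValueError("dysregulated set must be a subset of the universe")
    N = len(universe)
    n = len(dysregulated)
    rows = []
    for pid in db:
        K_set = db.members[pid] & universe
        K = len(K_set)
        if K == 0:
            continue
        k = len(K_set & dysregulated)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({
            "pathway_id": pid,
            "name": db.names.get(pid, pid),
            "overlap": k,
            "pathway_size": K,
            "p_value": p,
            "significant": p < p_cutoff,
        })
    df = pd.DataFrame(rows, columns=["pathway_id", "name", "overlap", "pathway_size", "p_value", "significant"])
    return df.sort_values("p_value").reset_index(drop=True) if len(df) else df


def pareto_scale(mat: pd.DataFrame) -> pd.DataFrame:
    """Pareto scaling per row: (x - mean) / sqrt(sd), sample sd (ddof=1).

    Rows with zero variance scale to all zeros.
    """
    mu = mat.mean(axis=1)
    sd = mat.std(axis=1, ddof=1)
    scaled = mat.sub(mu, axis=0)
    nz = sd > 0
    scaled.loc[nz] = scaled.loc[nz].div(np.sqrt(sd[nz]), axis=0)
    scaled.loc[~nz] = 0.0
    return scaled


def quantify_pathways(
    annotations: list[Annotation],
    groups: list[PeakGroup],
    peaks: list[MS1Peak],
    db: PathwayDB,
    pathway_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample metabolite and pathway expression matrices.

    All peak intensities are Pareto-scaled.  A peak group is represented by
    its most abundant member peak; a metabolite matched to several groups
    by the group whose representative annotation has the highest score.
    A pathway's expression is the mean over its quantified members; pathways
    with no quantified member are absent from the matrix.
    """
    peak_by_id = {p.peak_id: p for p in peaks}
    samples = list(next(iter(peak_by_id.values())).intensities) if peak_by_id else []
    raw = pd.DataFrame(
        {p.peak_id: [p.intensities[s] for s in samples] for p in peaks},
        index=samples,
    ).T
    scaled = pareto_scale(raw)

    met_rows: dict[str, tuple[float, str]] = {}  # metabolite -> (best score, peak)
    for g in groups:
        mono = [a for a in g.annotations if a.role == ROLE_MONO]
        if not mono:
            continue
        rep_peak = max(
            (a.peak_id for a in g.annotations),
            key=lambda pid: peak_by_id[pid].abundance,
        )
        score = max(a.total_score for a in mono)
        for a in mono:
            prev = met_rows.get(a.metabolite_id)
            if prev is None or score > prev[0]:
                met_rows[a.metabolite_id] = (score, rep_peak)

    met_mat = pd.DataFrame(
        {m: scaled.loc[pid] for m, (_, pid) in sorted(met_rows.items())}
    ).T
    met_mat.index.name = "metabolite_id"

    path_ids = pathway_ids if pathway_ids is not None else list(db)
    prows = {}
    for pid in path_ids:
        members = [m for m in db.members.get(pid, ()) if m in met_mat.index]
        if not members:
            continue
        prows[pid] = met_mat.loc[members].mean(axis=0)
    path_mat = pd.DataFrame(prows).T
    path_mat.index.name = "pathway_id"
    return met_mat, path_mat


def correlation_network(
    mat_a: pd.DataFrame,
    mat_b: pd.DataFrame | None = None,
    p_cutoff: float = 0.05,
    r_cutoff: float = 0.0,
) -> pd.DataFrame:
    """Pairwise Pearson correlation edges between matrix rows.

    Matrices must share sample columns.  With one matrix, all within-matrix
    pairs are tested; with two, all cross pairs (e.g. gene x metabolite,
    where the conventional thresholds are p < 0.01 and |r| > 0.7).
    Constant rows are skipped with a warning.
    """
    if mat_b is not None and list(mat_a.columns) != list(mat_b.columns):
        raise ValueError("matrices must share sample columns")
    rows = []

    def _pairs():
        if mat_b is None:
            idx = list(mat_a.index)
            for i, a in enumerate(idx):
                for b in idx[i + 1:]:
                    yield a, mat_a.loc[a], b, mat_a.loc[b]
        else:
            for a in mat_a.index:
                for b in mat_b.index:
                    yield a, mat_a.loc[a], b, mat_b.loc[b]

    for name_a, va, name_b, vb in _pairs():
        x = np.asarray(va, dtype=float)
        y = np.asarray(vb, dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            log.warning("constant row in correlation network (%s, %s); skipped", name_a, name_b)
            continue
        r, p = stats.pearsonr(x, y)
        if p < p_cutoff and abs(r) > r_cutoff:
            rows.append({"source": name_a, "target": name_b, "r": float(r), "p_value": float(p)})
    return pd.DataFrame(rows, columns=["source", "target", "r", "p_value"])
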