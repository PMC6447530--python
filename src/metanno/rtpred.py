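"""QSRR retention-time prediction.

Retention under a given LC method is largely determined by molecular
structure, summarized by numeric molecular descriptors (MDs).  The module
fits a random-forest regression of experimental RT on descriptors for the
library-identified metabolites and predicts RT for every network
metabolite, in five steps:

1. descriptors arrive as a numeric table (computed externally from SMILES
   by any descriptor engine — this module does no chemistry);
2. the training set is the library-matched metabolites after uniqueness
   rules (best dot product per peak, most intense peak per metabolite,
   reliable adducts only), and the descriptor matrix is cleaned: columns
   with >50% missing dropped, the rest KNN-imputed, constant columns
   dropped;
3. descriptor selection: 100 forests on random 68% splits, recording the
   top-5 important descriptors of each; descriptors appearing >50 times
   are kept;
4. (ntree, mtry) tuned by out-of-bag MSE on a small grid, best refit on all
   training data;
5. prediction for every metabolite with descriptors.

Everything is deterministic under the supplied seed.

Fallback descriptor lists (used when selection comes back empty, e.g. with
a tiny training set) mirror the published combinations for HILIC and
reversed-phase methods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.impute import KNNImputer

from .models import Annotation, MS1Peak, ROLE_MONO

log = logging.getLogger(__name__)

__all__ = [
    "RtModel",
    "FALLBACK_DESCRIPTORS",
    "build_training_set",
    "clean_descriptors",
    "select_descriptors",
    "tune_and_fit",
    "predict_rt",
    "train_rt_model",
]

RELIABLE_TRAINING_ADDUCTS = {
    "[M+H]+", "[M+Na]+", "[M+NH4]+",
    "[M-H]-", "[M+CH3COO]-", "[M+Cl]-",
}

FALLBACK_DESCRIPTORS = {
    "HILIC": ["XLogP", "tpsaEfficiency", "WTPT.5", "khs.dsCH", "MLogP", "nAcid", "nBase", "BCUTp.1l"],
    "RP": ["XLogP", "WTPT.5", "WTPT.4", "ALogp2", "BCUTp.1l"],
}

MIN_TRAINING_SIZE = 20


@dataclass
class RtModel:
    """A fitted QSRR model."""

    selected_descriptors: list[str]
    forest: RandomForestRegressor
    ntree: int
    mtry: int
    training_mse: float
    training_rt_range: tuple[float, float]
    n_training: int = 0
    oob_r2: float = 0.0
    column_medians: pd.Series = field(default=None, repr=False)

    @property
    def usable(self) -> bool:
        """Whether predictions carry any signal (out-of-bag R² > 0).

        A forest whose out-of-bag error exceeds the training RT variance
        predicts worse than the mean; vetoing annotations with it would be
        unjustified, so such a model is flagged unusable and downstream RT
        filtering is skipped.
        """
        return self.oob_r2 > 0.0

    @property
    def recommended_rt_tol_frac(self) -> float | None:
        """±50% instead of the usual ±30% when trained on < 20 metabolites.

        A small training set gives coarse predictions; widening the RT
        filter keeps the engine usable with small spectral libraries at the
        cost of specificity.  ``None`` means: use the configured default.
        """
        return 0.50 if self.n_training < MIN_TRAINING_SIZE else None


def build_training_set(
    round0_annotations: list[Annotation],
    peaks: list[MS1Peak],
) -> pd.DataFrame:
    """Reduce library annotations to one (metabolite, RT) row each.

    Uniqueness rules, in order: a peak with several annotations keeps the
    highest dot product; a metabolite on several peaks keeps the most
    intense peak; only reliable adducts qualify for training.
    """
    peak_by_id = {p.peak_id: p for p in peaks}
    anns = [
        a for a in round0_annotations
        if a.round == 0 and a.role == ROLE_MONO and a.adduct in RELIABLE_TRAINING_ADDUCTS
    ]
    best_per_peak: dict[str, Annotation] = {}
    for a in anns:
        prev = best_per_peak.get(a.peak_id)
        if prev is None or a.score_spec > prev.score_spec:
            best_per_peak[a.peak_id] = a
    best_per_met: dict[str, Annotation] = {}
    for a in best_per_peak.values():
        prev = best_per_met.get(a.metabolite_id)
        if prev is None or peak_by_id[a.peak_id].abundance > peak_by_id[prev.peak_id].abundance:
            best_per_met[a.metabolite_id] = a
    rows = [
        {"metabolite_id": a.metabolite_id, "rt": peak_by_id[a.peak_id].rt}
        for a in best_per_met.values()
    ]
    df = pd.DataFrame(rows, columns=["metabolite_id", "rt"])
    if len(df) < MIN_TRAINING_SIZE:
        log.warning(
            "RT training set has only %d metabolites (< %d); predictions will be "
            "coarse — downstream RT filtering should be widened",
            len(df), MIN_TRAINING_SIZE,
        )
    return df.sort_values("metabolite_id").reset_index(drop=True)


def clean_descriptors(mat: pd.DataFrame, knn_k: int = 10) -> pd.DataFrame:
    """Descriptor-matrix hygiene: drop sparse and constant columns, impute.

    Columns with more than 50% missing values are removed; remaining gaps
    are filled by k-nearest-neighbor imputation (Euclidean over
    standardized columns); columns constant across all rows are removed.
    """
    if mat.empty:
        raise ValueError("descriptor matrix is empty")
    mat = mat.loc[:, mat.isna().mean() <= 0.5]
    if mat.shape[1] == 0:
        raise ValueError("all descriptor columns exceeded the 50% missing-value limit")
    if mat.isna().any().any():
        mu = mat.mean()
        sd = mat.std(ddof=0).replace(0.0, 1.0)
        z = (mat - mu) / sd
        imputer = KNNImputer(n_neighbors=min(knn_k, max(1, len(mat) - 1)))
        z_imp = pd.DataFrame(imputer.fit_transform(z), index=mat.index, columns=mat.columns)
        mat = z_imp * sd + mu
    nunique = mat.nunique()
    mat = mat.loc[:, nunique > 1]
    if mat.shape[1] == 0:
        raise ValueError("no informative descriptor columns left after cleaning")
    return mat


def select_descriptors(
    mat: pd.DataFrame,
    rts: pd.Series,
    n_repeats: int = 100,
    top_per_repeat: int = 5,
    min_count: int = 50,
    split_frac: float = 0.68,
    seed: int = 0,
    lc: str = "HILIC",
    ntree: int = 100,
) -> list[str]:
    """Stability selection of descriptors by repeated forest importance.

    ``n_repeats`` forests are fit on random ``split_frac`` subsets (without
    replacement); each records its ``top_per_repeat`` descriptors by
    impurity importance, and descriptors recorded more than ``min_count``
    times are selected.  An empty selection falls back to the published
    descriptor combination for the configured LC mode (intersected with the
    available columns).
    """
    if mat.shape[1] < 2:
        raise ValueError("need at least 2 descriptors for selection")
    if len(mat) < 10:
        raise ValueError("need at least 10 training metabolites for selection")
    rng = np.random.default_rng(seed)
    counts: dict[str, int] = {c: 0 for c in mat.columns}
    X = mat.to_numpy()
    y = np.asarray(rts, dtype=float)
    n = len(mat)
    n_sub = max(2, int(round(split_frac * n)))
    for _ in range(n_repeats):
        idx = rng.choice(n, size=n_sub, replace=False)
        rf = RandomForestRegressor(
            n_estimators=ntree,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        rf.fit(X[idx], y[idx])
        top = np.argsort(rf.feature_importances_)[::-1][:top_per_repeat]
        for j in top:
            counts[mat.columns[j]] += 1
    selected = [c for c in mat.columns if counts[c] > min_count]
    if not selected:
        fallback = [c for c in FALLBACK_DESCRIPTORS.get(lc, []) if c in mat.columns]
        log.warning(
            "descriptor selection came back empty; falling back to the %s list (%d present)",
            lc, len(fallback),
        )
        selected = fallback if fallback else list(mat.columns)
    return selected


def tune_and_fit(
    mat_selected: pd.DataFrame,
    rts: pd.Series,
    grid: list[tuple[int, int]] | None = None,
    seed: int = 0,
) -> RtModel:
    """Grid-search (ntree, mtry) by out-of-bag MSE and refit the best.

    The default grid crosses ntree in {300, 500, 800, 1000} with mtry in
    {p/3, sqrt(p), p/2}.  A degenerate (single-point) grid skips the search.
    """
    p = mat_selected.shape[1]
    if grid is None:
        mtries = sorted({max(1, p // 3), max(1, int(round(np.sqrt(p)))), max(1, p // 2)})
        grid = [(nt, mt) for nt in (300, 500, 800, 1000) for mt in mtries]
    X = mat_selected.to_numpy()
    y = np.asarray(rts, dtype=float)
    best: tuple[float, int, int] | None = None
    for ntree, mtry in grid:
        rf = RandomForestRegressor(
            n_estimators=ntree, max_features=mtry, oob_score=True,
            bootstrap=True, random_state=seed, n_jobs=1,
        )
        rf.fit(X, y)
        mse = float(np.mean((rf.oob_prediction_ - y) ** 2))
        if best is None or mse < best[0]:
            best = (mse, ntree, mtry)
    mse, ntree, mtry = best
    forest = RandomForestRegressor(
        n_estimators=ntree, max_features=mtry, random_state=seed, n_jobs=1
    )
    forest.fit(X, y)
    return RtModel(
        selected_descriptors=list(mat_selected.columns),
        forest=forest,
        ntree=ntree,
        mtry=mtry,
        training_mse=mse,
        training_rt_range=(float(y.min()), float(y.max())),
        n_training=len(y),
        oob_r2=float(1.0 - mse / np.var(y)) if np.var(y) > 0 else 0.0,
        column_medians=mat_selected.median(),
    )


def predict_rt(model: RtModel, descriptors: pd.DataFrame) -> dict[str, float]:
    """Predict RT (seconds) for every row with descriptor data.

    Missing values in prediction rows are filled with the training-column
    medians; rows missing entire selected columns (no structure, no
    descriptors) are dropped and logged.
    """
    cols = model.selected_descriptors
    missing_cols = [c for c in cols if c not in descriptors.columns]
    if missing_cols:
        raise ValueError(f"descriptor table lacks selected columns {missing_cols}")
    sub = descriptors[cols].copy()
    all_missing = sub.isna().all(axis=1)
    if all_missing.any():
        log.info("%d metabolites have no descriptor values; RT not predicted", int(all_missing.sum()))
    sub = sub.loc[~all_missing]
    sub = sub.fillna(model.column_medians)
    preds = model.forest.predict(sub.to_numpy())
    preds = np.maximum(preds, 1e-6)  # RT is physically positive
    return {str(i): float(v) for i, v in zip(sub.index, preds)}


def train_rt_model(
    round0_annotations: list[Annotation],
    peaks: list[MS1Peak],
    descriptors: pd.DataFrame,
    seed: int = 0,
    lc: str = "HILIC",
    n_repeats: int = 100,
    selection_ntree: int = 100,
    grid: list[tuple[int, int]] | None = None,
) -> tuple[RtModel, dict[str, float]]:
    """Convenience wrapper: steps 2-5 end to end.

    Returns the fitted model and the RT predictions for every metabolite in
    the descriptor table.
    """
    train = build_training_set(round0_annotations, peaks)
    train = train[train["metabolite_id"].isin(descriptors.index)]
    if len(train) < 10:
        raise ValueError(
            f"only {len(train)} training metabolites with descriptors; cannot fit an RT model"
        )
    mat = clean_descriptors(descriptors.loc[train["metabolite_id"]])
    rts = pd.Series(train["rt"].to_numpy(), index=train["metabolite_id"])
    if len(train) < MIN_TRAINING_SIZE:
        # stability selection cannot resolve importance from ~7-point fits;
        # in the degraded small-library mode the forest keeps every cleaned
        # descriptor and relies on its own split selection
        log.warning(
            "training set too small (%d) for descriptor selection; using all %d descriptors",
            len(train), mat.shape[1],
        )
        selected = list(mat.columns)
    else:
        selected = select_descriptors(
            mat, rts, seed=seed, lc=lc, n_repeats=n_repeats, ntree=selection_ntree
        )
    model = tune_and_fit(mat[selected], rts, grid=grid, seed=seed)
    predictions = predict_rt(model, descriptors)
    return model, predictions
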