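"""Motif-window feature matrices and gradient-boosted site classification.

Around each anchor site three transcript-strand windows are defined:
'at' = [-10, +10], 'up' = [-60, -11] (5', negative offsets) and
'down' = [+11, +60], i.e. a 21-nt core with adjacent 50-nt flanks.  A
motif match counts in a window if it overlaps it at any point; counts are
truncated at 10 and standardized with statistics fitted on training rows
only.  One fifth of the rows is held out, stratified by label.

The classifier is a gradient-boosted tree ensemble (LightGBM) with the
conventional gbm-style settings (learning rate/shrinkage 0.05, interaction
depth 6, up to 2000 trees) where 5-fold cross-validation on the training
rows selects the tree count minimizing CV deviance.  Gain-based feature
importances are normalized to sum to 100; AUC on the held-out rows is
computed by the Mann-Whitney rank statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import lightgbm as lgb
import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.preprocessing import StandardScaler

from .genome import GenomeBundle

logger = logging.getLogger("tribeclip")

#: Transcript-strand windows: inclusive offset ranges relative to the anchor.
WINDOWS = {"up": (-60, -11), "at": (-10, 10), "down": (11, 60)}
COUNT_CAP = 10
HELD_OUT_FRACTION = 0.2


@dataclass
class GbmSettings:
    learning_rate: float = 0.05
    max_depth: int = 6
    n_trees: int = 2000
    cv_folds: int = 5
    seed: int = 0


@dataclass
class FeatureMatrix:
    """Sites x (motif x window) features with labels and a train/test split."""

    features: pd.DataFrame  # raw truncated counts
    labels: np.ndarray
    held_out: np.ndarray  # bool mask
    scaler: StandardScaler | None = None

    def split(self):
        return (
            self.features[~self.held_out],
            self.labels[~self.held_out],
            self.features[self.held_out],
            self.labels[self.held_out],
        )

    def normalized(self) -> tuple[np.ndarray, np.ndarray]:
        """Standardize using training-row statistics only (no leakage)."""
        xtr, _, xte, _ = self.split()
        self.scaler = StandardScaler().fit(xtr)
        return self.scaler.transform(xtr), self.scaler.transform(xte)


def deduplicate_anchors(anchors: pd.DataFrame, window: int = 120) -> pd.DataFrame:
    """Greedy redundancy reduction: keep the highest-scoring site, drop
    others within ``window`` nt on the same chromosome and strand."""
    keep_rows = []
    for _, grp in anchors.groupby(["chrom", "strand"]):
        grp = grp.sort_values("score", ascending=False)
        taken: list[int] = []
        for _, row in grp.iterrows():
            if all(abs(row["pos0"] - t) > window for t in taken):
                taken.append(row["pos0"])
                keep_rows.append(row)
    return pd.DataFrame(keep_rows).reset_index(drop=True)


def _window_counts(
    anchors: pd.DataFrame, matches: pd.DataFrame, motif_names
) -> pd.DataFrame:
    """Truncated per-(motif, window) match counts for each anchor."""
    cols = [f"{m}_{w}" for m in motif_names for w in WINDOWS]
    out = np.zeros((len(anchors), len(cols)), dtype=int)
    col_index = {c: i for i, c in enumerate(cols)}
    by_key: dict[tuple, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for (chrom, strand, motif), grp in matches.groupby(
        ["chrom", "strand", "motif"]
    ):
        order = np.argsort(grp["start"].to_numpy())
        by_key.setdefault((chrom, strand), {})[motif] = (
            grp["start"].to_numpy()[order],
            grp["end"].to_numpy()[order],
        )
    anchors = anchors.reset_index(drop=True)
    for i, (chrom, pos, strand) in enumerate(
        zip(anchors["chrom"], anchors["pos0"], anchors["strand"])
    ):
        sign = 1 if strand == "+" else -1
        per_chrom = by_key.get((chrom, strand), {})
        for motif, (starts, ends) in per_chrom.items():
            if motif not in motif_names:
                continue
            # signed transcript-strand offset span of each match
            if sign == 1:
                lo, hi = starts - pos, ends - 1 - pos
            else:
                lo, hi = pos - (ends - 1), pos - starts
            for w, (wlo, whi) in WINDOWS.items():
                n = int(np.count_nonzero((hi >= wlo) & (lo <= whi)))
                out[i, col_index[f"{motif}_{w}"]] = min(n, COUNT_CAP)
    return pd.DataFrame(out, columns=cols)


def build_features(
    anchors: pd.DataFrame,
    negatives: pd.DataFrame,
    matches: pd.DataFrame,
    motif_names,
    bundle: GenomeBundle | None = None,
    seed: int = 0,
    dedup_window: int = 120,
) -> FeatureMatrix:
    """Feature matrix of positives (anchors) vs negatives.

    Anchors are deduplicated within ``dedup_window`` nt first; rows whose
    full window falls off a contig are dropped with a log message.  The
    held-out fifth is selected stratified by label.
    """
    motif_names = list(motif_names)
    anchors = deduplicate_anchors(anchors, dedup_window)
    parts, labels = [], []
    for df, label in ((anchors, 1), (negatives, 0)):
        df = df.reset_index(drop=True)
        if bundle is not None:
            lo = df["pos0"] + WINDOWS["up"][0]
            hi = df["pos0"] + WINDOWS["down"][1]
            limit = df["chrom"].map(
                {c: bundle.contig_length(c) for c in bundle.seqs}
            )
            ok = (lo >= 0) & (hi < limit)
            if (~ok).any():
                logger.info(
                    "build_features: dropped %d label-%d rows at contig edges",
                    (~ok).sum(), label,
                )
            df = df[ok].reset_index(drop=True)
        parts.append(_window_counts(df, matches, motif_names))
        labels.append(np.full(len(df), label))
    features = pd.concat(parts, ignore_index=True)
    y = np.concatenate(labels)
    idx = np.arange(len(y))
    held_out = np.zeros(len(y), dtype=bool)
    counts = np.bincount(y, minlength=2)
    if counts.min() >= 2 and len(y) * HELD_OUT_FRACTION >= 2:
        _, test_idx = train_test_split(
            idx, test_size=HELD_OUT_FRACTION, stratify=y, random_state=seed
        )
        held_out[test_idx] = True
    else:
        logger.info("build_features: too few rows for a stratified held-out "
                    "split; all rows marked training")
    return FeatureMatrix(features=features, labels=y, held_out=held_out)


@dataclass
class FittedModel:
    model: "lgb.Booster"
    importances: pd.Series  # normalized to sum 100
    best_n_trees: int
    cv_curve: np.ndarray = field(repr=False, default=None)
    feature_names: list[str] = field(default_factory=list)

    def predict_scores(self, x: np.ndarray) -> np.ndarray:
        return self.model.predict(x, num_iteration=self.best_n_trees)


def _lgb_params(settings: GbmSettings) -> dict:
    return {
        "objective": "binary",
        "learning_rate": settings.learning_rate,
        "max_depth": settings.max_depth,
        "num_leaves": 2**settings.max_depth,
        "seed": settings.seed,
        "deterministic": True,
        "force_row_wise": True,
        "verbosity": -1,
    }


def train_gbm(fm: FeatureMatrix, settings: GbmSettings = GbmSettings()) -> FittedModel:
    """Fit the gradient-boosted classifier with CV-selected tree count.

    Five-fold cross-validation on the training rows tracks held-fold
    binomial deviance at every boosting stage; the final model is refit on
    all training rows with the deviance-minimizing tree count (capped at
    ``settings.n_trees``).
    """
    _, ytr, _, _ = fm.split()
    if len(np.unique(ytr)) < 2:
        raise ValueError("training rows must contain both classes")
    xtr, _ = fm.normalized()

    params = _lgb_params(settings)
    skf = StratifiedKFold(
        n_splits=settings.cv_folds, shuffle=True, random_state=settings.seed
    )
    train_set = lgb.Dataset(xtr, label=ytr)
    cv = lgb.cv(
        params,
        train_set,
        num_boost_round=settings.n_trees,
        folds=skf.split(xtr, ytr),
        callbacks=[lgb.early_stopping(stopping_rounds=100, verbose=False)],
    )
    cv_dev = np.asarray(cv["valid binary_logloss-mean"])
    best_n = int(np.argmin(cv_dev) + 1)
    final = lgb.train(
        params, lgb.Dataset(xtr, label=ytr), num_boost_round=best_n
    )
    imp = final.feature_importance(importance_type="gain").astype(float)
    imp = 100 * imp / imp.sum() if imp.sum() > 0 else imp
    names = list(fm.features.columns)
    logger.info("train_gbm: CV selected %d trees", best_n)
    return FittedModel(
        model=final,
        importances=pd.Series(imp, index=names).sort_values(ascending=False),
        best_n_trees=best_n,
        cv_curve=cv_dev,
        feature_names=names,
    )


def auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by the Mann-Whitney rank statistic (ties share ranks)."""
    from scipy.stats import rankdata

    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("held-out rows must contain both classes")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def evaluate_auc(fitted: FittedModel, fm: FeatureMatrix):
    """AUC and ROC table on the held-out rows."""
    _, _, xte_df, yte = fm.split()
    xte = fm.scaler.transform(xte_df[fitted.feature_names])
    scores = fitted.predict_scores(xte)
    auc = auc_rank(scores, yte)
    fpr, tpr, thr = roc_curve(yte, scores)
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return auc, roc


def reduced_model(
    fm: FeatureMatrix,
    fitted: FittedModel,
    k: int = 10,
    settings: GbmSettings = GbmSettings(),
):
    """Refit on the top-k importance features; AUC on the same held-out rows."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(fitted.feature_names):
        raise ValueError("k exceeds the number of features")
    top = list(fitted.importances.index[:k])
    sub = FeatureMatrix(
        features=fm.features[top], labels=fm.labels, held_out=fm.held_out
    )
    refit = train_gbm(sub, settings)
    auc, roc = evaluate_auc(refit, sub)
    return refit, auc, roc


def contrast_bound_vs_unbound(
    m6a_sites: pd.DataFrame,
    crosslinks: pd.DataFrame,
    matches: pd.DataFrame,
    motif_names,
    bundle: GenomeBundle | None = None,
    near_dist: int = 10,
    seed: int = 0,
) -> FeatureMatrix:
    """Features contrasting reader-bound vs unbound methylation sites.

    Positives are m6A sites with a crosslink site within ``near_dist`` nt
    (unsigned, same chromosome and strand); negatives have none.
    """
    from .clip import _nearest_distance

    m6a_sites = m6a_sites.reset_index(drop=True)
    dist = _nearest_distance(m6a_sites, crosslinks)
    pos = m6a_sites[dist <= near_dist]
    neg = m6a_sites[dist > near_dist]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both bound and unbound classes must be non-empty")
    return build_features(pos, neg, matches, motif_names, bundle, seed=seed)


def model_card(fitted: FittedModel, settings: GbmSettings, auc: float) -> dict:
    return {
        "settings": {
            "learning_rate": settings.learning_rate,
            "max_depth": settings.max_depth,
            "n_trees_max": settings.n_trees,
            "cv_folds": settings.cv_folds,
            "seed": settings.seed,
        },
        "best_n_trees": fitted.best_n_trees,
        "auc": auc,
        "importances": fitted.importances.round(4).to_dict(),
    }
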