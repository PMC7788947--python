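"""WRFEN gene selection: weighted fusion of random-forest and elastic-net rankings.

Two regressors rank the candidate genes independently — a bagged
regression-tree ensemble scored by impurity-reduction importance and an
elastic net scored by |coefficient| on standardised predictors.  Each
method's validation-set Pearson correlation becomes its fusion weight
through ``exp(Pearson)``; for each gene the fused score is the weighted
mean of its two ranks,

    fused(g) = ( e^rRF * rank_RF(g) + e^rEN * rank_EN(g) ) / ( e^rRF + e^rEN )

and genes are selected in ascending fused-score order.  A gene retained by
only one method takes the other method's worst-plus-one rank.  The number
of genes to keep defaults to the same exponential-weighted average applied
to the two methods' retained counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import train_test_split

logger = logging.getLogger(__name__)

DEFAULT_N_TREES = 40
DEFAULT_L1_RATIOS = (0.1, 0.2, 0.5, 0.7, 0.95, 1.0)
DEFAULT_PENALTIES = tuple(round(0.1 * i, 1) for i in range(1, 11))


@dataclass
class GeneRanking:
    """One method's importance ordering over its contributing genes."""

    method: str  # "RF" | "EN"
    genes: list  # rank 1 first
    importance: np.ndarray  # aligned with genes, non-increasing
    validation_pearson: float
    params: dict | None = None

    @property
    def retained_count(self) -> int:
        return len(self.genes)

    def rank_of(self) -> dict:
        return {g: r for r, g in enumerate(self.genes, start=1)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.genes,
                "rank": np.arange(1, len(self.genes) + 1),
                "score": self.importance,
                "method": self.method,
                "validation_pearson": self.validation_pearson,
            }
        )


@dataclass
class FusedRanking:
    """Result of the exponential-weighted rank fusion."""

    genes: list  # ascending fused score
    fused_score: np.ndarray
    selected_count: int
    rf_pearson: float
    en_pearson: float

    def __len__(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": self.genes, "fused_score": self.fused_score,
             "rank": np.arange(1, len(self.genes) + 1)}
        )


def _split(X: pd.DataFrame, y: pd.Series, seed: int, val_fraction: float):
    return train_test_split(X, y, test_size=val_fraction, random_state=seed)


def _pearson(a, b) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(pearsonr(a, b)[0])


def _ordered(genes: np.ndarray, importance: np.ndarray) -> tuple[list, np.ndarray]:
    # descending importance, ties broken by gene id for reproducibility
    order = sorted(range(len(genes)), key=lambda i: (-importance[i], genes[i]))
    return [genes[i] for i in order], importance[order]


def rf_rank(ds, n_trees: int = DEFAULT_N_TREES, seed: int = 0, val_fraction: float = 0.2) -> GeneRanking:
    """Rank genes by random-forest impurity importance.

    Fits a bagged regression-tree ensemble (``n_trees`` trees, per-node
    gene subsampling of ceil(M/3) genes) on a seeded training split,
    records the Pearson correlation of observed vs predicted viability on
    the held-out validation split, and drops genes with zero importance.
    """
    # canonical column order, so results do not depend on table layout
    X, y = ds.X[sorted(ds.genes)], ds.y
    if y.nunique() <= 1:
        raise ValueError("constant viability target: validation Pearson is undefined")
    Xtr, Xval, ytr, yval = _split(X, y, seed, val_fraction)
    m = X.shape[1]
    rf = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=max(1, math.ceil(m / 3)),
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(Xtr, ytr)
    r = _pearson(yval, rf.predict(Xval))
    if not np.isfinite(r):
        raise ValueError("random-forest validation Pearson is undefined (constant predictions)")
    imp = rf.feature_importances_
    keep = imp > 0
    genes, importance = _ordered(np.asarray(X.columns)[keep], imp[keep])
    logger.info("RF ranking: %d/%d genes contribute, validation Pearson %.4f", len(genes), m, r)
    return GeneRanking(method="RF", genes=genes, importance=importance, validation_pearson=r,
                       params={"n_trees": n_trees})


def en_rank(
    ds,
    l1_ratios=DEFAULT_L1_RATIOS,
    penalties=DEFAULT_PENALTIES,
    seed: int = 0,
    val_fraction: float = 0.2,
    max_iter: int = 5000,
) -> GeneRanking:
    """Rank genes by elastic-net |coefficient| on standardised predictors.

    Grid-searches (l1_ratio, penalty) and keeps the pair maximising
    validation Pearson; zero-coefficient genes are removed.  Penalties are
    visited in descending order with warm starts so the grid stays cheap.
    """
    X, y = ds.X[sorted(ds.genes)], ds.y
    if y.nunique() <= 1:
        raise ValueError("constant viability target: validation Pearson is undefined")
    Xtr, Xval, ytr, yval = _split(X, y, seed, val_fraction)
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0).replace(0.0, 1.0)
    Ztr = ((Xtr - mu) / sd).to_numpy()
    Zval = ((Xval - mu) / sd).to_numpy()
    ytr_np = ytr.to_numpy(float)

    best = None  # (pearson, l1_ratio, penalty, coef)
    for lr in l1_ratios:
        model = ElasticNet(l1_ratio=lr, warm_start=True, max_iter=max_iter, tol=1e-4)
        for pen in sorted(penalties, reverse=True):
            model.alpha = pen
            model.fit(Ztr, ytr_np)
            if not np.any(model.coef_):
                continue
            r = _pearson(yval, model.predict(Zval))
            if not np.isfinite(r):
                continue
            if best is None or r > best[0]:
                best = (r, lr, pen, model.coef_.copy())
    if best is None:
        raise ValueError("empty elastic-net support at every grid point")
    r, lr, pen, coef = best
    imp = np.abs(coef)
    keep = imp > 0
    genes, importance = _ordered(np.asarray(X.columns)[keep], imp[keep])
    logger.info(
        "EN ranking: %d genes retained at l1_ratio=%s penalty=%s, validation Pearson %.4f",
        len(genes), lr, pen, r,
    )
    return GeneRanking(method="EN", genes=genes, importance=importance, validation_pearson=r,
                       params={"l1_ratio": lr, "penalty": pen})


def fuse_rankings(rf: GeneRanking, en: GeneRanking) -> FusedRanking:
    """Fuse the two rankings by the exponential-Pearson weighted mean."""
    if not rf.genes or not en.genes:
        raise ValueError("both rankings must be nonempty")
    w_rf = math.exp(rf.validation_pearson)
    w_en = math.exp(en.validation_pearson)
    rank_rf = rf.rank_of()
    rank_en = en.rank_of()
    union = sorted(set(rf.genes) | set(en.genes))
    worst_rf = rf.retained_count + 1
    worst_en = en.retained_count + 1
    scores = {}
    for g in union:
        r1 = rank_rf.get(g)
        r2 = rank_en.get(g)
        if r1 is None:
            r1 = worst_rf
            logger.debug("gene %s absent from RF ranking: penalty rank %d", g, r1)
        if r2 is None:
            r2 = worst_en
            logger.debug("gene %s absent from EN ranking: penalty rank %d", g, r2)
        scores[g] = (w_rf * r1 + w_en * r2) / (w_rf + w_en)
    ordered = sorted(union, key=lambda g: (scores[g], g))
    selected = int(round((w_rf * rf.retained_count + w_en * en.retained_count) / (w_rf + w_en)))
    return FusedRanking(
        genes=ordered,
        fused_score=np.array([scores[g] for g in ordered]),
        selected_count=min(max(selected, 1), len(ordered)),
        rf_pearson=rf.validation_pearson,
        en_pearson=en.validation_pearson,
    )


def select_genes(fused: FusedRanking, k="auto") -> list:
    """Top-k genes of the fused ranking; ``"auto"`` uses the fused count."""
    if k == "auto":
        k = fused.selected_count
    if not 1 <= k <= len(fused):
        raise ValueError(f"k={k} out of range 1..{len(fused)}")
    return fused.genes[:k]
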