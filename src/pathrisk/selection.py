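"""Cross-validated choice of the feature-score threshold.

The training set is repeatedly split into three event-stratified folds.
For every candidate threshold, the full pipeline (standardization ->
feature building -> Cox scoring -> selection -> weighted first-PC fit)
is refit on each 2/3 and the held-out 1/3 is scored by the Cox
partial-likelihood ratio of its predicted risk. The threshold with the
best performance averaged over folds and repeats wins; ties go to the
larger threshold (fewer features). Nothing about a held-out fold —
means, SDs, scores, loadings — is computed from its samples before
prediction.

The candidate grid is scale-free: evenly spaced quantiles of the
full-training |score| distribution between the 50th and 99th
percentiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSetCollection, SurvivalData, ValidationError
from .summarize import build_feature_matrix
from .scoring import score_all
from .predict import feature_weights, weighted_first_pc
from ._cox import fit_univariate_cox

logger = logging.getLogger(__name__)

__all__ = ["ThresholdSearchResult", "select_features", "cv_select_threshold", "threshold_grid"]


@dataclass
class ThresholdSearchResult:
    thresholds: np.ndarray
    mean_performance: np.ndarray  # per threshold, averaged over repeats x folds
    performance: np.ndarray  # (n_thresholds, n_repeats, n_folds); NaN = not evaluable
    chosen_threshold: float
    seed: int | None
    n_folds: int
    n_repeats: int
    fold_details: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "thresholds": self.thresholds.tolist(),
            "mean_performance": self.mean_performance.tolist(),
            "chosen_threshold": float(self.chosen_threshold),
            "seed": self.seed,
            "n_folds": self.n_folds,
            "n_repeats": self.n_repeats,
        }


def select_features(scores: pd.Series, threshold: float) -> list[str]:
    """Feature IDs with |score| strictly above the threshold.

    Ordered by decreasing magnitude. An empty selection is an error; the
    caller decides the fallback.
    """
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    mags = scores.abs()
    picked = mags[mags > threshold].sort_values(ascending=False)
    if picked.empty:
        raise ValidationError(f"no feature has |score| > {threshold:.4g}")
    return list(picked.index)


def threshold_grid(scores: pd.Series, grid_size: int = 20) -> np.ndarray:
    """Candidate thresholds: |score| quantiles from the 50th to the 99th
    percentile."""
    if grid_size < 1:
        raise ValidationError("grid_size must be >= 1")
    qs = np.linspace(0.50, 0.99, grid_size)
    return np.quantile(scores.abs().to_numpy(), qs)


def _stratified_folds(
    event: np.ndarray,
    n_folds: int,
    rng: np.random.Generator,
    min_events: int = 2,
    max_redraws: int = 50,
) -> np.ndarray:
    """Random fold labels, stratified by the event indicator.

    Redraws (up to a cap) if any fold would carry fewer than
    ``min_events`` events, which the Cox machinery needs.
    """
    n = event.shape[0]
    for _ in range(max_redraws):
        labels = np.empty(n, dtype=int)
        for value in (1, 0):
            idx = np.flatnonzero(event == value)
            rng.shuffle(idx)
            labels[idx] = np.arange(idx.size) % n_folds
        counts = np.bincount(labels[event == 1], minlength=n_folds)
        if counts.min() >= min_events:
            return labels
    raise ValidationError(
        f"could not draw {n_folds} folds with >= {min_events} events each "
        f"({int(event.sum())} events total)"
    )


def cv_select_threshold(
    expr: ExpressionMatrix,
    surv: SurvivalData,
    collection: GeneSetCollection | None = None,
    include_single_genes: bool = True,
    n_folds: int = 3,
    n_repeats: int = 100,
    grid_size: int = 20,
    seed: int | None = None,
    weighting: str = "members",
    keep_fold_details: bool = False,
) -> ThresholdSearchResult:
    """Choose the |score| threshold by repeated k-fold cross-validation.

    Deterministic given ``seed``. Per (repeat, fold, threshold) the
    held-out Cox likelihood-ratio statistic is recorded; thresholds that
    never yield an evaluable predictor are excluded, and if none is
    evaluable the grid is declared too strict.
    """
    if list(expr.sample_ids) != list(surv.sample_ids):
        raise ValidationError("expression and survival are not sample-aligned")
    full_fm = build_feature_matrix(expr, collection, include_single_genes)
    full_scores = score_all(full_fm, surv)
    grid = threshold_grid(full_scores, grid_size)

    rng = np.random.default_rng(seed)
    perf = np.full((grid.size, n_repeats, n_folds), np.nan)
    details: list[dict] = []
    sample_ids = np.asarray(expr.sample_ids, dtype=object)

    for rep in range(n_repeats):
        folds = _stratified_folds(surv.event, n_folds, rng)
        for k in range(n_folds):
            train_ids = list(sample_ids[folds != k])
            test_ids = list(sample_ids[folds == k])
            expr_tr = expr.subset_samples(train_ids)
            surv_tr = surv.subset(train_ids)
            surv_te = surv.subset(test_ids)
            try:
                fm_tr = build_feature_matrix(expr_tr, collection, include_single_genes)
            except ValidationError:
                continue
            scores_tr = score_all(fm_tr, surv_tr)
            # held-out features rebuilt with the fold's training parameters
            fm_te = build_feature_matrix(
                expr.subset_samples(test_ids),
                collection,
                include_single_genes,
                model=fm_tr.standardization,
                transform=fm_tr.transform,
            )
            if keep_fold_details:
                details.append(
                    {
                        "repeat": rep,
                        "fold": k,
                        "train_sample_ids": train_ids,
                        "standardization_mu": fm_tr.standardization.mu.copy(),
                        "standardization_genes": list(fm_tr.standardization.gene_ids),
                    }
                )
            fidx_tr = fm_tr.feature_index()
            fidx_te = fm_te.feature_index()
            mags = scores_tr.abs()
            for ti, thr in enumerate(grid):
                ids = mags.index[mags > thr]
                if len(ids) == 0:
                    continue
                rows_tr = [fidx_tr[f] for f in ids]
                rows_te = [fidx_te[f] for f in ids]
                Xtr = fm_tr.values[rows_tr, :]
                centers = Xtr.mean(axis=1)
                wts = feature_weights(fm_tr.member_counts[rows_tr], weighting)
                try:
                    w, _ = weighted_first_pc((Xtr - centers[:, None]) * wts[:, None])
                except ValidationError:
                    continue
                risk = w @ ((fm_te.values[rows_te, :] - centers[:, None]) * wts[:, None])
                if risk.std(ddof=1) <= 0:
                    continue
                try:
                    fit = fit_univariate_cox(risk, surv_te.time, surv_te.event)
                except ValueError:
                    continue
                perf[ti, rep, k] = fit.likelihood_ratio

    evaluable = np.isfinite(perf).any(axis=(1, 2))
    if not evaluable.any():
        raise ValidationError("grid too strict: no threshold yielded an evaluable predictor")
    mean_perf = np.full(grid.size, -np.inf)
    mean_perf[evaluable] = np.nanmean(
        perf[evaluable].reshape(int(evaluable.sum()), -1), axis=1
    )
    best = float(np.nanmax(mean_perf[evaluable]))
    # ties -> larger threshold (grid is ascending)
    chosen_idx = int(np.flatnonzero(mean_perf >= best - 1e-12)[-1])
    result = ThresholdSearchResult(
        grid,
        mean_perf,
        perf,
        float(grid[chosen_idx]),
        seed,
        n_folds,
        n_repeats,
        details,
    )
    logger.info(
        "CV chose threshold %.4g (mean held-out LR %.3g over %d repeats x %d folds)",
        result.chosen_threshold, best, n_repeats, n_folds,
    )
    return result
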