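"""Cox score statistics for feature screening.

The feature score is the standardized score test of the Cox partial
likelihood at beta = 0:

    s = U(0) / sqrt(I(0))

with U(0) the sum over event times of (x at event - risk-set mean of x)
and I(0) the sum over event times of the risk-set variance of x, both
under the Breslow convention for tied event times. Asymptotically
standard normal for a null feature, so |s| is directly comparable across
gene-set and single-gene features and is what thresholding uses.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io import SurvivalData, ValidationError
from ._cox import risk_set_layout

logger = logging.getLogger(__name__)

__all__ = ["cox_score", "cox_scores_matrix", "score_all", "split_robustness"]


def cox_scores_matrix(X: np.ndarray, time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Cox score statistic for every row of ``X`` (features x samples).

    Rows with zero information (constant in every risk set) come back as
    NaN; callers decide whether that is an error or a skip.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    order, ev, starts, ends, d = risk_set_layout(time, event)
    Xs = X[:, order]
    n_at_risk = np.arange(1, Xs.shape[1] + 1)[ends]
    c1 = np.cumsum(Xs, axis=1)[:, ends]
    c2 = np.cumsum(Xs * Xs, axis=1)[:, ends]
    xbar = c1 / n_at_risk
    ev_x = np.add.reduceat(Xs * ev, starts, axis=1)
    u = np.sum(ev_x - d * xbar, axis=1)
    info = np.sum(d * (c2 / n_at_risk - xbar * xbar), axis=1)
    out = np.full(X.shape[0], np.nan)
    ok = info > 1e-12 * np.maximum(1.0, np.abs(c2).max(axis=1))
    out[ok] = u[ok] / np.sqrt(info[ok])
    return out


def cox_score(x: np.ndarray, surv: SurvivalData) -> float:
    """Score-test statistic of one feature against censored survival."""
    x = np.asarray(x, dtype=float)
    if x.shape != (surv.n_samples,):
        raise ValidationError("feature length does not match survival data")
    s = cox_scores_matrix(x[None, :], surv.time, surv.event)[0]
    if np.isnan(s):
        raise ValidationError("zero information: feature is constant within risk sets")
    return float(s)


def score_all(fm, surv: SurvivalData) -> pd.Series:
    """Cox scores for every feature of a FeatureMatrix.

    Returns a Series indexed by feature ID. Features that fail the score
    preconditions (zero information) are absent, with a logged reason.
    """
    if list(fm.sample_ids) != list(surv.sample_ids):
        raise ValidationError("feature matrix and survival data are not sample-aligned")
    s = cox_scores_matrix(fm.values, surv.time, surv.event)
    ok = np.isfinite(s)
    if not ok.all():
        skipped = [f for f, o in zip(fm.feature_ids, ok) if not o]
        logger.info("skipped %d zero-information feature(s): %s", len(skipped), skipped[:5])
    return pd.Series(s[ok], index=[f for f, o in zip(fm.feature_ids, ok) if o], name="cox_score")


def split_robustness(
    fm_a, surv_a: SurvivalData, fm_b, surv_b: SurvivalData, ids: list[str] | None = None
) -> float:
    """Spearman correlation of |score| across two exclusive sample splits.

    Scores are computed independently on each split; the rank correlation
    of their magnitudes over the common features measures how reproducible
    the feature ranking is. Magnitudes (not signed scores) are used
    because selection thresholds on magnitude.
    """
    if set(fm_a.sample_ids) & set(fm_b.sample_ids):
        raise ValidationError("splits share samples; robustness requires exclusive splits")
    scores_a = score_all(fm_a, surv_a)
    scores_b = score_all(fm_b, surv_b)
    if ids is None:
        ids = [f for f in scores_a.index if f in set(scores_b.index)]
    common = [f for f in ids if f in scores_a.index and f in scores_b.index]
    if len(common) < 3:
        raise ValidationError(f"only {len(common)} common scored features; need >=3")
    rho, _ = stats.spearmanr(scores_a[common].abs(), scores_b[common].abs())
    return float(rho)
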