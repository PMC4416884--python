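"""Model/Results front end for the hybrid gene-set survival predictor.

``GeneSetRiskModel`` bundles an expression matrix, censored outcomes and
(optionally) a gene-set collection; ``fit()`` runs the full training
pipeline — cross-validated threshold search, feature selection on
full-training Cox scores, weighted first-PC predictor — and returns a
``GeneSetRiskResults`` carrying the predictor, the selection diagnostics
and prediction/evaluation methods.

Example
-------
>>> model = GeneSetRiskModel(expr_train, surv_train, collection, mode="hybrid")
>>> res = model.fit(seed=0, n_repeats=100)
>>> risk = res.predict(expr_test)
>>> res.evaluate(expr_test, surv_test).c_index
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSetCollection, SurvivalData, ValidationError, align
from .summarize import build_feature_matrix
from .scoring import score_all
from .selection import ThresholdSearchResult, cv_select_threshold, select_features
from .predict import Predictor, fit_predictor, predict_risk
from .evaluate import EvaluationReport, evaluate_risk

__all__ = ["GeneSetRiskModel", "GeneSetRiskResults", "MODES"]

MODES = ("hybrid", "geneset_only", "single_gene_only")


class GeneSetRiskModel:
    """Hybrid gene-set + single-gene supervised-PC survival model.

    Parameters
    ----------
    expr, surv : training data; sample IDs must match (order is taken
        from the expression matrix).
    collection : gene-set collection; required unless
        ``mode="single_gene_only"``.
    mode : which feature kinds compete for selection — ``hybrid`` (gene
        sets plus single genes as one-member pseudo sets),
        ``geneset_only``, or ``single_gene_only``.
    weighting : PCA feature weights; ``members`` (published N_i weights)
        or ``sqrt_members``.
    """

    def __init__(
        self,
        expr: ExpressionMatrix,
        surv: SurvivalData,
        collection: GeneSetCollection | None = None,
        mode: str = "hybrid",
        weighting: str = "members",
    ):
        if mode not in MODES:
            raise ValidationError(f"mode must be one of {MODES}, got {mode!r}")
        if mode != "single_gene_only" and collection is None:
            raise ValidationError(f"mode {mode!r} requires a gene-set collection")
        self.expr, self.surv = align(expr, surv)
        self.collection = None if mode == "single_gene_only" else collection
        self.mode = mode
        self.weighting = weighting
        self.include_single_genes = mode != "geneset_only"

    @classmethod
    def from_dataframes(
        cls,
        expression: pd.DataFrame,
        survival: pd.DataFrame,
        collection: GeneSetCollection | None = None,
        **kwargs,
    ) -> "GeneSetRiskModel":
        """Build from a genes x samples DataFrame and a survival frame
        with columns ``sample_id``, ``time``, ``event``."""
        expr = ExpressionMatrix.from_dataframe(expression)
        surv = SurvivalData(
            list(survival["sample_id"].astype(str)),
            survival["time"].to_numpy(dtype=float),
            survival["event"].to_numpy(),
        )
        return cls(expr, surv, collection, **kwargs)

    def fit(
        self,
        n_folds: int = 3,
        n_repeats: int = 100,
        grid_size: int = 20,
        seed: int | None = None,
        threshold: float | None = None,
    ) -> "GeneSetRiskResults":
        """Train the predictor.

        ``threshold=None`` (default) selects it by repeated k-fold CV;
        passing a number skips the search.
        """
        search = None
        if threshold is None:
            search = cv_select_threshold(
                self.expr,
                self.surv,
                self.collection,
                self.include_single_genes,
                n_folds=n_folds,
                n_repeats=n_repeats,
                grid_size=grid_size,
                seed=seed,
                weighting=self.weighting,
            )
            threshold = search.chosen_threshold
        fm = build_feature_matrix(self.expr, self.collection, self.include_single_genes)
        scores = score_all(fm, self.surv)
        selected = select_features(scores, threshold)
        predictor = fit_predictor(fm.subset(selected), self.surv, weighting=self.weighting)
        return GeneSetRiskResults(self, predictor, scores, selected, float(threshold), search)


@dataclass
class GeneSetRiskResults:
    """Fitted predictor plus training diagnostics."""

    model: GeneSetRiskModel
    predictor: Predictor
    feature_scores: pd.Series
    selected_features: list[str]
    threshold: float
    threshold_search: ThresholdSearchResult | None = field(default=None, repr=False)

    def predict(self, expr: ExpressionMatrix) -> np.ndarray:
        """Risk scores for new samples (higher = shorter expected survival)."""
        return predict_risk(self.predictor, expr)

    def evaluate(self, expr: ExpressionMatrix, surv: SurvivalData) -> EvaluationReport:
        expr, surv = align(expr, surv)
        return evaluate_risk(self.predict(expr), surv)

    @property
    def selected_table(self) -> pd.DataFrame:
        """Selected features with kind, member count, score and loading."""
        p = self.predictor
        return pd.DataFrame(
            {
                "feature": p.feature_ids,
                "kind": p.kinds,
                "members": p.member_counts,
                "cox_score": self.feature_scores[p.feature_ids].to_numpy(),
                "loading": p.sign * p.loading,
            }
        )

    def summary(self) -> str:
        """Plain-text fit summary (statsmodels-flavoured)."""
        n_gs = sum(k == "gene_set" for k in self.predictor.kinds)
        n_sg = len(self.predictor.kinds) - n_gs
        lines = [
            "Hybrid gene-set survival predictor",
            "=" * 50,
            f"mode:               {self.model.mode}",
            f"training samples:   {self.model.surv.n_samples} "
            f"({self.model.surv.n_events} events)",
            f"candidate features: {len(self.feature_scores)}",
            f"chosen |score| threshold: {self.threshold:.4f}"
            + ("" if self.threshold_search is None else "  (by CV)"),
            f"selected features:  {len(self.selected_features)} "
            f"({n_gs} gene sets, {n_sg} single genes)",
            f"training Cox coef of PC score: {self.predictor.train_cox_coef:.4f}",
            "-" * 50,
            "top selected features by |Cox score|:",
        ]
        top = self.selected_table.reindex(
            self.selected_table.cox_score.abs().sort_values(ascending=False).index
        ).head(10)
        for _, row in top.iterrows():
            lines.append(
                f"  {row.feature:<28s} {row.kind:<12s} N={row.members:<4d} "
                f"score={row.cox_score:+.3f}"
            )
        return "\n".join(lines)
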