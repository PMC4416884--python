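"""Membership-weighted principal-component risk predictor.

Selected features x_1..x_n (gene sets and single genes) are centered at
their training means and stacked into the weighted feature matrix

    diag(N_1, ..., N_n) @ [x_1^T; ...; x_n^T]

where N_i is the member-gene count of feature i (1 for single genes).
The first right-singular direction of this matrix gives the per-sample
predictor score; with all N_i = 1 this is exactly conventional PCA on the
selected features. Weighting by N_i up-weights gene-set features
summarized from more member genes.

The PC sign is arbitrary, so the predictor is oriented such that higher
score means higher hazard on the training data (non-negative training
Cox coefficient). Risk for a new sample is the projection of its rebuilt,
centered, weighted feature column onto the stored loading vector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionMatrix, SurvivalData, ValidationError
from .summarize import (
    FeatureMatrix,
    GeneSetTransform,
    StandardizationModel,
    SINGLE_GENE,
    GENE_SET,
    apply_standardization,
)
from ._cox import fit_univariate_cox

__all__ = ["Predictor", "weighted_first_pc", "feature_weights", "fit_predictor", "predict_risk"]


def feature_weights(member_counts: np.ndarray, weighting: str = "members") -> np.ndarray:
    """Per-feature PCA weights: ``members`` (N_i) or ``sqrt_members``.

    ``members`` is the published weighting; ``sqrt_members`` is an
    alternative that tempers the variance inflation of large sets and is
    off by default.
    """
    counts = np.asarray(member_counts, dtype=float)
    if weighting == "members":
        return counts
    if weighting == "sqrt_members":
        return np.sqrt(counts)
    raise ValidationError(f"unknown weighting {weighting!r}")


def weighted_first_pc(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First singular direction of a features x samples matrix.

    Returns ``(w, scores)`` with ``||w|| = 1`` and
    ``scores = w @ A``. Uses whichever of the two Gram matrices is
    smaller, so cost is O(min(k, n)^3) plus one matmul.
    """
    k, n = A.shape
    if not np.isfinite(A).any() or np.allclose(A, 0.0):
        raise ValidationError("all-zero centered feature matrix; no principal component")
    if k <= n:
        G = A @ A.T
        vals, vecs = np.linalg.eigh(G)
        w = vecs[:, -1]
        scores = w @ A
    else:
        G = A.T @ A
        vals, vecs = np.linalg.eigh(G)
        v0 = vecs[:, -1]
        sigma = np.sqrt(max(vals[-1], 0.0))
        if sigma <= 0:
            raise ValidationError("zero leading singular value")
        w = (A @ v0) / sigma
        scores = sigma * v0
    return w, scores


@dataclass
class Predictor:
    """Frozen projection recipe for risk prediction on new samples."""

    feature_ids: list[str]
    kinds: list[str]
    member_counts: np.ndarray
    centers: np.ndarray
    loading: np.ndarray  # w, unit norm
    sign: int  # orientation: +1/-1 so that higher risk = shorter survival
    weighting: str
    train_cox_coef: float  # Cox coefficient of the oriented training score
    standardization: StandardizationModel
    transform: GeneSetTransform | None
    single_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.member_counts = np.asarray(self.member_counts, dtype=int)
        self.centers = np.asarray(self.centers, dtype=float)
        self.loading = np.asarray(self.loading, dtype=float)

    def to_dict(self) -> dict:
        return {
            "feature_ids": list(self.feature_ids),
            "kinds": list(self.kinds),
            "member_counts": self.member_counts.tolist(),
            "centers": self.centers.tolist(),
            "loading": self.loading.tolist(),
            "sign": int(self.sign),
            "weighting": self.weighting,
            "train_cox_coef": float(self.train_cox_coef),
            "standardization": self.standardization.to_dict(),
            "transform": self.transform.to_dict() if self.transform is not None else None,
            "single_genes": list(self.single_genes),
        }

    def save(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(self.to_dict(), handle)

    @classmethod
    def from_dict(cls, d: dict) -> "Predictor":
        return cls(
            list(d["feature_ids"]),
            list(d["kinds"]),
            np.asarray(d["member_counts"], dtype=int),
            np.asarray(d["centers"], dtype=float),
            np.asarray(d["loading"], dtype=float),
            int(d["sign"]),
            d["weighting"],
            float(d["train_cox_coef"]),
            StandardizationModel.from_dict(d["standardization"]),
            GeneSetTransform.from_dict(d["transform"]) if d["transform"] else None,
            list(d.get("single_genes", [])),
        )

    @classmethod
    def load(cls, path: str) -> "Predictor":
        with open(path, encoding="utf-8") as handle:
            return cls.from_dict(json.load(handle))


def fit_predictor(
    fm_selected: FeatureMatrix,
    surv: SurvivalData,
    weighting: str = "members",
    orient: bool = True,
) -> Predictor:
    """Fit the weighted first-PC predictor on selected training features.

    With ``orient=False`` the sign is left at +1 (useful inside
    cross-validation, where the held-out metric is sign-invariant).
    """
    if fm_selected.n_features < 1:
        raise ValidationError("no selected features")
    if list(fm_selected.sample_ids) != list(surv.sample_ids):
        raise ValidationError("feature matrix and survival data are not sample-aligned")
    X = fm_selected.values
    centers = X.mean(axis=1)
    weights = feature_weights(fm_selected.member_counts, weighting)
    A = (X - centers[:, None]) * weights[:, None]
    w, scores = weighted_first_pc(A)

    sign = 1
    coef = 0.0
    if orient:
        if scores.std(ddof=1) > 0:
            fit = fit_univariate_cox(scores, surv.time, surv.event)
            if fit.beta < 0:
                sign = -1
            coef = abs(fit.beta)
        else:
            raise ValidationError("degenerate predictor: constant training scores")

    # keep only the genes the selected features actually need
    selected_sets = [
        f[len("GS:"):] for f, k in zip(fm_selected.feature_ids, fm_selected.kinds) if k == GENE_SET
    ]
    single_genes = [
        f[len("SG:"):] for f, k in zip(fm_selected.feature_ids, fm_selected.kinds) if k == SINGLE_GENE
    ]
    transform = None
    needed_genes: set[str] = set(single_genes)
    if selected_sets:
        transform = fm_selected.transform.subset(selected_sets)
        for members in transform.members.values():
            needed_genes.update(members)
    std = fm_selected.standardization.subset(sorted(needed_genes))

    return Predictor(
        list(fm_selected.feature_ids),
        [str(k) for k in fm_selected.kinds],
        fm_selected.member_counts,
        centers,
        w,
        sign,
        weighting,
        coef,
        std,
        transform,
        single_genes,
    )


def rebuild_features(p: Predictor, expr: ExpressionMatrix) -> np.ndarray:
    """Recompute the selected features for new samples.

    Uses only training-derived parameters (standardization, maxmean
    rescale, centering). Raises naming the first missing gene if the
    expression matrix cannot supply a required gene.
    """
    index = expr.gene_index()
    missing = [g for g in p.standardization.gene_ids if g not in index]
    if missing:
        extra = f" (+{len(missing) - 1} more)" if len(missing) > 1 else ""
        raise ValidationError(f"expression matrix is missing required gene {missing[0]!r}{extra}")
    rows: dict[str, np.ndarray] = {}
    if p.transform is not None:
        e_std = apply_standardization(expr, p.standardization)
        gs_vals = p.transform.apply(e_std, p.standardization)
        for name, vec in zip(p.transform.set_names, gs_vals):
            rows[f"GS:{name}"] = vec
    for g in p.single_genes:
        rows[f"SG:{g}"] = expr.values[index[g], :]
    return np.vstack([rows[f] for f in p.feature_ids])


def predict_risk(p: Predictor, expr_test: ExpressionMatrix) -> np.ndarray:
    """Per-sample risk: oriented projection onto the stored loading."""
    X = rebuild_features(p, expr_test)
    weights = feature_weights(p.member_counts, p.weighting)
    A = (X - p.centers[:, None]) * weights[:, None]
    return p.sign * (p.loading @ A)
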