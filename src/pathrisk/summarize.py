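"""Gene-set expression indices via the maxmean statistic.

The summarization turns a genes x samples matrix into one expression
index per gene set, in two steps:

1. Each gene is standardized to mean 0 / SD 1 (training parameters).
   For gene set *g* with N_g member genes present in the matrix, the
   per-sample summary is

       u_gj = absmax[ mean of positive parts, mean of negative parts ]

   where the positive/negative parts are taken over the members'
   standardized values and ``absmax`` returns whichever argument has the
   larger magnitude. This captures coherent up- or down-shifts of the set
   without letting opposite-signed members cancel.

2. u_g is restandardized across training samples and rescaled so the
   gene-set index carries the *averaged* mean and variance of its member
   genes: x_gj = u'_gj * sqrt(mean member variance) + mean member mean.
   A one-member set therefore reproduces the original gene exactly, which
   is what lets single genes ride through the same machinery as
   "pseudo gene sets".

All standardization/rescaling parameters are estimated on training
samples only and stored, so test-set features are rebuilt without ever
touching test statistics.

Sample SD (n-1 denominator) is used throughout; with that convention the
mean/variance conservation contract of step 2 holds exactly on training
samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionMatrix, GeneSetCollection, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "StandardizationModel",
    "GeneSetTransform",
    "FeatureMatrix",
    "fit_standardization",
    "apply_standardization",
    "maxmean",
    "rescale_geneset",
    "fit_geneset_transform",
    "build_feature_matrix",
]

GENE_SET = "gene_set"
SINGLE_GENE = "single_gene"


@dataclass
class StandardizationModel:
    """Per-gene training mean/SD; constant genes are dropped on fit."""

    gene_ids: list[str]
    mu: np.ndarray
    sigma: np.ndarray
    dropped_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(self.sigma <= 0):
            raise ValidationError("standardization model has non-positive sigma")

    def to_dict(self) -> dict:
        return {
            "gene_ids": list(self.gene_ids),
            "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(),
            "dropped_genes": list(self.dropped_genes),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StandardizationModel":
        return cls(
            list(d["gene_ids"]),
            np.asarray(d["mu"], dtype=float),
            np.asarray(d["sigma"], dtype=float),
            list(d.get("dropped_genes", [])),
        )

    def subset(self, gene_ids: list[str]) -> "StandardizationModel":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in gene_ids]
        return StandardizationModel(list(gene_ids), self.mu[rows], self.sigma[rows], [])


def fit_standardization(expr: ExpressionMatrix) -> StandardizationModel:
    """Estimate per-gene mean and sample SD on training samples.

    Genes with zero variance are excluded (they carry no signal and make
    standardization undefined); their IDs are recorded on the model and a
    count is logged.
    """
    if expr.n_samples < 2:
        raise ValidationError("need >=2 samples to fit standardization")
    mu = expr.values.mean(axis=1)
    sigma = expr.values.std(axis=1, ddof=1)
    keep = sigma > 0
    if not keep.any():
        raise ValidationError("all genes are constant; nothing to standardize")
    dropped = [g for g, k in zip(expr.gene_ids, keep) if not k]
    if dropped:
        logger.info("dropping %d constant gene(s) from standardization", len(dropped))
    gene_ids = [g for g, k in zip(expr.gene_ids, keep) if k]
    return StandardizationModel(gene_ids, mu[keep], sigma[keep], dropped)


def apply_standardization(expr: ExpressionMatrix, model: StandardizationModel) -> np.ndarray:
    """Standardize ``expr`` with the *model's* (training) parameters.

    Returns the genes x samples array of e'_ij = (e_ij - mu_i) / sigma_i in
    the model's gene order. Test-set rows need not have mean 0: the model
    is never refit.
    """
    index = expr.gene_index()
    missing = [g for g in model.gene_ids if g not in index]
    if missing:
        raise ValidationError(f"genes in model missing from expression matrix: {missing[:10]}")
    rows = [index[g] for g in model.gene_ids]
    e = expr.values[rows, :]
    return (e - model.mu[:, None]) / model.sigma[:, None]


def maxmean(e_members: np.ndarray, n_members: int | None = None) -> np.ndarray:
    """Maxmean summary of one set's standardized member values.

    Parameters
    ----------
    e_members : (m, n_samples) array of standardized member expression.
    n_members : divisor N_g; defaults to the number of rows. It is the
        count of members *present* in the matrix (post-intersection) —
        absent genes contribute no measurement.

    Returns the per-sample u_gj. The positive-part mean and negative-part
    mean are both taken over all N_g members (zeros included), and the one
    with larger magnitude wins; an exact tie is only possible when both
    are zero, in which case u = 0.
    """
    e_members = np.atleast_2d(np.asarray(e_members, dtype=float))
    if e_members.shape[0] == 0:
        raise ValidationError("maxmean of an empty member list")
    n = n_members if n_members is not None else e_members.shape[0]
    pos = np.clip(e_members, 0.0, None).sum(axis=0) / n
    neg = np.clip(e_members, None, 0.0).sum(axis=0) / n
    return np.where(pos >= -neg, pos, neg)


def rescale_geneset(
    u: np.ndarray,
    member_mu: np.ndarray,
    member_sigma: np.ndarray,
    u_mean: float | None = None,
    u_sd: float | None = None,
) -> tuple[np.ndarray, float, float]:
    """Rescale a maxmean summary to the averaged member mean/variance.

    On training data ``u_mean``/``u_sd`` are estimated from ``u`` itself;
    on test data the stored training values are passed in. Returns
    ``(x, u_mean, u_sd)`` where across training samples mean(x) equals the
    mean of member means and var(x) the mean of member variances exactly.
    """
    u = np.asarray(u, dtype=float)
    if u_mean is None:
        u_mean = float(u.mean())
    if u_sd is None:
        u_sd = float(u.std(ddof=1))
    if u_sd <= 0:
        raise ValidationError("zero-variance maxmean summary; feature must be dropped")
    target_mean = float(np.mean(member_mu))
    target_sd = float(np.sqrt(np.mean(np.square(member_sigma))))
    x = (u - u_mean) / u_sd * target_sd + target_mean
    return x, u_mean, u_sd


@dataclass
class GeneSetTransform:
    """Frozen training-derived recipe to turn standardized expression into
    gene-set features on any sample set.

    Holds, per surviving set: the member genes present in the training
    matrix, the training mean/SD of the maxmean summary u_g, and the
    rescale targets (averaged member mean, sqrt of averaged member
    variance).
    """

    set_names: list[str]
    members: dict[str, list[str]]
    u_mean: np.ndarray
    u_sd: np.ndarray
    target_mean: np.ndarray
    target_sd: np.ndarray
    dropped_sets: dict[str, str] = field(default_factory=dict)

    def member_counts(self) -> np.ndarray:
        return np.array([len(self.members[s]) for s in self.set_names], dtype=int)

    def apply(self, e_std: np.ndarray, model: StandardizationModel) -> np.ndarray:
        """Compute set features (sets x samples) from standardized values."""
        gidx = {g: i for i, g in enumerate(model.gene_ids)}
        out = np.empty((len(self.set_names), e_std.shape[1]))
        for k, set_name in enumerate(self.set_names):
            rows = [gidx[g] for g in self.members[set_name]]
            u = maxmean(e_std[rows, :], len(rows))
            out[k] = (u - self.u_mean[k]) / self.u_sd[k] * self.target_sd[k] + self.target_mean[k]
        return out

    def subset(self, set_names: list[str]) -> "GeneSetTransform":
        idx = {s: i for i, s in enumerate(self.set_names)}
        rows = [idx[s] for s in set_names]
        return GeneSetTransform(
            list(set_names),
            {s: list(self.members[s]) for s in set_names},
            self.u_mean[rows],
            self.u_sd[rows],
            self.target_mean[rows],
            self.target_sd[rows],
        )

    def to_dict(self) -> dict:
        return {
            "set_names": list(self.set_names),
            "members": {s: list(m) for s, m in self.members.items()},
            "u_mean": self.u_mean.tolist(),
            "u_sd": self.u_sd.tolist(),
            "target_mean": self.target_mean.tolist(),
            "target_sd": self.target_sd.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneSetTransform":
        return cls(
            list(d["set_names"]),
            {s: list(m) for s, m in d["members"].items()},
            np.asarray(d["u_mean"], dtype=float),
            np.asarray(d["u_sd"], dtype=float),
            np.asarray(d["target_mean"], dtype=float),
            np.asarray(d["target_sd"], dtype=float),
        )


def fit_geneset_transform(
    e_std: np.ndarray, model: StandardizationModel, collection: GeneSetCollection
) -> GeneSetTransform:
    """Fit the gene-set summarization on training standardized values.

    Set members absent from the matrix are intersected out; sets with no
    surviving member, or whose maxmean summary has zero variance across
    training samples, are dropped with a recorded reason.
    """
    gidx = {g: i for i, g in enumerate(model.gene_ids)}
    set_names: list[str] = []
    members: dict[str, list[str]] = {}
    u_means: list[float] = []
    u_sds: list[float] = []
    t_means: list[float] = []
    t_sds: list[float] = []
    dropped: dict[str, str] = {}
    for set_name, gene_set in collection.sets.items():
        present = sorted(g for g in gene_set if g in gidx)
        if not present:
            dropped[set_name] = "no member genes in expression matrix"
            continue
        rows = [gidx[g] for g in present]
        u = maxmean(e_std[rows, :], len(rows))
        u_mean = float(u.mean())
        u_sd = float(u.std(ddof=1))
        if u_sd <= 0:
            dropped[set_name] = "zero-variance maxmean summary"
            continue
        set_names.append(set_name)
        members[set_name] = present
        u_means.append(u_mean)
        u_sds.append(u_sd)
        t_means.append(float(model.mu[rows].mean()))
        t_sds.append(float(np.sqrt(np.mean(np.square(model.sigma[rows])))))
    if dropped:
        logger.info("dropped %d gene set(s): %s", len(dropped),
                    "; ".join(f"{k} ({v})" for k, v in list(dropped.items())[:5]))
    return GeneSetTransform(
        set_names,
        members,
        np.asarray(u_means),
        np.asarray(u_sds),
        np.asarray(t_means),
        np.asarray(t_sds),
        dropped,
    )


@dataclass
class FeatureMatrix:
    """Unified gene-set + single-gene feature matrix (features x samples).

    Gene-set features carry their member count N_i; single genes are
    pseudo gene sets with N_i = 1 and raw (unstandardized) expression
    values. The standardization model and gene-set transform needed to
    rebuild the same features on new samples travel with the matrix.
    """

    feature_ids: list[str]
    kinds: np.ndarray  # GENE_SET / SINGLE_GENE per feature
    member_counts: np.ndarray
    values: np.ndarray
    sample_ids: list[str]
    standardization: StandardizationModel
    transform: GeneSetTransform | None

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def feature_index(self) -> dict[str, int]:
        return {f: i for i, f in enumerate(self.feature_ids)}

    def subset(self, feature_ids: list[str]) -> "FeatureMatrix":
        idx = self.feature_index()
        rows = [idx[f] for f in feature_ids]
        return FeatureMatrix(
            list(feature_ids),
            self.kinds[rows],
            self.member_counts[rows],
            self.values[rows, :],
            list(self.sample_ids),
            self.standardization,
            self.transform,
        )


def build_feature_matrix(
    expr: ExpressionMatrix,
    collection: GeneSetCollection | None = None,
    include_single_genes: bool = True,
    model: StandardizationModel | None = None,
    transform: GeneSetTransform | None = None,
) -> FeatureMatrix:
    """Assemble the hybrid feature matrix.

    On training data call with ``model=None`` / ``transform=None`` so both
    are fitted here; on test data pass the stored training ``model`` and
    ``transform`` so the exact same features are rebuilt with training
    parameters.

    Feature IDs are namespaced ``GS:<set>`` / ``SG:<gene>`` to avoid
    collisions between set names and gene names.
    """
    if collection is None and not include_single_genes:
        raise ValidationError("no features requested: need a collection or single genes")
    if model is None:
        model = fit_standardization(expr)
    ids: list[str] = []
    kinds: list[str] = []
    counts: list[int] = []
    blocks: list[np.ndarray] = []
    if collection is not None:
        e_std = apply_standardization(expr, model)
        if transform is None:
            transform = fit_geneset_transform(e_std, model, collection)
        if transform.set_names:
            blocks.append(transform.apply(e_std, model))
            ids.extend(f"GS:{s}" for s in transform.set_names)
            kinds.extend([GENE_SET] * len(transform.set_names))
            counts.extend(transform.member_counts().tolist())
    if include_single_genes:
        index = expr.gene_index()
        rows = [index[g] for g in model.gene_ids]
        blocks.append(expr.values[rows, :])
        ids.extend(f"SG:{g}" for g in model.gene_ids)
        kinds.extend([SINGLE_GENE] * len(model.gene_ids))
        counts.extend([1] * len(model.gene_ids))
    if not ids:
        raise ValidationError("no surviving features")
    return FeatureMatrix(
        ids,
        np.asarray(kinds, dtype=object),
        np.asarray(counts, dtype=int),
        np.vstack(blocks),
        list(expr.sample_ids),
        model,
        transform,
    )
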