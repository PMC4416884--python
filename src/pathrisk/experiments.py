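"""Reproducible property experiments on synthetic cohorts.

These are the package's standing Monte-Carlo checks: exact pipeline
identities (singleton sets, mean/variance conservation, PCA degeneracy),
null calibration of the end-to-end pipeline, planted-pathway recovery,
the hybrid vs. geneset-only vs. single-gene-only comparison under
incomplete annotation, and the split-robustness comparison of feature
kinds. Both the test suite and ``scripts/acceptance.py`` run them.

Problem sizes are deliberately desk-scale (see docs/methods.md): the
cross-validated threshold search inside Monte-Carlo loops uses 10–20
repeats rather than the pipeline default of 100, and cohort sizes are a
few hundred genes. Each function takes a seed and is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix, SurvivalData
from .summarize import (
    GENE_SET,
    SINGLE_GENE,
    build_feature_matrix,
    fit_standardization,
)
from .scoring import score_all, split_robustness
from .selection import cv_select_threshold, select_features
from .predict import fit_predictor, predict_risk
from .evaluate import harrell_c, likelihood_ratio, logrank_median_split
from .synthetic import SimConfig, SimDataset, generate
from .model import GeneSetRiskModel

__all__ = [
    "null_config",
    "recovery_config",
    "orphan_config",
    "graded_config",
    "singleton_identity_error",
    "conservation_error",
    "pca_degeneracy_error",
    "null_calibration",
    "planted_set_recovery",
    "mode_comparison",
    "robustness_comparison",
    "metric_sanity",
]

# ---------------------------------------------------------------- configs


def null_config(seed: int = 0) -> SimConfig:
    """No-signal cohort: correlated pathway structure, hazard flat."""
    return SimConfig(
        n_genes=650, n_train=100, n_test=100, n_sets=40,
        set_size_min=8, set_size_max=15, n_informative_sets=5,
        beta_factor=0.0, censoring_rate=0.3, seed=seed,
    )


def recovery_config(seed: int = 0) -> SimConfig:
    """Defaults: 5 informative pathways among 200, n_train = 150."""
    return SimConfig(seed=seed)


def orphan_config(seed: int = 0) -> SimConfig:
    """~30% of signal genes live in pathways missing from the annotation."""
    return SimConfig(
        n_genes=1700, n_sets=100, orphan_fraction=0.3, n_test=400, seed=seed,
    )


def graded_config(seed: int = 0) -> SimConfig:
    """Every pathway informative with a graded hazard coefficient.

    This is the regime in which per-feature robustness is measurable:
    score rankings carry real signal for both feature kinds, and the
    gene-set summaries aggregate member noise away.
    """
    return SimConfig(
        n_genes=700, n_train=150, n_test=150, n_sets=40,
        set_size_min=8, set_size_max=15, n_informative_sets=40,
        loading=0.5, noise_sd=math.sqrt(1.0 - 0.25),
        beta_factor_sd=0.15, factor_correlation=0.0,
        censoring_rate=0.3, seed=seed,
    )


# ------------------------------------------------------- exact identities


def singleton_identity_error(seed: int = 0, n_genes: int = 100, n_samples: int = 60) -> float:
    """Max |pipeline output - raw expression| over one-member gene sets.

    Standardize -> maxmean -> restandardize -> rescale is the identity on
    a singleton set, so the error should be at machine precision.
    """
    rng = np.random.default_rng(seed)
    expr = ExpressionMatrix(
        [f"G{i}" for i in range(n_genes)],
        [f"S{j}" for j in range(n_samples)],
        rng.normal(2.0, 1.5, size=(n_genes, n_samples)),
    )
    from .io import GeneSetCollection

    coll = GeneSetCollection("singletons", {f"ONE_{g}": frozenset([g]) for g in expr.gene_ids})
    fm = build_feature_matrix(expr, coll, include_single_genes=False)
    gidx = expr.gene_index()
    worst = 0.0
    for fid, row in zip(fm.feature_ids, fm.values):
        gene = fid[len("GS:ONE_"):]
        worst = max(worst, float(np.abs(row - expr.values[gidx[gene]]).max()))
    return worst


def conservation_error(seed: int = 0, n_genes: int = 200, n_samples: int = 80,
                       n_sets: int = 40) -> float:
    """Max deviation of gene-set feature mean/variance from the averaged
    member mean/variance on training samples (should be ~1e-12)."""
    rng = np.random.default_rng(seed)
    expr = ExpressionMatrix(
        [f"G{i}" for i in range(n_genes)],
        [f"S{j}" for j in range(n_samples)],
        rng.normal(5.0, 2.0, size=(n_genes, n_samples)) * rng.uniform(0.5, 2.0, (n_genes, 1)),
    )
    from .io import GeneSetCollection

    sets = {
        f"SET{k}": frozenset(
            rng.choice(expr.gene_ids, size=rng.integers(3, 20), replace=False)
        )
        for k in range(n_sets)
    }
    coll = GeneSetCollection("random", sets)
    model = fit_standardization(expr)
    fm = build_feature_matrix(expr, coll, include_single_genes=False, model=model)
    gidx = {g: i for i, g in enumerate(model.gene_ids)}
    worst = 0.0
    for fid, row in zip(fm.feature_ids, fm.values):
        members = fm.transform.members[fid[len("GS:"):]]
        rows = [gidx[g] for g in members]
        want_mean = model.mu[rows].mean()
        want_var = np.mean(model.sigma[rows] ** 2)
        worst = max(
            worst,
            abs(float(row.mean()) - want_mean),
            abs(float(row.var(ddof=1)) - want_var),
        )
    return worst


def pca_degeneracy_error(seed: int = 0, n_features: int = 30, n_samples: int = 50) -> float:
    """With all member counts 1, predictor scores must equal conventional
    first-PC scores (up to overall sign). Returns the max |difference|."""
    rng = np.random.default_rng(seed)
    expr = ExpressionMatrix(
        [f"G{i}" for i in range(n_features)],
        [f"S{j}" for j in range(n_samples)],
        rng.normal(0.0, 1.0, size=(n_features, n_samples)),
    )
    surv = SurvivalData(
        list(expr.sample_ids), rng.exponential(10.0, n_samples), np.ones(n_samples, dtype=int)
    )
    fm = build_feature_matrix(expr, None, include_single_genes=True)
    pred = fit_predictor(fm, surv, weighting="members")
    risks = predict_risk(pred, expr)
    # conventional PCA oracle: plain SVD of the centered matrix
    X = expr.values[[expr.gene_index()[g] for g in fm.standardization.gene_ids], :]
    A = X - X.mean(axis=1, keepdims=True)
    _, s, vt = np.linalg.svd(A, full_matrices=False)
    pc1 = s[0] * vt[0]
    err = min(
        float(np.abs(risks - pc1).max()),
        float(np.abs(risks + pc1).max()),
    )
    return err


# --------------------------------------------------------- Monte Carlo


@dataclass
class PipelineSettings:
    """Scaled-down pipeline settings used inside Monte-Carlo loops."""

    n_repeats: int = 10
    grid_size: int = 20
    n_folds: int = 3


def _run_pipeline(data: SimDataset, mode: str, seed: int,
                  settings: PipelineSettings):
    model = GeneSetRiskModel(
        data.expr_train, data.surv_train,
        None if mode == "single_gene_only" else data.collection, mode=mode,
    )
    return model.fit(
        n_folds=settings.n_folds,
        n_repeats=settings.n_repeats,
        grid_size=settings.grid_size,
        seed=seed,
    )


def null_calibration(n_replicates: int = 200, seed: int = 0, alpha: float = 0.05,
                     settings: PipelineSettings | None = None) -> dict:
    """End-to-end type-I error of the median-split log-rank test.

    Runs the full train -> select -> predict pipeline on no-signal
    cohorts and records how often the held-out log-rank p falls below
    alpha. Should be ~alpha.
    """
    settings = settings or PipelineSettings(n_repeats=10)
    rng = np.random.default_rng(seed)
    rejections = 0
    used = 0
    for _ in range(n_replicates):
        rep_seed = int(rng.integers(2**31 - 1))
        data = generate(null_config(rep_seed))
        res = _run_pipeline(data, "hybrid", rep_seed, settings)
        risk = res.predict(data.expr_test)
        p, _, _ = logrank_median_split(risk, data.surv_test)
        used += 1
        if p < alpha:
            rejections += 1
    return {"rejection_rate": rejections / used, "n": used, "alpha": alpha}


def planted_set_recovery(n_seeds: int = 20, seed: int = 0,
                         settings: PipelineSettings | None = None) -> dict:
    """How often CV-selected features keep >=4 of the 5 planted pathways."""
    settings = settings or PipelineSettings(n_repeats=20)
    rng = np.random.default_rng(seed)
    hits = 0
    recovered_counts = []
    for _ in range(n_seeds):
        rep_seed = int(rng.integers(2**31 - 1))
        data = generate(recovery_config(rep_seed))
        res = _run_pipeline(data, "hybrid", rep_seed, settings)
        selected_sets = {f[len("GS:"):] for f in res.selected_features if f.startswith("GS:")}
        n_found = len(selected_sets & set(data.truth.informative_sets))
        recovered_counts.append(n_found)
        if n_found >= 4:
            hits += 1
    return {
        "recovery_rate": hits / n_seeds,
        "mean_recovered": float(np.mean(recovered_counts)),
        "n": n_seeds,
    }


def mode_comparison(n_seeds: int = 20, seed: int = 0,
                    settings: PipelineSettings | None = None) -> dict:
    """Paired test-set C index of hybrid vs geneset-only vs single-gene-only
    on cohorts with ~30% of signal genes outside every annotated set."""
    settings = settings or PipelineSettings(n_repeats=20)
    rng = np.random.default_rng(seed)
    cs = {m: [] for m in ("hybrid", "geneset_only", "single_gene_only")}
    for _ in range(n_seeds):
        rep_seed = int(rng.integers(2**31 - 1))
        data = generate(orphan_config(rep_seed))
        for mode in cs:
            res = _run_pipeline(data, mode, rep_seed, settings)
            risk = res.predict(data.expr_test)
            cs[mode].append(harrell_c(risk, data.surv_test))
    arr = {m: np.asarray(v) for m, v in cs.items()}
    return {
        "hybrid_mean_c": float(arr["hybrid"].mean()),
        "geneset_only_mean_c": float(arr["geneset_only"].mean()),
        "single_gene_only_mean_c": float(arr["single_gene_only"].mean()),
        "hybrid_ge_geneset_fraction": float(
            np.mean(arr["hybrid"] >= arr["geneset_only"])
        ),
        "hybrid_ge_single_gene_fraction": float(
            np.mean(arr["hybrid"] >= arr["single_gene_only"])
        ),
        "n": n_seeds,
    }


def robustness_comparison(n_replicates: int = 20, seed: int = 0) -> dict:
    """Split-robustness of gene-set vs single-gene feature scores.

    For each replicate a graded-signal cohort's train/test halves are
    scored independently; the Spearman correlation of |score| across the
    halves is computed separately per feature kind.
    """
    rng = np.random.default_rng(seed)
    gs_rhos, sg_rhos = [], []
    for _ in range(n_replicates):
        rep_seed = int(rng.integers(2**31 - 1))
        data = generate(graded_config(rep_seed))
        fm_a = build_feature_matrix(data.expr_train, data.collection)
        fm_b = build_feature_matrix(data.expr_test, data.collection)
        gs_ids = [f for f, k in zip(fm_a.feature_ids, fm_a.kinds) if k == GENE_SET]
        sg_ids = [f for f, k in zip(fm_a.feature_ids, fm_a.kinds) if k == SINGLE_GENE]
        gs_rhos.append(
            split_robustness(fm_a, data.surv_train, fm_b, data.surv_test, gs_ids)
        )
        sg_rhos.append(
            split_robustness(fm_a, data.surv_train, fm_b, data.surv_test, sg_ids)
        )
    return {
        "geneset_mean_rho": float(np.mean(gs_rhos)),
        "single_gene_mean_rho": float(np.mean(sg_rhos)),
        "geneset_higher_fraction": float(np.mean(np.asarray(gs_rhos) > np.asarray(sg_rhos))),
        "n": n_replicates,
    }


def metric_sanity(seed: int = 0, n_null: int = 1000, n_samples: int = 50) -> dict:
    """Closed-form behaviour of the evaluation metrics.

    Perfect-rank risk with no censoring must give C = 1 exactly; under an
    independent-risk null the Cox LR statistic is ~chi-square(1), so its
    mean over replicates should be ~1.
    """
    rng = np.random.default_rng(seed)
    n = 100
    time = rng.exponential(10.0, size=n)
    surv = SurvivalData([f"S{j}" for j in range(n)], time, np.ones(n, dtype=int))
    c_perfect = harrell_c(-time, surv)  # risk reverse-ordered to time

    lrs = []
    for _ in range(n_null):
        t = rng.exponential(10.0, size=n_samples)
        ev = (rng.random(n_samples) > 0.3).astype(int)
        if ev.sum() < 2:
            ev[0] = 1
        s = SurvivalData([f"S{j}" for j in range(n_samples)], t, ev)
        risk = rng.standard_normal(n_samples)
        lrs.append(likelihood_ratio(risk, s))
    lrs = np.asarray(lrs)
    return {
        "perfect_rank_c_index": float(c_perfect),
        "null_lr_mean": float(lrs.mean()),
        "null_lr_q95": float(np.quantile(lrs, 0.95)),
        "n_null": n_null,
    }
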