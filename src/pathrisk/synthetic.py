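"""Synthetic expression cohorts with pathway-level survival signal.

The generator emulates the structure the hybrid gene-set method assumes:
groups of co-regulated genes (one shared latent factor per informative
pathway, plus independent per-gene noise) whose latent activity drives a
proportional-hazards survival outcome. Concretely, for informative
pathway *s* with factor f_s ~ N(0,1), each member gene is

    e_ij = loading * f_sj + noise_sd * eps_ij ,

decoy genes are pure N(0,1) noise. Pathway factors are not independent:
they share a common severity axis with pairwise correlation
``factor_correlation``, the structure under which a single supervised
principal component is a sensible predictor (and the one observed in
real prognostic cohorts, where selected pathways co-vary). The
per-sample log-hazard is

    eta_j = sum_s beta_s * f_sj  (+ optional direct orphan-gene terms),

with equal-effect coefficients normalized so that ``beta_factor`` is the
log-HR per SD of the aggregate pathway signal (eta then has SD
~beta_factor regardless of the number of factors).

Event times are exponential with rate baseline_hazard * exp(eta);
independent exponential censoring has its rate solved so the *expected*
censoring fraction hits the target.

Annotation incompleteness ("orphan" signal) is modelled at the pathway
level: a chosen fraction of signal genes belongs to orphan pathways that
carry the same per-factor hazard effect but are left out of the
annotated collection, so only single-gene features can see them.
Standalone direct-effect orphan genes are also available
(``n_direct_orphans`` / ``beta_orphan``) but off by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .io import ExpressionMatrix, GeneSetCollection, SurvivalData, ValidationError
from .scoring import cox_scores_matrix

logger = logging.getLogger(__name__)

__all__ = ["SimConfig", "SimTruth", "SimDataset", "generate", "realized_stats"]


@dataclass
class SimConfig:
    """Generator settings; defaults describe a trauma-cohort-scale study:
    150 training samples, 200 candidate pathways of which 5 are
    informative, ~30% censoring."""

    n_genes: int = 3200
    n_train: int = 150
    n_test: int = 150
    n_sets: int = 200
    set_size_min: int = 8
    set_size_max: int = 15
    n_informative_sets: int = 5
    loading: float = 0.3
    noise_sd: float = math.sqrt(1.0 - 0.09)
    beta_factor: float = 1.0
    beta_factor_sd: float = 0.0  # if > 0, per-factor betas ~ N(0, sd) (graded signal)
    factor_correlation: float = 0.5  # pairwise correlation of pathway factors
    orphan_fraction: float = 0.0
    n_direct_orphans: int = 0
    beta_orphan: float = 0.15
    baseline_hazard: float = 0.1
    censoring_rate: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_genes, self.n_train, self.n_test, self.n_sets) < 1:
            raise ValidationError("counts must be positive")
        if not 0 <= self.orphan_fraction < 1:
            raise ValidationError("orphan_fraction must be in [0, 1)")
        if not 0 <= self.factor_correlation < 1:
            raise ValidationError("factor_correlation must be in [0, 1)")
        if not 0 <= self.censoring_rate < 1:
            raise ValidationError(
                f"infeasible censoring target {self.censoring_rate}: must be in [0, 1)"
            )
        if self.set_size_min < 1 or self.set_size_max < self.set_size_min:
            raise ValidationError("bad set size range")
        if self.n_informative_sets > self.n_sets:
            raise ValidationError("more informative sets than sets")


@dataclass
class SimTruth:
    """Ground truth of one simulated cohort."""

    informative_sets: list[str]
    orphan_sets: list[str]  # pathways excluded from the annotated collection
    orphan_genes: list[str]  # genes of orphan pathways + direct-effect orphans
    factor_betas: np.ndarray  # per informative/orphan factor, annotation order
    factors_train: np.ndarray  # (n_factors, n_train)
    factors_test: np.ndarray
    linear_predictor_train: np.ndarray
    linear_predictor_test: np.ndarray


@dataclass
class SimDataset:
    expr_train: ExpressionMatrix
    expr_test: ExpressionMatrix
    surv_train: SurvivalData
    surv_test: SurvivalData
    collection: GeneSetCollection
    truth: SimTruth
    config: SimConfig = field(repr=False, default=None)


def _censoring_rate_for_target(event_rates: np.ndarray, target: float) -> float:
    """Solve E[ lam_c / (lam_c + lam_j) ] = target for the censoring rate."""

    def expected(log_lc: float) -> float:
        lc = math.exp(log_lc)
        return float(np.mean(lc / (lc + event_rates))) - target

    lo, hi = -30.0, 30.0
    if expected(lo) > 0 or expected(hi) < 0:
        raise ValidationError(f"infeasible censoring target {target}")
    return math.exp(optimize.brentq(expected, lo, hi, xtol=1e-12))


def generate(cfg: SimConfig) -> SimDataset:
    """Draw one train/test cohort pair; bit-reproducible from cfg.seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_all = cfg.n_train + cfg.n_test

    sizes = rng.integers(cfg.set_size_min, cfg.set_size_max + 1, size=cfg.n_sets)

    # orphan pathways: extra factor-driven gene groups absent from the
    # annotation, sized like ordinary sets, count chosen so their genes
    # make up ~orphan_fraction of all factor-signal genes
    n_orphan_sets = 0
    orphan_sizes = np.empty(0, dtype=int)
    if cfg.orphan_fraction > 0 and cfg.n_informative_sets > 0:
        informative_genes = int(sizes[: cfg.n_informative_sets].sum())
        mean_size = 0.5 * (cfg.set_size_min + cfg.set_size_max)
        want = cfg.orphan_fraction / (1 - cfg.orphan_fraction) * informative_genes
        n_orphan_sets = max(1, round(want / mean_size))
        orphan_sizes = rng.integers(
            cfg.set_size_min, cfg.set_size_max + 1, size=n_orphan_sets
        )

    # every pathway — informative, decoy and orphan — is a disjoint
    # co-expression module with its own latent factor; only the
    # informative and orphan factors drive the hazard. Structured but
    # non-prognostic decoy modules are what make "select liberally and
    # average everything" a bad strategy, as in real transcriptomes.
    n_hazard = cfg.n_informative_sets + n_orphan_sets
    module_sizes = np.r_[sizes, orphan_sizes].astype(int)  # annotated sets, then orphans
    n_modules = module_sizes.size
    n_module_genes = int(module_sizes.sum())
    needed = n_module_genes + cfg.n_direct_orphans
    if needed > cfg.n_genes:
        raise ValidationError(
            f"n_genes={cfg.n_genes} too small for {n_module_genes} module genes "
            f"+ {cfg.n_direct_orphans} direct orphans"
        )

    gene_ids = [f"G{i:05d}" for i in range(cfg.n_genes)]
    values = rng.standard_normal((cfg.n_genes, n_all))

    # hazard-linked factors share a common severity axis (pairwise
    # correlation factor_correlation); decoy-module factors are
    # independent of it and of each other
    factors = rng.standard_normal((n_modules, n_all))
    if n_hazard:
        shared = rng.standard_normal(n_all)
        rho = cfg.factor_correlation
        hazard_pos = np.r_[
            np.arange(cfg.n_informative_sets),
            np.arange(cfg.n_sets, cfg.n_sets + n_orphan_sets),
        ].astype(int)
        factors[hazard_pos, :] = (
            math.sqrt(rho) * shared[None, :] + math.sqrt(1.0 - rho) * factors[hazard_pos, :]
        )
    else:
        hazard_pos = np.empty(0, dtype=int)

    pos = 0
    blocks: list[np.ndarray] = []
    for m in range(n_modules):
        rows = np.arange(pos, pos + module_sizes[m])
        values[rows, :] = cfg.loading * factors[m] + cfg.noise_sd * values[rows, :]
        blocks.append(rows)
        pos += module_sizes[m]
    direct_rows = np.arange(pos, pos + cfg.n_direct_orphans)

    # annotated collection: one set per annotated module; orphan modules
    # are never annotated
    names = [f"PW{i:04d}" for i in range(cfg.n_sets)]
    sets = {
        names[i]: frozenset(gene_ids[r] for r in blocks[i]) for i in range(cfg.n_sets)
    }
    collection = GeneSetCollection("synthetic", sets)

    if cfg.beta_factor_sd > 0:
        # graded signal: every hazard factor gets its own coefficient
        hazard_betas = rng.normal(0.0, cfg.beta_factor_sd, size=n_hazard)
    elif n_hazard:
        # equal-effect factors: beta_factor is the log-HR per SD of the
        # aggregate pathway signal, so the coefficients are normalized by
        # the theoretical SD of sum(f_s) under the factor correlation
        agg_sd = math.sqrt(n_hazard + n_hazard * (n_hazard - 1) * cfg.factor_correlation)
        hazard_betas = np.full(n_hazard, cfg.beta_factor / agg_sd)
    else:
        hazard_betas = np.empty(0)
    eta = hazard_betas @ factors[hazard_pos, :] if n_hazard else np.zeros(n_all)
    if cfg.n_direct_orphans:
        eta = eta + cfg.beta_orphan * values[direct_rows, :].sum(axis=0)

    rates = cfg.baseline_hazard * np.exp(eta)
    t_event = rng.exponential(1.0 / rates)
    if cfg.censoring_rate > 0:
        lam_c = _censoring_rate_for_target(rates, cfg.censoring_rate)
        t_cens = rng.exponential(1.0 / lam_c, size=n_all)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(n_all, dtype=int)

    train_ids = [f"TR{j:04d}" for j in range(cfg.n_train)]
    test_ids = [f"TE{j:04d}" for j in range(cfg.n_test)]
    tr = slice(0, cfg.n_train)
    te = slice(cfg.n_train, n_all)

    orphan_set_names = [f"ORPHAN{i:02d}" for i in range(n_orphan_sets)]
    orphan_genes = [gene_ids[r] for b in blocks[cfg.n_sets:] for r in b]
    orphan_genes += [gene_ids[r] for r in direct_rows]

    hazard_factors = factors[hazard_pos, :]
    truth = SimTruth(
        informative_sets=names[: cfg.n_informative_sets],
        orphan_sets=orphan_set_names,
        orphan_genes=orphan_genes,
        factor_betas=hazard_betas,
        factors_train=hazard_factors[:, tr].copy(),
        factors_test=hazard_factors[:, te].copy(),
        linear_predictor_train=eta[tr].copy(),
        linear_predictor_test=eta[te].copy(),
    )
    return SimDataset(
        ExpressionMatrix(gene_ids, train_ids, values[:, tr].copy()),
        ExpressionMatrix(gene_ids, test_ids, values[:, te].copy()),
        SurvivalData(train_ids, time[tr], event[tr]),
        SurvivalData(test_ids, time[te], event[te]),
        collection,
        truth,
        replace(cfg),
    )


def realized_stats(data: SimDataset) -> dict:
    """Empirical summaries of a generated cohort (training half).

    Returns censoring fraction, mean within-set pairwise member
    correlation (per annotated set and averaged), and marginal per-gene
    Cox scores.
    """
    expr, surv = data.expr_train, data.surv_train
    cens = 1.0 - surv.event.mean()
    gidx = expr.gene_index()
    per_set: dict[str, float] = {}
    for name, members in data.collection.sets.items():
        rows = [gidx[g] for g in members if g in gidx]
        if len(rows) < 2:
            continue
        corr = np.corrcoef(expr.values[rows, :])
        off = corr[np.triu_indices_from(corr, k=1)]
        per_set[name] = float(off.mean())
    gene_scores = cox_scores_matrix(expr.values, surv.time, surv.event)
    return {
        "censoring_fraction": float(cens),
        "set_correlations": per_set,
        "mean_informative_correlation": float(
            np.mean([per_set[s] for s in data.truth.informative_sets if s in per_set])
        ) if data.truth.informative_sets else float("nan"),
        "gene_cox_scores": dict(zip(expr.gene_ids, gene_scores)),
    }
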