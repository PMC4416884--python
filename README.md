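# pathrisk

Hybrid gene-set + single-gene prediction of censored survival risk from
gene expression profiles.

Predicting patient survival from transcriptomes with a few hundred
samples and tens of thousands of genes is dominated by selection noise:
the genes picked on one cohort rarely reproduce on the next. `pathrisk`
attacks this by scoring *gene sets* — pathways, regulons, positional
bands — alongside individual genes in one pooled feature family. Set
summaries average measurement noise over their members and reproduce
better across cohorts, while single genes (treated as one-member
"pseudo gene sets") catch signal that pathway annotation misses. The
package is for computational biologists and biostatisticians building
expression-based prognostic scores, and it ships a synthetic cohort
generator so every component is testable without any external data.

## The method

Given training expression e_ij, censored outcomes (t_j, δ_j) and a
gene-set collection:

1. **Summarize.** Standardize each gene (training μ_i, σ_i). Each set
   g with N_g measured members gets the maxmean index
   u_gj = absmax[ (1/N_g)Σ(e'_ij)+, (1/N_g)Σ(e'_ij)− ], rescaled to the
   averaged member moments: x_gj = u'_gj·sqrt(Σσ_i²/N_g) + Σμ_i/N_g.
   A singleton set reproduces its gene exactly, so genes and sets are
   exchangeable features.
2. **Score.** Every feature gets the Cox score statistic
   s = U(0)/√I(0) (score test of the partial likelihood at β = 0,
   Breslow ties) — asymptotically N(0,1) under the null, so |s| is
   comparable across feature kinds.
3. **Select.** The |s| threshold is chosen by 3-fold cross-validation
   repeated 100 times inside the training set, maximizing the held-out
   Cox likelihood-ratio of the predicted risk.
4. **Predict.** Selected features are centered, weighted by their
   member counts, and stacked into diag(N_1..N_k)·[x_1ᵀ;…;x_kᵀ]; the
   first principal component of this weighted matrix is the predictor
   (plain PCA when all N_i = 1). Risk of a new sample is its projection
   on the loading vector, oriented so higher risk ⇒ shorter survival.
5. **Evaluate.** Cox likelihood ratio, Harrell's C, Cox–Snell R², and
   the median-split log-rank p.

See `docs/methods.md` for assumptions, numerical choices and
limitations.

## Worked example

```python
from pathrisk import SimConfig, generate, GeneSetRiskModel

data = generate(SimConfig(n_genes=700, n_sets=40, n_informative_sets=5,
                          n_train=100, n_test=100, seed=7))
model = GeneSetRiskModel(data.expr_train, data.surv_train,
                         data.collection, mode="hybrid")
res = model.fit(n_repeats=20, seed=7)
print(res.summary())
report = res.evaluate(data.expr_test, data.surv_test)
```

prints

```
Hybrid gene-set survival predictor
==================================================
mode:               hybrid
training samples:   100 (68 events)
candidate features: 740
chosen |score| threshold: 0.8221  (by CV)
selected features:  332 (23 gene sets, 309 single genes)
training Cox coef of PC score: 0.0293
--------------------------------------------------
top selected features by |Cox score|:
  GS:PW0004                    gene_set     N=12   score=+3.712
  SG:G00059                    single_gene  N=1    score=+3.518
  GS:PW0000                    gene_set     N=15   score=+3.415
  ...
```

and the held-out evaluation gives

```
test LR=14.82  C=0.663  R2=0.138  logrank_p=1.12e-03
```

Reading this: the cohort has 40 candidate pathways of which 5 truly
carry hazard; the CV-chosen threshold (0.82 on the |Cox score| scale)
keeps 332 features, and the five planted pathways (PW0000–PW0004) are
all among the selected gene sets, three of them in the top of the
ranking. On the independent 100-sample test cohort the risk score
separates survival strongly: concordance 0.663 and a median-split
log-rank p of 1.1×10⁻³.

The same pipeline runs from the shell:

```bash
pathrisk simulate --seed 7 --out-dir data/
pathrisk train --expression data/expression_train.tsv \
               --survival data/survival_train.tsv \
               --gmt data/gene_sets.gmt --seed 7 --out-dir fit/
pathrisk predict --predictor fit/predictor.json \
                 --expression data/expression_test.tsv --out risk.tsv
pathrisk evaluate --risk risk.tsv --survival data/survival_test.tsv \
                  --out report.json
```

Modes `hybrid`, `geneset_only` and `single_gene_only` expose the three
predictors the method compares.

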