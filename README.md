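# empowermap

Tools for studying geographic structure in women's empowerment as
measured by categorical household-survey items: k-modes classification of
respondents into empowerment categories, PSU-level spatial summaries, and
a fully Bayesian multinomial logit structured geo-additive regression
(STAR) that separates individual sociodemographic composition from a
spatially structured regional signal.

The intended users are quantitative demographers and spatial
epidemiologists working with DHS-style surveys: respondents nested in
primary sampling units (PSUs, ~15–100 women each), PSUs nested in
first-level administrative regions, with jittered PSU coordinates (up to
2 km urban / 5 km rural) and a region adjacency graph. Because such
microdata are access-restricted, the package ships a synthetic-data
generator that emulates this structure from a known ground truth, so
every stage — classification, mapping, estimation, model comparison — is
testable offline.

## The analysis

**Stage 1 — classification.** Each respondent's ten nominal items (five
wife-beating-justification attitudes, four household decision-making
items, one refuse-sex attitude) are classified by k-modes clustering with
simple matching distance, primed with five conceptually meaningful
initial modes: *more empowered*, *less empowered*, *modal empowered*,
*autonomous*, *other*. Iteration is batch (Lloyd-style) with
deterministic tie-breaks, so results are independent of respondent order.

**Stage 2 — mapping.** Per PSU, the shares (p1, p2, p3) of respondents in
the three dominant categories are blended into an RGB colour
(blue = more, red = less, green = modal empowered) for dense visual
assessment; minority categories are excluded from the denominators.

**Stage 3 — the STAR model.** With category 3 as reference
(η<sub>ij3</sub> = 0), for k = 1, 2:

    η_ijk = x_ij' β_k + f_k(a_ij) + b_{u(ij),k} + s_{jk}

* `x_ij` — intercept plus 7 dummies (urban; education primary,
  secondary+; income quintiles above poorest), flat prior on β_k;
* `f_k` — cubic P-spline in age on 20 equidistant knot intervals (M = 23
  basis functions), second-order random-walk prior on the coefficients;
* `b_{u,k}` — iid N(0, τ²_{k,u}) PSU effects for the clustered design;
* `s_{jk}` — intrinsic Markov-random-field (ICAR) region effects:
  s_jk | neighbours ~ N(mean of neighbours, τ²_{k,s}/N_j), constrained to
  sum to zero;
* τ² ~ IG(0.001, 0.001) throughout.

Estimation is by Gibbs sampling with exact Pólya-Gamma augmentation (the
partial-logit reduction makes every conditional Gaussian or
inverse-gamma; no proposal tuning). The *full* model is compared against
the *null* model (no s term) by DIC = D̄ + p_D with p_D = D̄ − D(θ̄), and
by Moran's I of region-aggregated posterior-median PSU effects — if a
real spatial signal exists, the full model should both win on DIC and
absorb the residual spatial autocorrelation out of the PSU effects.

## Worked example

```python
import numpy as np
import empowermap as em

graph = em.build_region_lattice(4, 4)                  # 16 regions, rook adjacency
truth = em.GroundTruth(
    beta=np.vstack([[0.3, 0.4, 0.3, 0.6, 0.0, 0.1, 0.2, 0.4],
                    [-0.3, -0.4, -0.3, -0.6, 0.0, -0.1, -0.2, -0.4]]),
    region_sd=0.8, epsilon=0.05)
survey, truth = em.simulate_survey(graph, truth, psus_per_region=4,
                                   respondents_per_psu_range=(15, 30),
                                   seed=2, lattice_shape=(4, 4))
assignment = em.fit_kmodes(survey)                     # primed k-modes
design = em.build_design(survey, assignment.labels)
fit = em.mcmc_fit(design, graph=graph, spatial=True, seed=3,
                  settings=em.McmcSettings(2000, 500, 5))

from sklearn.metrics import adjusted_rand_score
print("ARI vs generating labels:", adjusted_rand_score(truth.labels, assignment.labels))
print("DIC:", fit.dic())
s_med = np.median(fit.pooled("s"), axis=0)
print("corr(s_med, s_true):", np.corrcoef(s_med[0], truth.s[0])[0, 1])
```

Output (n = 1944 respondents):

```
ARI vs generating labels: 0.9982228843824108
DIC: DicResult(dbar=3275.241614759894, dhat=3204.011381903413,
               p_d=71.23023285648105, dic=3346.4718476163753)
corr(s_med, s_true): 0.9125353331951778
```

The classification recovers the generating categories almost perfectly
(adjusted Rand index 0.998), and the posterior medians of the structured
region effects track the generating spatial field (r ≈ 0.91). The same
analysis runs from the shell:

```sh
empowermap pipeline --seed 7 --out rundir/   # simulate → cluster → map → fit → compare
```

which writes `survey.csv`, `labels.csv`, `map.csv`, the two fit
directories, `dic_comparison.csv`, `morans_comparison.csv`,
`diagnostics.csv` (Geweke z-scores, and Gelman–Rubin PSRFs for
multi-chain runs) and a run log with all derived stage seeds.

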