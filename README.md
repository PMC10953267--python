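# panelnet

Two-wave panel network analysis for psychometric data: contemporaneous
partial-correlation networks, cross-lagged panel networks, centrality
indices, and bootstrap accuracy/stability diagnostics.

## The problem

Developmental and clinical researchers increasingly model sets of parenting
practices and youth mental-health problems as *networks*: nodes are scale
variables, edges are conditional associations. With two measurement waves a
study can ask both *what hangs together now* and *what predicts what later*:

* **Contemporaneous network (per wave).** A Gaussian graphical model whose
  edges are partial correlations, estimated by the graphical lasso —
  L1-penalized maximum likelihood on the precision matrix Θ, with edge
  weights `ρ_ij = −Θ_ij/√(Θ_ii Θ_jj)` — and the penalty chosen by the
  Extended BIC, `EBIC = −2ℓ + E log n + 4Eγ log p` (γ = 0.5).
* **Temporal network (T1 → T2).** A cross-lagged panel network: each T2
  variable is regressed on *all* T1 variables with LASSO,
  `min (1/2n)‖y − Xβ − β₀‖² + λ‖β‖₁`, λ per node by 10-fold CV. The
  directed matrix `d[i,j]` holds T1-i → T2-j coefficients; the diagonal
  carries the (dominant) autoregressive paths.
* **Centrality.** Expected influence `EI(i) = Σ_{j≠i} w_ij` for undirected
  networks; signed in-/out-prediction sums for the temporal network, in a
  cross-lagged variant (autoregressive path excluded) and a cross-construct
  variant (within-construct edges also excluded).
* **Stability.** Nonparametric bootstrap percentile CIs for every edge;
  case-drop bootstrap correlation-stability (CS) coefficients for
  centralities (CS < 0.25 = unstable, ≥ 0.50 = comfortable); paired
  bootstrap difference tests for edges and centralities.

All preprocessing is included: Likert scale scoring with reverse-keying,
Cronbach's-alpha reliability screening (a scale is dropped only when
α < 0.60 at *both* waves), per-scale descriptives, and OLS
residualization on covariates so the networks are covariate-adjusted.

Because raw dyadic panel data of this kind are rarely shareable, the
package ships a fully specified synthetic generator
(`panelnet.synthetic`): two waves of nine scales (five parenting practices,
four mental-health problems) with a known sparse partial-correlation
structure, a known stable VAR(1) transition matrix, covariate effects, and
item-level Likert measurement calibrated to per-wave reliability targets.
Every estimator in the package is validated against this ground truth.

## Worked example

Simulate a 591-dyad panel, then estimate both kinds of network from the
command line (the library API offers the same steps as scikit-learn-style
estimators — `GaussianGraphicalModel`, `CrossLaggedPanelNetwork`,
`CovariateResidualizer`):

```bash
panelnet simulate --n 591 --seed 1 --out panel.csv
panelnet ggm panel.csv --out edges.csv
```

```text
                 node_a               node_b  weight_t1  weight_t2  weight_avg
0               anxiety           depression       0.43       0.17        0.30
1                warmth  inductive_reasoning       0.30       0.10        0.20
2             hostility            harshness       0.27       0.10        0.19
3            aggression     conduct_problems       0.37       0.00        0.18
4                warmth           monitoring       0.27       0.00        0.14
...
11           monitoring     conduct_problems       0.00      -0.06       -0.03
12               warmth            hostility      -0.07       0.00       -0.04
```

Each row is one undirected edge: the partial correlation between two scales
at T1 and at T2 (exact zeros were shrunk away by the graphical lasso), and
their cross-wave average, rounded half-away-from-zero. The strong
within-construct edges (anxiety–depression, warmth–inductive reasoning,
hostility–harshness) and the weak negative monitoring–conduct bridge mirror
the generator's ground truth, attenuated by Likert measurement at this
sample size.

```bash
panelnet clpn panel.csv --seed 1 --out clpn.csv
```

```text
              from_node              to_node     d
0               anxiety           depression  0.18
1            depression              anxiety  0.17
2             harshness            hostility  0.16
3                warmth  inductive_reasoning  0.14
4             hostility           depression  0.13
```

Each row is a directed cross-lagged edge: an unstandardized LASSO
coefficient of a T1 scale predicting a T2 scale, autoregressive paths
excluded from the view. The generator's three strongest planted paths
(hostility→depression, harshness→hostility, anxiety→depression) head the
table.

The full pipeline — scoring, reliability screening, residualization, both
networks, centralities, layout, bootstrap CIs, CS coefficients, difference
tests, and a replayable manifest — runs from a YAML config:

```bash
panelnet run config.yaml      # writes CSVs/GraphML + manifest.json
panelnet replay out/manifest.json   # re-executes and verifies byte-identity
```

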