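# agbridge — adaptive group bridge estimation for partially linear models

`agbridge` fits the semiparametric regression model

    y_i = x_i' beta + f(u_i) + eps_i,        i = 1..n,

where the covariates `x` come in predefined groups (dummy blocks of a
categorical factor, basis expansions, genes in a pathway, ...), `f` is an
unknown smooth function of a scalar index `u` in [0, 1], and the goal is to
decide **which whole groups belong in the model** while estimating their
coefficients and `f` jointly. It is aimed at biostatistical / epidemiological
regression problems with many candidate grouped covariates (the number of
groups may grow with n) and one continuous confounder to be modelled
flexibly.

## The estimator

The smooth term is approximated in a normalized B-spline sieve
`f(u) ≈ B(u)'alpha` (cubic, q_n = 7 basis functions by default). With
`Z` the basis matrix and `H = Z(Z'Z)^{-1}Z'` its projection, `alpha` is
profiled out, leaving the penalized objective in beta alone:

    Q_n(beta) = ||(I-H)(Y - X beta)||^2 + sum_j lambda_j ||beta_j||^gamma,

a **group bridge** penalty on the group L2 norms. With exponent
`0 < gamma < 1` the penalty is concave and removes whole groups. The
**adaptive** variant weights each group by an initial profiled
least-squares estimate, `lambda_j = lambda / ||beta_j^(0)||`, so likely-null
groups are penalized more heavily; this is the estimator with the oracle
property (it selects exactly the true groups with probability tending to
one and estimates them at the efficient rate). `gamma = 1` with constant
weights is the group lasso, included as a comparator.

Optimization is by iterated **local quadratic approximation (LQA)**: each
step replaces the penalty by its tangent majorizer in `||beta_j||^2` and
solves a ridge system on the currently active groups; any group whose norm
falls below 1e-3 is set exactly to zero and dropped. `(lambda, gamma)` are
tuned by leave-one-observation-out cross-validation computed with the
ridge hat-matrix shortcut (no refitting).

## Worked example

```python
import numpy as np
from agbridge import PartiallyLinearGroupBridge, SimScenario, simulate_dataset

# 500 observations, 10 groups of 3 covariates, 3 truly active groups,
# smooth term cos(2*pi*u), noise sd 1
y, X, u, sizes, beta_true = simulate_dataset(
    SimScenario(n=500, p_n=10, sigma=1.0, seed=7))

model = PartiallyLinearGroupBridge(y, X, u, sizes)
res = model.fit(method="agb", denominator_power=2)   # CV-tuned (lambda, gamma)
print(res.summary())
```

```
Partially linear model — Adaptive group bridge
========================================================================
n obs: 500        groups: 10       covariates: 30       spline dim q_n: 7
lambda: 14.788       gamma: 0.75     iterations: 6      converged: True
selected groups: 3/10 ['g1', 'g2', 'g3']
residual scale sigma^2_hat: 0.98871
------------------------------------------------------------------------
group       coef            estimate     std err
g1          x1                0.5390      0.0561
            x2                1.0238      0.0546
            x3                1.4780      0.0582
g2          x4                1.0006      0.0574
...
```

The selected set {g1, g2, g3} is exactly the generating support (true
coefficients (0.5, 1, 1.5), (1, -1, 1), (0.5, 0.5, 0.5)); the estimates sit
within about one standard error of them, and the residual variance estimate
0.989 matches the generating sigma^2 = 1. `res.f_hat(u_grid)` evaluates the
spline estimate of the smooth term, `res.cv` holds the CV surface, and
`res.predict(X_new, u_new)` combines both parts for held-out data.

The same functionality is available from the shell:

```sh
agbridge simulate --n 500 --pn 10 --sigma 1 --seed 7 --out d.csv --groups-out g.csv
agbridge fit --data d.csv --groups g.csv --method agb
agbridge benchmark --pn 10 --sigma 0.5 --sigma 1 --reps 100 --seed 1 --out bench.csv
```

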