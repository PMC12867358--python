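# Methods

## The selection problem

Given a numeric cross-sectional table, which imputation method should fill
its missing cells?  The package answers by competition on the dataset
itself: insert artificial ("diagnostic") missing values whose truth is
known, score every candidate on how well it reconstructs them, and treat
performance on artificial gaps as the predictor of performance on the real
("persistent") ones.  The split mirrors a validation/test split: diagnostic
cells drive selection; persistent cells are touched once, by the winner.

## Masking model

Masking is per-cell Bernoulli with probability `p_miss` (default 0.1) over
the eligible cells (observed, not persistent).  Under MCAR every eligible
cell has the same probability.  Under MNAR the probability for cell (i, j)
is `p_miss · w(q_ij; s) / mean(w)` with `w(q; s) = exp(s·q)` and `q_ij` the
cell's mid-rank quantile within column j; `s = 0` recovers MCAR, positive
`s` preferentially masks large values.  The exponential family was chosen
as the simplest one-parameter monotone tilt that normalizes to a fixed
expected masking fraction.  Safeguards redraw a mask (up to 100 times,
distinct sub-seeds) until every column keeps at least 2 observed cells and
every row at least 1, and each diagnostic iteration masks at least one cell
(otherwise no metric is computable).  Diagnostic sets are drawn
independently per iteration and may overlap across iterations, never with
the persistent set.  When the input table already has real missing cells,
those cells *are* the persistent set and are never diagnostic candidates.

## Metrics and gating

Per (method, variable, iteration), with y the truth and y′ the imputation
at the diagnostic cells of that variable:

* `RMSD = sqrt(median((y′ − y)^2))` — robust error magnitude.
* `MD = |median(y′ − y)|` — consistent over-/under-estimation.  The
  absolute value sits outside the median: only that form vanishes for
  sign-balanced errors, which is what "no directional bias" means.
* `rBias = |b1|`, the Theil–Sen slope of d = y′ − y on the pair mean
  (y′ + y)/2 — the Bland–Altman notion of value-dependent bias, estimated
  rank-based; fewer than 3 pairs, or all-identical pair means, give 0.
* `zDelta = mean|y′ − y| / s` with m, s the mean and sd (ddof = 1) of the
  complete pre-masking column — the scale-free accuracy reported to users.
  When the input table itself is incomplete, the observed cells substitute
  for the complete column.

Gating sets a metric to zero when its deviation from zero is not
significant at `gate_alpha = 0.1` (configurable): MD by the two-sided
one-sample Wilcoxon signed-rank test of d against 0; RMSD by the same test
applied to |d| (an error-magnitude metric must not be excusable by sign
balance — otherwise a filler with large alternating errors would pass
every gate and outrank genuine methods); rBias by the two-sided Kendall-τ
association test between d and the pair means.  The signed-rank p-value
uses the exact null distribution for n ≤ 25 (dynamic programming over
tie-averaged doubled ranks, so ties are handled exactly) and the normal
approximation with continuity and tie correction above.  All-zero
differences give p = 1.

## References

Poisoned pseudo-imputers consult the truth y of each masked cell and
deliberately distort it, with E the median absolute observed value of the
cell's column in the masked table (so references never see more truth than
the one value they replace):

* PLUS: `y + c·E` (default c = 0.5) — pure shift, caught by MD.
* FACTOR: `y·(1 + c)` (default c = 0.5) — proportional bias, caught by
  rBias; its Bland–Altman slope on positive columns is exactly c/(1 + c/2).
* PLUSMINUS: `y + (−1)^i (1 + c) E` (default c = 0.1), alternating by the
  cell's row-ascending ordinal i within its column — mean-preserving,
  invisible to MD, caught by RMSD.

All three return the constant 1 when E = 0.  The calibrating ladder
tinyNoise_c returns `y + U(−c, +c)·E` for
c ∈ {10⁻⁶, 10⁻⁵, 10⁻⁴, 10⁻³, 0.01, 0.05, 0.1, 0.2, 0.5, 1}.  References
compete in the ranking (a poisoned method reaching cABC category A yields
an "imputation not advisable" warning) but are never selectable as winner;
calibrating methods are additionally excluded from categorization and
reported as a separate ladder.  References only fill cells whose truth is
known; they are evaluation devices, not final imputers.

## Ranking, standardization, cABC

Each (variable, iteration, metric) slice ranks the gated metric across all
M methods ascending with tie averaging; failed methods are forced to the
bottom (ties among failures averaged among themselves).  A method's score
is `R_m = mean over slices of (rank_RMSD + rank_MD + rank_rBias)/3`.  Under
the null of equal quality, R_m is a mean of d = V·k uniform ranks
(Irwin–Hall), approximated as Gaussian with mean m = (M + 1)/2 and spread
s = M/√(12·d); `Z = (R_m − m)/s`, p = Φ(Z).  The spread formula is kept in
this printed form for comparability; the variance-exact alternative
√((M² − 1)/(12·d)) is available via `corrected_variance=True` and changes Z
by the factor M/√(M² − 1) (< 0.2% for M ≥ 15).  `d` counts the slices
actually ranked; it equals V·k whenever every column receives a diagnostic
cell in every iteration, which holds at default sizes.

ABC scores are `Z²` for Z < 0, else 0.  Computed-ABC builds the cumulative
contribution curve over items sorted by descending score; the A|B boundary
is the curve point closest to the ideal (0, 1), the B|C boundary the last
item before the discrete slope first falls to ≤ 1; zero-score items are
always C, and an all-equal positive score vector (a flat curve of unit
slopes) degenerates to A = {first item}.  Under the null about a fifth of
methods reach A by chance with this boundary; category A is meaningful
relative to the poisoned/calibrating anchors, not in isolation.

The winner minimizes R_m among genuine (univariate/multivariate) methods,
ties broken by lower mean raw RMSD, then name.  The best univariate and
best multivariate methods' per-(variable, iteration) zDelta pools are
compared with a weighted ECDF-distance statistic
`Σ |F1 − F2| / sqrt(t(1 − t))` over pooled order statistics (t the pooled
ECDF height, endpoints excluded; p by seeded permutation, default 2000) and
the two-sided Wilcoxon rank-sum test, combined as Fisher's
X² = −2(ln p₁ + ln p₂) on 4 degrees of freedom.

## Imputer implementations

All methods run through one signature and return an outcome; any internal
exception is captured as a failure whose cells stay missing, and failed
(method, iteration) pairs are listed in the report and rank last.  Observed
cells are never altered.

* mode: most frequent observed value, ties toward the smallest; all-unique
  columns fall back to the half-sample mode (recursively keep the
  smallest-range half).
* kNN: standardized Euclidean distance over pairwise-complete columns,
  divided by the shared-column count; neighbour ties broken by row order;
  k clamped to the donor count; fill = mean of the k nearest donors'
  values.
* Chained equations (linear / pmm / cart / rf): median-initialize, then 5
  cycles visiting incomplete columns left to right, regressing each on all
  others.  Linear draws prediction + Gaussian noise at the residual sd (a
  tiny ridge keeps singular designs solvable); pmm draws among the 5
  observed donors with closest fitted values; cart draws from the donor
  leaf of a regression tree (minimum leaf 5); the rf variant draws from a
  random forest tree's donor leaf.
* Iterative random forest (missForest-style): median-initialize, sweep
  columns by ascending missingness, refit a forest per column, and stop at
  the first increase of the summed squared change in the imputed values
  (returning the previous sweep), or after 10 sweeps.
* Forests are explicit bagged regression trees (bootstrap per tree,
  terminal node size 5, mtry = p/3 as is conventional for regression
  forests), 25 trees by default (`n_trees`, config-exposed): with at most a
  handful of predictor columns the ensemble mean stabilizes well below 100
  trees, and the explicit loop keeps per-fit overhead low.  Bagged-trees
  imputation averages 25 full-split-search trees per target column in a
  single pass.
* EM multivariate normal: EM on the incomplete data for (μ, Σ) (maximum
  likelihood, rows grouped by missing-data pattern; tolerance 1e−8, at most
  500 iterations, non-convergence is a captured failure), then each
  incomplete row is filled with a *draw* from the conditional normal given
  its observed cells.  The fit is deterministic and memoized per input
  matrix, so the 20 repeated draws of the `_repeated` variant reuse one
  fit.
* `_repeated` variants average 20 seeded replicates cell-wise, following
  the convention of averaging repeated stochastic imputations.

Determinism: every source of randomness derives from the run seed by
SHA-256 hashing of (seed, method, iteration, repeat) tags, so results are
bit-identical across repeated runs and for any `n_cores` (work
partitioning never changes random streams).

## Synthetic benchmarks

* `TwoLinearXY` (default n = 500, noise sd = 0.05): x uniform on [−1, 1];
  half the rows on y = x, half on y = −x; z = x plus independent noise;
  Gaussian noise of the given sd on y and z.  The x–z pair carries strong
  structure a multivariate method can exploit; the y column is *branch
  ambiguous* — nothing in (x, z) reveals the sign of y, so the best
  possible per-cell error on y is about |x| and the best achievable
  all-cell mean zDelta is on the order of 0.3 for any method.  The ranking
  still cleanly separates multivariate from univariate methods (the x and z
  columns decide it), which is what the benchmark is for.
* `UniformRandom3VarIndependent`: three i.i.d. uniform[0, 1] columns — pure
  noise; no method can beat the column marginals, and the comparison should
  not anoint a clear winner.
* `Hepta`: seven isotropic Gaussian clusters (sd 0.3) at the origin and the
  six axis points at distance 3, sizes as equal as possible, labels
  returned for downstream clustering studies.  Coordinates are regenerated,
  not bundled.

What these generators do not emulate: heavy tails, measurement floors and
ceilings, mixed scales, correlated missingness across variables, and
block/monotone dropout.  Passing tests on them shows the machinery ranks
methods correctly where the data structure is known; it does not promise a
particular accuracy on real biomedical tables.

## Problem sizes used in the shipped checks

The end-to-end accuracy check runs the full 35-method registry at n = 500,
k = 10 (a few minutes on one CPU).  Multi-seed placement and
generalization checks run 20 seeds at n = 200, k = 3 with the 14
fast genuine methods (all univariate, all kNN, linear, pmm, cart, bagged
trees, EM) plus all references — the repeated forest variants add runtime
but no information to those particular properties.

## Known limitations

* MAR mechanisms conditioned on other observed columns, and block/monotone
  missingness, are out of scope.
* Categorical variables are rejected, not encoded.
* The poisoned references cannot reproduce one qualitative claim sometimes
  made for such designs — that on pure-noise data a poisoned method ranks
  among the best.  With these formulas, PLUS/FACTOR always retain a
  significant MD and PLUSMINUS's error magnitude (1 + c)·E exceeds any
  genuine fill's error on uniform noise, so all three rank mid-field or
  worse there.  The non-imputability signal on noise data comes instead
  from the absence of any genuine method ranking clearly ahead of the
  references and from the calibration ladder.
* The Gaussian approximation to the Irwin–Hall rank distribution is poor
  for very small V·k; with k = 1 and few variables, Z values are indicative
  only.
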