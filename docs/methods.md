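# Methods

## Model and assumptions

The framework treats knockout prediction as a one-step regression problem
on steady-state expression. For a target gene *T*, the objective genes that
are direct network neighbours of *T* each get a multiple linear regression
of their expression on the expression of *all* their own direct neighbours
(the target among them), fitted across spatial areas. A knockout replaces
the target's expression with zero in the fitted models and re-predicts the
objectives; nothing propagates further than this single regression step, so
indirect (multi-hop) consequences of a knockout are outside the model by
design.

Assumptions this rests on:

- **Linearity and stationarity.** Expression of an objective gene is an
  affine function of its neighbours' expression, with coefficients shared
  across all areas. Structure-specific biology enters only through the
  expression values themselves.
- **The network defines the model support.** Only direct neighbours enter a
  model; missing edges mean missing predictors, which is why robustness to
  network noise is measured explicitly (see rewiring below).
- **Symmetric neighbourhoods.** Regulatory direction, when present in the
  edge type, is kept as metadata but ignored by the construction.
- **Strictly positive expression.** The effect index divides by observed
  expression, so inputs are validated to exceed 1e-6; violations are
  rejected rather than floored, because flooring would silently distort
  relative changes.

## Effect and specificity indices

Per area, the knockout effect is the sum over objectives of
|E⁰(obj) − B| / E(obj), where E⁰ is the knockout prediction and the
baseline B is configurable:

- `baseline_mode="observed"` (default): B is the measured expression. This
  is the verbatim definition, and it entangles model misfit with the
  knockout effect — a model that fits poorly reports a nonzero "effect"
  even for a target with zero coefficient.
- `baseline_mode="predicted"`: B is the model's own baseline prediction,
  which isolates the target term exactly (a zero-coefficient target yields
  exactly zero effect). This mode backs the zero-effect invariant tests.

Structure effects are unweighted means of per-area effects within a
structure; the whole-set index is the unweighted mean over *all* areas (not
a mean of structure means), so larger structures weigh more. The
fold-change of a structure divides its effect by the mean over the other
structures; with all-zero other structures it is reported as +inf with a
flag. RankSpec ranks targets ascending on effect and on fold-change (ties
share the average rank), normalises each axis by its maximum rank value —
so genes tied at the top of an axis score 1.0 there — and averages the two.
Being rank-based, it is invariant under strictly monotone rescaling of
either axis.

Knockout predictions are plain linear extrapolations and may be negative;
the absolute value in the effect handles the sign and no clamping is
applied.

## Fitting, cross-validation, exclusion

Ordinary least squares over all areas; singular designs (collinear
neighbour sets, or more predictors than areas) fall back to the
minimum-norm pseudoinverse solution with a logged warning rather than
failing, because large neighbour sets are routinely collinear. The model
error is a repeated random-subsampling cross-validation: test sets of
⌈0.1·n⌉ areas drawn without replacement, the relative error
√(mean(((pred − obs)/obs)²)) on the test split, averaged over repetitions
(default 1000; smaller values are adequate for the small synthetic
problems in the test-suite, where the Monte-Carlo error of the CV estimate
is far below the 25% exclusion threshold). Splits come from a seeded
generator, and both areas and predictors are canonicalised to a sorted
order first, so the error is invariant to input ordering. Objective models
with error above `max_error` (default 0.25) are excluded; a target is
dropped only when none of its objective models survive, and the per-target
exclusion reasons are logged and counted in the run manifest because
surviving-model counts are a headline output.

## Networks

Edge scores above 1 are divided by 1000 on read (STRING's integer dialect),
and thresholds always apply on the [0, 1] scale. Duplicate edges keep the
maximum score and the union of type labels. Rewiring performs
degree-preserving double-edge swaps, rejecting self-loops and duplicates,
until ⌈fraction·|edges|⌉ edges have been replaced (each successful swap
replaces two); the degree of every node and the edge count are exactly
preserved, so downstream changes are attributable to mis-wiring alone.

The degree-matched connectivity null replaces every gene of a set with a
uniformly drawn gene of identical degree — never the gene itself, distinct
within a replicate — falling back to the nearest available degree with a
logged warning when a degree class is exhausted (hubs typically have unique
degrees). The empirical probability uses the (k+1)/(n+1) estimator so it is
never zero; the raw frequency k/n is reported alongside.

## Synthetic data: what it emulates, what it does not

`make_network` uses preferential attachment, giving the hub-dominated
degree distribution of real interaction networks; scores sit in
[0.9, 1.0], i.e. above the usual high-confidence threshold. `make_expression`
gives non-objective genes i.i.d. lognormal base expression (median ≈ 5,
shape 0.5, the right order for normalised microarray intensities) and each
objective a planted positive-coefficient linear model of its non-objective
neighbours: coefficients U(0.5, 1.5)/deg, intercept U(1, 5), plus Gaussian
noise proportional to the clean signal, so a correctly specified model's CV
error ≈ `noise_sd`. Non-positive draws are re-drawn, never clipped,
preserving the planted relationship. Objective-on-objective coefficients
are implicitly zero, which keeps the planted truth identifiable: the full
neighbour design stays full-rank and OLS recovers the planted coefficients
exactly at zero noise.

A planted structure-specific target has its coefficient inside every
objective model scaled per structure by the supplied multiplier. Its base
coefficient is calibrated to contribute a fixed share c = 0.25 of the
objective's mean signal: large enough that the knockout effect of the
planted target stands out from ordinary neighbours (whose share is ~1/deg),
yet small enough that the structure-varying term leaves a single global
linear fit inside the 25% exclusion threshold — for multiplier m = 3 and
equal structure sizes the worst-structure relative misfit is roughly
(4/3)·c/(1 + 3c) ≈ 0.19.

What the generator does **not** emulate: spatial autocorrelation between
neighbouring areas, probe-level measurement artefacts, non-linear or
saturating regulation, directionality of regulation, and correlated
expression between unlinked genes. Passing recovery tests therefore show
that the pipeline's machinery is correct under its own modelling
assumptions, not that those assumptions hold in real brain data.

The NOD1 fixture is a deterministic network reproducing a published worked
example of the target-centric construction: six objective neighbours with
neighbour-set sizes (27, 56, 25, 3, 141, 38), multiset total 290 and 219
unique nodes. Which nodes repeat is not determined by those counts; this
fixture puts the target in all six sets and shares two filler blocks (50
genes between the two largest sets, 22 between the largest and
third-largest), any other arrangement with the same counts being equally
valid.

## Statistical components

- **Mann-Whitney validation** is one-sided ("greater") by default because
  the scientific question is whether experimentally supported genes show
  *larger* predicted effects. The exact U distribution is used for small
  tie-free samples (product of sizes ≤ 10,000), the tie-corrected normal
  approximation otherwise; the exact path is verified against full
  enumeration in the tests.
- **Enrichment** is an upper-tail hypergeometric test per term with
  Benjamini-Hochberg correction across tested terms; an optional exclusion
  set removes, e.g., the objective genes themselves from the study set so
  enrichment is not dominated by the set the effects were computed against.
  The default universe is the genes shared by network and annotation.
- **Clustering** of structures uses the mismatch distance
  |union| − |intersection| between top-gene lists and average linkage by
  default (single/complete available); the tree serialises to Newick.
- **Known-target curve** bins genes by effect rank into equal-count bins
  and reports the fraction of known targets per bin.

## Numerical and design choices

- Ties in `top_n` break lexicographically and are logged; deterministic
  output was preferred over random tie-breaking everywhere.
- Objectives, predictors, areas and genes are processed in sorted order, so
  every result table is byte-reproducible for a given config and seed.
- One global seed fans out to per-stage, per-target child seeds through
  `numpy.random.SeedSequence` spawn keys (kept below 2^31), so stages can
  be re-run independently yet reproducibly.
- The expression scale is taken as given: all formulas apply verbatim to
  the input values, with no log transform assumed or applied.
- The per-structure effect table can optionally carry a column dividing
  each effect by the table-wide maximum, a dimensionless 0-1 scale useful
  for cross-target comparison.

## Known limitations

- One regression step only: no propagation of knockout effects through the
  network, and no multi-gene simultaneous knockouts.
- Observed-baseline effects conflate misfit with effect for poorly fitting
  models; use `baseline_mode="predicted"` to separate them.
- Identifier namespaces are not mapped: network, expression and gene sets
  must already share one gene namespace.
- The connectivity null conditions on exact degree; in networks whose hubs
  have unique degrees the nearest-degree fallback slightly blurs the null
  for those genes.
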