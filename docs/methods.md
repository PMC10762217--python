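# Methods

## The missingness model

pxmdc treats a metabolomics abundance matrix as an m × n table of nonnegative
intensities in which each missing cell was produced by one of two mechanisms:

- **MNAR (left-censoring).** Concentrations below the instrument's detection
  limit are not measured. In the mixed-missingness (MM) simulator this is
  modelled as a *single shared detection limit*: the MNAR set consists of the
  globally smallest values among cells of LOW-tier metabolites. The
  alternative — censoring each LOW metabolite at its own quantile — is equally
  defensible physically; the shared-limit reading matches the notion of one
  instrument threshold and is what the whole package uses (see
  "Identifiability" for its consequences).
- **MCAR (uniform).** Cells removed uniformly at random from whatever remains
  observed, drawn after the MNAR set so the two never collide. Missingness
  that depends only on observed covariates (MAR) is folded into MCAR: without
  ground truth the two are not distinguishable at the cell level, and
  imputation practice treats them alike.

Metabolite tiers come from one of two rules:

- **Percent rule** `(x, y, z)`: metabolites ranked by mean observed abundance,
  descending (ties broken by metabolite id, lexicographic); the first
  `round(x/100·m)` are HIGH, the next `round(y/100·m)` MEDIUM, the remainder
  LOW. Counts use round-half-up; the MEDIUM count is clamped so the three
  never exceed m.
- **Mean rule**: with g the grand mean of all cells, a metabolite with mean
  > g is HIGH, mean < g/10 LOW, otherwise MEDIUM. Inequalities are strict, so
  boundary equality resolves to MEDIUM.

Given a missing rate r and MNAR share α ∈ [0, 1], the simulator masks
k = round(r·m·n) cells, of which k_mnar = round(α·k) are MNAR (capped at the
LOW-tier cell count; any shortfall is reassigned to MCAR with a logged
warning). All draws are deterministic under the seed.

## Panning and the complete subset

Observed values are shifted to the leftmost columns per metabolite (order
preserved; labels dropped because column identity loses meaning). The first
w columns, w = min per-metabolite observed count, form the complete block the
search and training simulations run on. The 80% rule removes metabolites with
missing count strictly greater than 0.2·n ("exceeding 20%" read as strict).
The pipeline applies it automatically when w would fall below 10 columns — the
trigger width is our choice; 10 columns is the least we consider usable for
per-metabolite summary statistics.

## The search objective

A candidate `(x, y, z, α)` is scored by simulating missingness on the complete
subset at the observed overall missing rate, computing the per-metabolite
missing-rate vector (ordered by metabolite id), and taking the Euclidean
distance to the observed vector; the score is the arithmetic mean over 10
replicates. Replicate sub-seeds derive from (master seed, replicate index)
only — *common random numbers* — so every candidate sees identical draws and
the landscape is free of simulation jitter. The observed rate is the only rate
at which simulated and observed vectors are comparable, so it is fixed, not
searched.

Because the MNAR set depends on the parameters only through the LOW-tier count
and k_mnar, the objective is a function of that integer pair; evaluations are
cached exactly on it, which makes full enumeration cheap.

### Optimisers

- **PSO**: global-best topology, swarm 30, inertia 0.729, cognitive = social =
  1.49445 (standard constriction values), velocity clamped to half the
  coordinate range, at most 100 iterations with early stop after 20 iterations
  without improvement. Particles live in the box [0,100]² × [0,1] as
  (u₁, u₂, a) and decode as x = u₁, y = min(u₂, 100 − x), z = 100 − x − y,
  α = a, keeping coordinates interpretable and every grid point reachable.
- **Enumeration**: x, y, z over multiples of the step summing to 100, α from
  one step to 100%; visited in lexicographic order with strict improvement, so
  ties resolve to the lexicographically smallest tuple.

Both optimisers use the same tie-break (PSO updates its best on equal
objective only for a lexicographically smaller decoded tuple). On flat regions
of the landscape the two then agree on a canonical representative rather than
reporting arbitrary members of the optimal set.

### Identifiability

Under the shared-detection-limit MM model, HIGH and MEDIUM tiers have
identical missingness behaviour, so the x/y split is *exactly* flat in the
objective. Moreover the MNAR set stops changing once the LOW tier already
contains all metabolites holding the k_mnar smallest values, so z is
identified only up to a lower bound. What the data determine are the MNAR
share α (sharply — it sets the censored-cell count) and the identity of the
censored metabolites. The reported `(x, y, z)` is therefore the
lexicographically smallest equivalent split, typically (0, 0, 100). This does
not impair classification: the training simulation at the canonical
parameters reproduces the same censoring pattern, and the tier feature retains
its LOW/not-LOW discrimination.

## Features and classifier

One row per missing cell: row- and column-wise contiguous missing-run lengths
through the cell (the focal cell counts, so isolated cells score 1; the column
run depends on the matrix's given row order, which is frozen), metabolite
max/min/median/mean/missing-rate over *observed* values of the same matrix
(the training matrix has its own missingness, so complete-data statistics are
not available at prediction time either), integer-coded metabolite identity
(unseen metabolites get a reserved code), and the tier code. Five independent
training draws are concatenated (more draws enrich the MCAR placements; five
is the default balance of table size against redundancy).

Backends: XGBoost (300 trees, depth 6, learning rate 0.1, hist, single
thread), random forest (500 trees), Gaussian naive Bayes with one-hot
categorical features. The task is binary and tabular; defaults are
unremarkable and overridable. Training uses a stratified 80:20 split
(stratification prevents class collapse when α̂ is extreme) and reports
held-out accuracy.

Two degenerate situations get explicit fallbacks rather than errors:

- a metabolite with *no* observed values (possible at high rates under heavy
  censoring) has undefined summary statistics; its cells bypass the classifier
  and are called MNAR outright — full censoring is the extreme left-censoring
  signature. Such metabolites are likewise dropped from individual training
  draws.
- if the searched α̂ is so extreme that the simulated training set is
  single-class, the classifier degenerates to that constant (the `train`
  function itself still refuses single-class input, since silent constants are
  wrong for user-supplied tables).

## Evaluation protocol

Ground truth is simulated from a complete matrix with mean-rule tiers at each
(α, rate) on a grid — α in 40–60% by 5 points, rate 2.5–40% by 2.5 points, 10
batches each, in the full protocol — and the pipeline runs *blind*: labels
enter only the scorer. The score is plain accuracy over missing cells, always
reported next to the majority-class rate of the same run. Per-rate means
aggregate batches.

## Synthetic data

The generator draws metabolite mean abundances log-uniformly over a decade
range ((0, 3) by default — three orders of magnitude, typical of GC–MS
intensity spreads) and sample values log-normally around each mean with CV
0.25. This reproduces the property the tiering rules need: a heavy-tailed
spread of metabolite means so the mean-based HIGH and LOW tiers are nonempty.
It deliberately omits batch effects, QC drift, sample-group structure and
correlated metabolite blocks, so passing tests show the *mechanism logic* is
right, not that accuracy numbers transfer to any particular real dataset. The
standard fixture is 100 metabolites × 30 samples, which keeps the whole suite
in the minutes range on one CPU; the benchmark runs in the tests and the
acceptance script use reduced grids (rates {0.1, 0.2}, 2 batches) and a
lighter swarm (15 particles, ≤ 40 iterations, 5 replicates) for the same
reason — the problem sizes, not the conclusions, are scaled.

## Numerical conventions

- round-half-up for all count rounding (`floor(v + 0.5)`).
- MNAR ties (equal values at the detection limit) break by (metabolite id,
  sample id).
- Simplex validity enforced to 1e-9; objective values compared exactly where
  common random numbers guarantee exact equality.
- The percentage-difference diagnostic between two searches is
  |swarm − enum| / swarm per coordinate (α on the percent scale), 0 when both
  are zero; both the fractional and percent reading of this quantity are
  obtainable from the returned value.

## Known limitations

- The x/y split and the upper range of z are not identifiable from
  missing-rate vectors (see above); downstream stages are designed not to
  depend on them.
- α̂ estimated through the panned complete subset is biased low at high
  missing rates: the subset over-represents well-observed metabolites and its
  truncated value distribution compresses the censoring signature. The
  classifier proves robust to this in the benchmark, but the α̂ value itself
  should not be read as an unbiased estimate of the generating share.
- Per-metabolite (rather than shared-limit) censoring, MAR simulation
  conditioned on covariates, and probability calibration of the classifier are
  out of scope.
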