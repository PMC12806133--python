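# Methods

## Triad normalization and classification

A homoeolog triad's state in a sample group is the composition
(f_A, f_B, f_D) obtained by dividing each homoeolog's TPM by the triad
total.  Replicates are averaged on the TPM scale *before* normalization,
so each group contributes one composite sample; normalizing per replicate
and then averaging compositions would differ only at second order in the
replicate noise, but the averaged-first convention keeps the group value
interpretable as the composition of mean expression.

Classification is nearest-centroid under the Euclidean metric in the full
three-component space.  Any isometric planar embedding of the simplex
gives the same ordering of distances, so the 3-D computation is the
simplest correct choice.  The seven centroids (balanced = equal thirds;
dominant = a subgenome vertex; suppressed = zero weight on one subgenome,
equal halves on the other two) are the standard convention for wheat
triad-bias work and are exposed as a configurable table
(`DEFAULT_CENTROIDS`); the centroid set is the only free element of the
classifier.  Exact distance ties are broken by the fixed category order
(balanced, A/B/D.dominant, A/B/D.suppressed) and flagged in the
assignment record; ties occupy measure-zero boundaries but regular grids
can hit them.

**Expression floor.** Triads whose group-level total falls below
`min_total` (default 0.5 TPM) are `not_expressed`: a zero-sum triad is
unnormalizable and near-zero totals give numerically meaningless
fractions.  Not-expressed triads are excluded from category-proportion
denominators but kept, as a sentinel row/column, in transition tables so
that every table's total equals the number of shared triads.

## Transition analysis

Transition tables are tallied pairwise over consecutive groups in the
declared order; the consistency fraction is the diagonal share, by
default over the seven assignable categories only (whether triads that
change expressed status belong in the denominator is a reporting choice;
`include_not_expressed=True` gives the other convention).

Category changes are typed from centroid geometry:

* `opposite` — dominant ↔ suppressed of the same subgenome: the two
  states that reverse one subgenome's role (distance √1.5; note the
  directionally unrelated dominant–dominant pairs are farther apart, √2,
  so "opposite" is a directional notion, not a maximal-distance one).
* `adjacent` — any pair involving balanced (the balanced centroid lies
  between all six biased states), and cross-subgenome dominant/suppressed
  pairs, which share half their expressed support (A-dominant and
  B-suppressed both load on subgenome A).
* `other` — two dominants or two suppressed: no shared directional
  relationship.

The full 7×7 label table is emitted by `transition_type_table()` so the
convention can be audited.

## Synthetic-data generator

The generator emulates the structure of a multi-stage bulk experiment on
an allohexaploid, with known truth for every triad:

* **Categories.** The first group draws each triad's category from
  `initial_proportions`; later groups follow a 7-state Markov chain.
  Defaults: proportions {balanced 0.40, A/B suppressed 0.12, the rest
  0.09} — balanced largest, dominant smallest, the rank structure seen in
  developmental wheat data — and a stay probability of 0.80 with the
  remaining mass uniform, matching the ≈80% consecutive-stage consistency
  regime the pipeline is meant to detect.  Eight default stages (VE, EL,
  IM, DR, GP, FM, PP, AM) and 20,400 triads.
* **Fractions.** Dirichlet around the category centroid with a single
  precision scalar (`concentration`, default 200): shape = centroid ×
  concentration, with zero components floored at 1e-3 and renormalized so
  the density is proper.  Larger concentration means tighter scatter; the
  paper-scale dispersion of real triads around centroids is not
  characterized anywhere, so this default is a free parameter chosen to
  give visually tight but non-degenerate clouds, not an estimate.
* **Expression.** Triad totals are log-normal (log-mean ln 20 ≈ a 20 TPM
  median triad, log-sd 1.0 — a typical bulk dynamic range); replicates
  (default 3) get multiplicative log-normal noise with log-sd 0.1, which
  perturbs fractions only at second order.  `not_expressed_fraction`
  (default 5%) of triads are silenced (all-zero) in one randomly chosen
  group each.
* **Noise-free mode** bypasses every sampling step — fractions equal
  centroids, totals are constant, replicates exact — giving a regime
  where the classifier must recover the truth at 100% and transition
  tables must equal the realized truth counts entry for entry.
* **Determinism.** All randomness flows through one
  `numpy.random.Generator` (PCG64) seeded from `config.seed`; identical
  configs give bit-identical outputs.

What the generator does **not** emulate: read-level sampling, UMI
collisions, doublets, gene-length effects in TPM, correlated noise across
triads, or cell-type-specific expression programs.  Passing recovery
tests therefore demonstrates the pipeline's correctness and calibration
under the stated compositional model, not the biological accuracy of any
real-data figure.

The cell-matrix fixture is built, not sampled: each requested violator
breaks exactly one QC rule (e.g. a low-UMI cell has 499 total UMI spread
over 200 genes) while all other cells pass every rule with margin; the
barcode suffix records each cell's role, making the construction its own
ground truth.

## Single-cell QC and pseudo-bulk

Thresholds (UMI 500–50,000, genes 200–10,000, mito ≤ 1%, chloroplast
≤ 5%) are applied as strict-violation rules — a cell exactly on a bound
is retained — and every rule is evaluated for every cell, so the report
lists all failures, not the first; the retained set is independent of
rule order.  The per-rule summary counts each removed cell once per
failed rule, so its column sum can exceed the removed-cell count.  A
`doublet` rule name is reserved but never triggered: doublet detection
belongs to dedicated external tools.

Pseudo-bulk aggregation sums raw counts over the member cells of a cell
type and scales each column to counts per million.  Sum-then-CPM (rather
than averaging log-normalized values) keeps the output on a linear
relative scale comparable to TPM, which is what the triad normalization
expects; how published per-cell-type bias figures were aggregated is
generally unstated, so this is a documented assumption rather than a
replication of any specific choice.

## Numerical choices and limitations

* Simplex validity uses a 1e-6 tolerance on input sums (absorbing
  6-decimal file rounding); unit-sum of freshly normalized triads is
  exact to 1e-9.
* Nearest-centroid distances use `scipy.spatial.distance.cdist`; the test
  suite checks it against an independent plain-loop oracle on a 10,011
  point simplex grid, with agreement required at every point.
* Assignment tables print fractions at fixed 6-decimal precision;
  reading them back renormalizes the triple to absorb rounding drift, so
  write→read round trips preserve the category exactly and fractions to
  1e-6.
* Problem sizes in the test and acceptance runs (20,000–20,400 triads,
  eight stages, three replicates; 10,011 grid points; 80-cell QC
  fixtures) match the simulated study conditions while keeping a full
  run in seconds on one CPU.
* The CLI's YAML config covers the simulation block and the expression
  floor; centroid overrides are available through the library API.
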