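# Methods

This note documents the statistical model behind `sitefunc`, the
defaults it ships, the numerical choices made where the design was
open, and what the synthetic-data tests do and do not demonstrate.

## Template-anchored coordinates

All active-site positions are expressed in the 1-based residue
numbering of a template sequence (crystal-structure convention);
alignment columns are 0-based internally.  A position map is the
bijection between the template's ungapped positions and its non-gap
columns; renumbering a position into another family member's own
numbering goes template position → shared column → target's ungapped
index, and returns a gap flag (`None`) when the target is gapped there.
Because the map is a strict bijection, template→column→template and
template→homolog→template round trips are identities whenever no gap
intervenes; this is enforced by property tests on randomized gapped
alignments.

State extraction aborts, by default, if the template's observed residue
at any scheme position differs from the residue the scheme declares.
This is deliberate: the single most common failure mode in
structure-to-alignment work is an off-by-one (or off-by-a-signal-peptide)
numbering shift, and a silent shift poisons every downstream
correlation.  The check can be overridden for schemes anchored on a
homologous template.

A gap at a scheme position is a distinct state.  It is excluded from
diversity counts, makes the sequence ineligible for property
aggregation and correlation at that position, and is never imputed or
scored as zero.

## Property scales

The package ships one published table per axis, selectable and
overridable by a user YAML scale:

| scale      | source                       | units | default use          |
|------------|------------------------------|-------|----------------------|
| volume     | Zamyatnin (1972)             | Å³    | size correlations, T/H/A clusters |
| hydropathy | Kyte & Doolittle (1982)      | —     | hydrophobicity checks |
| polarity   | Grantham (1974)              | —     | W-cluster polarity    |

Residue `X` is treated as unknown: sequences carrying it at a position
are ineligible there, like gaps.  Ambiguity codes (B, Z, U) are
rejected at parse time because no scale defines them — failing loudly
beats silently dropping positions.

## The correlation model

For each (position, substrate) cell the package computes the Pearson
product–moment correlation between the property value of the residue a
family member carries at that position and the member's log10 activity
(rates in s⁻¹).  Pearson was chosen over rank correlation because the
companion display — ordinary least squares of log10 activity on a
summed ("combined") property — assumes the same linear-in-log-space
structure; a Spearman option exists for robustness checks.

Statuses are explicit, never numeric placeholders:

- `ok` — r defined, at least 3 usable (property, activity) pairs.  The
  floor of 3 exists because any 2 points give |r| = 1.
- `conserved` — the property is constant across usable members; "no
  correlation" is not r = 0 and is exported as a status, with the cell
  rendered neutral in heatmaps.
- `insufficient` — fewer than 3 usable pairs, or log-activities with
  zero variance (which also leave Pearson's r undefined; folding this
  rare degenerate case into `insufficient` avoids a fourth status).

Below-detection activities are **excluded by default**.  Flooring them
at the detection limit (available as `nd_policy="floor"`) creates
identical stacked points at the floor that act as high-leverage anchors
on the log scale and can manufacture correlation where none is
measured; exclusion is the conservative default, at the cost of
statistical power on poorly accepted substrates.

Hot spots are positions ranked by max |r| over substrates (among `ok`
cells with at least `min_n` members), ties broken by mean |r| and then
by position number, so the ranking is total and deterministic.
Conserved positions are never ranked: a position that never varies
cannot nominate a substitution.

## Phylogenetic context

Distances are uncorrected p-distances with pairwise deletion of
gap-containing column pairs by default (complete deletion available);
a pair with no comparable columns is an error rather than an arbitrary
distance.  Trees come from the classical neighbor-joining algorithm
(Q-criterion), which is exact on additive matrices — the test suite
verifies path-length reconstruction to 1e-9 on matrices generated from
random trees, and cross-checks against scikit-bio's independent NJ
implementation.  Negative branch-length estimates (possible on
non-additive inputs) are clamped to zero with the deficit moved onto
the sibling edge, preserving the path length through the joined pair
while keeping all branch lengths non-negative.

Clades are assigned by nearest characterized reference leaf in
patristic distance, ties broken lexicographically by clade name.  This
is a deliberate simplification: it does not enforce monophyly, and a
reference placed inside a long-branch region can attract leaves a
human would assign elsewhere.  For the intended use — labeling family
members by their closest characterized enzyme — it is the behavior a
practitioner expects.

## Kinetics

Shipped rate laws: Michaelis–Menten `v = kcat·S/(K_M + S)`, substrate
inhibition `v = kcat·S/(K_M + S + S²/K_i)`, and Hill
`v = kcat·Sⁿ/(K_halfⁿ + Sⁿ)`; additional laws can be registered.
Fitting is trust-region-reflective least squares with all parameters
bounded positive, started from a fixed grid — K_M from {min, median,
max} of the concentrations, kcat from max(v)·{1, 1.5}, K_i from
max(S), Hill n from 1 — evaluated in a fixed order with the best-RSS
converged fit winning (first winner on ties), so fits are
deterministic.  Standard errors are curvature-based (Jacobian
covariance at the optimum); a finite-difference gradient-norm
diagnostic is exposed for convergence auditing.

At the reference conditions used throughout the tests (K_M = 33 µM,
kcat = 18 s⁻¹, 8 concentrations from 5 to 640 µM), noiseless data are
recovered to 1e-6 relative error.  Under 5% multiplicative noise, a
200-replicate calibration simulation observed a median |relative K_M
bias| of 0.061; the regression test bounds it at 0.10, a margin fixed
from that one calibration run.

Screening normalization is
`score = (raw − mean blank) / (mean wildtype − mean blank)`, requiring
at least two wells of each control and erroring when the wildtype and
blank means are indistinguishable (the score would be unbounded).  The
score is invariant under affine transforms `a·x + b (a > 0)` of the raw
signal, which is what makes plate-to-plate comparison meaningful.  Hit
calling keeps wells at or above a fold threshold (> 1), ordered by
score then well label.

## The synthetic-family generator

The generator exists so that every pipeline stage has a ground truth.
It emulates the statistical structure the correlation analysis assumes,
at the scale of the study the package is built around:

- **Family**: 8 sequences by default (up to 50 in tests), 3 clades,
  alignment length 120.  A random ancestor is mutated along a two-level
  tree (root → clade ancestors → leaves); each branch substitutes each
  position independently with probability 0.1 to a uniformly drawn
  different residue, so the leaf-vs-clade-ancestor mismatch frequency
  equals the nominal rate exactly in expectation (verified by a
  law-of-large-numbers test at n = 1000).
- **Planted coupling**: one site (position 40) drawn per sequence from
  a small-to-large palette (G…W), with log10 activity slope −0.012 per
  Å³ of residue volume.
- **Activities**: `log10 v = 1.5 + Σ slope·V(state) + N(0, 0.15)` per
  substrate, independently; 0.15 log10 units ≈ ±40% multiplicative
  error, a realistic scale for endpoint oxidase assays.  Rates below
  the 1e-3 s⁻¹ detection floor become not-detected cells.  The default
  palette and slope give a planted signal-to-noise ratio of about 4.
- **Determinism**: all randomness flows through one seeded
  `numpy.random.Generator`; identical seeds give bit-identical output.

What passing the planted-recovery tests shows: the pipeline
(state extraction → log transform → correlation → ranking) finds a
genuine log-linear property signal of realistic strength among neutral
and conserved positions, with the correct sign, in ≥ 95% of 200 seeded
replicates.  What it does **not** show: performance on real families
with epistasis, non-linear property effects, alignment errors,
covarying positions, or phylogenetic confounding (clade membership
correlating with both residue and activity).  The generator's neutral
positions drift independently of activity, which is the easiest
realistic null; real data are harder.

## Degenerate inputs and tie-breaking

- Candidate ranking sorts by the first criterion's aggregate
  (ascending for ≤, descending for ≥), ties by sequence id; sequences
  with gap/unknown states in a criterion's cluster fail that criterion
  with a NaN value rather than scoring 0.
- Heatmap TSV exports are tidy (position, substrate, r, status) so a
  re-import reproduces values *and* statuses exactly.
- Activity cells may carry `value ± error`; the error half is parsed,
  stored, and ignored by all statistics.
- NJ join selection and all rankings resolve ties by fixed ordering
  rules, so every output is reproducible across runs and platforms.

## Known limitations

- Correlations are per-position and marginal; no multiple-testing
  correction is applied, and with 8-member families |r| values near
  0.7 arise by chance — the hot-spot threshold is a triage tool, not a
  significance test.
- The NJ/nearest-reference clade machinery is a pragmatic stand-in for
  curated phylogenetics; for publication-grade trees use a dedicated
  ML tool and import the Newick.
- Problem sizes in the test and acceptance runs (families of 8–50,
  200 replicates, 1000 mapping fixtures) were chosen as the smallest
  scales at which the statistical claims are meaningful.
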