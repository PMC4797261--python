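# Methods

## Model

A double-stranded hidden Markov model (dsHMM) describes genome-wide signal
tracks with two *tied* Markov chains over one strand-generic state set `D`.
The forward chain `S+` runs left-to-right; the reverse chain `S-` runs
right-to-left.  Tying means a transition on the reverse strand, read in its
own 5'→3' direction, has the same probability `a_ij` as the corresponding
forward-strand transition, and both chains start (at position 1 and position
T respectively) from the same distribution `π`.  We require `A` to be ergodic
and define `π` as its unique stationary distribution; `π` is therefore never
a free parameter and is re-derived (by a linear solve of `πA = π, Σπ = 1`)
after every change to `A`.  The ergodicity check demands strong connectivity
and aperiodicity of the digraph of entries above `1e-12`.

The observation space splits into undirected tracks `B` (ChIP-style
occupancy, nucleosome density) and strand-specific track pairs `E+`/`E-`
(forward/reverse expression), two copies of a shared coordinate set `E`.
Each state `i` carries one single-strand Gaussian `N(μ^i, Σ^i)` on `B ∪ E`.

### Paired-state transformation

The dsHMM is equivalent to a standard HMM over state pairs `s = (s+, s-)`:

* transitions `Bmat[r, s] = A[r+, s+] · A[s-, r-] · π[s-] / π[r-]`,
* initial law `τ[s] = π[s+] · π[s-]`.

Row-stochasticity of `Bmat` and stationarity of `τ` are algebraic
consequences of `πA = π`; both are asserted numerically (1e-10) in the test
suite.  Pairs are indexed row-major with the forward state outer; this
ordering is fixed so serialized models are portable.

### Dominance sets and pair emissions

Each pair partitions the track set: strand-specific tracks always belong to
their own strand; an undirected track `b` goes to the forward member iff
`μ_b^{s+} ≥ μ_b^{s-}` (ties to the forward member, exactly as the
construction defines).  Tracks flagged `transcribed_dominates` (nucleosome
occupancy) are instead assigned to the transcribed member whenever exactly
one member is transcribed — otherwise the higher occupancy of an intergenic
state would mask nucleosome depletion in the transcribed state; when both or
neither member is transcribed, mean dominance applies.

The pair mean copies each member's mean on the tracks it dominates; the pair
covariance tiles `Σ^{s+}` on the forward block and `Σ^{s-}` on the reverse
block and is exactly zero between blocks.  Because the blocks can be
singular (e.g. a cluster with near-constant expression), a configurable
diagonal jitter (default `1e-8 ×` the mean diagonal) makes every pair
covariance strictly positive definite; a failure after jitter raises an
error naming the pair.  This sparse construction gives the paired model
exactly the free-parameter count of a standard `|D|`-state Gaussian HMM on
`B ∪ E` (`n(n−1)` transition entries plus `n` means and symmetric
covariances), asserted by counting in the tests.

### Reversibility caveat

Reversing bin order while swapping each `e+`/`e-` pair should leave the
likelihood unchanged.  With the "≥" tie rule this mirror symmetry is exact
for all distinct pairs, but a *self*-pair `(i, i)` assigns a tied undirected
track to the forward block, so any cross-covariance in `Σ^i` between that
track and the shared `E` coordinate attaches to `e+` only.  The invariance
therefore holds to machine precision exactly on models whose state
covariances have no `B × E` cross-covariance; the reversibility tests use
that subfamily (`random_model(..., correlated=False)`), and the general
construction is kept as defined.

## Inference

The forward–backward pass uses per-position scaling constants; emission
log-densities are additionally shifted by their per-position maximum before
exponentiation, so the recursion is stable for long sequences and extreme
observations.  Emission densities exploit the Cholesky factor of each pair
covariance; the block structure would allow a factorized evaluation but the
full-matrix value is what is computed and tested.  Viterbi runs in log
space with ties broken toward the lower pair index (deterministic given the
fixed pair ordering).  A brute-force path-enumeration oracle (refusing more
than 10^6 paths) defines the reference values for both; the suite checks
agreement to 1e-10 on 50 seeded micro-instances and additionally
cross-checks against an independent standard-HMM implementation (hmmlearn)
on the transformed model.  Masked bins are not supported: observations must
be complete and finite (validated with an explicit error).

## Learning

Training is generalized EM on the paired model:

* **Initialization.**  Bins are split into transcriptionally active and
  inactive sets by thresholding the mean forward-strand expression; the
  default threshold is the 60% quantile of the pooled strand-specific
  values, overridable by an absolute value.  k-means (10 seeded restarts)
  on the forward-oriented single-strand coordinates yields `n_transcribed`
  centers from the active set and `n_intergenic` centers from the inactive
  set; each state's covariance is the empirical covariance of its cluster,
  with variances floored at `1e-6 ×` each coordinate's global variance, and
  is **never updated** afterwards.  `A` starts uniform (hence `π` uniform).
  The default state budget is 15 transcribed + 5 intergenic states,
  mirroring the configuration used for genome-scale annotation.
* **E-step.**  Scaled forward–backward.
* **M-step.**  `A` is re-estimated from tied expected counts — each expected
  pair transition `r → s` contributes to `a[i, j]` through the forward chain
  (`r+ = i, s+ = j`) and through the reverse chain (`s- = i, r- = j`); the
  `π` ratios inside the pair transition are treated as constants during this
  maximization and `π` is re-derived afterwards (joint maximization over
  `(A, π(A))` has no closed form).  Each single-strand mean entry is the
  posterior-weighted average of the observations on the tracks the state
  *determines* under the current dominance partition (the two expression
  copies pool into the shared `E` coordinate, each attributed to its own
  strand's state); partitions are recomputed from the new means afterwards.
  A zero-weight determiner keeps its previous value with a warning.
* **Monitoring.**  Because dominance partitions may flip between iterations,
  the likelihood can in principle decrease; any decrease triggers damping
  (halving back toward the previous parameters, up to 10 times, logged in
  the trace) and, if damping fails, the previous model is returned with the
  trace flagged `damping_exhausted`.  Convergence is declared when the
  relative log-likelihood change falls below `tol` (default 1e-6); hitting
  `max_iter` is flagged, not raised.  Runs are bit-reproducible given the
  seed.

## Preprocessing and IO

Inputs are bedGraph, fixed-step wiggle, or a single tabular matrix, listed
in a YAML manifest carrying each track's strand class, partner and dominance
rule.  All tracks must share one grid of contiguous equal-width bins;
overlapping or gapped intervals are rejected.  Coordinates are 0-based
half-open internally; BED exports keep that convention, GFF3 is 1-based
closed (the consistency of the two is tested record-by-record).  The only
normalization implemented is the final rescaling step of a ChIP-chip
pipeline: an affine map sending the empirical 5% quantile to 0 and the 95%
quantile to 1, using the linear-interpolation (type-7) quantile convention;
tails are kept (no clipping), making the map strictly monotone and
idempotent.  Upstream array normalization (platform protocols, mock-IP
subtraction) is assumed done and is out of scope.

## Synthetic data

`sample_from_model` draws both chains and the pair-Gaussian emissions
exactly from the generative semantics (reverse chain sampled from `π` at the
last position, extended right-to-left with `A`).  `make_overlap_scenario`
plants four gene-sized intervals — two per strand, one convergent pair
overlapping by 50 bins at the 3' ends — with piecewise-constant signals:
an undirected occupancy track high (1.0) over each gene's 5' half and low
(0.25) over its 3' half in the gene's own direction, and a strand-specific
expression pair at 1.0 over genes on the corresponding strand; independent
Gaussian noise (default σ = 0.1) is added to every track.  Defaults (genes
200 bins, gaps 100, overlap 50) are chosen for clear separability at that
noise level.  Planted truth uses three states per strand (intergenic,
gene-start, gene-end).  A `mirror` flag reverses coordinates and swaps
strands of the finished dataset as a deterministic final transform, making
the mirror-symmetry property exact by construction.

What the generator does *not* emulate: probe-level array artifacts (GC bias,
mock-IP structure), covariance between tracks in the scenario (noise is
independent there; the full covariance path is exercised by
`sample_from_model`), and the diversity of real transcription-unit
structure.  Passing tests on this generator therefore demonstrate
correctness of the algorithms under the stated model, not performance on
real arrays.

## Validation experiments and problem sizes

The recovery experiment samples T = 5000 bins from a known 3-state model
(one intergenic, two transcribed states with unit-scale means, diagonal
covariance σ = 0.1, symmetric `A` with 0.96 self-transitions) over 5 seeds
and re-estimates it; fitted means and transition entries agree with the
generating values to well within 0.05 after matching states by mean
distance.  The scenario experiment fits a 3-state model at noise σ = 0.1
and reaches ≥ 0.95 per-strand Viterbi accuracy on every seed tested, calling
both strands transcribed across the entire planted overlap.  For synthetic
fits where expression is planted at levels 0/1 the active/inactive split
uses the absolute threshold 0.45 (the planted midpoint); the 60%-quantile
default remains for real data, whose expression scale is not known a
priori.  Oracle and reversibility checks run at T ≤ 20 with 2–4 states
where enumeration is exact.

## Summaries

* Pair co-occurrence: entry (x, y) is the fraction of bins annotated
  (x forward, y reverse) plus (y forward, x reverse); the matrix is
  symmetric with total mass 2 (diagonal bins counted twice), stated in the
  output header.
* The 2×2 transcription contingency table is computed over *all* annotated
  bins (not only track-covered positions) and sums to 1.
* Metagene profiles orient every feature 5'→3' (reverse-strand features are
  flipped with strand roles swapped), resample the body to 100 positions by
  nearest-bin lookup and attach fixed flanks (default 500 bp worth of bins);
  per-position state frequencies sum to 1.  Features shorter than 2 bins
  are skipped with a warning.
* The transition graph counts observed transitions on both per-strand paths
  in their own reading direction, row-normalizes, blanks self-loops and
  prunes edges below 0.012 by default (the conventional display cutoff for
  genome-scale annotations).
* Regions are maximal runs of one state with strict adjacency (no gap
  tolerance); a region "overlaps" when it shares ≥ 1 bin with a same-state
  region on the opposite strand.

## Known limitations

* Covariances are fixed at their initialization values; a poor initial
  clustering cannot be repaired by EM in the covariance dimension.
* The exact closed-form mean update of the original formulation is not
  recoverable from the available description; the dominance-aware weighted
  average implemented here maximizes the expected complete-data likelihood
  for *fixed* partitions and reduces to standard Baum–Welch when no
  undirected tracks exist, but partition flips make the overall scheme
  generalized EM (hence the damping safeguard).
* Exact likelihood reversibility requires the covariance condition above.
* No posterior path sampling, banded/approximate inference, discrete or
  non-Gaussian emissions, higher-order chains, or model selection over the
  number of states.
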