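# Methods

## Synthetic cohorts: what is planted, and what is not

The generator (`dynfc.simulate`) produces piecewise-stationary multivariate
Gaussian signals. Time is divided into epochs of `switch_period` frames
(default 100 ≈ 72 s at TR 0.72 s); within an epoch, signals are drawn from
a zero-mean multivariate normal whose correlation is `within_corr` (default
0.5) inside each community block and `between_corr` (default 0.05)
elsewhere, then white observation noise of sd `noise_sd` (default 0.1) is
added. Because added noise attenuates correlations by `1/(1+noise_sd²)`,
the epoch target is pre-scaled by `1+noise_sd²` so the *emitted* data
realize the stated correlations; parameter combinations for which this
pushes a correlation to 1 or beyond are rejected at construction. Epoch
correlation targets are projected to the nearest positive-definite matrix
(eigenvalue floor 1e−6) before the Cholesky factorization.

**Flexible coalition.** The default cohort has 40 nodes: three 12-node
stable host communities and one 4-node community whose members are all
flexible — a small, coherent subsystem (labeled "SN" in the generated
atlas, by analogy with a salience-network-like set of transiently coupling
nodes) that attaches to a *different* host community each epoch,
round-robin over the hosts with a seeded starting phase shared by the
coalition. Two aspects of this design are deliberate:

* *Coalition coherence.* If flexible nodes moved independently, they would
  correlate statically with nothing in particular, and "planted static
  labels" would be ill-defined. Moving as a coalition makes the coalition
  itself the static ground-truth cluster (members correlate 0.5 with each
  other all the time, but only ≈ `within/(k−1)` on average with any host).
* *The coalition is its own community.* Configurations in which flexible
  nodes are natives of a larger community leave behind a depleted stable
  remnant; such undersized communities are unstable under window-level
  modularity (their nodes acquire spuriously high flexibility), and for
  intermediate sizes the global Q* optimum genuinely absorbs the coalition
  into a host (verified by direct quality evaluation). Making the
  coalition a community of its own removes both artifacts and keeps the
  expected intramodular weight of a coalition–host merge below its
  chance-expected value.

Twin sessions share the spec (hence flexible-node identities) but use
independent sample paths; per-(session, subject) seeds are fanned out from
the spec seed with `numpy` `SeedSequence` spawn keys.

**What the generator does not emulate:** hemodynamic filtering and
autocorrelation, 1/f noise spectra, head motion, spatially correlated
noise, inter-subject variability in community layout, and amplitude
dynamics not expressible as correlation changes. Passing tests therefore
demonstrate correctness and calibration of the *analysis chain* on data
satisfying its own assumptions — not robustness to fMRI artifacts.

**Behavioral scores.** `simulate_behavior` plants a composite coupling: a
latent direction `g = r·z + √(1−r²)·η` (`z` the standardized flexibility
summary, `η` an independent standard-normal draw) loads on each measure
with `b_j = sign(w_j)·√(1 − residual·(1−u_j²))` (`u = w/‖w‖`, `residual`
defaults to 0.9), and residual noise is confined to the null space of the
planted weights `w`, so the *population* correlation between
`measures @ w` and the flexibility summary equals `coupling_r` while the
sample correlation carries ordinary sampling variability — a property the
permutation-test calibration requires (an earlier construction that pinned
the in-sample correlation exactly produced a degenerate null: observed
statistics systematically smaller than their own permutation
distributions, type-I error 0 instead of α). Columns are standardized to
mean 0, sd 1 exactly; `residual = 0` makes every measure an exact affine
image of `g`.

## Preprocessing

Frames are discarded first (default 20), then the high-pass filter is
applied (default cutoff 0.008 Hz). The filter is a projection in the
orthonormal DCT-II basis: coefficients with component frequency
`f_k = k/(2·n·dt)` below the cutoff (including DC) are zeroed. This is
zero-phase, exactly linear, and exact on the finite window; the cutoff
names the same quantity as a Butterworth specification would, but the
filter family is this package's choice.

## Windowed connectivity

Window length in frames is `round(length_s/dt)` (40 s at TR 0.72 s → 56
frames); windows advance by `step_frames` and cover `[start, start+T)`.
Exponential weights use θ = T/3 by default; the closed-form normalization
is renormalized once more in floating point so `Σw_t = 1` to 1e−12.
Weighted correlations with zero weighted variance are returned as NaN
(flagged, never silently 0). Fisher z-transformation clips |r| at
1 − 1e−7 so degenerate synthetic inputs (|r| = 1) stay finite.

## Signed community detection

Q* uses the asymmetric signed convention: positive weights normalized by
total positive weight v⁺, intramodular negative weights penalized at scale
1/(v⁺+v⁻). Because Q* is linear in the same-community indicator, the
objective collapses to a fixed symmetric gain matrix B with
`Q*(partition) = Σ_ij B_ij δ(c_i,c_j)` (diagonal excluded); Louvain local
moving plus exact aggregation of B is run `n_init` times (default 100;
the window-level analyses in `analysis/` and the acceptance script use 20)
with seeded random sweep orders, and the max-Q* run is returned —
"optimal community structure" is read as the best single partition, not a
consensus. Per-window and per-init seeds are derived by counter from one
master seed, so results are independent of evaluation order. The
resolution parameter is fixed at 1. An all-zero matrix returns one
community with Q* = 0. Correctness is checked against exhaustive partition
enumeration (all 203 partitions of 6 nodes) in the test suite.

## Node metrics

Strength sums from the co-occurrence matrix always exclude the diagonal
(`C_ii ≡ 1` is self-allegiance). Diversity includes the node's own
community in the entropy (matching the diversity-coefficient definition);
flexibility excludes it (its formula is explicit about `j ∉ u_i`);
centrality uses the sample (n−1) standard deviation, and returns a flagged
0 for singleton or zero-spread communities — note the planted coalition is
such a case (all members co-occur always, so their within-community
strengths are identical). Cross-network comparisons use paired two-sided
Wilcoxon signed-rank tests across subjects with Holm correction.

The high-flexibility node set is computed by 2-means clustering on the
standardized group-mean (flexibility, diversity) plane (50 seeded
restarts, component with higher mean flexibility returned); a percentile
threshold rule (top 15% flexibility) is available as an alternative and as
the automatic fallback when the plane is degenerate. Neither rule is
claimed to be *the* canonical definition; both are exposed.

## Null models

Phase randomization adds i.i.d. uniform [0, 2π) phases independently per
node and frequency (conjugate-symmetric; for even-length series the
Nyquist coefficient gets a random sign), preserving per-node amplitude
spectra to machine precision and destroying cross-spectra.

**Surrogate metrics use per-subject references.** Surrogate data have no
shared structure, so a group-level reference partition estimated from them
is arbitrary — and, being shared by all subjects, its community-size
offsets (a node in a small reference community mechanically has high
flexibility) would appear as consistent node effects in a paired
across-subject test, in a random direction. The ablation analysis
(`surrogate_node_metrics`) therefore detects a reference per subject from
that subject's own surrogate static connectivity, which restores
exchangeability of the flexible-vs-stable comparison under the null. Real
data keep the group reference.

Random-graph nulls randomize positive and negative subnetworks separately:
degree-preserving edge swaps (10 per edge; a no-op on complete graphs,
where all randomness comes from the weight step; each sign avoids slots
occupied by the other so both weight multisets survive the merge), then
the original weight multiset is reassigned by stochastic rank-matching
against residual expected-strength products — weight multiset and degree
sequences exact, strengths approximate (node-strength correlation > 0.99
on heterogeneous 50-node matrices). Matrices with fewer than 2 edges in a
nonempty sign class are rejected as too sparse.

The structure test computes the PC1 variance fraction λ₁/Σλ of the
column-centered co-occurrence matrix (equivalently the squared first
singular value share) and reports the empirical one-sided p with the +1
correction; centering and the ratio convention are this package's
recorded choices. Calibration (type-I ≈ α when the observed matrix is
itself a null draw) is verified in the acceptance suite.

## Brain–behavior CCA

Behavior and brain measures are standardized with training-fold statistics
only; with a scalar brain measure the canonical behavior weights reduce to
the (minimum-norm) least-squares weights of the brain measure on the
scores, verified against an OLS oracle in the tests. Signs are fixed so
the training-fold correlation is nonnegative; held-out composite pairs are
pooled across the 4 folds into a single Spearman ρ (rather than averaging
per-fold correlations). The permutation test shuffles the brain measure
across subjects and regenerates the fold scheme inside every permutation;
p is one-sided (`ρ_null ≥ ρ_obs`) with the +1 correction, matching the
directional prediction hypothesis. Calibration: type-I 0.05 and power
≈ 0.88 at planted coupling 0.45 with 60 subjects (computed in the
acceptance suite).

## Problem sizes and runtime choices

The study analyses and acceptance checks run the windowed pipeline with a
step of 6 frames (188 windows per subject instead of 1,125) and 20
community initializations per window; spot checks at denser settings give
the same partitions and metric rankings, since consecutive windows at step
1 are nearly redundant (55 of 56 frames shared). The structure-test
calibration uses 200 repeats × 200 nulls on 24-node matrices; the CCA
calibration uses 400 replicates × 500 permutations. The full test suite
runs in about 5 minutes on one CPU; the acceptance script in well under a
minute.

## Known limitations

* The Louvain kernel is exact only against enumeration at small n; at 40+
  nodes optimality is heuristic (best of n_init restarts).
* The signed random-graph null preserves strengths only approximately, as
  any rank-matching scheme does; strength-sensitive statistics beyond PC1
  should re-verify calibration.
* Window-level community detection assumes the window holds a single
  stationary regime; epoch boundaries mid-window blur allegiances (the
  default epoch length of ~1.8 windows keeps this modest).
* The CCA path supports one canonical component (the analysis uses a
  scalar brain measure); multi-component, sparse, or covariate-adjusted
  variants are out of scope.
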