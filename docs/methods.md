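# Methods notes

This note records the package's model choices, defaults and known
limitations, in the spirit of a statistical reference manual: what is
computed, under which assumptions, and what the synthetic tests do and
do not establish.

## Edge weighting

The connection strength between parcellation nodes i and j is

    w(e_ij) = (2 / (A_i + A_j)) · (V_voxel / P_voxel) · Σ_f χ_R(f) / l(f).

Dimensional bookkeeping fixes the grouping: V_voxel/l(f) has units of
area, normalized by the mean node surface area, so w is dimensionless;
dividing by P_voxel removes the seeding paradigm, and the 1/l factor the
length bias of deterministic tracking. The package treats this grouping
as definitional and verifies it by a unit-rescaling invariance test
(lengths ×s, areas ×s², volumes ×s³ leave w unchanged to roundoff).

Choices where tracking pipelines differ, declared here once:

* **Streamline-to-edge assignment** is by endpoint containment: a
  streamline belongs to (i, j) iff its first and last points fall in the
  two nodes' voxel masks. Self-loops and streamlines with fewer than two
  node endpoints are dropped with a logged count.
* **The white-matter support R** of an edge is the union of voxels
  traversed by the pair's candidate streamlines minus both nodes' voxel
  masks. Traversal is decided by point-in-voxel tests on the polyline
  resampled at one quarter of the smallest voxel edge; voxel indices are
  0-based and boxes are half-open (a point at coordinate x belongs to
  voxel floor(x/edge)).
* **The characteristic filter** retains a streamline iff its seed voxel
  lies in R; seeds inside either node's mask or off the path are
  excluded. Each retained seed counts once; duplicate trajectories from
  different seeds are not collapsed.
* **Node surface area** is taken as supplied parcellation metadata (in
  mm²); the package does not recompute it from voxel masks.
* **FA weighting** (mean fractional anisotropy over R) reuses the same
  supports as the dimensionless weight, for comparability; an edge with
  an empty support is absent under FA weighting.

No threshold is applied at any stage; an all-zero matrix is legal output
(with a warning) for an empty tractogram.

## Topology indices

All indices run on the raw weighted matrix. Weighted clustering is the
Zhang–Horvath form, which requires weights in [0, 1]; weights are
normalized per graph by the maximum weight, making clustering invariant
to global weight rescaling. Path length is deliberately strength-like:
with distances d = 1/w, the value reported for a pair is the reciprocal
of the minimal total distance, so it increases with connectivity and
equals w when the direct edge is optimal (the raw-distance alternative
can be read off as 1/L). Disconnected pairs are excluded from all path
averages and marked NaN, never coerced to zero. Dijkstra tie-breaks
cannot affect the reported value, only the path identity.

Small-worldness compares observed mean clustering and mean path length
to an Erdős–Rényi ensemble matched on node count, density and the
observed weight pool (weights resampled with replacement), 20
realizations by default, averaged before the ratio. The ensemble
preserves the weight distribution but not the weight placement; a
degenerate ensemble (zero clustering or no connected pairs) raises
rather than returning a misleading ratio.

## Group inference

Node-level indices are residualized on graph density by pooled ordinary
least squares across all subjects (residual + grand mean); when every
subject has the same density the values pass through unchanged. Group
contrasts use the two-sided Mann–Whitney test: exact enumeration when
min(n) ≤ 8 without ties — keeping comparisons against a 9-subject group
reproducible — and the normal approximation with tie and continuity
corrections otherwise. Global indices are tested uncorrected; node-level
tests are corrected within each (index × group-pair) family of N node
tests.

The correction estimates the p-value distribution by the least concave
majorant (LCM) of the ECDF — the Grenander estimator, a nonincreasing
step density integrating to one; it equals the pool-adjacent-violators
fit of the empirical density, which the tests use as an independent
oracle. The null proportion η₀ is the height of the density's dominant
flat step, implemented as the slope of the widest positive-slope LCM
segment, clipped to [0, 1]. Restricting to positive-slope segments
matters when the tests in a family are strongly correlated: all raw
p-values then bunch together and the empty interval up to 1 would
otherwise be read as "no nulls" (η₀ = 0), declaring everything
significant. Adjusted p-values are the tail-area quantity
q(t) = min(1, η₀·t/F̂(t)), monotone in the raw p by construction (F̂
concave) and enforced explicitly; the false-nondiscovery rate
FNDR(t) = (1−η₀)(1−F̂₁(t))/(1−F̂(t)), with F̂₁ = (F̂−η₀t)/(1−η₀), is
reported alongside and set to 0 when η₀ = 1 or F̂(t) = 1. P-values below
1e-300 are folded into an atom at zero so hull slopes stay
representable. Benjamini–Hochberg is exposed as a comparison mode.

## Correlations

Partial Spearman correlations midrank all three vectors and apply the
standard partial-correlation identity on the ranks; they are invariant
under strictly monotone transforms of every argument. The covariate is
a configuration field, defaulting to years of education with age
selectable, since both are defensible confounders of cognition–network
associations. Zero-variance variables yield an undefined (NaN) record
that is excluded from count matrices with a logged tally; a covariate
perfectly rank-correlated with a variable is an error at the function
level and an undefined record at the cohort level. Strong-correlation
flags use |z| > 0.55 for global tables and |ρ| > 0.50 for node tables,
both configurable. Controls carry three cognitive composites; Parkinson
groups add UPDRS III, so a 27-node, 3-index analysis evaluates at most
243 correlations in controls and 324 in a Parkinson group.

## Synthetic data: what it emulates, and what it does not

**Phantoms** place cubic nodes along a line (default ten 4 mm-side
nodes, 20 mm apart on a 2 mm grid) joined by straight or arced bundles
(default: a chain of 9 bundles of 50 streamlines). Seeds are drawn
uniformly over the bundle corridor with 25 seeds per voxel by default
(a desk-scale stand-in for the 125-seeds-per-voxel paradigm of
whole-brain tracking). Bundle geometry is deterministic, so the
closed-form edge weight is exactly checkable, and the ground-truth edge
membership is returned for oracle tests. Spurious connections are
single arced streamlines (> 40 mm here, versus 20 mm bundle lengths)
between unconnected pairs, each present with the configured rate.

**Cohorts** share one base network: a fixed random support at density
0.40 with log-normal weights (μ = ln 1e-3, σ = 1 — nonnegative,
right-skewed, heavy-tailed like streamline-count-derived weights). Each
subject's matrix is the base times a group strength multiplier (1.0 /
0.9501 / 0.8677 — i.e. injected reductions of 4.99% and 13.23%), a
per-subject log-normal factor (σ = 0.10) and per-edge log-normal noise
(σ = 0.20), both mean-one so expectations are exact. The PD-MI group
additionally shrinks edges incident to a designated 27-node focal set
(the shipped bilateral list) by 0.85, after which the matrix is
rescaled so the expected global mean strength still equals the group
multiplier times baseline — keeping the injected global contrast exact
while focal nodes carry the largest local differences. Cognitive
composites and UPDRS III are generated per group from published-scale
means and SDs via a Gaussian copula on normal scores of realized mean
strength and education, with latent coefficients 2·sin(πρ/6) so the
target Spearman correlations hold in expectation. UPDRS III is left as
an unclipped normal score: clipping at zero would distort the injected
rank correlations, and all downstream use is rank-based.

What the generator does *not* emulate: brain-like topology (the support
is random, so clustering and small-worldness magnitudes are not
brain-like — a real connectome's lattice-like local structure yields
much higher values), spatial autocorrelation of edges, subject-specific
supports (graph density is identical across subjects, so the
density-adjustment step passes values through unchanged on synthetic
cohorts and is exercised separately with synthetic regressions), or any
diffusion-signal physics. Passing tests therefore establish the
correctness and calibration of the computations, not anatomical
realism.

One consequence worth knowing: because a group multiplier moves every
edge, node-level tests within a family are strongly correlated on
synthetic cohorts, and when the injected effect is real, most or all
nodes in a family come out significant. Selectivity like "27 of 82
nodes" arises only from focal-dominated effects.

## Problem sizes and runtime envelope

The default test-suite sizes are chosen to make each statistical claim
measurable in seconds to minutes on one CPU: exhaustive graph oracles
up to 8 nodes; Grenander ≡ PAVA up to n = 50; Mann–Whitney type-I
calibration at 2,000 simulated repetitions with the study's group sizes
(40 vs 31); parameter recovery over 200 seeded cohort replicates at the
full default cohort (80 subjects, 82 nodes); null-pipeline type-I
control over 6 seeded effect-free cohorts; spurious-link robustness
over 20 seeded phantoms. The acceptance script reruns only the phantom
robustness computation (20 phantoms, ~4 s).

## Known limitations

* The TRK adapter cannot recover seed provenance (TRK stores none); it
  assumes the first point is the seed, which makes the characteristic
  filter permissive for such inputs.
* η₀ from the widest LCM step is conservative for strongly
  signal-dominated families (it can report η₀ = 1 when almost all
  hypotheses are false); adjusted p-values are then still driven by
  t/F̂(t) and remain small, but the reported FNDR goes to zero.
* Exact Mann–Whitney enumeration is only engaged for tie-free pooled
  samples; heavily tied data always use the corrected normal
  approximation.
* The pipeline's "significant node" selection for local correlations
  follows the control vs PD-MI strength contrast; with no significant
  nodes it falls back to all nodes, which can be slow for large
  parcellations.
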