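# Methods

This note documents the models, algorithms, and design choices behind
`hmtg`, and what the synthetic-data experiments do and do not establish.

## Task and utility models

The Hidden Multiplier Trust Game is represented by an 80-trial schedule:
20/40/20 trials at multipliers ×2/×4/×6, of which 1/2/1 per condition carry
a zero investment (the Trustee cannot respond; these trials are fixed at
return 0 and excluded from all modeling, leaving 76 modeled trials).
Nonzero investments cycle through 1..10 as evenly as the per-condition
counts allow, so the investment distribution is nearly identical across
conditions; trial order is shuffled by a seed and the same schedule is
shared by a cohort. The Trustee's second-order expectation is fixed at
`2I` for everyone — half the pot the Investor believes exists — rather than
elicited per participant, so differences in fit reflect sensitivity to
expectations, not differences in the expectations themselves.

The Moral Strategy model and the three single-motive models are implemented
exactly as stated in the README. Two formulation details matter:

* The MS payoff is normalized by the pot (`π₂ ∈ [0, 1]`), placing it on the
  same scale as the squared social-loss terms; the component models use the
  raw payoff and an unbounded weight `Θ ≥ 0` (default box [0, 1000]).
  With integer returns, the guilt-aversion component only reaches its
  `2I` prototype when `Θ > 16I²` (the marginal guilt relief for the last
  token must exceed 1), so the prototype is out of reach at `I ≥ 8` under
  the default box. This is a property of the printed equations, not a
  fitting artifact.
* At the MS model's theta upper bound (0.5) the payoff and social terms
  have *equal* weight, and the model still returns a little in the most
  lucrative condition (e.g. 7 of 60 tokens at `I = 10`, ×6). The "greedy"
  region of parameter space is therefore near-zero, not exactly zero;
  exact greed is the limit `Θ → 1`, outside the fitted box. Tests that
  need the exact greed prototype use `Θ = 1` as a test-only
  parameterization, the same device used for forcing the guilt branch
  (`Φ = −0.2`) and inequity branch (`Φ = +0.2`).

Argmax ties are broken toward the smallest return (ascending scan, first
maximum): with any greed weight the payoff term already pushes this way,
so the rule is consistent with the model's structure. The candidate set is
every integer in `[0, I·M₂]`; the response slider's 10% increments are a UI
mechanic, not model structure.

## Fitting

The objective is the sum of squared errors between argmax predictions and
observed returns over modeled trials. Because predictions are discrete
argmaxes, the objective is piecewise constant with zero gradient almost
everywhere; gradient-based least squares cannot move. The fitter therefore
evaluates `n_starts` uniform random points in the parameter box (defaults:
10,000 for data fits, 1,000 for recovery) and keeps the earliest start
attaining the minimum (SSE values are exact integers, so ties are exact),
then runs a strict-improvement coordinate pattern search (initial step 10%
of each range, halved on failure, terminating at 10⁻⁴ of range). Strict
improvement preserves the first-tie-wins rule on plateaus.

Known limitation: parameter points lying exactly on an argmax tie boundary
(e.g. round values like Θ = 0.2 for some schedules) have a measure-thin
zero-error set that random multi-start cannot hit, and a few percent of
random points have plateaus small enough to be missed at 1,000 starts.
This is intrinsic to the objective and is exactly why phi recovery
correlates at ≈ 0.93 rather than 1.0: where behavior is insensitive to phi
(high theta), the recovered phi is the first random start on the plateau.
Theta recovery is unaffected (r ≥ 0.995) because theta plateaus are
narrow over most of the box.

Model comparison uses `AIC = n·ln(SSE/n) + 2k` per subject (k = 0, 1, 1, 2
for GR/GA/IA/MS); subjects with SSE = 0 have undefined AIC and are excluded
pairwise. ΔAIC is reported as mean(A − B) with MS as A, so negative values
favor MS. Inference is a sign-flip permutation of subject-wise AIC
differences — exhaustive over all 2ⁿ sign patterns when 2ⁿ ≤ n_perm (raw
proportion, identity included), Monte Carlo with a +1/(n+1) guard otherwise
— two-sided by default, with a paired t test available. Cross-validation
splits the 76 modeled trials into five random folds (15/15/15/15/16;
remainder trials go to the last folds), refits on four, predicts the held
one, and pools MSE, Pearson r and r² over all held-out trials; r is flagged
undefined when either vector is constant (e.g. an all-zero responder).

## Strategy zones

Behavior is simulated at 101×101 evenly spaced (Θ, Φ) points — one
33-vector of predicted returns per point over investment 0..10 ×
multiplier {2, 4, 6}. Ward-linkage agglomerative clustering (Ward's
objective is within-cluster squared-Euclidean variance; other linkages can
be applied to the condensed squared-Euclidean distance matrix) cuts the
tree at four clusters, and each cluster is named by the closed-form
prototype (GR → 0, GA → 2I, IA → equal-split integer, MO → pointwise min of
GA and IA) nearest its centroid. Non-bijective naming raises an error: it
signals a degenerate grid (e.g. a slice where all points behave
identically) or a grid too coarse for centroid naming — the default
resolution names all four zones cleanly. Participants are assigned the
label of the Euclidean-nearest grid point in raw parameter units (theta
range 0.5, phi range 0.2; a normalized option exists but is off, matching
the literal nearest-in-parameter-space rule); ties break to the lowest
row-major grid index.

Because the zones are built purely from simulation, they are invariant to
any participant sample — an intentionally sample-independent alternative to
k-means on observed participants.

## Synthetic data

The cohort generator draws each participant's (Θ, Φ) uniformly from their
assigned zone by rejection sampling, by default restricted to zone
*interiors* (every corner of the enclosing grid cell must share the zone
label). The restriction exists because a boundary-cell parameter point can
produce behavior bit-identical to the neighboring zone's, making its label
an artifact of the nearest-grid-point rule rather than of behavior.
Default group sizes are 24 IA, 5 GA, 21 MO, 7 GR (the observed strategy
distribution); behavioral noise adds rounded Gaussian deviations (default
sd 2.3 tokens, matching the empirical per-trial model error scale of
MSE ≈ 5.3) clipped to the feasible range.

The neural generator emits per-parcel voxel vectors (default 60 voxels,
20 parcels, 5 per kind) per participant × condition:

* **null** — i.i.d. Gaussian noise; calibrates false-positive rates.
* **geometry** — mean pattern `a·(2·b + θ̃·u + φ̃·v)` with orthonormal
  random directions b, u, v fixed per parcel and (θ̃, φ̃) the participant's
  parameters rescaled *isotropically* (one scale factor for both axes, so
  the theta:phi aspect ratio of raw units is preserved; a per-axis rescale
  would decouple the planted geometry from the raw-unit model RDM). The
  shared baseline direction `b` matters: around a common mean pattern,
  correlation distance grows monotonically with (squared) Euclidean
  parameter distance, whereas without it correlation distance is a pure
  angle and cannot track radial separation. At zero noise the parcel RDM
  rank-correlates with the model RDM above 0.99.
* **group_template** — one fixed unit template per coded strategy group,
  identical across conditions; uncoded groups get noise only.
* **switching** — orthogonal GA and IA templates; GA/IA members use their
  own template everywhere, while moral opportunists use the IA template in
  ×2, the GA template in ×6, and an equal mixture in ×4 (the ×4 neural
  state of opportunists is unconstrained by theory; the 0.5 weight is a
  free simulation knob).

The default amplitude (4, with voxel noise sd 1) was calibrated once so the
planted geometry signal sits roughly nine null standard deviations above
the Mantel null distribution, and then frozen. With amplitude 0 every
parcel is statistically null.

What the generator does *not* emulate: BOLD time series, hemodynamics,
spatial autocorrelation within parcels, anatomical structure, or realistic
effect sizes — the true within-strategy neural similarity of real data is
unknown, so all neural tests are planted-truth recovery and calibration
checks, not effect-size predictions. Passing them shows the analysis code
detects the structure it is designed to detect, at the rates it claims,
under its own noise model; it does not show the structure exists in brains.

## IS-RSA and pattern analyses

Parcel RDMs are 1 − Pearson r between voxel patterns; the model RDM is raw
Euclidean distance in (Θ, Φ). Association is Spearman's rho over the lower
triangles. Inference permutes participant labels of one RDM jointly over
rows and columns (Mantel scheme — permuting triangle entries independently
would break the matrix structure), one-sided for positive association.
The default p-value is (exceedances + 1)/(n_perm + 1), which cannot be
zero and is valid by construction; a `paper_exact` option reproduces the
raw strict-exceedance proportion. Bonferroni correction multiplies by the
family size (the parcel battery by default; 200 reproduces the whole-brain
arithmetic, where raw p < 0.00025 ⇔ familywise 0.05).

Cluster strength for a participant is `(between − within)/max(between,
within)` over correlation distances, within = same-group others (self
excluded), between = participants of the other non-excluded groups. Greedy
participants are excluded by default from the ×4 pattern analyses (their
behavior differs there, so their inclusion would confound pattern and
behavior differences); whether the between pool of the original analysis
included them is not documented, so the exclusion is configurable.
Group-level inference flips the signs of the member scores (exhaustive
when 2ⁿ ≤ n_perm, guarded Monte Carlo otherwise), which implicitly
controls for group size — though a group of 4 or fewer can never reach
p < 0.05 exhaustively (min p = 1/16). Cross-condition scores correlate a
member's ×4 pattern with *other* participants' ×2 (or ×6) patterns. A
strategy map is the conjunction of the within-×4 test and both
generalization tests at α = 0.05.

The MO shift analysis z-scores patterns across voxels within participant ×
condition × parcel, builds the GA−IA difference map from group-mean
z-patterns per condition, and scores each MO participant's ×2 and ×6
patterns against the corresponding map by Pearson correlation. Aggregates:
the mean over all parcels with a paired t test of ×6 vs ×2 (a sign-flip
alternative is available through `group_sign_test` on the per-subject
differences); means restricted to GA-only and IA-only parcels of the
strategy map; and classification accuracy under the ordering rule
similarity(×6) > similarity(×2). The ordering rule is one reading of
"classified using the relative similarity score"; per-condition sign
agreement is an alternative the similarity table supports directly.

## Pipeline and reproducibility

A single config (YAML-serializable, hash-stamped) drives all stages in
order: zones → behavior → fits → comparison → assignment → neural → IS-RSA
→ cluster strength/strategy maps → MO shift. One global seed fans out into
per-stage child seeds recorded in a manifest together with output paths and
timings; identical configs produce byte-identical CSV outputs, and each
stage can be rerun from its predecessor's serialized outputs via the CLI.
Pattern analyses in the pipeline use the *fitted* strategy labels, as an
analysis of real data would; under the default behavioral noise a few
participants near zone boundaries may be relabeled relative to ground
truth.

## Problem sizes used in tests

The test suite runs the recovery experiment at the study size (57 subjects
× 1,000 starts), permutation calibrations on 200 null parcels at 200–500
permutations each, planted-signal recovery on the default 20-parcel
battery, and the end-to-end pipeline on a reduced cohort (19 participants,
8 parcels, hundreds of permutations). These sizes were chosen to keep the
full suite under a minute of compute while leaving every statistical check
adequately powered; all defaults in the package itself remain at the
study-scale values (10,000 data-fit starts, 10,000 Mantel and 5,000
sign permutations).
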