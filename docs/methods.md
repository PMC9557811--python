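# Methods

This note records the statistical model behind each stage of the pipeline,
the defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical conventions that affect results.

## Superimposition

GPA iterates: center each configuration, scale to unit centroid size (full
Procrustes fit), rotate every configuration to the current consensus by the
orthogonal-Procrustes solution with the smallest singular value
sign-corrected so det(R) = +1, then replace the consensus by the mean of
the aligned shapes re-scaled to unit size. Convergence is declared when the
summed squared change in consensus coordinates drops below `tol = 1e-8`
(max 100 iterations; non-convergence is flagged on the result, never
raised). Shape variation in the intended applications is small, so
convergence typically takes 2–3 iterations.

The full fit (rather than a partial, no-scaling fit) is used because size
enters the downstream models separately as ln centroid size; this matches
the convention of the standard geometric-morphometrics toolchains.

After convergence the whole aligned set is rotated to a canonical frame:
the principal axes of the consensus, with signs fixed so that the
largest-|coordinate| landmark on each of the first two axes is positive and
the third axis follows from det(+1). Without this step the aligned frame
would inherit the arbitrary orientation of the first specimen, and
re-running the pipeline on rigidly transformed raw data would produce
rotated (though equivalent) outputs. The convention is well-conditioned
only when the consensus' principal spreads are distinct; biological
configurations essentially always satisfy this. Consensus shapes from
*independently* superimposed datasets (e.g. per-habitat subsets) are still
only comparable up to rotation and should be compared via a pairwise
Procrustes fit.

Tangent projection (on by default, recorded in the result) maps each
aligned shape x to x + (1 − x·c)c with c the unit consensus vector — the
orthogonal projection onto the tangent plane of the preshape sphere at the
consensus. The projection changes centroid sizes by O(d²) (fractions of a
percent here); the unit-size invariant holds exactly only in the
unprojected frame. Both frames are supported and labeled because the frame
used is part of any reported result.

Screening reports follow the upper-quartile convention: a specimen is
flagged when its Procrustes distance to the consensus exceeds Q3 (literal
rule) or Q3 + 1.5·IQR (conservative rule); quartiles use linear
interpolation (numpy default, R type 7), on which membership can depend. A
1e-9 absolute floor prevents flagging exactly-equal distances through
floating-point noise. Flagging never removes specimens. Landmark
variability sums the three coordinate variances per landmark (ddof 1); the
landmark total equals the total shape variance exactly.

## Ordination and retention

PCA is computed by SVD of the centered n × 3p matrix of vectorized aligned
shapes; eigenvalues are squared singular values over n − 1, so they sum to
the total variance to machine precision. Axis signs follow a deterministic
convention (largest-magnitude loading positive). After 3D GPA the spectrum
has rank at most min(n − 1, 3p − 7): superimposition consumes 3
translations, 3 rotations and 1 scale.

The broken-stick expectation is evaluated on the *realized* positive
spectrum (m = count of eigenvalues above 1e-12 of the total), not on 3p:
with n possibly below 3p and seven degrees of freedom removed by GPA, the
null partition must be over the components that exist. Retention is
contiguous-prefix — stop at the first component at or below its stick —
with a pointwise variant behind a flag. At least one component is always
retained (with a warning when PC1 itself fails), since downstream models
need a response.

## Permutation shape models (RRPP, Type III)

Factors are sum-to-zero effect coded (sorted levels; +1 own level, −1 last
level), numeric covariates enter as-is, and interaction columns are
element-wise products. Effect coding, rather than treatment dummies, is
deliberate: it keeps main effects marginal to interactions, so deleting a
term's columns from the full design (the Type III convention used here) is
meaningful in the presence of interactions and term sums of squares
decompose additively in balanced orthogonal designs. The per-term reduced
design is literally the full design minus that term's columns.

For each term: SS = tr(E_red) − tr(E_full) from the residual cross-product
traces, F = (SS/df_term)/(SS_res/df_res). Permutation inference shuffles
whole residual rows of the reduced model (specimen-level, preserving
within-specimen covariance), adds them to the reduced-model fitted values
and recomputes F. Because designs are nested, both hat matrices annihilate
the reduced fitted values, so each permuted statistic needs only two small
projections of the permuted residuals — 10,000 permutations on hundreds of
specimens take well under a second. One shared permutation schedule serves
all terms. p uses the add-one rule (observed arrangement counted), which
makes p exact under the null and strictly positive; when the requested
count reaches n! every distinct ordering is enumerated instead and p is
the exact fraction. Z = (ln F_obs − mean ln F*)/sd(ln F*) over the
permutation distribution (non-positive F excluded), the standard effect
size for this family; fixed seeds make p, F and Z bit-for-bit
reproducible.

Sequential comparison fits a nested formula list in order; a more complex
model supersedes the current best when at least one of its added terms is
significant at α = 0.05 (configurable). Common allometry is rejected when
a size-by-habitat interaction is significant in the most complex model
containing one. When the split factor's main effect is significant, each
of its levels is re-analyzed from the raw coordinates — fresh GPA, fresh
PCA, fresh retention — never by subsetting the pooled alignment. No
multiple-testing correction is applied across terms or body regions.

The default model response is the broken-stick-retained PC scores; the
full Procrustes coordinates are equally supported (pass `al.flat()` as the
response) and give identical SS when the retained basis spans the data.

## Dimorphism index

index = D²/(V_f + V_m) with D the Procrustes distance between the sex mean
shapes and V_g = Σ d²(xᵢ, mean_g)/(n_g − 1) the within-sex Procrustes
variance. The n − 1 divisor is the sample convention; a divisor-n variant
sits behind `ddof=0`. The published summary tables this index reproduces
describe the denominator loosely as a variance "of the squared distances";
the magnitudes in those tables are only consistent with the mean squared
distance to the group mean (the Procrustes variance), which is what is
implemented — two rows of the source table that are not internally
consistent with the formula under any reading are treated as probable
table-assembly errors and excluded from verification. The "distance"
reported is the distance between mean shapes (which reproduces the
published ratios), not the mean of pairwise male–female distances.

Degenerate inputs return an explicit undefined marker (NaN plus a reason),
never infinity. The index carries a small positive sampling bias under the
null: E[D²] ≈ (1/n_f + 1/n_m)·V when the sexes share a distribution, so
the null expectation of the index is roughly 1/n̄ per group, shrinking with
sample size. An optional bootstrap CI (resampling specimens within sex) is
available but off by default.

## Synthetic data generator

The generator emulates a two-habitat × two-sites-per-habitat × two-sex
design with the study's unbalanced per-cell sample sizes (179 specimens;
e.g. one site with 9 females vs 37 males) so that unbalanced Type III
behavior is exercised by default. Landmark-count presets cover 70 (skull),
14 (pectoral) and 16/18 (pelvic) points.

Per specimen: log centroid size is Gaussian per cell (base 3.0 ≈ 20 mm,
marine +0.15, male +0.05, sd 0.12); the true shape adds to a deterministic
template the habitat/site/sex/interaction offsets along fixed unit
directions in shape space, an allometric displacement (slope 0.10 per unit
ln CS) along its own direction, and iid Gaussian digitizing noise (sd 0.01
per coordinate, shape units); the raw configuration is then rotated
uniformly, translated uniformly in a box, and scaled by exp(ln CS). Effect
directions are orthogonalized against the template (pure shape, no scale
leakage) and against each other, so injected effects decompose additively.
Default magnitudes — habitat 0.08, site 0.03, sex 0.035, interaction 0 —
were chosen so that within-sex Procrustes variances (~0.004 at p = 16) and
term Rsq values land in the ranges typical of wild vertebrate datasets of
this size, and the dimorphism index falls in the 0.06–0.29 band of the
published tables.

What the generator does *not* emulate: correlated "integration" structure
among landmarks. Real digitized data have smoothly decaying eigen-spectra,
which is why broken stick retains 5–11 components on real skulls and
girdles; under iid noise the spectrum beyond the injected contrasts is
flat and retention typically keeps only the dominant axis. Two
consequences: (i) passing tests demonstrate correctness of the machinery,
not realism of spectra; (ii) detection power for a specific injected
direction is assessed on the full-coordinate response, because a PC-score
response can exclude an orthogonally injected direction regardless of its
magnitude. Noise is added in shape space before the nuisance transforms
(digitizing error is shape-level); a separate nuisance stream
(`nuisance_seed`) allows re-drawing rotations/translations while holding
shapes fixed, which the pipeline must be — and is — immune to.

Reproducibility: one RNG stream with fixed draw order (effect directions;
then per specimen: log size, noise, rotation, translation); a (spec, seed)
pair regenerates a dataset bit for bit.

## Problem sizes used in validation

The validation suite runs entirely on generated data at the default design
(n = 179, p = 16) or smaller: the null-calibration study uses 500
replicates of n = 40 with 999 permutations on a 2-column response; the
exhaustive-enumeration cross-check uses n = 6 (720 orderings); recovery
studies use 100 replicates for the index-monotonicity curve and 60 for
detection power with 499 permutations per fit. These sizes give
Monte-Carlo error comfortably inside the asserted bounds while keeping the
whole suite fast.

## Known limitations

* No sliding semilandmarks, bilateral-symmetry decomposition, or
  missing-landmark estimation; missing coordinates are an error.
* Procrustes distance is the tangent-space (Euclidean) approximation, not
  the shape-space geodesic — appropriate for the small variation the
  models assume.
* Mixed/nested random effects (site within habitat) are out of scope; site
  is modeled as a fixed factor within habitat subsets.
* The dimorphism index is defined for exactly two groups.
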