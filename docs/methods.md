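# Methods

## Pipeline model and assumptions

The analysis treats each participant's resting-state scan as a T × N matrix
of BOLD samples (T time points, N ROIs in a fixed atlas order) and assumes:
stationary second-order structure within a scan, temporal autocorrelation
adequately captured by a first-order autoregressive model, and linear,
additive nuisance contributions from head motion and tissue signals. All
group inference is permutation-based and therefore relies only on
exchangeability of participants under the null, not on Gaussian errors.

### Atlas and extraction

ROIs are spheres (default radius 5 mm) at MNI coordinates. A voxel belongs
to a sphere iff its center (world mm via the image affine) lies within the
radius — a closed ball, with no de-duplication across overlapping spheres
(MarsBaR-style behaviour). Extraction is the voxel mean per time point and
is exactly linear in the image data. The packaged 232-ROI table
(`data/atlas232_synthetic.tsv`) is a *synthetic* stand-in fixture laid out
in the style of the Power parcellation: coordinates and labels are
generated, and its network counts are designed so that merging the two
somatomotor sub-networks and dropping the cerebellar, uncertain and
subcortical networks leaves 131 ROIs over 7 networks. Real analyses should
load their own atlas table; all merge/exclusion rules are arguments, not
hard-coded.

### Prewhitening

Two steps. Step 1: ordinary least squares of the raw series on the six
motion parameters (intercept always included); the lag-1 autocorrelation of
the residuals gives φ per ROI (Yule–Walker order 1, clipped to ±0.99); the
raw series is filtered as `x̃_t = x_{t+1} − φ x_t`. Step 2: motion (trimmed
by one row to match, deliberately not re-whitened), WM and CSF are regressed
out of the whitened data. Choices exposed as flags: a pooled φ (mean across
ROIs) instead of per-ROI estimates, and a stationarity-scaled first row
`√(1−φ²)·x_1` instead of dropping the first sample. Defaults: per-ROI φ,
drop the first sample — at T = 260 the edge effect is negligible.
Rank-deficient designs fall back to the minimum-norm least-squares solution
with a logged warning, which equals dropping the dependent columns.

### Functional connectivity and permutation inference

z = atanh(r) with |r| clipped to 1 − 1e−15; diagonals are excluded from all
summaries. The whole-brain statistic per participant is the mean
upper-triangle z; the group comparison statistic is the difference of group
*medians* of these values (difference of means by flag). Permutation p uses
the add-one rule, `p = (1 + #{|null| ≥ |obs|}) / (n_perm + 1)`, two-sided
via absolute values, so p is never 0 and never below `1/(n_perm+1)`. An
exact mode enumerates all C(n, n_a) label assignments (identity included;
`p = count/total`). Family-wise error control is by the max-statistic
method over the family supplied in one call — the caller defines the family
(e.g. the hub set), not all N ROIs; Bonferroni is available by flag. Ties
at |observed| count as extreme (tolerance 1e−12).

### Eigenvector centrality

Adjacency `A = r + 1` (entries in [0, 2]); the diagonal convention is 2 and
is provably immaterial: eigenvectors are invariant to adding cI, which the
test suite asserts numerically rather than assumes. Power iteration starts
from the uniform positive vector and stops when successive normalized
iterates differ by < 1e−12 in max-norm (cap 10,000 iterations;
non-convergence is flagged, not fatal). The eigenvalue is the Rayleigh
quotient. Group-level centrality is the per-ROI mean over participants of
per-participant EC vectors (EC of the group-mean adjacency by flag). Hubs
are ROIs with group-mean EC at or above the linear-interpolation 95th
percentile; ties at the threshold are included so no ROI is silently
dropped.

### Surrogate and bootstrap distributions

iAAFT surrogates alternate (i) imposing a working amplitude spectrum while
keeping current phases and (ii) rank-remapping onto the sorted original
values. Plain alternation leaves a spectral bias because the value remap
perturbs the just-imposed spectrum; the implementation therefore nudges the
working amplitudes by the damped correction
`A_imp ← A_imp · (A_target/A_achieved)^0.5` each iteration and returns the
post-remap iterate with the smallest mean relative periodogram error. The
value multiset is consequently *exact* on every output, and the mean
relative periodogram error on AR(1) test series (φ = 0.6, T = 260) is ≈ 1%.
Iteration cap: 100 (public single-series call); the pipeline driver uses 15
for its replicate loops. Surrogates are drawn independently per ROI and per
participant, which destroys cross-ROI correlation — the resulting EC null
describes "no functional communication" and centers near the uniform value
1/√N (for N = 131, ≈ 0.0874), not at zero, because EC entries are
constrained nonnegative on a positive matrix.

The bootstrap draws one with-replacement time-index vector per participant
per replicate and applies it to all ROI columns jointly, preserving
cross-ROI structure; it is a confidence distribution for the EC point
estimate. Simple (non-block) resampling destroys autocorrelation; a
moving-block variant (block length ⌈√T⌉) is available by flag. Gaussian
summaries are the sample mean and SD (ddof 1) per ROI.

### Behavioral scores

Grids are standard 24-2 (54 points, 52 after excluding the two blind-spot
locations at (±15°, ±3°)) and 30-2 (76/74) patterns in visual-field degrees,
x positive rightward for both eyes, so "the same location" means the same
point in visual space; left-eye grids mirror the nasal extension. WorseMD =
min of the two eyes' MD; AbsDiffMD = |MD_R − MD_L|; BIVF = mean over the
location intersection of the pointwise maximum total deviation — a 30-2 vs
24-2 pairing overlaps on the common subset. MD is read from the instrument
export when available (instrument MD is age-adjusted and not recomputable
from TD); the fallback `md = mean(td)` used for synthetic maps is flagged.
Spearman correlation uses average ranks; the two-sided p is an exact
permutation enumeration for n ≤ 9 and the t-approximation otherwise;
participants missing a score are dropped pairwise and pairings with < 4
complete pairs are marked not computable.

## Synthetic cohort generator

Each ROI series is `x_j(t) = λ_j s(t) + γ c_{net(j)}(t) + (confounds) +
noise_j(t)` with unit-variance AR(1) latents and noise (φ = 0.3, typical of
BOLD at TR ≈ 1.35 s). Defaults define the study conditions: 131 ROIs over 7
networks, 260 time points at TR 1.35 s, 24 controls and 20 patients, two
scans with shared loadings and independent noise, and 7 controls plus 1
patient without perimetry (effective behavioral n = 36). Planted hubs
(6 ROIs) load on the shared signal with λ = 1.5 against a base loading of
0.5 (ratio 3) and network loading γ = 0.8 — giving hub–hub correlations
≈ 0.6, within-network ≈ 0.35 and background ≈ 0.2, plausible resting-state
magnitudes. Disease severity (patients: normal with mean 3, SD 1.5, clipped
at 0; controls: 0) attenuates hub loadings multiplicatively with coupling
0.1 — about a 30% loading reduction at the mean, a moderate effect — and
simultaneously drives visual-field loss through
`td = −softplus(severity + asymmetry·eye_sign + field)` clipped to
[−32, 2] dB, with a squared-exponential spatial field (SD 0.8, length scale
10°). Confounds are smoothed random-walk motion and low-frequency sinusoid
WM/CSF mixtures added with per-ROI random loadings (overall SD 0.5).

What the generator emulates: planted high-centrality structure, AR(1)
temporal noise, additive confounds, test–retest structure, and
severity-coupled paired-eye perimetry. What it does not: hemodynamic
response shape, image-level motion artifacts, spatial smoothness of real
parcellations, non-stationarity, and the instrument's age-normalized MD
scale (so synthetic MD magnitudes are not on the clinical dB scale).
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated generative assumptions, not clinical validity on
real cohorts.

## Problem sizes and numerical choices

The driver's default replicate counts are scaled for a single-CPU desk run:
15 surrogate replicates (iteration cap 15), 50 bootstrap replicates and
10,000 label permutations; all counts are configuration fields and the test
suite exercises the same code paths at a mixture of full analysis scale
(131 ROIs × 260 time points × 44 participants) and reduced scale. Every
stochastic operation takes an explicit seed, recorded in the run manifest;
the driver spawns per-stage seeds from one root seed in a fixed order, and
result JSON is rounded to 10 decimals and key-sorted so reruns are
byte-identical.

Degenerate inputs: zero-variance ROI columns are an error in correlation
stages and a warned φ = 0 in AR(1) estimation; constant series pass through
the surrogate generator unchanged with a warning; all-equal centrality makes
every ROI a hub (tie rule); fewer than 2 samples give a zero-SD Gaussian fit
with a warning.

## Known limitations

- The whitening filter assumes AR(1); higher-order or spatially varying
  autocorrelation (FILM-style) is out of scope.
- The surrogate null randomizes each ROI independently; multivariate
  surrogates preserving the cross-spectrum are not provided.
- Voxel-wise ECM on full volumes (implicit adjacency at 10⁵-voxel scale) is
  out of scope; the implementation operates at ROI resolution.
- The packaged atlas fixture is synthetic; results on it characterize the
  software, not any real parcellation.
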