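# Methods

`nsiscreen` re-creates, end to end and on synthetic data, a live-cell
high-content screen for compound *non-stickiness*: the ability of a
fluorescent small molecule to enter cells during an incubation period
and wash out again during a clearance period.  Because the original raw
screen images and the real library structures are not publicly
available, the package pairs the analysis pipeline with a generator
that produces plate images with exact ground truth, so every stage can
be validated by parameter recovery rather than by eye.

## The screening model

A combinatorial library of fluorescent compounds is built on a
xanthene-like scaffold with two diversity positions: an R1 block
(letters A–L, an amine substituent on the tricyclic core) and an R2
block (numbers 1–33, a substituent on the pendant phenyl).  The default
library takes the first 20 R2 numbers in each of the 12 R1 blocks
(240 compounds); the real 240-member subset of the 12 x 33 grid is not
published, so a deterministic rule was chosen.  Fragments were selected
so that sharing an R1 letter implies sharing a large substructure;
mean path-fingerprint distance within an R1 block (~0.2) is well below
the between-block mean (~0.5), which is the only structural property
the downstream analysis relies on.

Each well holds one compound on one cell line and is imaged in three
channels (nuclear stain at 655 nm; compound emission at 475 and
549 nm) at two timepoints: T0 right after incubation and wash, and T1
after a further ~60 min clearance window.  Per (compound, cell line),
the generator draws one of four flux behavior classes —

* `no_entry` (k_in ~ 0),
* `membrane_bound` (bright rim, dark interior, no clearance),
* `accumulate` (enters, retained; net rate >= 0),
* `in_and_out` (enters and clears; k_out in 0.012–0.05 /min) —

plus a subcellular localization (nuclear, perinuclear, or diffuse) for
compounds that enter.  The population T1/T0 ratio is
exp((growth − k_out) · 60 min); its logarithm is the quantity the
screen's statistic estimates.  Per-cell amplitudes are lognormal with a
20% coefficient of variation, and per-cell T1/T0 ratios carry an extra
5% lognormal jitter, emulating the heterogeneity that motivates
cell-by-cell (rather than well-level) quantification.  Cell lines
differ by uniform multipliers (0.7–1.3) on uptake and clearance rates.
With probability `structure_link` (default 0.7) a compound inherits its
class from an R1-block-level draw, creating the structure–activity
association the chemoinformatics arm is designed to detect; at 0 the
association vanishes (verified by chi-square).

## Image formation

Nuclei are anisotropic Gaussian-profile ellipses (semi-axis 5–9 px,
axis ratio 0.7–1.0); the nucleus mask is the 1-sigma ellipse and the
cell body is the same ellipse scaled 2.2x.  Compound signal is
deposited per cell according to its class: a near-uniform plateau with
a soft logistic edge for diffuse (a center-peaked profile would be
indistinguishable from nuclear-bound), a Gaussian confined to the
nucleus for nuclear, an annulus hugging the nucleus for perinuclear,
and a ~2-px ring at the body edge for membrane-bound.  Profiles are
normalized so the integrated signal equals the cell's true flux
exactly; ground truth records centroids, label images, fluxes, and the
inter-timepoint transform before any noise.

About 10% of nuclei are placed as touching pairs — boundaries in
contact (center distance 1.05x the summed radii), which merges their
above-threshold glow into a single foreground component while the two
cores remain resolvable.  This is the configuration the touching-cell
splitting step exists for; substantially closer centers produce one
unimodal blob that no detector can separate.

Noise is additive Gaussian read noise (sd 8 a.u.) over a flat
background (200 a.u.), with optional Poisson photon noise, followed by
16-bit quantization.  Quantization is itself a noise source: on flat
profiles every pixel shares the same rounding error, which does not
average out, so "noiseless" validation fixtures disable quantization as
well (`NoiseParams(quantize=False)`).  The T1 frame is the same scene
advanced in time and moved by a random stage drift (up to ±8 px
translation per field).  No point-spread-function or photobleaching
model is included.

## Quantification pipeline

1. **Background correction**, per image: foreground/background
   segmentation by a two-phase piecewise-constant active contour
   (Chan–Vese, tolerance 1e-4), Otsu threshold, or a two-Poisson EM
   mixture; the background level is the median of background-class
   pixels and is subtracted with clipping at zero.  The three policies
   give background estimates within 1% of each other on rendered
   fields; Otsu is the default for full-screen runs purely for speed.
   Note that soft Gaussian edges have no unique foreground boundary, so
   the methods' absolute foreground *fractions* differ even when their
   corrections agree.
2. **Nuclear segmentation**: multiscale Laplacian-of-Gaussian blob
   detection seeds a marker-based watershed on the distance transform
   of the Otsu foreground, which splits merged components covering two
   seeds ("geometric reasoning" concretized); candidates under
   30 px² are dropped and centroids are intensity-weighted.
3. **Territory tessellation**: each pixel within reach of a nucleus
   (1.25 x 1.2 equivalent radii + 2 px, per nucleus — covering the
   2.2x body with margin for ellipse anisotropy) is assigned to its
   geodesic nearest seed by watershed on the distance-to-nucleus
   transform.  Regions partition the foreground exactly, so summed
   per-cell fluorescence conserves the total by construction.
4. **Readouts** per cell and channel: integrated sums over nucleus and
   territory; fixed-band rim (outer 2 px), interior, and perinuclear
   (3-px annulus) means; and self-calibrating *radial shell* means —
   inner, middle, and outer thirds of the cell body by distance from
   the nucleus, with the shell extent capped at the expected body edge
   (1.2 x (cell_scale − 1) nucleus radii) rather than the territory
   boundary.  The shells drive phenotype calls because the territory
   is drawn with a safety margin: its outer 2-px band generally lies
   beyond the physical membrane, a whole-cell mean diluted by empty
   territory pixels biases every localization call toward "nuclear",
   and shells stretched to the territory edge wash out rim contrast.
5. **Channel selection**: per well, the wavelength (475 vs 549) with
   the larger total T0 response is used for both timepoints; ties go to
   549.
6. **Registration**: nuclei centroids are matched by mutual nearest
   neighbor, an affine transform is fit by least squares with
   iterative outlier rejection (cutoff 3 sd, floored at 1.5 px so
   ordinary jitter is never discarded), then matching is refined
   through the fitted transform (repairing mispairings when drift
   approaches the cell spacing).  Matched pairs become flux records;
   unmatched cells are reported and excluded.  Drift accuracy is
   assessed at the field center, where the pipeline uses it — the raw
   translation column extrapolates to pixel (0,0) where jitter is
   amplified by leverage.

## The non-stickiness index

Within each compound x cell-line group, fluxes are min–max normalized
with the group extrema over both timepoints,
F̂_t = (F_t − F_min) / (F_max − F_min + ε), and each cell is scored

    NSI = ln((F̂_T1 + μ) / (F̂_T0 + μ)),   μ = 0.01, ε = 1e-9.

Negative NSI means the signal cleared (desirable).  The pseudocount μ
is small relative to the unit-normalized scale and guards the
logarithm; whether the original assay placed its constant inside or
outside the normalization is unknowable from the available description,
so μ is an exposed parameter, not a reconstruction.  The statistic is
exactly invariant to a shared additive offset or positive scaling of a
group's fluxes — which also absorbs most of the clipped-noise bias the
background correction introduces on dim wells.  A `percent_drop`
variant, (F_T0 − F_T1)/F_T0 on an inverted sign scale, is available;
the log-ratio is the default for its robustness to outliers.

Wells are summarized by the arithmetic mean NSI (median and dispersion
retained); per-line R1 x R2 heatmaps are combined elementwise across
lines by mean (default), median, or worst-line (elementwise maximum — a
compound is only as good as its stickiest line); compounds are ranked
ascending with lexicographic tie-breaks.  Missing grid cells (the 156
unsynthesized pairs) are kept distinct from NSI = 0 throughout.

Behavior calls use a threshold tree: interior density (mean of nucleus
+ inner/mid shells) below tau_u = 0.2 of the plate's 95th-percentile
reference → no entry, unless the outer shell is both tau_m = 2x the
interior and above tau_r = 5% of the reference (membrane-bound);
entered cells split at NSI < −theta (theta = 0.5) into in-and-out vs
accumulate.  Localization compares nucleus and shell densities against
each other at a 1.5x contrast.  All thresholds are package decisions
with no counterpart in the original description.

## Secondary screen and agreement statistics

The secondary (root-hair-like) assay is simulated at scalar level — one
NSI-scale observation per compound — via a Gaussian copula on the
mammalian consensus true log-ratio: normal scores are mixed with noise
at r = 2·sin(π·ρ/6), the inverse of the bivariate-normal Spearman
relation, then quantile-matched back onto the primary value
distribution so signs are comparable.  Realized rank correlation is
calibrated to the requested ρ within ±0.1 over 50 replicates.
Cross-screen agreement is reported as Pearson/Spearman plus a 2x2 sign
co-occurrence table at cut 0 (negative = desirable) with a Haldane 0.5
correction for zero margins.

## Chemoinformatics arm

Structural dissimilarity is 1 − Tanimoto similarity on hashed
topological-path fingerprints (paths up to 7 bonds, 2048 bits).  This
is an openly specified stand-in for the maximal-common-subgraph and
commercial descriptors behind the original analysis, which consumed
only a dissimilarity matrix; numerical agreement with that analysis is
neither attainable nor claimed.  Compounds are embedded in 2-D by
classical (Torgerson) MDS — double-centering, eigendecomposition,
top-2 nonnegative eigenpairs, negative eigenvalues truncated but
reported.  For genuinely planar inputs the embedding reproduces the
configuration to Procrustes residual < 1e-6.

Block clustering is quantified by the mean silhouette with R1 as the
cluster label plus within/between-block distance means.  Two caveats
discovered during validation.  First, with 12 clusters the silhouette
of *randomly permuted* labels is structurally negative (≈ −0.2),
because each point's between-cluster term is a minimum over 11 noisy
cluster means; the permutation null is zero-centered only for a
balanced two-cluster split.  Tests therefore check the two-cluster
null against zero and require the true R1 labeling to exceed its own
12-block null by more than five standard deviations.  Second, twelve
well-separated, near-equidistant blocks form a simplex that no planar
embedding can separate, so the 2-D silhouette hovers near zero even
when the distance-space silhouette (precomputed metric) is ~0.5; the
within/between distance contrast is the robust block-structure
statistic, and the 2-D map is treated as a visualization.

Property–response association (molecular weight, logP, TPSA, rotatable
bonds, H-bond donors/acceptors, ring count vs mean uptake and mean
NSI) is reported as Spearman and Pearson coefficients with seeded
permutation p-values (10,000 permutations).

## Problem sizes and numerical choices

Validation workloads were sized for a single-CPU workstation run: the
full-screen recovery uses the 240-compound library on one cell line,
two 256 x 256 fields per well and 25 cells per field (~12,000 cells);
segmentation quality uses 20 fields of 30 cells at default noise;
registration uses 50 point-set fixtures (0.5-px jitter, ≤10-px drift);
phenotype-call accuracy uses five 40-compound noiseless mini-screens.
Under these conditions per-compound mean NSI recovers the generator's
true log-ratio ranking at Spearman ≥ 0.9.  The `no_entry` class
contributes near-zero rank information by construction — a compound
that never enters cells produces no signal, so its clearance rate is
unmeasurable; its true log-ratios span only [−0.23, 0], which bounds
the achievable correlation but does not push it below 0.9.

Degenerate inputs are defined rather than left to chance: constant
images yield an empty foreground and background equal to the constant;
blank fields yield zero nuclei without error; flat flux groups
(F_max = F_min) score NSI = 0 and are flagged uninformative; wells with
no cells are flagged rather than scored.  All randomness flows through
explicit integer seeds; generators called twice with the same arguments
are byte-identical.

## What passing tests do and do not show

The generator emulates the features the analysis depends on — two-point
kinetics, four behavior classes, three localizations, per-cell
heterogeneity, stage drift, channel bleed-through, read noise and
digitization — but not optics (PSF blur), illumination fields,
photobleaching, cell division or movement between timepoints, or
segmentation-hostile morphologies of real adherent cells.  Recovery
results here therefore demonstrate correctness of the computation, not
expected performance on real microscopy; on real data the segmentation
and registration stages would dominate the error budget.  The library,
likewise, preserves block-wise structural similarity but not the real
compounds' chemistry, so the structure–activity findings are
qualitative properties of the model, not of any physical library.
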