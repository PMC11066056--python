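# Methods

## The measurement problem

Three co-registered fluorescence channels are recorded per field of view:
DNA (DAPI), 16S rRNA (CARD-FISH, SAR11-specific probe mix by default), and
intracellular phage DNA (direct-geneFISH polynucleotide probes).  Cells are
classified by which channels they light up in; the quantities of interest
are the fraction of SAR11 cells that are phage-infected, the fraction of
all cells that are "zombies" (DNA⁺ phage⁺ rRNA⁻), the SAR11 fraction, and
the frequency of dividing cells (FDC, a division-rate proxy).  Real data
for this assay is microscopy; here a parametric scene generator stands in
for the microscope so that each downstream stage can be checked against a
known ground truth.

## Scene generator

Cells are axis-aligned ellipses with equivalent diameters drawn uniformly
from `cell_diameter_range` (default 0.4–0.8 µm — SAR11 are among the
smallest free-living bacteria) and mild aspect ratios (1–1.25).  Free
phage particles are sub-resolution disks (default 0.15 µm, well below the
minimum cell diameter).  Per class, per channel mean amplitudes are given
in 8-bit intensity units above a constant background (default 20) with
additive Gaussian read noise (default sd 2) clipped at zero; the optics
are an isotropic Gaussian PSF (default sigma 0.1 µm, a standard widefield
approximation).  No Poisson shot noise, vignetting or chromatic shift is
modeled — the point is a closed-form-checkable optical chain, not
photorealism.

Dividing cells are drawn from the upper half of the size range, elongated
1.6× along the major axis, and rendered in the DNA channel as a dim
envelope (0.4× the class amplitude) plus two condensed nucleoid foci.
The foci are continuous 2-D Gaussians rather than rasterized disks: with
disks, sub-pixel placement makes the two blurred peaks unequal by tens of
grey levels, which turns the "two local maxima" rule into a coin flip for
the smallest cells.

Placement is rejection sampling with zero overlap between the PSF-dilated
exclusion zones (per-object margin 4·sigma_psf + 1 px); a field that
cannot accommodate the request raises `PackingError` rather than silently
overlapping objects, so segmentation errors and gating errors stay
separable in tests.  `scene_for_fractions` auto-sizes the field (~4000 px²
per object) when no shape is given.  A fraction of infected cells can be
rendered with sub-threshold rRNA amplitude (`ribosome_continuum_fraction`)
to emulate the continuum of ribosome depletion seen in infected cultures;
the default is 0 so ground-truth recovery tests stay exact.

Negative controls re-render the identical scene (same seed, same
placement, same noise draws) with every phage amplitude zeroed, matching
control samples never exposed to the phage-probe mix.

What the generator does *not* emulate: optical crowding and overlapping
cells, autofluorescence structure, focus drift, hybridization efficiency
variation.  Passing tests therefore demonstrate the correctness of the
counting rules and the statistical machinery, not robustness to every
artifact of real micrographs.

## Cytometry

Per-channel thresholds default to modal background + 5 robust sigmas
(median and 1.4826·MAD over the plane), with a floor of 2 intensity units
above background so the zero-noise degenerate case (MAD = 0) keeps a
finite threshold.  Objects are connected components (8-connectivity by
default) of the union of channel masks.  An object is channel-positive
when its *mean* intensity over the mask exceeds the channel threshold
(max-based rule available by config); the mean is stable for small
objects and makes rRNA-negativity of zombies unambiguous.

The free-phage size gate deserves a note.  Conceptually the cutoff is a
true size (~0.25 µm equivalent diameter, far above ~100 nm capsids), and
`GateConfig.free_phage_max_area` defaults to the corresponding 0.05 µm².
Measured areas, however, are thresholded supports inflated by the PSF —
a point source blurred by sigma 0.1 µm measures ~0.2–0.3 µm².
`calibrate_gates(spec)` therefore renders one isolated free phage and one
isolated minimum-diameter cell under the scene's optics, measures both,
and places the gate at the geometric mean of the two measured areas
(min_cell_area at 0.8× the measured smallest cell).  All recovery tests
use calibrated gates; with them, class counts on noise-free scenes match
ground truth exactly, and the false-positive (infected+zombie) rate on
negative controls at default noise is 0 of >5000 cells.

Classification is a total partition: small phage⁺ objects are free
phage/vesicles; small phage⁻ objects are sub-cellular specks (rejected,
excluded from totals); DNA⁺rRNA⁺ is SAR11 (+phage⁺ infected); DNA⁺phage⁺
rRNA⁻ above the gate is a zombie (zombies must contain DNA — large DNA-free
phage⁺ objects are rejected); DNA-only objects enter only the total count.
`total_cells` is every DNA⁺ object above the gate.  Ratios use the
published denominators (infected/SAR11, zombie/total); zero denominators
yield NaN plus an explicit flag, never silent zeros.

Dividing cells: the DNA plane is smoothed (sigma 1 px), h-maxima with
prominence h = 10 grey levels are extracted, and maxima components
intersecting the object mask are counted; plateaus merge to one maximum.
Exactly two maxima ⇒ dividing; more than two is treated as an aggregate
and not counted.  Under default noise the detector finds ≥ 99% of
rendered dividing cells; FDC accuracy is asserted statistically
(|FDC − d| ≤ 3 binomial SEs at n ≥ 500), not exactly.

An `eub_mode` flag re-interprets the rRNA channel as an all-bacteria
(EUB I-III) probe so that zombie abundance among all bacteria can be
compared to zombie abundance among SAR11 (the probe-specificity design
analyzed with repeated-measures ANOVA); the gating logic is unchanged.

## Probe design

Candidates are windows of length {156, 200, 250, 318} at a 10-bp step
(bounds 156–318 bp), kept when GC ∈ [0.22, 0.432] and ungapped identity
to every reference is ≥ 0.90.  Identity is the maximum over all
equal-length reference substrings of matches/length; the candidate scan
seeds diagonals with exact 9-mers, which by pigeonhole cannot miss any
alignment at ≥ 90% identity for these window lengths, so the thresholded
decision equals the exhaustive O(L·W) scan (verified against it in
tests).  Off-target screening removes candidates whose identity to any
off-target sequence *strictly exceeds* 0.80 (a shared-k-mer metric is
available); the boundary case is retained.  Selection is greedy:
score = class preference (terminase/polymerase/structural 2.0 vs 1.0)
+ identity + (1 − |GC − genome GC|) − 0.5·crowding, where crowding
penalizes centers closer than genome_length/13 to an already-selected
probe (an even-spacing soft constraint); ties break to the leftmost
start; selection stops at 13 and fewer than 10 feasible probes is an
error naming the binding constraint.  The scan step, the scanned length
set and the scoring weights are conventions of this implementation — the
original probes were designed manually — and all are exposed in
`ProbeConfig`.

## Abundance

`mag_rpkm` and `phage_relative_rpkm` are the two display formulas, exact
arithmetic.  "Total reads in a sample" is read as library size (all
reads), per the formula's wording.  Multi-mapping is allowed
(mapped > total is not rejected).  A phage record in a sample without any
SAR11-MAG reads is undefined and flagged, not zero: "no SAR11 detected"
and "no phage" are different observations.  The module consumes count
tables; the bundled exact-substring toy mapper exists only to feed
end-to-end tests.

## Statistics

*Welch's t*: textbook unequal-variance statistic with Welch–Satterthwaite
df, two-sided p; accepts summaries (n, mean, sd) or raw samples.  On the
published triplicate zombie-fraction summaries it reproduces
t(3.6) = −0.26, p = 0.81 and df = 3.9 for the second culture.

*Repeated-measures ANOVA*: one within-subject factor, F = MS_condition /
MS_(condition×subject), df (k−1, (k−1)(n−1)); missing cells error (no
imputation).  Equals a paired t² at k = 2 and the explicit sum-of-squares
decomposition everywhere (both tested, plus a pingouin cross-check).

*Zero transform*: proportions shift by +0.001 uniformly so exact zeros
enter the open beta support; inputs with x + 0.001 ≥ 1 are rejected.

*Beta regression*: mean-precision parameterization with logit link.
Priors are improper flat on intercept and slope; the precision φ gets a
half-normal(0, 50) — proper, weak, and documented, since "flat priors"
alone leave φ's prior unspecified.  The sampler is adaptive random-walk
Metropolis over (β₀, β₁, log φ), all 4 chains advanced in lockstep:
the first warmup half adapts per-chain diagonal step sizes toward ~0.375
acceptance, then a pooled-covariance proposal (2.38²/d scaling) is
estimated and its global scale tuned for the remaining warmup, and the
kernel is frozen for the 2000 retained draws per chain (4 × 2000 = 8000
draws, the published schedule).  The 3-dimensional posterior is
well-behaved, so a gradient-free kernel with covariance adaptation mixes
adequately (acceptance ~0.3–0.45, split-R̂ < 1.01 in practice);
non-convergence (split-R̂ ≥ 1.05) flags the fit rather than failing
silently.  Posterior means, sds, equal-tailed 95% intervals and
directional tail fractions are computed from the retained draws; tail
fractions are reported as raw fractions with the draw count (1 of 8000 is
0.000125).  At large n the posterior mean agrees with an independent
maximum-likelihood optimum (tested at n = 2000 within 0.1 on the slope).

*Simulator*: covariates default to uniform on [0, 0.15] (the observed
zombie-fraction range); the SAR11-covariate model uses [0.02, 0.5]
(SAR11 typically 20–50% of cells, dropping ~90% during bloom collapse)
and the FDC model a percent-scale covariate.  Responses are
Beta(µφ, (1−µ)φ) draws with φ = 30 in recovery experiments, chosen to
give dispersion comparable to the published posterior uncertainty at
n = 148.

The third published regression is implemented as rel_infT ~ FDC_percent
(FDC on the percent scale, matching the reported slope magnitude of 0.04
per percent).

## Pipeline

`run_end_to_end` renders a 12-day bloom-shaped series (Gaussian
prevalence bump peaking at 19% of SAR11 infected, zombie fraction
tracking it, SAR11 fraction dipping as infection peaks), counts each day,
and fits the three regressions on the recovered fractions.  Twelve days
is the demo default because the regression stage requires ≥ 10 rows.
Problem sizes throughout (field sizes, cells per field, scene counts in
tests) are chosen so the full suite and the acceptance script each run in
about a minute on one core while keeping ≥ 5000 cells in the
negative-control audit and ≥ 1000 SAR11 cells in the prevalence-recovery
experiment.

## Known limitations

* The generator's per-channel signal-to-noise and the cell-size
  distribution are conventions, not calibrations — the original study
  does not report them.
* The exact channel settings and zombie size criterion of the original
  image-analysis software are not public; the robust-threshold and
  calibrated-gate defaults here are this package's own declared rules.
* Ungapped identity is not an alignment; probes spanning indel-rich
  regions would be scored differently by an aligner.
* The Metropolis sampler is adequate for these 3-parameter posteriors but
  is not a general-purpose replacement for HMC at higher dimension.
* FDC is reported as a fraction; conversion to divisions per day requires
  an external calibration and is out of scope.
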