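# Methods

`vogquant` reimplements, as a tested pipeline over synthetic data with exact
ground truth, the single-virion quantification used to validate fluorescently
tagged HIV-1 integrase (IN) constructs: virus-on-glass (VOG) imaging of
labeled virions, colocalization of the IN label with mature capsids, and
infectivity readouts from flow-cytometry-like event tables.

## The synthetic virus-on-glass field

Virions spun onto a fibronectin-coated coverslip form a thin monolayer of
diffraction-limited point emitters.  The generator (`vogquant.synth`) draws
particle positions from a uniform spatial Poisson process over the field
(clumps allowed — chance colocalization is handled downstream by the null,
not suppressed in the generator), places them in a thin axial layer
(Gaussian, SD 0.1 µm, centred in the stack), and renders each as a 3-D
pixel-integrated Gaussian PSF spot.  Poisson shot noise, a constant photon
background and Gaussian read noise are added.  One seed expands into
per-purpose substreams (geometry, labels, reference stain, shot noise, read
noise) so enabling or disabling one noise source never shifts the others.

Per-particle label copy numbers follow the packaging stoichiometry of the
labeling system:

| labeling mode  | copies per virion | rationale |
|----------------|-------------------|-----------|
| `gag_anchored` | log-normal, mean 2000, CV 0.25 | Gag is packaged at >1500 copies per virion; the Gag-fused IN label is 1:1 with the labeled construct's Gag |
| `pol_anchored` | `round(gag_copies / 20)` (~100) | Gag-Pol is packaged at the natural 1:20 Pol:Gag ratio |
| `vpr_anchored` | log-normal, mean 700 | Vpr-mediated incorporation saturates at a few hundred copies |

In trans configurations each construct labels a particle independently with
its `incorporation_prob`; a cis (packaging-vector) system corresponds to
probability 1.  A `dual_label_fraction` argument instead makes labeling
jointly all-or-none, for preparations where the labeled constructs
co-segregate.

A fraction of particles (default 0.9) is flagged *mature*; only these carry
signal in the far-red reference channel, emulating an anti-capsid
immunostain that recognizes only mature cores (the antibody channel,
log-normal ~3000 photons, CV 0.3).  Expected integrated signal is
`copies × photons_per_copy` with a per-channel gain of 2 photons/copy, which
puts Gag-anchored particles (~4000 photons) comfortably above the detection
floor and Pol-anchored particles (~200 photons) near it, mirroring the
qualitative brightness ordering of the constructs.

Defaults the data do not pin down and that were therefore fixed once, a
priori: pixel pitch 0.108 µm (60× magnification with 6.5 µm camera pixels),
NA 1.4 oil objective (n = 1.515), 512×512 px fields, 5 z-planes at 0.25 µm,
particle density 0.02/µm² (sub-confluent, mean nearest-neighbour spacing
~3.5 µm), background 10 photons/px, read noise SD 2.  All are exposed in
`FieldParams`/`RunConfig`.

What the generator does **not** emulate: optical aberrations and PSF
asymmetry, non-uniform illumination, uneven antibody staining, particle
aggregation beyond Poisson clumping, camera fixed-pattern noise, and
auto-fluorescent debris.  Passing recovery tests therefore show that the
analysis chain is correct and unbiased under the assumed imaging physics,
not that it is robust to every real-microscope artifact.

## Optics: PSF, deconvolution, projection

The theoretical PSF is a separable Gaussian discretized on the voxel grid
with `sigma_lateral = 0.21 λ/NA` and `sigma_axial = 0.66 λ n/NA²` — the
standard Gaussian approximation to the diffraction-limited widefield PSF,
chosen over vectorial models because it is analytically checkable and
adequate for isolated sub-diffraction puncta.  Kernels are truncated at 3σ
(capped to the image extent and renormalized when the stack is shallow) and
normalized to unit sum.

Richardson–Lucy deconvolution uses the standard multiplicative update, run
in Fourier space with the kernel transform computed once, on an image padded
reflectively by one kernel radius (suppresses edge ringing; detections near
edges are additionally excluded downstream).  Internals run in float32 —
ample for photon-count data.  Default 15 iterations.  Flux is conserved to
within 1–2% on interior-dominated fields; a delta kernel reproduces the
input and a flat image is a fixed point (tested).

Z maximum-intensity projection follows deconvolution, then detection runs on
the projected 2-D image, matching the acquisition-analysis order
(deconvolve → project → detect).

## Detection

Crocker–Grier style: a difference-of-Gaussians band-pass (noise scale 1 px,
background scale = spot diameter) with negatives clipped; candidate local
maxima above the 64th percentile of positive filtered pixels; greedy
brightness-ranked suppression so that of any pair closer than `separation`
(default = diameter = 7 px) only the brighter survives; sub-pixel centroids
by iterated intensity-weighted centre of mass in a circular mask of radius
diameter/2 (convergence 0.005 px or 10 iterations); detections within that
radius of the border are discarded.  Mask attributes: mass (integrated
background-corrected intensity), radius of gyration (µm) and eccentricity
from second moments.

The default mass threshold is Otsu's method on the **log** candidate masses:
noise speckle (which Richardson–Lucy amplifies) and real particles differ
multiplicatively, so the log scale separates them where linear Otsu bisects
the noise mode.  With fewer than 10 candidates no mass filter is applied.
Size/eccentricity filtering is off by default.

Under the validated conditions (SNR ≥ 10, density 0.02/µm²) recall and
precision are ≥ 0.95 against ground truth at a 2 px match radius and
centroid RMSE is ≤ 0.05 µm (typically ~0.006 µm).  Recall is assessed on
particles away from the excluded border band; losses inside it are by
design, and pair-merging at < separation accounts for most of the remaining
~2–3%.

**Anchored photometry.**  Detection-based intensity measurement is biased
for populations near the detection floor twice over: selection favours the
bright tail, and (empirically) the flux a dim spot retains in the
max-projected deconvolved image depends on its brightness, because
Richardson–Lucy convergence is contrast-driven.  `measure_at` therefore
measures per-particle intensity at externally supplied positions — the
detections of the bright mature-capsid reference channel — on the **raw**
projection of the channel of interest, with annulus-median background and
*no per-pixel floor* (the floor rectifies noise and inflates weak masses by
tens of photons).  This estimator is linear in photon flux across the full
brightness range, which is what lets the Gag/Gag-Pol comparison recover the
1:20 packaging ratio; `compute_features` keeps the per-pixel floor as its
default for detection-image masses, where it only stabilizes shape moments.

## Colocalization

Reference-anchored nearest neighbours: for every reference (mature-capsid)
detection, its nearest query-channel detection, kept when the 2-D Euclidean
centroid distance is strictly below 0.500 µm.  A kd-tree provides the
lookup; tests require exact agreement with an O(n²) exhaustive oracle.
Matching is many-to-one by default (reference-anchored with no explicit
one-to-one constraint); a strict one-to-one mode (greedy by ascending
distance) is available for sensitivity analysis.  Ties exactly at the
threshold are excluded (strict inequality).  Reference detections within
one threshold of the field border are dropped from the denominator — their
neighbourhood is censored — and the exclusion count is recorded.

The colocalized fraction `n_paired/n_reference` carries a Wilson 95%
binomial interval.  Chance colocalization is quantified by re-drawing query
positions uniformly over the field with toroidal distances (3×3 tiling), so
the null mean matches the Poisson void probability `1 − exp(−λπr²)` without
edge losses; the observed fraction is reported alongside the null mean and
its shuffle distribution.

Intensity summaries report per-construct median and mean mass with
percentile-bootstrap intervals on the median and on pairwise median ratios.

## Flow cytometry and group statistics

Singlet gating retains events whose FSC-W/FSC-H and SSC-W/SSC-H ratios fall
within median ± 3 × 1.4826·MAD, iterated to a fixed point (re-fit on the
retained events until nothing more is removed) so that gating is idempotent;
convergence takes 2–3 passes and retains ≥ 99% of true singlets while
rejecting > 95% of doublets generated at a 2× width ratio.

The GFP gate is the 0.999 quantile of the non-infected control's
fluorescence (so ~0.1% of control events exceed it by construction), and
`percent_positive` is the percent of gated condition events above it.  In
the generator the infected mixture component sits `separation` (default 4)
negative-population SDs above the negative mean in log space and is narrower
(0.25× the negative SD): a tight, bright reporter-positive population.  The
narrower width is a deliberate design choice — with an equal-width infected
component, a gate at +3.09 SD would cut ~18% of it and a 70% infected truth
could never read out near 70%; real reporter-positive populations are
well-separated from the autofluorescence background in exactly this way.

Kruskal–Wallis (tie-corrected, chi-square reference with k−1 df; delegated
to scipy behind the module surface and cross-checked against an exhaustive
permutation oracle at n ≤ 8) provides the omnibus test; Dunn's pairwise
z-tests on pooled mean ranks with tie-corrected variance follow, with Holm
adjustment by default (the adjustment method is configurable; Holm is
uniformly more powerful than Bonferroni at the same FWER).  The
identical-everything degenerate case returns H = 0, p = 1.

Luciferase tables are summarized as background-subtracted RLU per unit p24
input (background = mean of the designated uninfected wells), with replicate
mean and SD per condition.  Integration-blocked conditions (raltegravir,
D116N without rescue) are generated at background level and must normalize
to within noise of zero.

## Pipeline, provenance, determinism

`run_pipeline` chains simulate/load → deconvolve → project → detect (per
channel) → colocalize and writes per-channel detection CSVs (positions in
µm, intensities in photons), a colocalization JSON, and a plain-text run log
with every parameter, per-stage counts, and a config hash (SHA-256 over the
full parameter set, truncated to 12 hex digits) embedded in every artifact.
Unknown config keys are rejected.  Identical config + seed reproduces
byte-identical CSVs.

## Problem sizes

The validation workflows (`vogquant.workflows`) use: 16 fields (~1000
particles) for colocalization recovery, 37 fields (~2200 particles, ≥ 2000
mature) for labeling frequency, 50,000 events per table for infectivity,
and 3 fields per preparation (~180 reference-anchored particles each) for
the stoichiometry ratio.  These sizes keep each workflow within minutes on
one CPU while leaving binomial/bootstrap errors small against the margins
being tested.

## Known limitations

- The Gaussian PSF ignores aberration and depth-dependence; absolute
  mass-recovery factors (e.g. the fraction of flux captured by a
  max-projection) are specific to this model.
- Detection near the field border is excluded rather than corrected.
- Colocalization is 2-D; axial offsets are invisible after projection.
- Mass measured on the deconvolved projection is not linear in photon flux
  near the detection floor (see *Anchored photometry*); cross-construct
  intensity comparisons should use anchored raw-projection photometry.
- The flow generator draws scatter and fluorescence independently; real
  populations correlate size with reporter signal.
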