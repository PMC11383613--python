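# Methods

## The problem

Resting-state functional connectivity (fcMRI) measures the temporal
correlation of BOLD signals between brain locations. In deeply sampled
individuals, the cerebral cortex decomposes into ~15 individual-specific
networks, and the five higher-order association networks (FPN-A, FPN-B,
LANG, DN-B, DN-A) recur in side-by-side rows — supra-areal association
megaclusters (SAAMs). `striomap` implements the within-individual analysis
that maps this organization into the striatum: every striatal voxel is
assigned to the cortical network it is most strongly coupled to, with
controls for cortical signal bleeding into the striatum, model-free
seed-map validation, and quantification of hemispheric laterality.

Because the method's claims are about *recovery* — does the pipeline find
the coupling structure that is actually there? — the package is built
around a synthetic phantom whose ground truth is fully known. Every stage
is then verifiable without any data download.

## The phantom

**Geometry.** Each "hemisphere" is a triangulated sphere (Fibonacci point
set + convex hull; 2,000 vertices per hemisphere by default, a scaled
stand-in for fsaverage6's 40,962), radius 25 mm, centered at x = ±55 mm so
the medial cap of each sphere approaches the lateral striatum — giving a
realistic near-cortex rim without the sheet cutting through the striatum.
The striatal grid is 32×40×32 voxels at 2.4 mm (the acquisition's voxel
size) holding mirrored caudate, putamen, and NAc ellipsoids (~490 voxels);
the analysis mask is the striatum dilated 3× with a 3×3×3 box (~5.9k
voxels), so the vote can extend just past the anatomical boundary exactly
as the parcellation protocol requires.

**Cortical labels.** The 15 networks tile each hemisphere by
capacity-constrained region growing from seeded directions: per-network
geodesic distances from the seeds are consumed in ascending order, with
each network capped at its target vertex count. Capacities implement the
laterality plan exactly (default: LANG left:right extent 1.5:1, FPN-B the
inverse), so planted asymmetries are correct to ±1 vertex. The five
association networks are seeded along two short arcs per hemisphere,
producing two SAAM-like rows of adjacent patches. A posterior cap (~2.5%
of vertices) is the medial wall: unlabeled and excluded from votes.

**Striatal truth.** The caudate is partitioned into five contiguous zones
by weighted nearest-anchor assignment, with anchors placed to reproduce
the relative positions reported for the caudate megacluster (DN-A
dorsomedial head, DN-B posterior, LANG lateral, FPN-A/FPN-B ventral) and
anchor weights carrying the laterality plan. The putamen is split into
foot/hand/tongue tertiles along a dorsolateral→ventromedial score, each
paired with a small cortical patch carved inside SMOT-A; patch and zone
share a zone-specific latent mixed 50/50 with the SMOT-A network latent,
which preserves winner-takes-all behavior while making somatomotor seed
maps zone-selective. The NAc couples to SAL/PMN and sits inside the
dropout sphere (radius 6 mm): dropout voxels keep 2% of their coupling
amplitude (≥90% attenuation), double noise, and a 70% reduced baseline, so
they are visible in tSNR maps and behave like susceptibility dropout.

**Signal model.** Each network (and somatomotor zone, and two tissue
nuisance components) gets an independent Gaussian latent band-limited to
0.01–0.10 Hz and standardized per run. A location's series is
`baseline + snr × loading × latent-mix + nuisance + N(0,1)`; `snr_cortex`
defaults to 1.0 and `snr_striatum` to 0.5 (the striatum's relative SNR is
not quantified in the literature we emulate; 0.5 is a deliberate,
config-exposed choice). Runs are 422 frames at TR = 1 s with the first 12
frames already removed (T = 410). Nuisance is 6 motion random walks +
whole-brain (the empirical global mean) + ventricle + white matter + their
backward-difference derivatives (first element 0): 18 zero-mean rows.
Voxels within 2×FWHM of the cortical sheet receive an additive copy of
their nearest vertex's clean signal, Gaussian-weighted in world mm
(default bleed FWHM 4 mm) — a point-spread model of cortical bleed, not
acquisition physics. All randomness derives from one master seed via
`SeedSequence([master, subject, run])`.

**What the phantom does not emulate** — and hence what passing tests do
not show about real data: hemodynamic autocorrelation and non-Gaussian
noise, head-motion-induced artifact structure (motion here is only a
regressor target), registration/distortion error (data are born
"registered"), folded cortical geometry, network spatial covariance
beyond shared latents, and realistic absolute tSNR levels (baselines are
arbitrary units chosen to make the dropout contrast visible).

## Preprocessing

Order: nuisance regression → band-pass 0.01–0.10 Hz → spatial smoothing
(2-mm FWHM on the surface graph, 4-mm FWHM mask-aware in the volume).

* **Band-pass** is an FFT-bin projection (bins with low ≤ f ≤ high kept,
  DC removed). A projection is exactly zero-phase and exactly idempotent;
  an IIR forward-backward filter of practical order is neither, and its
  wide transition bands at 0.01 Hz re-attenuate real signal on every
  pass. Pass-band sinusoids retain amplitude 1.0; stop-band leakage at
  2× the high edge is far below the 10% contract.
* **Regression** uses OLS on [intercept + 18 nuisance rows], with a hard
  error naming collinear columns. In the pipeline the regressors are
  band-limited to the analysis band first, so the subsequent filter
  cannot reintroduce nuisance covariance; regress→band-pass is then
  idempotent to machine precision. tSNR (mean/SD per run, unbiased SD,
  averaged over runs) is always computed from pre-regression data and the
  map carries a `pre_regression` flag.
* **Volume smoothing** is a sparse mask-aware Gaussian operator: weights
  are a Gaussian of inter-voxel world distance truncated at 3σ and
  renormalized over in-mask voxels, so nothing mixes in from outside the
  mask and constants are preserved.
* **Surface smoothing** is neighbor-averaging diffusion on the mesh graph
  (never across hemispheres), with the iteration count calibrated on an
  actual delta so its half-maximum geodesic radius reaches ~FWHM/2. On
  meshes whose edge length exceeds FWHM/2 (true of the default mesh at
  2-mm FWHM, and of fsaverage6) the achievable radius is
  resolution-limited: the calibration then applies the smallest effective
  smoothing the mesh supports.
* Spatial smoothing is *not* idempotent (diffusion is not a projection);
  re-running the full chain changes smoothed outputs by tens of percent
  RMS even though regress→band-pass is exact. This is a property of any
  genuine smoothing kernel, and is why the blur-control analysis compares
  raw against smoothed conditions rather than assuming smoothing is
  harmless.

## Connectivity and parcellation

Per run, Pearson correlations between every analysis-mask voxel and every
cortical vertex are computed in voxel blocks (identical to the
whole-matrix product, bounded peak memory), clamped to |r| ≤ 1−1e-7,
Fisher r-to-z transformed, and averaged across runs into a single
voxel × vertex matrix. Zero-variance series are flagged and excluded from
ranking rather than silently zeroed.

The winner-takes-all vote for a voxel takes its k = 400 strongest-z
vertices across both hemispheres pooled, drops unlabeled (medial-wall)
vertices from the count *without* replacement from deeper ranks (keeping
"top 400" semantics without inventing a 16th category), and assigns the
network with the largest count. Ties are broken by the larger summed z
among the tied networks' contributing vertices, then the lower network
id; every tie is flagged in the per-voxel provenance (counts,
contributing-vertex number, threshold used).

The thresholded variant additionally drops, within the top 400, vertices
whose z falls below a fixed threshold; a voxel whose entire top 400 is
sub-threshold is UNASSIGNED. Thresholds are interpreted on the
run-averaged Fisher-z scale (at |r| ≤ 0.4 the two scales differ by <6%;
the scale is a config knob). The blur sweep runs thresholds 0.01 and
0.05–0.40 in steps of 0.05 over raw and smoothed matrices; the
UNASSIGNED count is monotone non-decreasing in threshold by construction
and asserted.

**Run counts.** The default phantom uses 4 runs — ample for ≥90% caudate
recovery at default SNR. The blur/dropout analysis instead uses 62 runs,
the deep-sampling condition of the discovery subjects: the Fisher-z noise
floor over the ~144k dropout-voxel × vertex pairs has expected maximum
≈ 4.9 σ_z with σ_z ≈ 0.118/√n_runs (the 0.01–0.10 Hz band leaves ~74
effective temporal dof of 410 frames), so clearing a z = 0.10 threshold
for *every* pair needs ≳45 runs. With fewer runs the sweep is still
monotone, but dropout voxels retain supra-threshold noise vertices — a
statistical floor, not a pipeline defect.

The bleed-detection contrast (do assignments change between the plain
vote and the high-threshold vote more often near the cortical sheet than
in the striatal interior?) is evaluated on the *unsmoothed* matrix, with
"near" meaning within the bleed kernel's support (2x its FWHM): volume
smoothing pools coherent bleed across neighboring rim voxels and keeps
them supra-threshold, masking exactly the effect the control is meant to
expose — which is the reason the sweep includes an unsmoothed condition
at all.

## Seed maps and laterality

Seeds are spheres in world mm (striatum, default radius 4.8 mm = 2
voxels) or graph-hop disks (cortex, default 2 hops); the seed series is
the arithmetic mean over members. Maps are per-run Pearson r to every
target location, Fisher-z, run-averaged. The recapitulation score
`network_selectivity` = (mean z inside the target network) − (best mean z
of any other network); positive means the map respects the target's
boundaries. Seed analyses are split-half: seeds are placed on a
parcellation built from the first half of the runs (the medoid caudate
voxel of each network's assigned zone), maps are computed from the second
half — so recapitulation is never circular. Somatomotor cortical seeds
are the body-part patches themselves (one hemisphere): a fixed-radius
disk around the patch center would spill into surrounding somatomotor
cortex and dilute the body-part-specific signal.

Laterality tables count, per network and hemisphere, assigned locations
divided by the hemisphere's total (UNASSIGNED contributes to totals but
to no network row; caudate counts are restricted to the undilated caudate
mask). The laterality index is (pL − pR)/(pL + pR) ∈ [−1, 1], 0 by
convention when a network is absent bilaterally. Hemisphere of a voxel is
the sign of world x (left negative). Group summaries report mean ± SE
only.

## Numerical choices and degenerate inputs

* Ties anywhere (top-k ranking, profile binarization, vote) resolve to
  the lowest index/id after the documented score, and are logged.
* r is clamped to 1−1e-7 before arctanh; ConnMatrix construction rejects
  non-finite entries.
* Zero-variance series → flagged, r defined 0; all-flagged vote rows →
  empty ranking with a warning; zero-variance seed series → error.
* Profile binarization keeps round(keep_fraction × n_rois) entries per
  vertex row (exact for tie-free rows); ROI centers come from
  deterministic farthest-point sampling on the mesh graph and ROI series
  are 1-ring patch means.
* A "threshold 0" sweep cell equals the threshold-free parcellation
  whenever top-k correlations are positive (the phantom regime); with
  negative correlations in the top k, threshold 0 would additionally
  drop them — the sweep's thresholds are all > 0.
* The pipeline recomputes stages deterministically from the master seed;
  every artifact carries the config hash, so any parameter change is
  visible in provenance.

## Problem sizes

Defaults were chosen so the full verification study runs on a single
core at desk scale: 2,000 vertices/hemisphere, ~5.9k analysis voxels,
4 runs × 410 frames per phantom subject (~25 s end-to-end including the
split-half seed analysis), ten independently seeded subjects for the
recovery/laterality/recapitulation claims, and one 62-run subject for
the blur-control study.
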