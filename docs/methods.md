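# Methods

## Coordinate frame and grid

All volumes live on one axis-aligned RAS+ lattice in template millimetres
(default: 1 mm isotropic, 40×50×40 mm, covering the left pallidal region;
the mid-sagittal plane is x = 0). Right-hemisphere stimulation volumes are
mirrored to the left (x ↦ −x) so the whole cohort shares a single target
model; mask mirroring requires a lattice symmetric about x = 0, while
coordinate mirroring is exact for any point. Volumes are stored as float32
(maps) or uint8 (masks) NIfTI-1; all statistics run in double precision.

## VTA surrogate

Finite-element activation models are out of scope here; the stimulation
field is a documented parametric surrogate with the same interface. The
volume of tissue activated around an active contact is a sphere of radius

    r(A, pw) = k_r · sqrt(A / A_ref) · (pw / 60 µs)^γ,

with defaults k_r = 2.5 mm, A_ref = 3 (mA, or V for voltage-mode leads)
and γ = 0.3. The square root reflects the inverse-square decay of a
point-source field (the activation threshold is reached where |E| falls to
a fixed value, so the radius grows like √A), and the pulse-width power
captures the strength–duration trade-off of axonal activation. The
constants are exposed (`VTAParams`) and documented as surrogates; nothing
downstream depends on their exact values. Current- and voltage-mode
settings share the calibration, with the unit recorded per setting; the
rare bipolar configuration is modelled as a monopolar source at the
cathode. Rasterization includes every voxel whose centre lies within the
radius (inclusive boundary); a positive radius smaller than the nearest
voxel-centre distance still claims the nearest voxel, so a nonzero setting
never produces an empty volume. The electric-field surrogate used by the
rank-map validation is a capped point source, |E|(r) = I/(4πσr²); only its
ranks matter downstream.

## Voxelwise signed p-map

A subject covers a voxel if either VTA of its mirrored pair contains it
(outcomes are per subject, not per hemisphere, so coverage is counted once
per subject). At each voxel with at least `min_coverage` = 2 subjects on
*both* sides of the split, a pooled-variance (Student) two-sample t-test
compares covering vs non-covering outcomes; p is two-sided, and the map
value is (1 − p)·sign(t). Voxels failing the coverage rule are flagged
undefined and carry 0; voxels where all outcomes coincide are flagged
degenerate (t = 0). No voxel-level multiple-comparison correction is
applied: the aggregate map is validated predictively instead, which is the
appropriate control when the map is used as a unit rather than voxel by
voxel. Accumulation runs in a canonical subject order, so the map is
bit-identical under permutation of the input cohort.

Sweet- and sourspots are connected components (6-neighbourhood by default;
18/26 available) of significant (p < 0.05) defined voxels, split by t sign
before labelling, kept when strictly larger than 50 voxels. The centre of
gravity is the unweighted mean of member voxel-centre coordinates, also
reported relative to the midcommissural point (0, −11.8, −3.3) mm — a
constant back-derived from the template geometry and config-exposed. The
3-voxel box smoothing (edge-replicated) exists for display and export
only; statistics and clustering always run on the unsmoothed map.

## Interference histograms and the outcome model

The heatmap range [−1, +1] is divided into `n_bins` = 15 equal bins
(~0.13 wide; a 9-bin variant controls for the predictor count). Both VTAs
of a pair are sampled independently and their counts summed, so a voxel
inside both volumes counts twice (multiplicity pooling; union pooling is a
switch). Bins are half-open with the last closed at +1. Undefined heatmap
voxels under a VTA are sampled as 0 — stimulating unmapped territory is
treated as neutral evidence — with an "exclude" mode available. Raw counts
(not proportions) are the predictors, so VTA size itself carries signal.

To keep training independent of the predicted subject, histogram *i* is
sampled on the heatmap rebuilt from the other n−1 subjects. The outcome
model is OLS with an intercept and one coefficient per bin, solved by a
rank-revealing least-squares decomposition: 15 predictors on ~40 subjects
is near-saturated by design, so rank deficiency falls back to the
minimum-norm solution with a logged warning instead of crashing, and a
fully saturated fit reports a NaN F p-value while remaining usable for
prediction. Leave-one-out cross-validation refits the model per fold on
the fixed histogram set; validity is the Pearson correlation (exact
t-transform p, n−2 df) between the n held-out predictions and the
empirical improvements. Predictions for arbitrary (e.g. optimized)
settings use the full-fit model — fold models exist only to score
generalization.

Baselines: improvement regressed on the mean distance of the (mirrored)
active contacts to the sweetspot COG, and on the side-averaged amplitude,
pulse width and frequency (constant columns dropped with a warning).

## Rank-map validation

An independent map correlates (Spearman, average-rank ties, per voxel)
the subjects' point-source field magnitudes with their improvements.
Voxels with all-tied magnitudes are undefined. The R-map is validated by
the leave-one-out mean-R score (mean of defined R values under the
held-out pair; a fully undefined sample scores 0 and is flagged) and
compared with the signed p-map by spatial Pearson correlation over the
intersection of defined voxels.

## In-silico monopolar review

Candidates are the cartesian product of 4 contacts × 5 amplitudes
(1–5 mA) per side at 60 µs — 400 bilateral pairs. Each pair's VTAs are
built by the same surrogate, sampled on the group heatmap, histogrammed
and scored by the model. Ranking is by predicted improvement; exact ties
prefer the lower total amplitude (less energy), then lower contact
indices. The clinical setting is predicted from the subject's actual VTA
pair without snapping to the grid. A subject whose rank-1 candidate still
predicts worsening is flagged an implant-failure candidate: no enumerable
programming choice reaches beneficial territory from that lead. Cohort
comparisons (optimized vs empirical, optimized vs predicted-at-clinical)
use one-tailed Wilcoxon signed-rank tests on differences shifted by a
5-percentage-point minimal clinically important difference.

## Clinical statistics

Outcomes are percentage improvements, 100·(pre − post)/pre. Response
categories: worsening (< 0), non-responder [0, 15), medium [15, 50), good
[50, 70], excellent (> 70) — as printed, the clinical bins overlap at
their edges, so the convention is fixed left-closed with "good" closed at
70 (config-exposed). Cohorts rated per-item on the shorter motor scale are
made comparable by rescaling the per-item mean by the 33 items of the MDS
scale. The Wilcoxon signed-rank test drops zero differences, mid-ranks
ties, enumerates the exact null (by convolution over sign assignments,
conditional on the observed ranks) up to n = 25, and uses the
tie-corrected normal approximation with continuity correction above.
Sample SDs use the n−1 denominator.

## Synthetic cohort: what it emulates, and what it does not

The generator plants a ground-truth effect field — Gaussian blobs, clipped
to [−1, +1]: a beneficial peak (+0.9, 4 mm scale) at the pallidal
sweetspot reference point (−18.4, −7.3, −7.0) mm and a detrimental peak
(−0.71, 4.5 mm) dorsal to it along the lead trajectory, emulating the
dorsoventral beneficial-to-detrimental gradient of the target region.
Bilateral quadripolar leads (2 mm pitch, trajectory tilted 20° from
vertical) are placed with 1.5 mm isotropic Gaussian jitter, contact 0 at
the target; the right lead is the mirror image. One active contact per
side is chosen uniformly (the clinical selection process is unknown, so
no informative prior is assumed), amplitude is uniform on 1–4 mA at
60 µs/130 Hz, and

    improvement % = outcome_scale · mean(field under the VTA pair) + N(0, noise_sd),

with outcome_scale = 120 and noise_sd = 23 percentage points. These
defaults were calibrated once so the cohort improvement distribution has
mean ≈ 16% and SD ≈ 37% — a highly variable response profile with a
substantial worsening fraction — while leaving roughly 60% of the outcome
variance spatially explainable. Baselines are Normal(53, 17) clipped to
[10, 100]; post scores are derived, never drawn, so the percentage change
round-trips exactly. One RNG stream is spawned per subject from the
cohort seed, so enlarging a cohort never perturbs existing subjects.

The generator emulates coverage structure, outcome noise and
amplitude-dependent field size. It does **not** emulate registration
error, brain shift, atlas segmentation variability, directional leads,
non-spherical activation volumes, or rater drift — so passing recovery
tests demonstrate the correctness and statistical behaviour of the
pipeline, not the accuracy of any particular clinical dataset processed
with it.

## Numerical choices and problem sizes

Defaults throughout: α = 0.05, cluster threshold 50 (strict), 15 bins,
60 µs, 1–5 mA review grid, 6-connectivity, min_coverage 2. Test and
acceptance runs use the default n = 40 cohort on the 1 mm grid; the
permutation null uses 20 outcome permutations of the noise-free cohort.
Histogram-model predictions are unconstrained linear extrapolations and
can exceed 100% for large simulated VTAs; they order candidates and must
not be read as literal score changes. Pearson/Spearman p-values use the
exact t transform; zero-variance inputs raise rather than return NaN.

## Known limitations

The spherical VTA and point-source field are deliberate simplifications;
constants are calibration targets, not physiology. The signed p-map
inherits the two-sample t-test's equal-variance assumption (the classic
choice for this mapping approach; Welch is a one-line change in
`heatmap_from_coverage` if wanted). The optimizer ignores
stimulation-induced adverse effects, so its energy-tie-break is the only
brake on large amplitudes. The analysis domain defaults to all covered
voxels; an anatomical region mask can be applied upstream by restricting
the cohort's VTAs.
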