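# Methods

This note documents the models, conventions and numerical choices behind
`spbquant`, and what the synthetic validation does and does not establish
about real data.

## Forward model (module `synth`)

A scene is a set of point emitters — per SPB, a reference-channel focus at
the SPB core and query-channel foci at the inner plaque (at the core
position) and outer plaque (displaced `ip_op_separation` = 150 nm along
the plaque axis) — plus an optional bridge-pool emitter at the midpoint of
unseparated SPB pairs. The expected image is

    E[I(v)] = B + Σ_e A_e · ∫_v G(x − x_e; σ_xy, σ_z) dx,

the sum of anisotropic Gaussians *integrated over each voxel* (separable
erf differences per axis), plus a uniform background *B* (counts/voxel).
`A_e` is therefore the emitter's integrated flux, and photon counts are
conserved up to boundary truncation (< 0.1 % with ≥ 3σ margins). Noise is
Poisson shot noise on the expected counts, then additive Gaussian read
noise; both are optional. With the default flux scale (10 000 counts per
outer plaque; no absolute plaque photon budgets exist in the literature,
so the scale is a free parameter) the peak-pixel SNR is ≈ 17.

Conventions: positions are continuous (x, y, z) in nm; voxel index
(0, 0, 0) has its centre at (voxel_xy/2, voxel_xy/2, voxel_z/2); arrays
are (channel, z, y, x). One global integer seed fans out to per-scene
substreams by scene counter, so populations are reproducible scene by
scene.

Two optics presets: SIM-like (σ_xy 50 nm, σ_z 140 nm; voxels 40 × 40 ×
125 nm) and wide-field (σ_xy 110 nm, σ_z 300 nm; voxels 129 nm with the
0.8 µm plane spacing and five planes of that acquisition mode). Only the
wide-field z step is instrument-documented; the remaining values are
chosen for realism and are configurable.

### Stages and geometry

Stage labels draw the inter-SPB distance from intervals consistent with
the distance-based staging rule (see `metrics`): side-by-side 150–340 nm,
short spindle 400–990 nm, medium 1000–2400 nm, elongated 2600–4000 nm;
unduplicated scenes have a single SPB. For separated spindles the plaque
axis coincides with the spindle axis (outer plaques face outward); for
unseparated pairs it is drawn perpendicular to the bridge axis. The
old:new fold-ratios of the query label (outer plaque; `inf` means the new
outer plaque carries no label — its incompletely assembled state early in
duplication), the inner:outer ratio (default 2.5, within the ~2–3 range
measured for γTC components), and a modest reference-channel old:new fold
(1.5) used for old/new assignment are all configurable.

Orientations: non-top-view scenes tilt at most 30° out of the focal plane
(cells flattened on a coverslip; analysable spindles lie near the imaging
plane), while a configurable fraction (default 0.12, the empirically
observed regime) has its plaque axis within 5° of the optical axis. This
separation makes the lateral-overlap top-view rule (below) essentially
deterministic per scene, so the flagged fraction tracks the generated
fraction.

The reference-channel core focus is stored with role `inner_plaque`
(channel index distinguishes it from the query-channel inner plaque): at
this resolution the central-plaque reference label is not separable from
the inner plaque, and the role vocabulary is kept to the four structural
sites.

## Spot fitting (module `spotfit`)

The fitted model is the *same* voxel-integrated Gaussian as the forward
model — laterally isotropic (σ_x = σ_y), independent axial width — so the
amplitude parameter is integrated flux and recovery is unbiased at zero
noise; a centre-sampled Gaussian would carry a ~1 % discretisation bias at
σ/pitch ≈ 1.25. Optimisation is bounded nonlinear least squares (trf,
tolerances 1e−8, ≤ 500 function evaluations). Dual fits share one
background. Width bounds default to (0.25, 4)× the initial value; callers
that know the PSF can tighten them, and centres can optionally be confined
to a box around their seeds — used by the pipeline when plaque positions
are anchored by the reference channel, so that neighbouring structure is
not absorbed. Dual fits whose centres collapse below 0.25 σ_xy are flagged
`unresolved`; constant ROIs raise a degenerate-input error.

Seeding mirrors practice on real data: manual/tabulated seeds, or
local-maxima auto-seeding on a smoothed reference channel for batch work.

Measured performance (test suite, 200 simulated noisy pairs at SNR ≥ 10):
median 3D centre error ≈ 2 nm (bound: voxel_xy/4 = 10 nm), median
amplitude error ≈ 1 % (bound 5 %), inter-distance exact to machine
precision at zero noise (bound 3 nm).

## Realignment and averaging (modules `realign`, `average`)

The brighter reference spot is the old SPB (ties broken deterministically:
smaller x is old, flagged); for plaque pairs of one SPB the same rule
assigns the stronger focus to the inner plaque. The stack is rotated
rigidly about the pair midpoint so the old→new axis maps onto +x (old on
the left, the display convention), in full 3D by default with an in-plane
(about-z) option. The output grid keeps the input voxel sizes over a
1.6 × 1.6 × 1.2 µm field, widened along x when a long spindle plus plaque
margin would not fit; out-of-field samples are filled with the fitted
background to avoid edge bias in averages.

Resampling uses cubic-spline interpolation by default (`order=1` gives
trilinear). At the near-Nyquist sampling of these stacks, trilinear
resampling biases post-realignment refitted centres by up to ~1.7 nm,
breaking the ≤ 1 nm realignment contract; cubic interpolation meets it
with margin (worst 0.45 nm in an 8-scene zero-noise sweep) and conserves
total intensity within 1 %.

Class averages are voxelwise arithmetic means over realigned images of one
(stage × genotype) class, with n and a per-voxel variance map retained.
Images contribute raw intensities; reference normalisation, where a figure
convention requires it, is applied downstream in the linescan step.
Display versions are laterally 4× upscaled with bilinear interpolation
(corner-aligned sampling, exact on affine ramps) and optionally converted
to 8-bit under a shared brightness/contrast window; float averages are
always kept.

## Linescans (module `linescan`)

Profiles are sampled on the z max-projection along a segment at one-pixel
pitch, averaging 1, 3 or 5 parallel single-pixel lines perpendicular to
the axis, with bilinear in-plane interpolation. Normalisation is either
internal (min→0, max→1 per channel) or relative to the maximum of a
reference profile (e.g. the old SPB of an elongated spindle). Peaks are
local maxima above a robust floor (median + 3·MAD of the profile; MAD is
the raw median absolute deviation, no Gaussian consistency factor) and are
assigned to plaque roles by order along the axis — a realigned spindle
reads outer_old, inner_old, inner_new, outer_new left to right; a
side-by-side profile has the bridge at the centre. Missing roles are
flagged rather than guessed. Peak height is the profile value at the
maximum (no sub-sample refinement), mirroring figure-style linescan
quantitation.

At the default geometry (150 nm IP–OP separation, σ_xy 50 nm) an outer
plaque 2.5-fold dimmer than its inner plaque forms a *shoulder*, not a
separate local maximum — linescan peak detection resolves the plaques only
when their intensities are comparable. The pipeline therefore measures
plaque intensities by dual fitting and uses the linescan only for the
detection floor and display.

## Metrics (module `metrics`)

- `asymmetry_index(a, b) = |a − b| / (a + b)`; errors for a + b = 0.
  Symmetric, scale-invariant, bounded in [0, 1].
- `ip_op_ratio`: ip/op, undefined (flagged one-sided) at op = 0.
- `classify_mode`: one_pole if the dimmer outer plaque is below the
  detection floor; else with r = max/min: strongly_asymmetric (r ≥ 8),
  symmetric (r < 1.3), asymmetric between. The stated fold boundaries
  leave inclusivity open; r ≥ 8 and r < 1.3 make the classes exhaustive
  and disjoint.
- `stage_by_distance`: < 0.35 µm unseparated; 0.35 ≤ d < 1 short;
  1 ≤ d ≤ 2.5 medium; > 2.5 elongated. Interior boundaries are assigned
  rightward (0.35 → short, 2.5 → medium) so every d ≥ 0 gets exactly one
  label.
- `is_top_view`: lateral IP–OP distance < 2 σ_xy with the axial separation
  dominating. The 2 σ_xy default is calibrated so that simulated
  populations with the observed ~12 % vertical-axis fraction are flagged
  at that fraction; it is exposed in config.
- `summarize_distribution`: 5/25/50/75/95th centiles by linear
  interpolation of order statistics, with the conventional median notch
  median ± 1.58·IQR/√n. Inferential tests are deliberately out of scope.

## Wide-field quantitation (module `widefield`)

Five-plane stacks are max-projected per channel; integrated intensities
are taken in a 7 × 7 px window around each SPB with per-channel background
subtraction (`corrected = raw − side²·background_per_px`). Background
defaults to the median of a 15-px annulus beyond the window when no
cytoplasmic ROI is given (the original protocol is manual). Per-SPB
relative label = query/reference corrected intensity; the asymmetry index
over the two relative values is recorded with basis
`widefield_ref_normalized`, making it invariant to per-cell illumination
scaling. On matched synthetic spindles the wide-field and SIM measurements
rank asymmetry identically (Spearman ρ > 0.99 over a 100-scene fold
sweep).

## Pipeline (module `pipeline`)

Per scene: dual-fit the reference channel at the seeds → edge-slice
exclusion (either channel's local maximum in the first or last z slice
excludes the pair) → old/new assignment and distance staging → query
plaque fits (per SPB, IP seeded at the reference core and OP displaced
outward along the spindle axis; widths and centres bounded as above) →
top-view exclusion → realignment → spindle linescan. Excluded pairs carry
a reason and no partial metrics, and never enter averages or linescans.

Mode classification uses the fitted outer-plaque fluxes (free of
inner-plaque tail contamination; see the linescan note above). The
visibility floor is the linescan noise floor computed over the background
*margins* of the profile (beyond the outer plaques) — whole-profile
statistics would be dominated by the plaque signal on these short,
structure-filled segments — converted to flux units via the inner-plaque
peak. Classification is reported for separated-spindle stages; unseparated
rows carry IP, old-OP and bridge intensities instead.

Unseparated pairs are measured by alternating refinement: tight-bounded
dual IP fits, residual search and single fits for the cytoplasmic foci
(classified old-OP / new-OP / bridge by proximity), then an IP refit on
the decontaminated data. Full joint deconvolution of > 2 emitters is out
of scope.

Sizes used by the shipped analyses and tests (chosen as the package's own
validation scale): populations of 30–60 scenes per condition, 50 + 50 for
the ploidy comparison, 200 pairs for fit-recovery statistics, 50
replicates for averaging noise scaling.

## What the synthetic validation does not show

The generator emulates isolated, well-separated SPBs with an ideal
Gaussian PSF, uniform background and exact channel registration. It does
not model reconstruction artifacts of structured-illumination imaging
(stripes, Wiener ringing), chromatic mis-registration, cytoplasmic
autofluorescence gradients, microtubule signal, or clustering of multiple
cells. Passing recovery tests therefore validates the measurement chain's
correctness and internal consistency, not its robustness to those
real-data effects. Known limitations: very tight side-by-side pairs
(d ≈ 150 nm) put five emitters within ~300 nm and their decomposition is
at the resolution limit — inner-plaque intensities can absorb bridge/OP
flux there; and the one_pole/strongly-asymmetric boundary depends on the
noise-derived visibility floor, so scenes with a true fold near the
detection limit are split stochastically between those two classes.
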