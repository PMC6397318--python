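# Methods

This note documents the models, estimators, numerical choices and known
limitations of `mcoct`. It states no empirical claim that the test suite or
the acceptance script does not itself compute.

## Phantom model

The generator emulates the statistical structure the analysis chain relies
on, not optical wave propagation.

**Speckle.** Every voxel's complex backscattered amplitude is circular
complex Gaussian with variance equal to the Beer–Lambert expectation
`backscatter × exp(−2 Σ μ dz)` accumulated along the A-line, so linear
intensity is exponentially distributed (mean²/variance = 1), the defining
property of fully developed speckle.

**Polarization.** The instrument class measures two orthogonal polarization
channels; the phantom emits a single incident state `(h, v) = (1, 0)`.
Melanin voxels replace it with an independent random pure state,
Haar-uniform on the Poincaré sphere; kernel averaging downstream produces
the low-DOPU signature. True partial polarization within a voxel is not
modelled — the per-voxel-pure-state mechanism is the minimal one that
reproduces the measured phenomenon. A consequence worth knowing: with the
3×3 kernel, fully scrambled tissue converges to DOPU ≈ 0.47 (the
intensity-weighted resultant of 9 random unit vectors), not 0.

**Flow and repeats.** Static voxels reuse one speckle draw across the four
repeats, up to a global per-repeat phase drawn per B-scan (bulk axial
motion surrogate); the composition stage must estimate and remove it. Flow
voxels redraw speckle independently per repeat, which makes the
inter-repeat correlation ≈ 0. Choroidal flow fraction defaults to 0.9:
in this instrument class both the choroidal lumen and stroma carry high
flow signal, and this is precisely the mechanism that lets F_RPE reject
choroidal melanin.

**Geometry and optics.** Default reduced grid 128 × 64 × 200 voxels over a
6 × 6 mm field (dx = 6/128 mm, dy = 6/64 mm, dz = 6 µm); the clinical
512 × 256 raster is available via `full_grid=True`. Layer stack
(backscatter, μ in mm⁻¹): inner retina (0.35, 1.5), ELM (0.25, 2), EZ
(0.6, 3), photoreceptor outer segments (0.08, 0.8), RPE–Bruch's band
(1.0, 25, melanin fraction 0.9), choroid (0.8, 4, melanin 0.5, flow 0.9).
The weakly scattering outer-segment gap is anatomically real and keeps the
DOPU kernel halo above the band from acquiring attenuation support; choroid
μ = 4 mm⁻¹ reflects the deep choroidal penetration of 1-µm-band OCT.
Detector noise σ² = 2×10⁻⁵ per channel per repeat puts the band ≈ 42 dB
above the noise floor, a typical dynamic range. A serous PED lifts the
retina/RPE into a half-ellipsoid dome above a fixed Bruch's line, the
cavity fills with fluid (0.02, 0.3); HRF are bright ellipsoids (0.9, 8)
inside the cavity. Focal defects remove band melanin over rectangular
lateral footprints and leave a weak remnant (backscatter 0.05, μ 0.3):
complete focal atrophy with choroidal hyper-transmission implies near-total
loss of band scattering and attenuation. These optical defaults were fixed
once from typical posterior-segment values plus a one-time boundary-fidelity
characterization of the defect remnant against ground truth, and are not
tuned per experiment.

**What a green phantom test does not establish.** No eye motion, no
birefringence/retardation, no sensitivity roll-off, no vessel geometry
(flow is voxel-wise i.i.d.), no partial-volume melanin, no inter-repeat
speckle decorrelation of static tissue. Results transfer to real data only
to the extent these effects are second-order for the quantity under test.

## Estimators

**DOPU.** Unnormalized Stokes elements are kernel-averaged (default
3 px transverse × 3 px depth, per B-scan) and normalized by the
noise-corrected mean intensity `Ī − 2σ²` (additive circular noise biases I
by 2σ² across the two channels but is zero-mean in Q, U, V). Windows whose
corrected intensity falls below `ε = 10 × machine-epsilon × max Ī`
(configurable) are invalid. The classical normalize-then-average estimator
is available behind `average_normalized=True`. Values are clipped to [0, 1].

**OCTA.** For each adjacent repeat pair, a windowed channel-summed
coherence with noise-corrected powers; OCTA = 1 − mean ρ over the three
pairs. The default squared ("intensity") form
`ρ = |⟨g₁g₂*⟩|² / ((⟨|g₁|²⟩−2σ²)(⟨|g₂|²⟩−2σ²))` has a decorrelated-limit
bias of only 1/M (M = window pixels × channels), so independent speckle
scores ≈ 0.99 even at 7×7; the modulus ("amplitude") form, bias
√(π/4M) ≈ 0.09 at 7×7, is a documented switch. Windows with non-positive
corrected power are invalid, and that invalidity propagates into F_RPE —
in noise-dominated tissue the corrected coherence is unreliable in *both*
directions. All-pairs averaging is available; adjacent pairs are the
default to keep inter-frame time gaps homogeneous. The Otsu threshold is
taken per volume on the valid OCTA histogram (256 bins) for stability; ties
break toward the lower threshold.

**Standard OCT and attenuation.** Repeats are phase-aligned to the first
via the per-A-line complex inner product, complex-averaged, and squared;
coherent averaging reduces noise power by 1/N and (as in real data)
suppresses decorrelated flow voxels. The depth-resolved attenuation uses
`μ[i] = ln(1 + I[i]/S[i]) / (2 dz)` with `S[i] = Σ_{j>i} I[j]`, which is
exact on sampled exponentials for any μ·dz; the familiar small-step form
`I/(2 dz S)` (positively biased by (e^{2μdz}−1)/(2μdz), ≈ +13 % at
μ = 20 mm⁻¹, dz = 6 µm) is kept as `method="linear"`. The truncated tail
inflates μ near the bottom: `tail_policy="trim"` (default) invalidates the
deepest 10 %, `"extrapolate"` extends the sum with a geometric tail fit to
the deepest samples. `a_log = log10 μ` is deliberately not clamped at
zero — μ < 1 mm⁻¹ yields a negative factor that the F_RPE threshold
rejects on its own. In the pipeline the composed intensity passes through a
3-px *lateral* median filter before attenuation estimation: lateral speckle
averaging is standard in attenuation imaging, the median keeps lesion
boundaries sharp against a single bright neighbouring A-line, and no axial
mixing means depth resolution is untouched. `attenuation_coefficient`
itself applies no smoothing.

**F_RPE.** `a_log × (1 − DOPU) × (1 − OCTA_b)` voxel-wise, DOPU computed on
repeat 0 (repeat-averaged Stokes is a switch), per B-scan, with conjunctive
invalid propagation: a voxel with any invalid component is invalid, never
melanin-positive — degenerate denominators must not manufacture signal.
Melanin mask: `F_RPE ≥ 0.15` (inclusive) on valid voxels.

**Band and defects.** The band heuristic implements the anatomical
definition of the RPE as the posterior-most hyperreflective layer: per
column, the deepest run of depth pixels above 0.35 × a robust (90th
percentile) column brightness reference, band top at the run start (an
attenuating layer peaks at its top), center at top + half-thickness − 1.
The 90th-percentile reference, rather than the column max, keeps single
bright speckle clusters from inflating the threshold. Ground-truth bands
pass through untouched. A column is *defect* iff no melanin-mask voxel
lies in `center ± half-thickness`; runs merge across gaps of at most
`gap_tolerance` columns (default 0) and link across adjacent B-scans by
lateral overlap (4-connectivity). Areas are Σ per-B-scan length × dy.

**Volumes.** PED: pixel-count cross-section areas × dx·dz summed × dy
(Cavalieri). HRF: per-B-scan Shanbhag fuzzy-information threshold on the
dB image, intersected with the PED region and the (manual, here
truth-derived) ROI. The Shanbhag criterion follows the original
information-measure formulation; because several reformulations circulate,
the correctness contract is agreement with an independently coded
exhaustive evaluation of the criterion, not a literature constant.

**Statistics.** Mann-Whitney U via rank sums with midranks; exact
permutation null when both n ≤ 10 and there are no ties (two-sided p by
doubling the smaller tail, capped at 1), otherwise normal approximation
with tie-corrected variance and continuity correction. Weighted kappa with
linear weights by default and quadratic as a switch (the grading study's
scheme is not stated; both are reported side by side); degenerate marginals
raise rather than return a number.

## Known limitations

* Voxel-level melanin-mask boundaries blur by ≈ 1 column per lesion side
  (3-px transverse kernels), so defect areas erode by roughly one
  column-row around the footprint; relative error grows as defects shrink
  toward a single column.
* At steep PED margins the band depth can change by more than the band
  half-thickness between adjacent columns; isolated one-column false
  defects can appear there — the same configuration that makes margins
  hard in clinical reading.
* Deep, noise-dominated choroid is excluded by invalidity rather than
  measured; melanin mapping is only meaningful above the noise floor.
* HRF volumetry inherits Shanbhag-threshold placement on speckled dB
  histograms; expect errors of a few percent even at high contrast.
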