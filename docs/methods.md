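# Methods

## Problem and model

When a robotic radiosurgery system tracks a moving lung target, the beam
aperture follows the *predicted* target position while the target is actually
at the *imaged* position; their difference — the treatment delivery error,
combining correlation-model and prediction-model errors — displaces the
aperture relative to the target at every imaging time point. `irisopt`
quantifies the resulting tradeoff between target coverage and normal-tissue
irradiation and uses it to choose the Iris variable-aperture collimator
diameter.

The aperture is modeled as a ball of the nominal field diameter centered on
the predicted position; the target (CTV) is rigid. Because only the relative
displacement matters for the target–aperture intersection, accumulation works
in the **target frame**: the CTV stays fixed on its grid and the aperture
center is offset by the per-point error vector e = pred − true from the
tracked reference point (the CTV centroid). This deliberately sidesteps the
unmodeled motion of surrounding anatomy; "leakage" voxels are non-target
voxels in the target's neighborhood, not anatomically identified lung.

For each voxel we accumulate the fraction of imaging time points (pooled over
all fractions with equal weight) in which the voxel center lies inside the
aperture ball — the **coverage possibility** on CTV voxels, and the **leakage
possibility** on non-CTV voxels that ever enter the aperture. Membership is
binary on voxel centers; partial-volume weighting is not modeled. Beam
divergence and the non-isocentric beam geometry are collapsed into the
nominal-diameter ball.

## Histograms and scalar metrics

The CVH is the coverage analog of the cumulative DVH: percent of structure
volume with coverage possibility ≥ level. The LVH is absolute: cm³ of
leakage-support volume with leakage possibility ≥ level. Curves are exported
on 1001 evenly spaced levels, but every scalar metric is computed from the
raw voxel values and is therefore independent of that discretization:

- **C95 / C90** — the coverage level reached by ≥ 95% / 90% of the structure
  volume: the exact order statistic (the value of the ⌈0.95 n⌉-th
  best-covered voxel), mirroring the DVH D95 convention, ties included.
- **AUC** — possibility-weighted volume. Computed exactly as
  voxel volume × Σ values (the layer-cake identity); both coverage and
  leakage AUCs are kept on the absolute cm³·possibility scale so the
  **leakage/coverage ratio** (leak AUC / PTV coverage AUC) is dimensionless.
- **Absolute mean leakage** — leak AUC divided by the leakage-support
  volume, i.e. the mean leakage possibility over irradiated normal-tissue
  voxels; always in [0, 1].
- **Φ/a_min, Φ/a_max** — selected diameter normalized by the PTV's short and
  long axis lengths.

PTV-level coverage restricts the same accumulation to PTV voxels; PTV voxels
outside the CTV score their plain aperture-inclusion fraction. The PTV is
also the denominator of its own quantiles (the column label, not the CTV,
governs).

## Geometry

Grids are regular, axis-aligned, voxel-center convention
(world = origin + (i + 0.5)·spacing). Margins (GTV→CTV 2 mm, CTV→PTV 4 mm,
isotropic) are Euclidean-distance dilations computed by exact distance
transform on voxel centers; the grid auto-enlarges when the expansion or a
displaced aperture would not fit. Center-based dilation of a digitized ball
measures an effective radius within one voxel of the analytic one — tests
compare effective radii, not raw volumes.

Axis lengths are not given a standard definition in clinical practice, so the
package defines: **a_max** = maximum Feret diameter over surface-voxel
centers (via convex hull) plus one voxel spacing (so a digitized ball of
diameter d measures d, not d − spacing); **a_min** = minimum width of the
projection onto the plane orthogonal to the a_max direction
(rotating-calipers on the projected hull) plus the same padding. This is
rotation-robust, unlike bounding-box extents. A single-voxel structure
reports both lengths equal to the voxel spacing, keeping the candidate
interval below well defined.

## Collimator selection

1. **Candidates**: Iris diameters d with 0.5·a_min ≤ d ≤ a_max + 5 mm; an
   empty intersection raises an explicit error.
2. **Feasibility cascade**: candidates with CTV C95 ≥ 90%; if none, CTV
   C90 ≥ 90%; if still none, the tier is "none-feasible" and the full cost
   table is reported without a selection.
3. **Cost**: F(d) = w·C95_PTV(d) − mean_leakage(d)/v_lung, with C95_PTV as a
   fraction in [0, 1] and v_lung the affected-lung volume (cm³, per-patient
   input). The selector **maximizes** F: the stated clinical goal — keep
   coverage, spare tissue — requires the coverage term to help and the
   leakage term to hurt, and with the default w = 0 maximizing F minimizes
   mean leakage. A literal minimize-F mode is available behind
   `literal_minimize` for comparison experiments. Ties break toward the
   smaller aperture (spares more tissue at equal measured cost). With w = 0
   the selection is invariant to any positive rescaling of v_lung.

The two clinical comparison groups re-run the selection per tier: the "C95
group" runs the full cascade, the "C90 group" applies only the C90 threshold.
The per-candidate accumulation is tier-independent and shared.

## Synthetic data

Real tracking log files are proprietary, so the motion module simulates
traces: true positions follow a per-axis cosine breathing path (default
period 4 s, SI-dominant amplitude; irrelevant to the metrics under the
target-frame convention but kept for realism), one imaging point per 15 s,
and errors drawn as independent per-axis Gaussians. Only combined
delivery-error statistics are emulated — correlation and prediction errors
are not drawn separately, and no autocorrelation, hysteresis or baseline
drift is modeled. Default SDs (LR 1.21, AP 0.58, SI 0.86 mm) are typical
lung-tracking delivery errors.

The cohort module samples patients as axis-aligned ellipsoids: PTV long/short
axes from truncated normals (56.80 ± 17.26 / 36.36 ± 10.44 mm, jointly
rejected until a_max ≥ a_min, and floored at 12 mm so a CTV survives the 4 mm
erosion), PTV volume from a lognormal matching 41.15 ± 30.17 cm³ (the middle
semi-axis is fit to the sampled volume, clipped between the other two),
per-axis error SDs from truncated normals around the defaults, fractions from
a rounded normal (5.11 ± 1.73) clipped to 3–7, and affected-lung volume from
a lognormal (median 1500 cm³, σ = 0.25 — invented, config-exposed). The
distribution families are package choices; only means and SDs are anchored.

**What passing cohort tests show**: idealized convex targets with independent
Gaussian errors reproduce the *orderings* of the clinical analysis (C95 group
→ larger apertures, more coverage, more leakage; Φ/a_min positively
correlated with the leakage/coverage ratio). They do not reproduce clinical
magnitudes: real targets are irregular, errors are autocorrelated and
patient-specific, and the published per-patient numbers derive from
unavailable log files. Statistical comparisons use Wilcoxon signed-rank
(two-tailed, zero differences dropped, midranks for ties) and Spearman
correlation via scipy.stats, cross-checked in the test suite against exact
sign-enumeration and rank-formula oracles.

## Numerical choices and problem sizes

- Default evaluation spacing 1 mm isotropic (a config parameter; nothing in
  the method fixes the planning-CT resolution).
- The cohort study runs at 2 mm spacing with 40 imaging points per fraction —
  diameter selection is insensitive to finer grids on ellipsoidal phantoms,
  and the full 37-patient, two-tier study completes in seconds.
- Accumulation touches only the bounding box of all aperture positions;
  everything outside has inclusion fraction exactly 0, so maps can be
  zero-extended losslessly when a larger evaluation structure needs them.
- Coverage quantiles at exact ties return the largest level still satisfied
  (order-statistic convention).
- Degenerate inputs fail loudly: empty masks, non-positive diameters, empty
  traces, non-finite coordinates, grids on incompatible lattices.

## Known limitations

Geometric possibility, not dose: no Monte Carlo or ray-trace transport, no
DVH/NTCP conversion, no tissue heterogeneity. Rigid target, no segmentation
or deformation error. Single-aperture plans only (no small+large collimator
combinations). Axis-aligned grids and NIfTI masks only; no DICOM-RT parsing.
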