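# Methods

## Scope and model

`pctpath` estimates the interior trajectory of a proton through a known
(or estimated) material distribution, conditioned on tracker measurements
of its entry and exit position/direction and a calorimeter measurement of
its exit energy. The estimate is the maximiser of the bivariate Gaussian
posterior implied by Fermi–Eyges transport theory; the same matrices give
a lateral standard error used to draw a k·σ probability envelope. Only
the projection onto the t–u plane is estimated; the v–u projection is an
independent process and reuses the same machinery when requested.

Assumptions, in decreasing order of importance:

- **Gaussian MCS.** Scattering is the aggregate of many small deflections;
  nuclear interactions and single large-angle (Molière-tail) scatters are
  outside the model and, in practice, are suppressed by the statistical
  data cuts.
- **Local scattering power.** `T(u) = T̂ · T_w(E(u))` depends only on the
  material at depth u and the current energy (Gottschalk's simplified
  form, valid for 3–300 MeV protons). A hook for a nonlocal
  single-scattering correction factor exists in principle but is not
  implemented: with both endpoints measured, the correction matters only
  near the faces, where the envelope is pinched anyway.
- **Small angles.** Angles are treated as slopes; retained tracks satisfy
  |θ| < 0.3 rad after cuts.
- **Energy-independent relative powers.** RScP is exactly
  energy-independent in this formulation. RStP is nominated as the mean
  of S_m(E)/S_w(E) over 10–300 MeV (1 MeV steps); for the stiffest tissue
  in the catalogue (cortical bone) the energy-resolved RStP stays within
  1% of the nominated value for 30–300 MeV and within 2% down to 10 MeV.

## Materials and calibration

Elemental scattering summands follow
`(Z²/A)[2 ln(33219 (AZ)^(−1/3)) − 1]`; the reciprocal of the
mass-weighted sum for liquid water evaluates to 0.016359, matching the
conventional constant 0.01636, and the water scattering length to
46.88 cm — these two checks pin down the algebraic form. Stopping powers
use the Bethe–Bloch formula without shell or density corrections
(validated to ≤1% against published water values at 100/200 MeV); mean
excitation energies default to the Bragg additivity rule over ICRU-37/49
constituent values (water: 75 eV fixed; cortical bone: 106.4 eV fixed,
its published compound value).

The bundled catalogue transcribes the 46 adult reference tissues
(elemental mass fractions and densities) plus air (79% N / 21% O,
ρ = 0.001225 g/cm³). The RStP↔RScP calibration fits solid tissues by
ordinary least squares and the low-density group by a line through the
origin. The published sample counts (45 solid + 4 low-density from 46
tissues + air) are reproduced by letting the two lightest fatty tissues —
the anchoring adipose and yellow marrow — contribute to **both**
segments; among the plausible labellings this one comes closest to the
published fit parameters. The fitted values here are
p1 = 0.3847, p2 = 0.6544 (r² = 0.9941) and p1 = 1.2197 (r² = 0.9956),
within ~2% of the published 0.3905/0.6448 and 1.2127; the residual
discrepancy reflects transcription-level differences in trace-element
fractions, not the method. The inverse map (RStP → RScP) is the
continuous piecewise-linear inverse, switching branches at the fitted
intersection.

## Energy estimation

Depth grids use δu = 1 mm internally; query depths default to 5 mm
(slab/water) or 1 mm (voxel phantoms). Finer internal grids change the
benchmark results negligibly. The forward Euler branch starts from the
nominal accelerator energy, the backward branch from the per-track
measured exit energy; the combined profile weights them linearly by
normalized distance from the opposite face, so both boundary conditions
hold exactly and no reconciliation of inconsistent boundary energies is
attempted. If the forward branch exhausts its range inside the phantom it
is floored at 1 MeV and the weighting (which favours the backward branch
there) absorbs the discrepancy. Scattering powers below the 3 MeV
validity floor are clamped at the 3 MeV value with a warning.

## Numerical choices

- Moments are accumulated with composite trapezoid sums; cumulative
  tables of ∫T, ∫ηT, ∫η²T make any segment's (A0, A1, A2) an O(1)
  lookup, so the per-track cost is linear in the grid size.
- The 2×2 systems are solved in closed form. A determinant below 1e−30
  marks a zero-scatter (degenerate) segment and triggers a straight-line
  fallback with σ = 0.
- The factor 2 in the published error matrix is implemented exactly as
  printed (it widens the envelope by √2 over the true conditional
  standard deviation); `factor_two=False` exposes the no-factor variant
  for sensitivity analysis, and the per-depth containment test of the
  Gaussian simulator is run in that mode, where ±3σ contains the nominal
  99.7%.
- The homogeneous water baseline (`mlph2o`) follows the classic water
  formalism: a fifth-order polynomial fit of the energy factor
  1/(β²p²) versus depth on the deterministic water energy curve for the
  nominal beam energy (least squares weighted for relative error; RMS
  relative residual ≈0.25% at 200 MeV/20 cm), the Highland logarithmic
  thickness correction per covariance segment, and X0 = 36.1 cm. In
  water it agrees with the inhomogeneous machinery to <2% RMS in the
  path and ~3% at the envelope peak.

## Spline hybrid

The hybrid evaluates the full matrix MLP only at entry, exit and depths
where the RStP profile changes region (air < 0.3 ≤ tissue ≤ 1.1 < bone)
or jumps by more than 0.15 (so cranium/cortical interfaces are caught),
then reconstructs the path with a clamped cubic spline using the measured
entry/exit directions as end slopes. Envelope bounds are separate
natural-end-condition splines through t ± kσ at the sample depths (only
the centre path has measured directions; k defaults to 3). On the slab
stack this reduces 41 calculation depths to 6; on the synthetic head,
depth profiles select ~8% of 1 mm query points.

## Simulator: what it emulates, and what it does not

The track generator is a Gaussian MCS engine consistent with the same
Fermi–Eyges theory the estimator uses: per 1 mm step the projected angle
receives an independent N(0, T δu) kick and the lateral position the
correlated within-step displacement (joint sampling reproduces the
(A0, A1, A2) moments exactly for piecewise-constant T); energy loss is
deterministic Bethe–Bloch through the local RStP. Parallel beams are the
default; a fan geometry from a 160 cm point source spanning the exit face
is available (the benchmark metrics are endpoint-conditioned and
insensitive to this choice). Two documented configurations:

- **clean** (default): no straggling, no contamination — exactly the
  process the MLP assumes. Benchmarks and envelope-containment results
  use this preset; this is also why the headline numbers probe the
  *formalism* (path estimation given Gaussian MCS) rather than any Monte
  Carlo engine's tail physics.
- **realism**: Bohr-like Gaussian energy straggling (variance
  0.0871 MeV²/cm scaled by relative electron density) and 2% of steps
  drawn with 9× kick variance, giving the 2σ data cuts a non-Gaussian
  population to remove; used by the data-cut tests.

Consequently, passing benchmarks show that the estimator and envelope are
correct *for Gaussian MCS transport*; they do not certify behaviour under
nuclear interactions, Molière tails or detector noise, none of which are
modelled. Published escape fractions obtained with a full Monte Carlo
(water phantom, ~0.2% after 2σ cuts) include exactly those residuals and
are therefore approached from below here.

## Metrics and conventions

RMS lateral error is computed per query depth over tracks, in mm, with
bootstrap (200 resamples) standard errors; it is zero at the faces by
construction. Envelope containment is reported under **two conventions**:
per-track (escaped if outside k·σ at *any* interior query depth) and
per-sample (fraction of (track, depth) samples outside). Under exactly
Gaussian transport the water-baseline slab escape matches the published
scale and energy ordering only under the per-sample convention (~7% vs
published 9.6% at 210 MeV, ~0.7% vs 1.4% at 230 MeV), while the any-depth
count is ~5× larger; both are always reported, and the water-baseline
containment figure quoted against the published table uses the per-sample
count. Samples whose envelope half-width is below 50 µm (far below
tracker resolution; the envelope pinches to zero at the faces and at hull
boundaries) carry no meaningful envelope and are excluded from both
counts.

## Benchmark problem sizes

Water: 200 MeV, 20 cm cube, 3000 histories, 2σ cuts. Slab: 2 cm water /
7 cm cranium / 2 cm cortical bone / 7 cm cranium / 2 cm water at
{210, 215, 220, 225, 230} MeV, 3000 histories each, 2σ cuts. Voxel head:
synthetic elliptical head stand-in (bone annulus, air cavities, bone
septa; 1 mm voxels, 14.3 cm depth), 200 MeV, 1 mm queries, used for the
voxel code paths (pre-path spline material lookup, bounding-box hull
baseline, per-track subsampling). At these sizes every benchmark runs in
seconds on one core.

## Known limitations

- The tissue catalogue is transcribed; trace-element fractions may differ
  slightly from the printed reference tables, which shifts the
  calibration fit in its third decimal and the bone RStP/RScP scalars by
  a few tenths of a percent.
- The simulated slab exit energy at 210 MeV (~21 MeV) sits above the
  published Monte Carlo value (15.7 MeV), so the water-assumption error
  at the lowest energy — and hence the measured reduction (~15% vs the
  published 17%, ~2.5% vs 5% at 230 MeV) — is slightly conservative.
- The bounding-box hull is a trivial stand-in for hull detection; the
  voxel phantom is a synthetic fixture, not imaging data; HU-based
  calibration of real CT scans is out of scope.
- Runtime claims of the original study (ms/track, relative speed-ups)
  are hardware-bound and only logged, never asserted.
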