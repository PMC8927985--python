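# Methods

`fibwave` implements an in-silico atrial-fibrillation (AF) study pipeline on
synthetic two-dimensional atrial tissue: substrate construction from a
bipolar-voltage map, monodomain propagation with Courtemanche-Ramirez-Nattel
(CRN) ionic kinetics under chronic-AF electrical remodeling, AF induction by
ramp pacing, restitution-slope (Smax) and dominant-frequency (DF) mapping,
virtual ablation (CPVI with or without highest-DF ablation), and
cohort-level statistics.  This note records the model, the defaults, and the
design choices a maintainer would need to reassess.

## Substrate construction

The sheet is a regular grid of nodes (spacing configurable; 300 μm default,
matching the node scale of clinical-grade atrial models).  The synthetic
"clinical map" is built in four steps:

1. **Ground-truth voltage field** — Gaussian-smoothed white noise mapped to
   a healthy bipolar-voltage range (default 1.8–2.4 mV), multiplicatively
   depressed by circular low-voltage patches (centers optionally pinned,
   otherwise random; Gaussian radial profile, depth ≈ 0.8–0.95).  The
   healthy floor sits above the 1.74 mV fibrosis cutoff so a zero-patch
   configuration is fibrosis-free by construction.
2. **Catheter-style sampling** — `n_samples` nodes (default 500, the order
   of points an electroanatomical map acquires) are sampled and
   re-interpolated to all nodes by inverse-distance weighting, weights
   d^-a within a 10 mm radius.  The exponent a is not fixed by the source
   material; a = 2 (Shepard's default) is used and exposed in config.
   Out-of-coverage nodes fall back to the nearest sample.
3. **Fibrosis** — per-node probability from the piecewise voltage map:
   1 at X = 0; (−40.0X³ + 155X² − 206X + 99.8)/100 for 0 < X ≤ 1.74 mV
   (the cubic is a percentage — its X→0 limit is 99.8 — hence the division
   by 100); 0 above 1.74 mV.  The yes/no status is realized as a seeded
   per-node Bernoulli draw (`sample` mode); a deterministic `threshold`
   mode is provided because the realization rule is not otherwise
   specified.
4. **Conductivities** — nonfibrotic (σ_L, σ_T) = (0.1264, 0.0252) S/m and
   fibrotic (0.0546, 0.0068) S/m.  The source list labels all four values
   "longitudinal"; the 0.0252/0.0068 pair is read as transverse, which
   yields the conventional ≈5:1 atrial anisotropy.

Fiber fields: `uniform`, `wavy` (smooth ±26° modulation), `random_smooth`,
or `circumferential` (tangential around PV openings, as at real ostia).
PV openings are circular node voids with no-flux rims; linear scar strands
(`scar_slots`) are segment-shaped voids.  Regions are equal-area rectangular
blocks (default R = 10, mirroring a 10-region left-atrial partition).

## Ionic model and remodeling

The CRN human atrial myocyte model (21 state variables) is implemented with
voltage-indexed lookup tables (0.05 mV grid over −120…80 mV) holding gate
steady states, Rush-Larsen decay factors exp(−dt/τ(V)), and the pure-voltage
current factors.  Gates advance by Rush-Larsen exponential integration;
concentrations and V by forward Euler.  Nernst potentials are cached and
refreshed every 1 ms (intracellular concentrations drift on second
timescales; E_Ca enters only the small background Ca current).

Chronic-AF remodeling scales maximal conductances: IK1 ×2.0, Na/Ca
exchanger ×1.4 (applied to the exchanger maximal flux), INa ×0.9, Ito ×0.3,
ICaL ×0.5, IKur ×0.5.  Under these defaults the package computes a control
APD90 of ≈277 ms at 1000 ms cycle length and an AF-remodeled APD90 of
≈160 ms at 600 ms (the shortening is the expected remodeling signature and
is asserted against an independent adaptive-stiff-solver integration in the
test suite).

Numerics: single-cell default dt = 0.02 ms; tissue default dt = 0.05 ms
(cohort runs use 0.075 ms).  Halving dt moves the steady-state APD90 by
< 1% and first activation times by < 2% below dt ≈ 0.025 ms (first-order
convergence; both are tested).  The stimulus is a rectangular 2 ms pulse;
the default amplitude (40 pA/pF tissue tests, 60 pA/pF cohort) is 2–3×
diastolic threshold.  State initialization: published resting values, then
pre-pacing (default 20 beats at 600 ms for single-cell protocols).

The numba kernels restrict fast-math to value-safe flags
(`nsz`, `arcp`, `contract`) so results are reproducible across x86-64
hosts: full reassociation licenses CPU-dependent vectorization, which would
let bitwise results depend on the machine that JIT-compiled the kernel.

## Monodomain solver

Per-node diffusion tensor D = R(θ) diag(D_L, D_T) R(θ)ᵀ with
D = `diffusion_scale` × σ; the scale (mm² ms⁻¹ per S/m, default 1.2) folds
the surface-to-volume ratio and membrane capacitance into one tunable
constant, which `tune_diffusion` bisects to match a target conduction
velocity on a homogeneous probe strip (wave speed ∝ √D).  Spatial
discretization: conservative face-flux form for the axis terms (face
conductivity = arithmetic mean, zeroed across voids/ablated nodes, no-flux
edges) plus a masked 9-point cross term for fiber rotation.  Ablated nodes
are decoupled and clamped at rest.  The CFL bound is checked up front and
the maximal admissible dt reported.

Activation detection: upward crossing of −40 mV with 50 ms lockout,
sub-sample timing by linear interpolation on the 1 ms recording grid.

**Discrete propagation limits.**  On coarse grids propagation fails when
D/dx² falls below ≈0.1 ms⁻¹.  At the printed conductivities the transverse
direction crosses this limit first (D_T is 5× smaller than D_L); grid
spacing and diffusion scale must be chosen jointly so that transverse
coupling stays above it wherever waves must turn.  Fibrotic tissue sits
below the limit at desk-scale spacings — dense fibrotic patches act as
jagged conduction-block zones, which is the intended arrhythmogenic role.

## Protocols

Ramp induction: 8 beats at each cycle length 200, 190, …, 120 ms — 72
stimuli spanning exactly 11.52 s (each beat occupies its own cycle length;
this is the only reading that reproduces the printed total).  AF is called
induced when self-sustained activity outlasts the final stimulus by ≥ 1 s;
the observation window runs to 34 s.  The pacing site is either a disc
(default, radius 1.5 mm) or a full edge strip; the strip launches planar
waves where repeated focal launches would fail from source–sink mismatch
near the propagation limit.  The cohort paces with a disc inside the
driver lane, beside the scar isthmus, where the narrow lane removes the
focal-launch curvature penalty.

Restitution: per-node (DI, APD90) pairs are collected from the start of
pacing to 3 beats past AF onset (onset operationalized as the end of the
ramp).  APD90 is measured per beat against that beat's own peak and
preceding diastolic minimum; the first beat is dropped (no preceding DI).
The curve y(DI) = y0 − A1(1 − e^(−DI/τ1)) is fitted by multi-start
nonlinear least squares (A1 ∈ ±{1,2}×APD-range, τ1 ∈ {20, 60, 150} ms;
best RMS wins, ties to the smallest τ1; a start with RMS < 0.05 ms ends the
search deterministically).  Smax = (|A1|/τ1)·e^(−DI_min/τ1) at the minimum
observed DI; the DI→0 limit |A1|/τ1 is kept as a diagnostic.  Nodes with
< 4 pairs or < 10 ms DI spread are unfit and excluded from maps.

DF: magnitude spectrum of the mean-subtracted, Hann-tapered 6 s segment,
searched in 0.5–20 Hz (1/6 Hz resolution), windows 16–22, 22–28, 28–34 s.
Quiescent segments (< 10 mV span) are undefined.  The highest-5% DF area is
the value rule — nodes within 5% of the window maximum — with a
count-quantile mode available.

Rhythm classification over the 10 s post-ablation observation:
TERMINATED = no activation beyond the post-stimulus lockout; AT = pooled
cycle-length coefficient of variation < 0.1 **and** median per-node
dominant-peak(+harmonics) power fraction > 0.6 (per-node spectra are used
because circulating rhythms phase-cancel in a global mean signal);
otherwise AF.  Both thresholds are package operationalizations and are
config-exposed.

## Desk-scale study design

A patient-scale atrium (~10 cm, ~4·10⁵ nodes) cannot be simulated here, and
the remodeled CRN wavelength (λ ≈ CV × APD ≈ 30–40 mm at the tuned
conduction velocities) makes free functional reentry unsustainable on
centimeter sheets — cross-field-initiated spirals self-terminate within a
few rotations, with or without anchoring obstacles.  The cohort substrate
therefore anchors the AF driver anatomically as a protected macro-reentry,
which is also the regime the source study associates with effective DF
ablation (a dominant driver maintaining AF):

- 96×48 nodes at 0.4 mm (38×19 mm sheet), diffusion scale 0.7 and
  `circuit` fibers wrapping a 29 mm scar strand, so the racetrack corridor
  around the strand conducts longitudinally everywhere (free-circulation
  cycle length ≈ 230 ms, DF ≈ 4.3 Hz);
- a scar pinch narrows the lower lane to a 1.2 mm isthmus channel: paced
  wavefronts travelling through it toward the expansion fail at short
  coupling intervals (rate-dependent one-way block), so the final ramp
  beats leave exactly one wave circulating — induction is geometric, not
  a stochastic-fibrosis accident;
- the pacing disc sits in the lower lane beside the isthmus ("anterior"
  pacing adjacent to the scar);
- a transverse scar divider with a 2 mm gap separates the driver
  compartment from an outer band holding two PV openings (for CPVI) and a
  low-voltage fibrotic patch; the driver activates the outer band through
  the gap.

Because the clinical cohort was, by enrollment, 100% AF-inducible, the
packaged cohort can draw substrates from seeds screened for inducibility
(`substrate_seeds` / `screen_max_tries`); screening conditions on
induction only, never on the downstream endpoints (correlations,
defragmentation rates).

Inter-patient electrophysiological variation is generated by scaling ICaL
alone (×0.55–1.05 on top of the remodeled ×0.5): more ICaL lengthens APD
and steepens restitution (higher Smax).  IK1 is deliberately not
co-varied: it changes conduction velocity, which on an anatomically fixed
circuit would confound the driver rate with a non-restitution mechanism.

**A measured desk-scale limitation.**  On a fixed anatomical circuit the
driver cycle length is path-length/CV-limited: across the inducible part
of the ionic grid the measured post-pacing cycle length is nearly constant
(≈ 230 ms), because profiles whose wavelength approaches the path length
(where head–tail interaction would slow the driver) sit at or beyond the
edge of both inducibility and maintenance.  The clinically observed
inverse DF–Smax relationship arises from functional-reentry rate limiting,
which this desk scale cannot reach; the cohort machinery computes and
reports the regional correlation regardless, and the corresponding
end-to-end test documents the shortfall rather than masking it.

## What the generator does and does not emulate

Emulated: spatially correlated voltage maps with low-voltage zones, sparse
catheter sampling + interpolation, voltage-dependent fibrosis, ~5:1
anisotropy, PV ostia, regional partitions, ramp-inducible driver-maintained
AF, and paired virtual-ablation arms.  Not emulated: 3D atrial anatomy and
wall-thickness gradients, biatrial/interatrial conduction, atlas-derived
fiber maps, multi-wavelet AF maintained by steep-restitution wavebreak
(desk-scale sheets cannot hold the required number of wavelets), autonomic
and calcium-overload triggers, and clinical lesion biophysics.  Passing
tests therefore show that the pipeline recovers the engineered
driver-vs-restitution structure at desk scale, not that it reproduces
patient-scale AF dynamics.

## Statistics

Spearman rank correlation (average ranks), Mann-Whitney U (exact for small
untied samples, tie-corrected normal approximation otherwise) and the 2×2
association tests (Pearson chi-squared without continuity correction when
all expected counts ≥ 5, otherwise Fisher's exact test) are delegated to
scipy.stats behind the package's interfaces; the test suite checks each
against hand-written enumeration oracles.  No multiple-testing correction
is applied anywhere.  Cohort summaries report both the per-model and the
pooled model×region level.

## Known limitations

- Induction is seed-dependent; unscreened cohorts can contain a majority of
  non-inducible substrates, which are recorded and excluded from DF and
  ablation summaries.
- The desk-scale driver is a single anatomical macro-reentry; DF values
  (≈ 4–5 Hz) sit below typical clinical AF DF (6–8 Hz) because the circuit
  is long and conduction deliberately slow.
- Smax at extreme ICaL scalings can be depressed by 2:1 capture and
  alternans contaminating the restitution data.
- The forward-Euler/Rush-Larsen scheme is first-order; conduction
  velocities carry a few percent discretization bias at the default dt and
  coarse-grid spacings, which the √D-scaling and anisotropy checks
  tolerate by design.
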