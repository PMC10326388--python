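# Methods

This note documents the models, parameter choices and numerical decisions
behind the package, and what the synthetic test bed does and does not
establish about real data.

## Signal model of the drug-challenge simulator

Each voxel of a simulated subject follows a multiplicative model around a
constant baseline level L (default 1000 arbitrary units):

    s_v(t) = L · (1 + drift(t) + a_v · ramp(t) + n_v(t) + spike(t))

* **Response** `a_v · ramp(t)`: zero before the injection (acquisition 50 of
  350, TR 6 s), rising linearly over `ramp_length` acquisitions to a
  plateau.  The default ramp of 236 acquisitions places the plateau at
  acquisition 286, matching a slow pharmacological response that separates
  from vehicle only late in the session.  A linear-ramp-plus-plateau is
  used because no pharmacokinetic time constant is available for the kind
  of compound being emulated; the onset and ramp length are free parameters
  of the design, not claims about any specific drug.
* **Amplitude** `a_v`: the dose's peak percent change / 100 in voxels of the
  configured active regions, 0 elsewhere.  The default dose profile is an
  inverted U — 0 (vehicle), 0.5, 2.0, 0.5 percent — with group sizes
  6/7/7/7; 2% is the realistic scale of a weak-but-real drug response in
  awake rodent imaging, and sits at the edge of single-subject
  detectability given the noise level below.
* **Noise** `n_v(t)`: stationary AR(1), marginal SD 1.0% of baseline,
  lag-one coefficient 0.3, independent across voxels.  1% is the
  conventional "normal BOLD fluctuation" scale that motivates the 1%
  magnitude gate; 0.3 is a moderate temporal autocorrelation for ~6 s
  sampling.
* **Drift**: linear, default 0.001 %/acquisition (≈0.35% over a session) —
  large enough to matter if unhandled, small enough to be screened by the
  magnitude gate.
* **Motion spikes**: with probability 0.01 per acquisition, a global 2–5%
  intensity deviation of random sign is added and the acquisition is
  flagged.  The pipeline scrubs by flag (window exclusion, spike
  regressors), not by re-registration, so the simulator records the flag
  rather than modelling actual head displacement.

The resting-state simulator draws region ("node") courses jointly from a
user-specified unit-diagonal covariance (factored by eigendecomposition so
semidefinite networks are allowed), assigns each voxel its region's course
plus independent observation noise (SD 0.3 in node-signal units), and
expresses everything as percent-scale fluctuation around the same baseline
level.  Scans are 150 acquisitions at TR 1 s.

The synthetic atlas is a nearest-seed (Voronoi) partition of an ellipsoidal
brain.  Region geometry is deliberately unrealistic — blocky, convex-ish
patches — because none of the statistics under test depend on anatomy, only
on the partition structure.  Simulation studies in the tests use 40 regions
on a 32×32×16 grid (~6,200 in-brain voxels), a size chosen so a 200-subject
null calibration and a 27-subject dose study both run in minutes on one
CPU; the generator scales to the full 173-region, 96×96×20 configuration
when asked.

**What passing tests do not show.** The generator has no spatial noise
correlation, no physiological (cardiac/respiratory) structure, no
hemodynamic impulse response, no partial-volume mixing at region borders,
and drift is linear rather than scanner-like.  Sensitivity and
false-positive numbers obtained here therefore characterize the statistics
under idealized noise, not expected performance on scanner data.

## Activation statistics

* **Windows** are inclusive acquisition ranges, [5, 45] versus [300, 345]
  (41 vs 46 acquisitions), with motion-flagged acquisitions excluded from
  both means and from the t-test samples.  Exclusion (rather than
  inclusion) of flagged acquisitions in the voxel t-test is the package
  default.
* **Welch t-test** per voxel (two-tailed, unequal variances).  Degenerate
  voxels: constant-and-equal windows give p = 1 by convention;
  constant-but-different give p = 0.
* **Rank filter**: the step-up reading of P₍ᵢ₎ ≤ (i/V)·q/c(V) — find the
  largest qualifying rank, keep everything below it.  Step-up is the
  standard reading of this class of false-discovery control; q defaults to
  0.2 with c(V) = 1.  NaN p-values (invalid voxels) neither count toward V
  nor can be kept.  By default the filter runs over the whole in-brain
  voxel population per subject; a per-region option reruns it with V equal
  to each region's voxel count.
* **Magnitude gate**: significance additionally requires |ΔS%| ≥ 1. The
  alternative reading of the same 1% figure — an α = 0.01 level on the
  t-test instead of a percent-change floor — is available via
  `magnitude_as_alpha=True`.
* **Composites** average subject percent-change maps (non-significant
  voxels zeroed) into the atlas grid through each subject's inverse affine
  transform with trilinear interpolation.  Out-of-field contributions are
  treated as missing and excluded from the mean, not averaged in as zeros,
  to avoid edge dilution.
* **Dose statistics**: Kruskal–Wallis H (tie-corrected, chi-square
  approximation) per region, sorted by p with stable region-id
  tie-breaking; all-identical regions get p = 1.  The post-hoc rank-sum
  uses exhaustive enumeration over C(n_a+n_b, n_a) rank assignments
  whenever min(n) ≤ 10 — exact even under ties, and the group sizes this
  package targets are 6 and 7 — otherwise a tie-corrected normal
  approximation with continuity correction.  The reported effect size is
  ω² = (z² − 1)/N from the normal-scale z, a variance-explained estimate
  consistent with the rank-biserial family; it is reported alongside the
  raw z and can be slightly negative for near-null contrasts.
* **Repeated measures**: the classical two-factor mixed decomposition
  (group between, time within subject), interaction F tested against the
  time × subject-within-group error.  Per-acquisition group contrasts use
  Welch t at the Šidák level α_per = 1 − (1 − 0.05)^(1/m) with m the
  number of post-injection acquisitions — the family is every acquisition
  after injection, since no other family size is canonical.

## Preprocessing

* **Band-pass**: order-4 Butterworth applied forward-backward
  (zero-phase), passband 0.01–0.1 Hz.  Zero phase preserves event timing;
  the effective attenuation is the square of the single-pass response.
* **Smoothing**: Gaussian, σ = FWHM/(2√(2 ln 2)) per axis in voxel units,
  default FWHM 0.8 mm.
* **Nuisance regression**: per-voxel OLS on [intercept, six motion
  parameters, one indicator per flagged acquisition, white-matter mean,
  CSF mean].  Spike indicators keep the time axis intact (important for
  filtering) while zeroing the flagged residuals exactly.  Collinear
  columns are dropped greedily with a warning.
* **Registration**: 9-parameter family (translation, rotation, per-axis
  scale; no shear), optimized by normalized correlation under Powell's
  method over a coarse-to-fine smoothing pyramid.  Scales are searched in
  log space and rotation/scale act about the volume centre — both choices
  decorrelate the parameters and were necessary for reliable scale
  recovery.  During the search, out-of-field voxels are treated as
  background (zero) so the optimum is not distorted by a shrinking overlap
  region; the final quality check uses overlap-only normalized correlation
  and raises if it stays below 0.5.
* **Resampling**: trilinear through world-coordinate affines (voxel
  indices 0-based, world = index × voxel size from the volume corner).
  Out-of-field voxels are NaN (missing), never zero.
* **Slice-timing correction** (per-slice linear temporal interpolation,
  interleaved or sequential order) exists but defaults off: the simulator
  does not generate slice offsets.
* Pipeline order for resting data follows the conventional sequence:
  outlier detection → (slice timing) → band-pass → detrend → smooth →
  nuisance regression, then region extraction.

## Connectivity

* Node set = atlas regions with voxel support in the mask; empty regions
  are dropped with a warning and the surviving ids recorded in every
  output, so the node count is data-determined rather than assumed.
* One-sample t → Z conversion maps the t CDF through the standard-normal
  quantile, preserving sign; under the null the resulting Z is exactly
  standard normal, which makes the |Z| ≥ 2.3 threshold's null edge rate
  2·Φ(−2.3) ≈ 2.1% by construction.  Survival functions are clipped at
  1e-300 so extreme edges stay finite.
* The |Z| = 2.3 threshold is applied before degree computation by default
  (`threshold_before_degree`); degrees on the unthresholded weighted
  matrix are not provided — degree centrality is defined on the binary
  undirected graph.
* "K-nearest-neighbors clustering" of a connectivity matrix is ambiguous
  (k-NN is nominally a classifier); the implementation builds the
  symmetrized k-NN graph on row profiles under correlation distance and
  returns its connected components (k default 5), with spectral clustering
  on the profile-correlation affinity available behind a flag.  Both are
  deterministic given the input.
* The degree comparison pairs the two conditions region-by-region within
  each named subregion — with two independent animal groups, pairing is
  only meaningful at the region level, and this is stated prominently in
  the API documentation.  A Shapiro–Wilk test on the paired differences at
  α = 0.05 gates paired t versus Wilcoxon signed-rank; all-zero
  differences short-circuit to p = 1, and constant nonzero differences are
  routed to the nonparametric branch.

## Known limitations

* Affine-only registration; no deformable refinement.
* No negative-control calibration for the connectivity arm beyond the
  analytic null edge rate; inter-subject covariance heterogeneity is not
  simulated.
* The exact rank-sum enumeration is combinatorial; above min(n) = 10 the
  implementation switches to the normal approximation.
* Config files are flat YAML with a strict key schema; unknown keys are
  errors by design (silent threshold typos are the main operational risk),
  which means configs are not forward-compatible across schema versions.
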