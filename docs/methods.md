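# Methods

## Physical model and forward solver

Tissue is modeled as a 2D heterogeneous linear viscoelastic medium with
complex shear modulus G*(x) = G′ + iG″ (Pa) and uniform density ρ
(default 1000 kg/m³, the standard soft-tissue value; the source study never
states ρ). The through-plane displacement amplitude u(x, ω) at the drive
frequency satisfies the scalar heterogeneous Helmholtz equation
∇·(G*∇u) + ρω²u = 0. This 2D scalar reduction matches how single-slice,
through-plane-encoded MRE data are actually inverted; compression waves
appear only as the low-wavenumber nuisance component the band-pass removes.

The solver discretizes the divergence form conservatively: interface moduli
between neighboring pixels are harmonic means, giving a 5-point stencil
that reduces to the standard Laplacian stencil in homogeneous regions. The
system is solved by a direct sparse LU factorization — deterministic and
independent of iteration tolerances. Boundary handling:

* non-tissue pixels (region label 0) clamp u = 0 (rigid surround);
* grid edges are zero-flux (Neumann), so a phantom that fills the grid
  supports an exactly laterally-invariant plane wave — the configuration
  used for oracle comparisons;
* the drive is a Dirichlet condition on the first tissue pixel of each scan
  line from one edge (plane piston), or on the entire tissue surface
  (`drive_boundary="all"`), which emulates the real apparatus where the
  skull is vibrated and waves enter the parenchyma from all sides;
* tissue within `sponge_width` pixels of the edge opposite the drive gets a
  graded loss factor G* → G*(1 + iσ r²), σ = 1.5 over 12 pixels by default,
  emulating outgoing radiation. The sponge must span roughly one
  wavelength to absorb well; the pointwise-agreement tests size it
  accordingly.

A resolution precondition (≥ 6 pixels per shear wavelength, computed from
the softest tissue value) rejects under-resolved runs with the computed
pixels-per-wavelength in the message.

### Discretization accuracy

The 5-point stencil is second order. Two distinct consequences matter:

* **Local bias of the inversion.** On a sampled plane wave the discrete
  Laplacian satisfies ∇²ₕ e^{ikx} = −(4/h²)sin²(kh/2)e^{ikx}, so algebraic
  inversion of an *analytically* sampled wave returns
  G_est = G_true · (kh/2)²/sin²(kh/2). At the acquisition grid (128 px over
  25 mm, ~12.6 px/wavelength at 4.6 kPa and 900 Hz) this bias is ≈ +2.2 %;
  at 25 px/wavelength it drops below 0.6 %. Tests assert the 2 %
  closed-form agreement at the finer grid and assert the bias formula
  itself at acquisition resolution.
* **Accumulated dispersion of the forward solve.** The numerical wavenumber
  differs relatively by ≈ (kh)²/24 per wavelength, which accumulates over
  propagation distance; pointwise field agreement with the analytic wave at
  the 2 % level therefore also needs the finer grid. Crucially, the
  *pipeline* does not suffer from either effect: forward solve and
  inversion share the same stencil, so on a homogeneous phantom the
  recovered modulus equals the ground truth up to filtering effects —
  which is why the end-to-end recovery criterion holds comfortably at the
  native 128×128 acquisition matrix.

## Motion encoding and reconstruction

Encoding efficiency ξ = γ·A_MSG·N_cycles/(2f) ≈ 3.81×10⁵ rad/m with the
default protocol (γ = 2.675×10⁸ rad s⁻¹T⁻¹, 285 mT/m, 9 cycles, 900 Hz).
Dynamic d of n acquires wrap(±ξ·Re[u e^{−2πid/n}] + static + noise). The
static background phase is a low-order 2D polynomial; noise is additive
Gaussian per pixel before wrapping, with a mandatory seed whenever
noise_sd > 0.

The half phase-difference wrap(pos − neg)/2 cancels the static field
exactly and has wrap period π, carried explicitly on the series so the
unwrapping stage scales correctly. Unwrapping is quality-guided
(scikit-image) by default with a row-wise Itoh fallback. A hard limit
follows from the doubled encoded component: adjacent-pixel phase steps of
the difference must stay below π, i.e. ξ·A·k·h < π/2. At the default
protocol this caps the unambiguous drive amplitude near 4 µm at the drive
surface; larger amplitudes (the realistic tens of micrometers) unwrap
correctly away from the immediate drive vicinity, and the unstable ring is
removed by the validity mask. Per-dynamic global unwrap offsets are
spatially constant and are eliminated by the filter's DC rejection.

Temporal Fourier extraction uses the fundamental DFT bin normalized by 2/n,
so a time course ξA·cos(2πd/n − θ) yields modulus ξA and phase θ; dividing
by ξ gives displacement in meters. The band-pass is a radial Butterworth
(order 3) with cutoffs 0.3·k_ref and 3·k_ref, k_ref = 2πf√(ρ/G_ref),
G_ref = 5 kPa — the cutoffs are not recoverable from the source study, so
they are configuration with defaults that bracket physiological
wavenumbers and reject the near-DC compression regime (gain(0) = 0).

Inversion masks a pixel when (i) it lies on the one-pixel border (no
stencil support), (ii) |∇²u| falls below 0.05× the interior median
(unstable division), or (iii) the recovered G′ ≤ 0 or G″ < 0 (unphysical;
the fraction is logged, never clamped). ROI averages use valid pixels only
and fail loudly when an ROI has none. Each of the four derived maps is
averaged independently — φ is the mean of per-pixel loss tangents, not the
arctan of averaged components. The alternative ordering is exposed because
the source tables are ambiguous on this point (their printed φ = 0.549 is
inconsistent with arctan(1.388/4.608) ≈ 0.29).

## Synthetic study generator

The longitudinal generator draws a balanced 2×n×6×2×4 table from a
random-intercept model: value = control_mean × multiplier(treatment, time)
+ animal intercept + residual, with intercepts per (animal, ROI, parameter)
and residuals per record. |G*| and φ are derived per record from the
sampled G′, G″, keeping the four parameters internally consistent.
Defaults encode the study conditions: control means 4608/1388 Pa
(hippocampus) and 5234/1447 Pa (whole brain); a single transient effect at
6 dpi in the MPTP arm (×1.51 on G′ and ×1.27 on G″ in the hippocampus,
×1.29/×1.16 whole brain); per-animal SDs implied by the printed SEMs at
n = 5 (SEM·√5), split equally in variance between the animal and residual
levels since the split is not recoverable from printed summaries.

Counts are negative-binomial around specified means (default shape 30,
i.e. ~20–25 % animal-to-animal CV on typical counts — overdispersed
relative to Poisson, as real histology is). Time courses emulate a
labeled cohort: BrdU cohorts decline after the pulse, a precursor surge at
3 dpi and a neuron surge at 6 dpi in the MPTP arm, a 3-dpi microglial
peak, stable total granule-layer nuclei.

What the generator does **not** emulate: scanner artifacts beyond additive
phase noise (ghosting, B0 drift, motion), anatomically realistic geometry,
3D wave propagation and mode conversion, partial-volume effects at ROI
borders, and any correlation between the MRE and histology arms (the real
study sacrificed separate groups). Passing tests therefore demonstrate
internal consistency of the computational chain under the stated noise
model, not fidelity to any individual animal's data.

## Statistics

The mixed-design (split-plot) two-way ANOVA computes sums of squares by
direct summation over cell and marginal means, in two strata: Treatment is
tested against subjects-within-groups (df 1, 2n−2), Time and
Treatment×Time against Time×subjects-within-groups (df t−1 and
(g−1)(t−1), error (2n−2)(t−1)). No sphericity correction is applied by
default, matching the uncorrected degrees of freedom the study reports;
the decomposition is exactly additive per stratum, which the tests assert.
The fully-between two-way ANOVA tests all effects against the single
residual term (df 48 for 2×6×5). Degenerate inputs (zero total SS) flag
F as undefined rather than raising.

Bonferroni pairwise comparisons require an explicitly enumerated family;
the adjusted p is min(1, m·p). Group-at-time contrasts use a
pooled-variance independent-samples t on the animals at that time point;
time-pair contrasts within a group use a paired t across animals. Using
the per-contrast error rather than a pooled model stratum term is a
deliberate, documented choice: the error term the original SPSS analysis
used is not recoverable, and the per-contrast t is the conservative,
assumption-light option. Under the generator's default noise (per-animal
SD = printed SEM·√5) the power of the 6-dpi group contrast at n = 5 with
m = 6 is only ≈ 0.2, so the smoke tests assert calibrated discrimination
(6-dpi rejection rate far above the baseline rate, baseline at the nominal
level) rather than near-certain detection.

## Stereology

`series_total` multiplies an exhaustive 1-in-k series count by k (k = 12,
sections 480 µm apart). `double_label_absolute` converts a proportion
measured on a fixed sample (50 BrdU⁺ cells) into an absolute number via the
marker total. The optical fractionator is N = ΣQ⁻/(ssf·asf·hsf) with
section sampling fraction 1/12, area fraction (30×30)/(120×100) = 0.075 and
height fraction 20/40 = 0.5; the 5 µm guard zone constrains disector
placement but does not enter the height fraction. All estimators return
exact floats; rounding happens only at the report layer.

## Problem sizes and numerical choices

Forward solves run at the native 128×128 acquisition matrix (sparse LU,
~0.2 s); oracle-grade comparisons use 256-pixel grids (~2 s). Monte-Carlo
checks use 10 seeds (noise recovery), 200 seeds (power smoke tests) and
500 seeds (type-I calibration), sized so the binomial confidence bands are
decisive while the whole suite stays interactive. Seeds are explicit in
every stochastic signature; noise-free paths are bit-reproducible.
Degenerate inputs are contracts, not accidents: zero drive yields the zero
field, a constant wave image is a reported reconstruction failure (zero
Laplacian everywhere), empty comparison families and unbalanced designs
are rejected with the offending cell named.

## Known limitations

* The inversion is 2D scalar; out-of-plane propagation biases real data in
  ways the simulation cannot probe.
* Amplitudes beyond the Itoh limit leave a path-dependent unwrap region
  near the drive surface; it is masked, not corrected.
* The absorbing sponge is imperfect below one wavelength of width;
  residual reflections are negligible in lossy media but visible in
  lossless test configurations.
* The ANOVA layer covers balanced, complete designs only — the study's own
  design — and offers no mixed-model (REML) alternative for missing data.
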