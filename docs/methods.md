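# Methods

## Pressure estimation from a color M-mode velocity map

The estimator integrates the 1-D inviscid Euler equation
∂P/∂s = −ρ(∂v/∂t + v ∂v/∂s) along the scanline, with blood density
ρ = 1060 kg/m³ and 1 mmHg = 133.322 Pa. Numerics:

* derivatives: second-order central differences, second-order one-sided
  stencils at the grid edges (`numpy.gradient`, `edge_order=2`);
* spatial integration: composite trapezoid rule from row 0, so
  P(row 0, t) ≡ 0 — only pressure *differences* are meaningful, which is
  all that is ever reported;
* no temporal filtering inside the estimator itself; preprocessing is
  explicit and separate (below).

The independent oracle (`synthetic_cmm.oracle_pressure`) solves the same
equation by a deliberately different route — bicubic-spline
interpolation of the sampled field, analytic spline derivatives, and
trapezoid quadrature on a spatially supersampled grid (default 8×).
On analytic fields (steady convective v = a·s; uniform oscillatory
v = A sin 2πft) both routes match the closed forms
P = −ρa²s²/2 and ΔP = −ρ·2πfA·s·cos 2πft to well under 1 %, and they
agree with each other within 1 % at the apex on generated inflow fields.

### Segmentation and peak extraction

The LV span [annulus, apex] is trisected in continuous position;
boundaries are not snapped to the grid and pressures at non-grid
positions are linearly interpolated. Within each beat's diastolic
window (mitral-valve opening to the next Q wave; markers snapped to the
nearest time sample) the time of **peak total base-to-apex difference**
is located (earliest sample on exact ties). All segment drops are
evaluated at that single instant, which enforces, to machine precision,

* mid_to_apical = mid + apical, and
* basal + mid + apical = P(annulus) − P(apex) at the peak.

The *total* IVPD spans the whole scanline (row 0 → apex) by default.
The scanline may extend proximal of the mitral annulus into the left
atrium, so the total can exceed the sum of the three LV segments; this
is the package's reading of summary tables in which the total exceeds
basal+mid+apical while mid+apical equals mid-to-apical exactly. A
`total_span="lv_only"` toggle restricts the total to the annulus→apex
span. IVPG units are mmHg/cm (IVPD divided by the LV length in cm) —
chosen because it makes typical IVPG magnitudes a fraction of the
corresponding IVPD, consistent with reported ranges; the display unit
is a configuration, not a physical necessity.

An optional `e_wave_only` mode restricts the peak search to early
filling (MV opening → Q-to-peak-E plus a 2σ_E margin); default off,
since late (A-wave) peaks are legitimate in some physiologies.

### Preprocessing

* **Dealiasing** — Doppler wrapping into [−V_N, V_N) is inverted by
  phase unwrapping (period 2V_N) along time per scanline row, then a
  column-consistency pass anchored at the map's first sample. Exact
  recovery is guaranteed for fields whose true sample-to-sample jumps
  stay below V_N and whose first sample is unaliased; when more than
  20 % of samples need correction a quality warning is emitted.
* **Smoothing** — separable Gaussian, reflecting boundaries, defaults
  σ_s = 2 mm, σ_t = 6 ms. Peak extraction takes a maximum over ~10²
  noisy samples and is therefore upward-biased under noise; at the
  generator's default noise (0.02 m/s on a 0.57 m/s E wave) these
  widths cut that bias to < 1 % while attenuating the clean peak by
  ~1.5 %. Stronger smoothing trades bias for attenuation roughly 1:2
  beyond this point.

## The synthetic inflow generator

`synthetic_cmm` emulates what a CMME line records across the mitral
valve, not intraventricular fluid dynamics: each of the E and A waves is
a Gaussian pulse in time (peaks 0.57 / 0.55 m/s, widths 45 / 35 ms)
that propagates apex-ward at c = 0.5 m/s and decays linearly in
amplitude (fraction β = 0.4 annulus→apex); proximal to the annulus the
wave is applied without delay or decay through a C¹ cubic-Hermite clamp
(blend width 4 mm) so the field stays differentiable. Heart period
0.55 s (~110 bpm), 60 mm scanline with the annulus at 20 mm, 40 mm LV
length, grid ds = 1 mm and dt = 1/300 s (the sampling implied by a
300 mm/s sweep display). Noise is i.i.d. additive Gaussian per sample.

What this does **not** emulate: speckle-correlated noise, beat-to-beat
physiologic variability, valve clutter, scanline curvature, or genuine
Navier–Stokes flow. Passing tests therefore demonstrate correctness of
the *estimation chain* under a controlled velocity model, not fidelity
to any animal's hemodynamics.

The generator refuses grids with fewer than 6 temporal samples per wave
width, where the pulse would be unresolvable.

## The cohort simulators

* Repeatability: y_ijk = μ + g_i + t_j + (gt)_ij + ε_ijk with Gaussian
  components, so the implied ICC σ_g²/(σ_g²+σ_t²+σ_gt²+σ_ε²) is exact
  bookkeeping. Gaussian components keep that bookkeeping tractable and
  match a setting where a Shapiro–Wilk gate is expected to pass.
* Paired: per-goat multiplicative effect with jitter; the number of
  discordant animals, and optionally the exact ranks their |differences|
  occupy, are enforced by construction (these determine the exact
  signed-rank p and rc). Magnitudes are continuous draws, distinct by
  default, because the exact enumeration assumes untied ranks; an
  `allow_ties` option exercises midrank handling.

## Statistics

* **CV%** — 100·SD(n−1)/mean. Between-cycle: mean over goat×scan cells
  of the CV across cycles. Between-scan: mean over goats of the CV of
  the per-scan means. Classes: <15 low, 15–25 moderate (both boundaries
  inclusive in "moderate"), >25 high. A "95 % CV" label sometimes
  attached to such tables is treated as naming this CV, not a separate
  statistic.
* **ANOVA** — classical balanced-design sums of squares (exact
  decomposition; the balanced case needs no regression machinery),
  F against the within-cell mean square. All-constant input is reported
  as degenerate with p = 1 rather than NaN. Unbalanced designs are
  rejected with an explicit error (a documented non-goal).
* **ICC** — every scan×cycle measurement is a "rater" (k = n_scans ×
  n_cycles). Default form ICC(2,1) (two-way random, absolute agreement,
  single measurement), because scans are interchangeable observers;
  ICC(3,1) is available and the report labels the form used. At the
  study scale (n = 8, k = 8) the estimator carries a small negative
  bias (mean ≈ −0.02 at true ICC 0.91), verified by simulation and left
  uncorrected. Acceptability: ICC ≥ 0.75.
* **Wilcoxon signed-rank** — d = first − second argument; zeros dropped
  (Pratt's method by flag); midranks on |d|; exact two-sided p as the
  doubled smaller tail of the full 2ⁿ sign-pattern distribution,
  computed by convolution over doubled midranks, for n ≤ 20 (~10⁶
  patterns at the cutoff — exact where studies of this size live, cheap
  enough to enumerate); beyond that a normal approximation with
  continuity and tie corrections. rc = (W⁺−W⁻)/(W⁺+W⁻), classified at
  |rc| 0.1/0.4/0.6. The exact test is conservative at small n: the
  simulated null rejection rate at α = 0.05, n = 8 sits near the lower
  edge of [0.03, 0.07].
* **Spearman / Shapiro–Wilk / Fisher exact** — delegated to scipy's
  implementations of the identical classical procedures (rank-Pearson
  with t-approximation; Royston's algorithm; two-sided hypergeometric
  enumeration). Shapiro–Wilk is reported as a gate only and never
  switches methods silently. No multiple-testing correction is applied
  anywhere; reports are per-variable and say so.
* The repeatability report's 95 % CI of the mean is the textbook
  t-interval over per-goat means, and is labelled as such.

## Pipeline and reproducibility

All randomness flows from one root seed through named
`numpy.random.SeedSequence` substreams per stage; identical config +
seed gives byte-identical `summary.json`. The end-to-end `run-study`
uses 8 goats per arm, 2 scans, 4 cycles — the design scale the
statistics target — and finishes in seconds. The acceptance script
averages 200 simulated cohorts for the parameter-recovery quantities;
at that replication the Monte-Carlo error of the mean ICC is ≈ 0.002,
an order of magnitude below the ±0.05 band it is judged against.

## Known limitations

* The Euler model neglects viscous and off-axis terms; this is inherent
  to the method, not a numerical choice.
* Dealiasing cannot recover fields aliased by more than one Nyquist
  span at the anchor sample.
* ANOVA is balanced-only; missing cycles must be handled upstream.
* The sedation arm of `run-study` induces its effect through inflow
  amplitude and heart rate only; it is a demonstration of the analysis
  shape, not a pharmacological model.
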