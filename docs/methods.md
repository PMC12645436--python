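# Methods

This note documents the models, estimators and design choices behind
flowspps, in the order data flows through the pipeline.

## The generative model of a deprotection trace

`synthetic_data.simulate_deprotection_trace` emulates what an in-line
310 nm detector records during a flow synthesis of *n* residues:

* One peak per residue, centered in its cycle window.  The default
  shape is an exponentially modified Gaussian (EMG, Gaussian core σ
  convolved with an exponential tail τ) because flow dispersion between
  reactor and detector skews real deprotection transients toward a
  tailing edge; a pure Gaussian is kept for analytic tests.  Shapes are
  evaluated as unit-area densities (scipy's `norm`/`exponnorm`) and
  scaled to a target area, so area bookkeeping is exact by
  construction.
* Aggregation starts at a configurable synthesis index: from that
  residue on, the whole time profile of the peak dilates by a factor
  (1+g) per residue — both σ and τ, so the FWHM grows by exactly
  (1+g)ᵏ whatever the shape; g is a *width* growth rate, and slowed
  deprotection kinetics stretch the entire release transient, not just
  its core.  Simultaneously the peak area attenuates by a per-residue
  retention factor ("yield"), so peaks broaden *and* flatten — the
  signature the aggregation factor is built to read.
* An optional single "slow-coupling" residue dilates one peak (area
  preserved) without starting an onset, emulating a deliberately cold
  Cys coupling; it exercises the exclusion logic downstream.
* White Gaussian detector noise and a linear baseline drift are added
  last; the RNG is always explicitly seeded.

Per-residue ground truth (true h, FWHM, area, onset label) is measured
on a fine noiseless grid (step dt/20) with the same half-height-crossing
definition the analysis uses, making the generator a self-contained
oracle for every downstream stage.

Defaults: σ = 2 s, τ = 3 s, apex 1 AU, dt = 0.1 s, cycle length 180 s
(`afps` preset; the `peptipilot` preset uses 3600 s cycles — an
economical larger-scale regime analyzed by the identical path), g = 0.15,
yield = 0.97 per residue after onset.  These are the study conditions
the test suite runs under; noise, when used, is 5% of the base peak
height.  A peak whose tails exceed 0.1% of its apex at the cycle
boundaries raises "peak exceeds cycle window" rather than silently
leaking into the neighbour.

What the generator does **not** emulate: correlated (1/f) detector
noise, retention-time wander within a run, double/failed deprotection
peaks with multiple maxima, pump pressure artifacts, or any coupling
chemistry.  Passing tests therefore demonstrate the estimators'
correctness and noise robustness under this model, not instrument
validation on real archives.

## Peak measurement

`peak_analysis` turns a trace plus cycle schedule into per-residue
(h, w, area) records.

**Baseline.**  Per cycle window, a straight line through the minima of
the first and last 5% of the window is subtracted.  Windows shorter
than 20 samples are rejected.

**Metrics.**  Apex, height and the two half-height crossings are read
from a Savitzky–Golay smoothed copy of the window (polynomial degree 2).
The span is chosen in two passes: a minimal 5-sample pass yields a
provisional width, and the final span is one third of that FWHM.
Degree-2 local polynomials reproduce the apex and flanks of peaks at
chromatographic scales to O((span/w)⁴) — below 0.1% here — while
cutting white noise by more than half.  This matters: reading h from a
single raw sample and each crossing from one raw bracket pair would
leave a relative width error of about √2·σ_noise/(h·2ln2) ≈ 5% at 5%
detector noise, which propagates to an AF standard deviation of ~0.1 —
too coarse to call onset reliably against the default threshold.  With
the smoothed read-out the AF noise drops to ~0.05 under the same
conditions.  Because the span is tied to the peak's own width (in
time, not in samples), the bias does not grow with sampling rate and
measured widths still converge to the analytic FWHM as dt → 0.

Crossings are searched outward from the apex; the first crossing on
each side wins (deterministic, robust to satellite bumps) and is
refined by linear interpolation between its bracketing samples.  The
area is the trapezoidal sum of the positive part of the *raw* window —
smoothing never touches it.  Metrics are measured, never fitted: no
shape parameters are estimated, so skewed peaks carry no model bias.

Failure modes are explicit: an apex on the window edge is a "truncated
peak", a flank that never falls below h/2 is an "unresolved half-width",
and a height under 5× the robust noise scale (1.4826 × MAD of the first
5% of the window) flags `low_snr` without failing.  `analyze_run`
collects per-window failures instead of aborting, and only errors out
when more than half the windows fail.

## Aggregation factor and onset

The aggregation factor subtracts a height from a width.  Raw
subtraction would carry the instrument's arbitrary absorbance and time
scales into the statistic, so both metrics are first normalized to a
reference residue chosen early in the synthesis (before any plausible
aggregation):

    AF_i = w_i / w_ref − h_i / h_ref

This is dimensionless, exactly zero at the reference, strictly
increasing in w and decreasing in h, and invariant under uniform
rescaling of either axis.  The alternative convention — dividing the
raw difference by its reference value — is available as
`convention="ratio"` but is not scale-free and pins the sign to the
reference's own w−h; it exists for comparison only.  Residues flagged
as slow couplings are carried in the profile but excluded from onset
logic (skipped, never interpolated).

**Onset rule.**  The first residue (synthesis order, exclusions
skipped) with AF ≥ θ sustained over m consecutive residues, never
within the first `baseline_n` positions.  Defaults θ = 0.2, m = 2,
baseline_n = 3.  θ sits roughly half-way between the AF noise floor at
5% detector noise (sd ≈ 0.05) and the AF of the first aggregated
residue under the default generative conditions
((1+g) − yield/(1+g) ≈ 0.31); m = 2 rejects any single-cycle artifact
by construction.  A threshold-plus-persistence rule was chosen over a
derivative rule because the underlying judgement is "has the profile
risen and stayed up", and a derivative would double the noise.

`compare_profiles` aligns runs (e.g. tagged vs untagged syntheses of
the same fragment) on their shared residue labels — the tag's own
residues simply drop out of the intersection — and reports each
profile's onset delay relative to a baseline profile in residues, or
the category `"suppressed"` when the variant never aggregates at all.

## Chromatogram integration and crude purity

Crude purity is the product peak's percentage of total integrated area
in the crude UHPLC trace.  The integrator:

1. anchors a straight baseline on the first/last 5% of the retention
   window, each anchor being the **median** of its edge region — the
   minimum of a few hundred noisy samples sits ~2.5 noise-sd below the
   floor, and that offset multiplied by the slice widths measurably
   distorts every area fraction, while the median is unbiased for a
   peak-free edge;
2. detects peaks on a lightly smoothed copy (Savitzky–Golay, default
   span 0.025 min) as local maxima with prominence ≥ k × robust noise
   (default k = 5; noise from the median absolute successive
   difference, which peaks cannot inflate);
3. places boundaries valley-to-valley (signal minimum between adjacent
   apexes, window edges outermost), then trims each slice to the
   contiguous stretch above twice the smoothed-trace noise around its
   apex, so empty gap stretches cannot multiply residual baseline error
   into the areas;
4. integrates signed trapezoids above the baseline — zero-mean noise
   then cancels instead of rectifying into spurious area — and drops
   peaks below 0.1% of total area before renormalizing the fractions.

The product peak is identified by retention time within a tolerance
(default ±0.1 min); zero or several candidates raise an error naming
them rather than guessing.  Drop-line (perpendicular) integration and
co-elution deconvolution are deliberately not implemented; purity on
strongly overlapping peaks is outside this integrator's remit.

## Masses and the ArgTag

Masses are formula-free sums over a 20-residue monoisotopic (and
average) residue-mass table plus one water for the free-acid
C-terminus; the amide terminus subtracts 0.984016 Da (OH→NH₂).  The
neutral monoisotopic convention reproduces the calculated mass of
GLP-1[7–37] (3353.6681 Da) and is cross-checked against pyteomics in
the test suite.  No protecting groups, PTMs or adducts: these are
post-cleavage, side-chain-free masses.

`strip_argtag` removes the **maximal** trailing Arg run — the
exopeptidase removes C-terminal basic residues processively and no
partially detagged intermediates are expected to survive — and
`verify_detag` classifies an observed mass shift Δ against k × 156.10111
Da within a ppm tolerance (default 20 ppm of the starting mass):
`complete` (k = n expected), `partial(k)`, `none` (Δ ≈ 0), or
`inconsistent`; a mass *gain* beyond tolerance is an error.  Lys is not
stripped by default (the enzyme also cleaves it, but the tag is pure
Arg); a sequence ending in the tag region is the caller's
responsibility to interpret.

## Numerical and degenerate-input conventions

* All readers validate and reject rather than coerce: non-monotone
  time axes, overlapping schedule windows, non-canonical sequence
  letters (named with positions), short traces.
* CSV is the only trace interchange format, decimal-point only, with
  `# key = value` comment metadata; floats are written with 17
  significant digits so round trips are bit-faithful.
* Ties in the half-height search cannot occur (first crossing outward
  wins); a flat segment at exactly h/2 interpolates to its midpoint.
* Reference residues flagged `low_snr` are refused ("unreliable
  reference") instead of silently normalizing to noise.
* Seeds are mandatory for every simulation entry point.

## Problem sizes used by the test suite

The stochastic checks run 20 replicate syntheses of 16 residues each
(plus 20 clean runs) at the default `afps` sampling (28 800 samples per
trace), and seeded four/five-component chromatograms at 0.002 min
sampling.  These sizes make every statistical property testable in
seconds while leaving the estimators' noise regimes identical to a
full-length synthesis — per-peak measurement depends on the samples
within one cycle window, not on run length.

## Known limitations

* The AF reference is a single residue; a noisy reference shifts the
  whole profile coherently.  Choosing an early residue with clean SNR
  is the user's responsibility (the code refuses flagged references
  but cannot judge subtler pathologies).
* Onset calling assumes aggregation is persistent once started; a
  genuinely intermittent aggregation (recovering for several residues)
  would be called at its last sustained rise only.
* The integrator's valley-to-valley convention under-resolves
  shoulders; purity values on co-eluting product species require
  manual curation upstream.
* Synthetic-data realism bounds what green tests prove (see above);
  instrument exports must be converted to the documented CSV dialects
  before analysis.
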