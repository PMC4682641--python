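# Methods

## The kinetic model

The simulator treats each labelled molecule as an independent
continuous-time Markov chain over three states: freely diffusible
(FREE), bound to methylated chromatin at one of 2–6 bright nuclear foci
(CHROM), and bound to RNA in the nucleoplasm (RNA). Binding is
pseudo-first-order — sites never saturate — which makes the population
mean an exactly solvable linear system and keeps the stochastic and
mean-field paths provably consistent. Diffusion is not spatially
resolved: FREE and RNA molecules are well mixed, the reaction-dominant
assumption. This is appropriate because measured half-recovery times
(hundreds of milliseconds at heterochromatic foci) far exceed diffusive
mixing times in a ~2 µm nucleus; the analysis therefore reads the
recovery rate as an exchange (dissociation) rate, not a diffusion
coefficient. RNA-bound molecules are nucleoplasmic and contribute
nothing to focus signal, reflecting the competition between RNA binding
and chromatin binding at the same protein interface.

Internally the chain is augmented to (FREE, RNA, CHROM@focus-1, …):
a molecule entering CHROM draws its focus from the configured binding
weights, so exchange between foci necessarily transits the shared pool —
the mechanism behind FLIP coupling. The rate-matrix topology is free;
the default uses CHROM→RNA (RNA-mediated eviction), RNA→FREE and
FREE⇄CHROM, a modelling choice since nothing forces RNA-bound molecules
to pass through the free state — the matrix accepts either topology.

An `immobile_fraction` of molecules is permanently bound at a focus
(exit rate 0); the true mobile fraction of a bleached focus is then the
exchanging share of its steady-state signal.

### Default study conditions

Chosen once, as the conditions of the system being emulated, and then
left alone:

| parameter | default | rationale |
|---|---|---|
| rate FREE→CHROM | 12 /s | together with the exits this puts ~87% of molecules in foci — the pool outside foci is marginal for this protein |
| rate CHROM→FREE | 1.2 /s, CHROM→RNA 0.15 /s | chromatin residence ~0.7 s; total exit 1.35 /s gives an expected t½ near 0.5 s, the observed regime; consistent with in-vitro off-rates of 10–1000 /s once avidity of the dimer on chromatin is allowed for |
| rate RNA→FREE | 4 /s | short-lived RNA-bound intermediate (~5% occupancy) |
| n_molecules | 2×10⁴ | literature-scale abundance for HP1-family proteins in a yeast nucleus |
| nucleus radius | 1 µm; 3 foci of 0.12 µm | typical fission-yeast nucleus with most cells holding three bright foci |
| acquisition | 120 frames / 60 ms, 20 ms diffraction-limited bleach (radius 0.3 µm), pre/post z-stacks (15 planes, 0.3 µm) | the acquisition geometry of the experiments being modelled |
| detector | 20 photons·molecule⁻¹·frame⁻¹, Poisson noise | realistic EGFP photon budget |
| axial drift | off by default; σ=0.3 µm, τ=5 s when enabled | isolates the artifact; the process starts at z=0 because the experimenter focuses the plane on the locus at acquisition start |
| bleach efficiency | 1.0 inside the spot; acquisition bleaching 0 | isolate effects; tests switch them on explicitly |

With these defaults, bleaching a single focus removes ~29% of total
nuclear fluorescence, inside the 20–35% band observed for this class of
experiment.

A second named condition, `reaction_dominant_kinetics(k_off)`, is the
validation regime for parameter recovery: a two-state system with a
small bound fraction (5%, split over two foci) in a large free pool, for
which every relaxation mode is ≈ k_off and the fitted half-time should
equal ln 2 / k_off to within ~2.6% systematic bias (the k_on
contribution to the relaxation rate). Recovery benchmarks use 4×10⁴
molecules so that molecule-counting noise, not the estimator, limits
per-replicate precision.

## Bleaching and its mean-field oracle

The bleach pulse removes fluorescence (with the configured efficiency)
from molecules inside the bleach sphere at either end of the pulse
window; chromatin-bound molecules sit at their focus centre, pool
molecules at independently sampled uniform positions. The mean-field
oracle reproduces this exactly: with q_i the in-region probability of
augmented state i and T = exp(Q·Δ) the transition matrix across the
pulse, a molecule's survival on path i→j is (1−eff) + eff(1−q_i)(1−q_j),
giving the fluorescent state distribution just after the pulse, which is
then propagated by the matrix exponential. Expected half-times are read
off this curve by bisection; stochastic and mean-field paths agree
within binomial error by construction, and the oracle itself is verified
against brute-force RK4 integration in the tests.

## Rendering

Foci are 2-D Gaussian spots (σ = focus radius) whose integral is
gain × fluorescent count × exp(−Δz²/2σ_axial²); the pool is a uniform
background inside the nucleus mask. Axial drift is an
Ornstein–Uhlenbeck path per focus. Z-stacks weight each focus by a
normalized Gaussian partition over planes, so the plane-summed stack
intensity is invariant to drift (plane spacing = σ_axial makes the
Riemann sum of the Gaussian essentially exact); this is what makes the
whole-nucleus correction work. Acquisition photobleaching multiplies
frame f by (1−rate)^f; Poisson noise is applied last.

## Trace analysis

Fixed order: extract (mean ROI intensity per frame, circle membership by
pixel centre) → subtract the series minimum → detect the bleach frame
(frame after the largest single-step drop, requiring the drop to exceed
3× the pre-drop frame-to-frame noise) → normalize to the mean of the
last 15 acquired time points. If fewer than 15 post-bleach frames exist,
all post-bleach frames are used with a warning. Background is the
per-trace minimum rather than a separate background ROI (a background-ROI
mode exists but is off by default), and FRAP traces are not corrected
for acquisition photobleaching by default; unbleached control loci
quantify it in the FLIP analysis.

The fit's time origin is the first post-bleach frame. This pairs with
minimum subtraction: when the series minimum falls on that frame (it
does whenever recovery is slower than one frame interval, and
approximately always), the subtracted, rescaled data are exactly of the
form a(1−e^{−bt}) from that origin with an unbiased rate — however much
fluorescence returned between the pulse and the first frame. Forcing the
model through zero at the pulse time instead would bias fast rates.

## Fitting

Nonlinear least squares (trust-region-reflective, bounds a,c ∈ (0,2],
b,d ∈ (10⁻³,10³] /s — spanning the measured off-rate range) with
multi-start initialization: a₀ from the plateau, b₀ from a log-linear
regression of (plateau − y), the two-component start at
(0.5a₀, 5b₀, 0.5a₀, 0.2b₀), plus 8 multiplicative jitters; the best SSE
wins. Components are relabelled post-fit so b ≥ d, rates within 1% are
flagged indistinguishable, and two-component half-times are solved by
bisection to 10⁻⁶ s. Standard errors come from the Gauss–Newton
covariance; R² is computed on the fitted (post-bleach) data only; AIC is
reported alongside. Model choice is a nested F-test,
F = ((SSE₁−SSE₂)/2)/(SSE₂/(n−4)), keeping the second component only at
p < 0.05 — the declared reading of "did not significantly improve the
fit". Fits are unweighted because the workflow averages normalized
traces and fits the mean; per-point weighting is available. Both
per-trace and averaged-curve half-times are supported since the field
reports both.

## Mobile fraction

F_M = (F∞/F_initial)/(N_after/N_before) with the nuclear totals N taken
from the pre/post z-stacks. The locus F_initial and F∞ are, by default,
the locus-ROI sums over those same stacks: the stacks were acquired
precisely to measure the recovery fraction, and plane-summed stack
intensities are insensitive to the axial drift that biases single-plane
readings low (the package reproduces that artifact: under drift the
single-plane final/initial ratio underestimates recovery while the
stack-based, corrected F_M stays within a few percent of truth). A
trace-based mode (`locus_source="trace"`) is available; the single-plane
ratio is always reported for comparison. "End of the time lapse" is the
mean of the last 15 frames, consistent with the normalization window.
Nuclear masks are user-supplied ROIs with an Otsu-threshold fallback.
A correction ratio above 1.05 (totals rising after a bleach) is rejected
as a mask error.

## Line-scan analysis

Bleached and control nuclei are scanned at 2 ms nominal sampling (jitter
ignored). The bleach-region mean of the FRAP nucleus is divided by the
time-matched control region mean (cancelling shared illumination drift
and acquisition bleaching exactly) and rescaled so the pre-bleach level
is 1 — region-mean-then-ratio, the declared order. Smoothing is a
centred gliding average (default window 40) with truncated windows at
the edges, so no values are fabricated. For the half-time, samples
inside the pulse window are excluded (recovery starts at pulse end,
which is the time origin), and the model y0 + a(1−e^{−bt}) is fitted
with the same gliding average applied to the model inside the residual —
otherwise the truncated edge windows at the bleach boundary would bias
fast rates. The free floor y0 absorbs the permanent pool loss. A tail
rising less than 0.02 above the floor is reported as "no recovery"
rather than fitted.

## Cohort statistics

Box summaries use type-7 (linear-interpolation) quartiles — declared,
since conventions differ — with whiskers at the most extreme points
within 1.5×IQR of the box. Group comparisons are two-tailed Welch
t-tests (implemented from the formula, p-values from the t distribution
with Welch–Satterthwaite df, cross-checked in tests against an
independent reference implementation). Cell-cycle phase is an input
label; the package never infers it, and M phase is out of scope because
the protein disperses then. Pairwise phase comparisons report raw
p-values by default (Holm correction behind a flag), mirroring how such
studies report them.

## What the synthetic data do and do not emulate

Emulated: steady-state exchange among three kinetic states, focus-
specific binding, a shared nucleoplasmic pool coupling foci (FLIP),
permanently bound subpopulations, a diffraction-limited 20 ms bleach,
out-of-plane locus drift, acquisition photobleaching, shot noise, and
the exact acquisition geometry (120 frames / 60 ms plus bracketing
z-stacks; ~2 ms line scans).

Not emulated: spatially resolved diffusion (no diffusion-limited
recovery phase — measured rates are exchange rates by construction),
binding-site saturation and competition, cell-to-cell variability in
expression level or geometry, focus movement in the imaging plane,
reversible photobleaching/blinking, and detector specifics beyond
Poisson gain. Passing tests therefore demonstrate that the analysis
recovers exchange parameters, mobile fractions and regime orderings
correctly when its kinetic assumptions hold; they cannot certify
behaviour on diffusion-dominated or saturated systems.

## Numerical choices and degenerate inputs

Stationary initialization prunes states with no inflow (zero-rate
RNA states, zero-weight foci) before solving the null space; an all-zero
rate matrix is a valid frozen system but requires an explicit initial
state. Event simulation is exact (exponential holding times, vectorized
over molecules); identical seeds give bit-identical trajectories and
images. Quantities reported in milliseconds are rounded only at
presentation. Validation problem sizes (30 replicates for recovery and
mobile-fraction benchmarks, 100 for selection calibration, 50 for regime
ordering, 10⁴ molecules or null simulations for distributional checks)
were chosen to hold Monte-Carlo error comfortably below the tolerances
being checked.

## Known limitations

The mean-field oracle treats the pulse window's two-endpoint bleach
geometry exactly but ignores third-order correlations between bleach
survival and post-pulse state (negligible at a 20 ms pulse). The Otsu
nucleus-mask fallback underestimates totals on synthetic images whose
foci dominate the histogram; supply a nucleus ROI for quantitative work.
The line-scan model maps local binding structure onto a single effective
bleach-region compartment, so it measures exchange, not diffusion
profiles along the line.
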