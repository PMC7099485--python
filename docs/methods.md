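# Methods

## Model

The package implements a three-population neural mass model of a neocortical
microcircuit: one excitatory population `E` (pyramidal cells), one
dendrite-targeting inhibitory population `I_dend` (somatostatin-like) and one
soma-targeting inhibitory population `I_soma` (parvalbumin-like).  It is an
extension of the classical Wilson–Cowan equations in which the input–output
sigmoid accepts two modulation channels,

    F(x, Θ, A) = α / (α + qA) · [ σ(α(x − (θ + Θ + (1−q)A))) − σ(αθ)ᶜ ],

where `σ` is the logistic function, `σ(αθ)ᶜ = 1/(1+exp(αθ))` makes
`F(0,0,0) = 0`, `Θ` is a subtractive modulation (a rightward shift of the
curve), and `A` is a divisive modulation whose character is set by the
divisiveness `q ∈ [0,1]`: at `q = 0` it collapses into a pure shift, at
`q = 1` it purely rescales the gain and maximal output.  Saturation levels
`k = exp(αθ)/(1+exp(αθ))` bound each population's activity.  The dynamics
are

    τ dE/dt      = −E      + (k_e − E)      F_e(w₁E + P(t), w₂ I_dend, w₃ I_soma)
    τ dI_dend/dt = −I_dend + (k_i − I_dend) F_i(w₄E, 0, 0)
    τ dI_soma/dt = −I_soma + (k_i − I_soma) F_i(w₅E, w₆ I_dend + w₇ I_soma, 0).

Only the `I_soma → E` connection carries the divisive channel; `I_dend`
inhibition is always subtractive, matching the physiological association of
divisive gain control with soma-targeting interneurons.

**Fixed constants.** Sigmoid constants θ_e = 4, θ_i = 3.7, α_e = 1.3,
α_i = 2 (the classical Wilson–Cowan values); time constant τ = 0.05 s, which
places intrinsic oscillations in the δ/θ range.  Mouse-V1 connectivity
constrains three weights to ratios of w₃: w₇ = w₃, w₂ = 0.54·w₃,
w₆ = 0.33·w₃.  The reference parameter set used in the worked examples is
{P = 1.428, w₁ = 24.368, w₃ = 9.677, w₄ = 27.249, w₅ = 30.913}; it
oscillates at ≈ 6.4 Hz fully subtractive (q = 0) and ≈ 5.7 Hz fully divisive
(q = 1).

**Units.** τ is in seconds, all frequencies in Hz, all durations in seconds;
activities, drives and weights are dimensionless.

## Numerical integration

The system is smooth and non-stiff.  The default integrator is a compiled
(numba) fixed-step classical Runge–Kutta 4 scheme with a 0.25 ms internal
step, resampled on a uniform 1 ms output grid.  At this step the solution
agrees with the adaptive Runge–Kutta 4(5) reference (`method="rk45"`,
rtol 1e−8 / atol 1e−10, scipy) to better than 1e−4 max-norm over 20 s, and
steady-state amplitudes agree to ~1e−8, while integrating two orders of
magnitude faster — the parameter-space pipeline integrates the model
~10⁵ times, so this is the difference between minutes and days.  Screening
and optimization use a 1 ms internal step (amplitude agreement ~1e−7 with
the reference step).  The equations are integrated as written: state
variables are not clipped, and the small negative excursions the modulated
sigmoid permits are part of the model.

The initial state is (0.1, 0.1, 0.1) for every run.  Any state in the limit
cycle's basin would do — the 10 s settle window absorbs transients — but
fixing one value makes runs bit-reproducible.

## Drive protocol

Each entrainment run receives the constant drive `P` for at least 10 s and
then a sinusoid `P + Λ sin(2πf_in(t − t₀) + φ₀)` until t = 20 s.  The switch
time t₀ is the first 1 ms grid instant after the settle window at which the
phase difference between the (restarting) sinusoid and the ongoing
oscillation equals the requested Δφ, resolved to within one grid step of
phase; the residual is absorbed into φ₀ so the difference at the switch is
exact.  The waveform switches abruptly; the discontinuity is bounded by Λ.
Drives with Λ > P are rejected because the realized input would violate the
model's non-negative input domain.

**Oscillation phase.** The phase of the ongoing oscillation is anchored to
the upward peaks of E(t): zero at each peak, advancing linearly to 2π at the
next peak (`intrinsic_phase`).  This is deterministic and windowing-free,
unlike a Hilbert transform.  The *bookkeeping* phase used to define Δφ
places its zero a quarter cycle after each peak (`PHASE_ANCHOR_OFFSET =
−π/2`).  The offset between the drive's sine phase and any anchor on the
ongoing oscillation is a pure convention — nothing in the protocol
identifies it — but it relabels the Δφ axis of every result.  The anchor
used here is identified by a known landmark of this circuit family: with it,
the median convergence time is minimized at Δφ = 3π/2 for every
divisiveness, and maximized at Δφ = π/2 for strongly divisive circuits.
Under a plain peak anchor the same physics appears shifted by a quarter
cycle (minimum at π).  The *final* phase difference after entrainment is a
different, physically anchored quantity: both the input and E(t) are
expressed in the peak convention (zero lag = "E peaks where the input
peaks"), and anti-phase is flagged within π ± π/4.

## Entrainment measures

**Entrainment index.**  The periodogram (squared magnitude of the DFT, no
taper, mean subtracted) of E(t) is computed over the post-convergence
portion of the run — or the final 10 s when convergence is undefined — after
cropping the segment to a whole number of drive cycles, which pins the drive
frequency onto a Fourier bin and suppresses leakage there.  Local maxima
below 1e−5 of the strongest peak are ignored.  Peaks are scanned in
descending power; a peak whose frequency is an integer multiple (n = 2…10,
within one frequency bin) of a stronger retained peak is removed as a
harmonic — unless it lies within one bin of f_in, which is always retained
so that subharmonic (1:2) locking stays visible.  Surviving powers are
normalized to sum to 1, and the index is the normalized power within one bin
of f_in.  Removing harmonics first means the index measures *where* the
power is, not how sinusoidal the waveform looks.

**Convergence time.**  The final limit cycle is the set of tolerance-unique
3-D state points over the last 3 s of the 20 s run (uniqueness tolerance
0.001); scanning backward from 3 s before the end, the first state that
fails limit-cycle membership (tolerance 0.01, Chebyshev metric) marks the
end of the transient, and the convergence time is that instant minus the
switch time, clamped at zero.  Both tolerances are relative by default,
scaled by the largest absolute coordinate in the compared data — mirroring
the semantics of the tolerance-based set operations in common numerical
environments — with an absolute mode available.  A constant trajectory is a
degenerate cycle and converges immediately.  If the final window is not yet
periodic (successive-cycle deviation above the membership tolerance), the
run is flagged non-converged instead of returning a number.  Convergence
times are only *reported* for complete entrainment (index > 0.98), which in
this model always corresponds to 1:1 locking.

**Natural frequency.**  Dominant periodogram peak of E(t) over the final
3 s (on a whole number of cycles, so the peak is bin-centered), refined by
the mean inter-peak interval; the two estimates must agree within 0.2 Hz or
the activity is treated as non-oscillatory (this also rejects aperiodic or
chaotic regimes).  The oscillation threshold everywhere is a peak-to-peak
amplitude of E above 0.01 — an order of magnitude above solver noise and an
order below typical cycle amplitudes.

## Parameter-space pipeline

A parameter set (P, w₁, w₃, w₄, w₅; dependent weights by the ratio rule) is
*valid* for the divisiveness comparison when (1) it follows the ratio rule,
(2) it oscillates under constant drive at both q = 0 and q = 1, (3) its
E-amplitudes at the two extremes differ by less than 0.001 (absolute — the
typical amplitude is 0.05–0.4), and (4) its I_soma amplitude is at least its
E amplitude at both extremes, which excludes circuits whose soma-targeting
population is effectively silent (those reduce to the classic
two-population system, where q is meaningless).

Candidates are drawn uniformly from P ∈ [0, 5], w_k ∈ [0, 35] and screened
with 10 s runs (diagnostics on the last 3 s).  Oscillatory candidates seed
an optimization toward conditions 3–4, solved in stages:

1. *Pre-search*: a coarse grid over the directions that control the
   soma-targeting amplitude (w₃ scaling — its self-inhibition via w₇ — w₄
   scaling, and w₅ toward its upper bound) picks the most feasible seed.
   Random oscillatory draws almost always violate condition 4 badly, and a
   simplex started far from the feasible pocket stalls.
2. *Feasibility phase*: Nelder–Mead (adaptive, ≤ 500 evaluations) on the L1
   condition-4 violation with a 0.002 margin.  An L1 (exact) penalty keeps a
   nonzero gradient at the constraint boundary, where a quadratic penalty
   flattens and stalls the simplex just outside feasibility.  Losing the
   oscillation is priced far above any violation, so the simplex cannot
   escape through the Hopf boundary into the quiescent region where
   amplitudes match trivially.  Starts whose residual violation stays above
   0.05 are rejected with a reason.
3. *Matching phase*: Nelder–Mead on |ppE(q=0) − ppE(q=1)| plus 100 × the L1
   violation, restarted once from the incumbent on stall.
4. *Polish*: the signed mismatch ppE(q=0) − ppE(q=1) is driven to zero by
   bracketing and bisection along P (then w₁) when a sign change exists
   nearby.

Excursions outside the hypercube carry a quadratic penalty (weight 10³)
throughout, and the final point is clipped and re-screened; it is accepted
only if all four conditions hold.  Accepted optima are deduplicated
greedily at tolerance 0.05 (Chebyshev metric, scaled by the largest
coordinate magnitude in the collection).  On seeded oscillatory starts,
roughly a quarter of optimizations converge to fully valid sets, and the
accepted sets' P values concentrate near 1.3 — close to the reference set.

For each valid set the nine-setting input battery is Λ ∈ {0.1P, 0.3P, 0.5P}
× f_in ∈ {f*(q=0), midpoint, f*(q=1)}.  The generalization study probes
every set with all nine settings at both q extremes (Δφ = 3π/2, the phase
that promotes the fastest convergence at every q, so neither extreme is
favored); a set that fails to oscillate after drive onset under any setting
is excluded from the pairing.  Convergence-time pairing is further
restricted to combinations fully entrained at both q.

## Synthetic fixtures

`wcentrain.synthetic` builds trajectories with known ground truth: sums of
sinusoids (so the spectral content is known exactly), per-channel phase lags
(so the three channels trace a genuine closed loop in state space rather
than a degenerate line, which would defeat limit-cycle membership tests), a
decaying perturbation cut off abruptly at a planted time (so the true
convergence instant is known to the sample), and seeded Gaussian noise.
These fixtures exercise the metrics, not the model: they emulate the
*geometry* the metrics must handle (planted peaks, transients, quasi-
periodicity) but none of the dynamics — passing metric tests on them says
nothing about the ODE itself, which is validated separately against
independent integrators and the two-population reduction.

## Problem sizes

The test suite and the acceptance script run everything at desk scale: the
screening check uses 25,000 draws (the full published funnel used 250,000),
the generalization study uses a collection of ~5–10 valid sets (not 96),
and sweep-based structure checks use a coarse 8 × 3 grid over
f_in ∈ [3, 10] Hz × Λ ∈ {0.2, 0.4, 0.6} rather than publication-resolution
heat maps.  Scaled-down summaries (medians, region containment, orderings)
are stable at these sizes; cell-exact maps and extreme quantiles are not,
and are not asserted.

## Known limitations

* The published screening yield (≈ 0.49% of uniform draws oscillatory at
  both q extremes) is not reproduced: this implementation measures ≈ 5.5%
  under its stated screen, and no admissible variation of the threshold,
  initial condition or horizon closes the gap.  The upstream screening
  procedure is not specified numerically, so the package keeps its own
  explicit, documented criterion; the corresponding acceptance check fails
  honestly.
* The Δφ axis is identified only up to the documented anchor convention;
  comparisons of absolute Δφ values across implementations require aligning
  conventions first.
* The drive targets only the excitatory population, inhibition onto
  `I_soma` is purely subtractive, and there is a single shared time
  constant — structural simplifications inherited from the model family.
* A generic pulse-response utility is provided through the drive machinery,
  but impulse-response characteristics (e.g. response half-life) are not
  calibrated quantities of this package.
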