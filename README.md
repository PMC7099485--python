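# wcentrain

Entrainment of a neocortical microcircuit model with tunable divisive
inhibition.

Neocortical circuits adjust their oscillation frequency to match rhythmic
input — *neural entrainment* — and inhibitory interneurons shape how well
and how quickly they do it.  Soma-targeting (parvalbumin-like) interneurons
deliver *divisive* gain modulation, scaling down the slope and maximal
output of their target's input–output function, while dendrite-targeting
(somatostatin-like) interneurons deliver *subtractive* modulation, shifting
the function toward higher inputs.  This package implements a
three-population extension of the Wilson–Cowan neural mass model in which
the character of the soma-targeting inhibition is a single dial, the
divisiveness `q ∈ [0, 1]`, and provides the machinery to quantify how `q`
shapes entrainment.  It is aimed at computational neuroscientists studying
oscillatory dynamics, gain control, and rhythmic stimulation.

## Model

Population activities E (excitatory), I_dend and I_soma evolve as

    τ dE/dt      = −E      + (k_e − E)      F_e(w₁E + P(t), w₂ I_dend, w₃ I_soma)
    τ dI_dend/dt = −I_dend + (k_i − I_dend) F_i(w₄E, 0, 0)
    τ dI_soma/dt = −I_soma + (k_i − I_soma) F_i(w₅E, w₆ I_dend + w₇ I_soma, 0)

with the modulated sigmoid

    F(x, Θ, A) = α/(α + qA) · [ 1/(1 + e^{−α(x − (θ + Θ + (1−q)A))}) − 1/(1 + e^{αθ}) ],

where Θ is a subtractive and A a divisive modulation, and
k = e^{αθ}/(1 + e^{αθ}) is the saturation level.  At `q = 0` the
soma-targeting inhibition of E acts as a pure shift; at `q = 1` it purely
divides the gain.

Entrainment is probed by switching the drive from constant `P` to
`P + Λ sin(2π f_in t)` at a controlled initial phase difference Δφ, and
quantified by

* the **entrainment index** — the fraction of normalized spectral peak
  power at `f_in` after harmonic pruning (1 = complete entrainment, and the
  `f_in` peak is always preserved so 1:2 subharmonic locking stays
  visible), and
* the **convergence time** — the time from drive onset until the state
  reaches its final limit cycle (reported for index > 0.98).

A sampling/optimization pipeline produces *valid* parameter sets — circuits
that oscillate at both `q = 0` and `q = 1` with amplitudes matched to
within 0.001 and a non-degenerate soma-targeting population — to test
whether conclusions drawn from one circuit generalize across the parameter
space.

## Worked example

```python
from wcentrain import (example_params, simulate, natural_frequency,
                       DriveProtocol, run_protocol, evaluate_entrainment)

# intrinsic oscillation at the two extremes of divisiveness
for q in (0.0, 1.0):
    traj = simulate(example_params(q), duration=10.0)
    print(f"q = {q:.0f}: natural frequency = {natural_frequency(traj):.2f} Hz")

# drive the circuit ~3 Hz above its natural frequency
drive = DriveProtocol(Lambda=0.4, f_in=9.0, delta_phi=0.0)
for q in (0.0, 1.0):
    traj, realized = run_protocol(example_params(q), drive)
    res = evaluate_entrainment(traj, realized.t_switch, drive.f_in,
                               realized.phi0)
    conv = (f"{res.convergence_time:.2f} s" if res.convergence_time
            is not None else "undefined")
    print(f"q = {q:.0f}: entrainment index = {res.index:.3f}, "
          f"convergence time = {conv}")
```

prints

```
q = 0: natural frequency = 6.41 Hz
q = 1: natural frequency = 5.68 Hz
q = 0: entrainment index = 0.797, convergence time = undefined
q = 1: entrainment index = 1.000, convergence time = 1.53 s
```

The intrinsic oscillation barely changes with `q` (6.4 → 5.7 Hz, matched
amplitudes), yet a drive 3 Hz above the natural frequency only partially
entrains the fully subtractive circuit (index 0.80, never settling into a
locked cycle) while the fully divisive circuit locks completely and reaches
its entrained limit cycle in about a second and a half.  Divisive
inhibition widens the range of entrainable frequencies and speeds up
convergence; the same comparison run across a pipeline-produced collection
of valid parameter sets (`wcentrain.generalization_study`) shows the effect
is not a quirk of one circuit.

A command-line interface mirrors the library:

```
wcentrain simulate   --config cfg.yaml --out-dir results
wcentrain sweep      --config cfg.yaml --out-dir results   # (f_in, Λ) heat maps
wcentrain phase-sweep --config cfg.yaml --out-dir results  # Δφ medians
wcentrain sample     --config cfg.yaml --out-dir results   # hypercube screening
wcentrain optimize   --config cfg.yaml --out-dir results   # full pipeline
wcentrain generalize --config cfg.yaml --out-dir results   # paired q=0 vs q=1 study
```

Configs are YAML (see `docs/methods.md` for parameters, units and
defaults); results are long-format CSV with a config-hash/seed header.

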