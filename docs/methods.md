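# Methods

## Model structure

A channel is a list of binary elements — one pore gate plus any number of
ligand binding sites — each flipping between two configurations with
intrinsic rates (s⁻¹ for gates; the association step of a site is second
order, M⁻¹s⁻¹, and is multiplied by the free ligand concentration).
The joint state space is the n-dimensional hypercube (2ⁿ states; state
index bit *i* is element *i*'s configuration, an ordering that is stable
and documented). Only single-element flips are allowed, so the generator
Q has the n-cube sparsity pattern.

Interactions enter in two ways:

* **Barrier couplings.** When a source element is in a stated
  configuration, a target transition's activation barrier changes by
  ΔΔG‡ (kcal/mol), multiplying the rate by exp(−ΔΔG‡/RT). Couplings are
  stored directionally, but the constructor `pair_coupling` takes the
  three independently stated energies of an interacting pair and derives
  the fourth from thermodynamic-cycle closure
  (ΔΔG‡_fwd − ΔΔG‡_bwd must agree between the two orientations). An
  equilibrium-shifting coupling therefore can never be one-sided; a
  one-sided request raises an error rather than silently breaking
  reversibility.

* **State destabilizations.** A free-energy penalty dG on every state
  satisfying a condition (here: proton site and Zn²⁺ activating site both
  occupied, dG = +6 kcal/mol), implementing competition of two ligands
  for one physical site. The penalty must be partitioned onto rates; we
  default to the **exit-only convention** (partition coefficient α = 1):
  transition-state energies are left untouched, so every transition
  *leaving* the destabilized set is multiplied by exp(+dG/RT)
  (≈ 2.47×10⁴ for 6 kcal/mol), entries and transitions inside the set are
  unmodified. Any α ∈ [0, 1] (exit ×exp(+α·dG/RT), entry
  ×exp(−(1−α)·dG/RT)) preserves detailed balance and the equilibrium; α
  only redistributes the kinetic burden, and `ChannelModel.with_partition`
  exists for exactly that sensitivity check. Exit-only was chosen because
  it expresses pure competitive destabilization and leaves pore kinetics
  untouched.

Free-parameter accounting counts two intrinsic rates per element, each
stated (non-derived, nonzero) coupling energy, and each destabilization:
8 + 5 + 1 = 14 for the built-in preset.

Thermal energy defaults to RT = 0.593 kcal/mol (room temperature, 298 K);
proton activity is taken as [H⁺] = 10^(−pH) exactly, with no activity
corrections. Units are fixed globally — s, M, kcal/mol, mV, pS, pA — and
converted only at the I/O boundary (e.g. `zn_mM` in protocol files).

## Equilibria and consistency checks

The equilibrium distribution is computed by two independent routes that
are required to agree to 1e−9: (a) Boltzmann weights from explicit state
free energies (per-element −RT·ln(k_on[L]/k_off) terms, one equilibrium
coupling energy per interacting pair, destabilization penalties) and
(b) the null vector of Qᵀ. Zero ligand concentration is allowed: the
affected bound states get zero weight and the solver warns about the
reduced support instead of failing.

`verify_cycles` measures the maximum relative detailed-balance flux
imbalance max|πᵢQᵢⱼ − πⱼQⱼᵢ|/max(πᵢQᵢⱼ, πⱼQⱼᵢ). The equilibrium candidate
for this check comes from exact edge-rate path products along a spanning
tree of the hypercube (the Kolmogorov-criterion route): when detailed
balance holds this is exact to machine precision, and when a single edge
is perturbed the imbalance appears at order of the perturbation. The
eigenvector route is used as a fallback when an edge rate is zero; its
own accuracy (~1e−9 for generators spanning ten orders of magnitude in
rate) is why it is not the primary candidate here.

## Protocol simulation

Protocols are sequences of epochs (duration, pH, [Zn²⁺], driving force).
Within an epoch Q is constant and the row vector advances by cached
matrix exponentials, p(t+Δ) = p(t)·expm(QΔ); scipy's scaling-and-squaring
expm is accurate far below the 1e−8 contract, which the tests enforce
against an independent spectral-decomposition oracle and the two-state
closed form. Epochs chain by propagating the exact epoch duration;
solution exchange is instantaneous by default (`with_exchange_tau`
discretizes an exponential exchange when realism is wanted; its time
constant defaults to 0). The initial state defaults to equilibrium at the
first epoch's conditions, since cells rest in the first solution before
recording.

Driving forces are per-epoch; the two values known from ramp experiments
(0 mV at pH 7.4, −80 mV at pH 5.5) are filled automatically and **any
other pH requires an explicit driving force** — there is deliberately no
interpolation. Output is sampled on a uniform grid (default 1 ms);
propagation accuracy is independent of the grid. Desensitization, ion
accumulation, rundown and series-resistance artifacts are not modeled:
the simulated potentiated current decays only by Zn²⁺ unbinding.

## Stochastic oracle

Because channels are independent and identical, the ensemble occupancy is
itself a Markov jump process on per-state counts with propensities
count[s]·Q[s,t]. `gillespie_protocol` simulates that aggregated process
with exact exponential waiting times (statistically identical to
per-channel simulation), discarding the pending waiting time at each
epoch boundary — exact by memorylessness. One named generator per
simulation; the seed is recorded in the output. The running propensity
sum is re-accumulated every 4096 events to stop float drift. Counts are
compared to the deterministic propagator within binomial standard errors
in the tests, and time averages of long stationary runs are compared to
the equilibrium distribution using batch-means standard errors (plain
binomial SEs would ignore temporal autocorrelation).

## Trace metrics

Peaks are global extrema of inward (negative) current inside an analysis
window, earliest sample on ties; an optional moving-average pre-filter
(50 ms in the noisy pipelines, disabled for noiseless model output) makes
peak picking robust to recording noise. Latency to peak is scored as the
cap (default 8 s) when the extremum sits on the window edge with the
current still growing. Fractional inhibition uses 50 ms local averages
around the two measurement times. The Hill fit uses the remaining-
fraction form f = 1/(1+([Zn]/IC₅₀)ⁿ) with floor 0 and ceiling 1 fixed,
solved by Levenberg–Marquardt in log-parameter space (positivity by
construction) from a neutral initial guess (IC₅₀ at the geometric mean of
the tested concentrations, n = 1); on noiseless monotone data the round
trip is exact to better than 1e−6 relative across IC₅₀ ∈ [10 µM, 10 mM]
and n ∈ [0.5, 3].

## Synthetic recordings

The generator emulates the acquisition conditions of the experiments:
many-channel scaling (default 5000 channels of 1 pS), 5 kHz sampling, and
Gaussian recording noise shaped by a 4-pole digital Bessel low-pass at
1 kHz (the hardware anti-alias filter's realization is not specified
anywhere authoritative; a causal Bessel is the conventional choice and
the cutoff is configurable). Channel current comes either from the
deterministic mean (no channel noise) or from a Gillespie ensemble
(binomial channel noise). Dose–response datasets add truncated Gaussian
noise so fractions stay in [0, 1]. What the generator does *not*
reproduce — seal leak drift, capacitive transients, desensitization,
liquid-junction offsets — bounds what passing tests show: the pipeline is
validated against the model's own statistical structure, not against all
failure modes of real recordings. An optional linear leak term exists
purely for robustness testing.

The experiment battery writes control + Zn-variant traces for the three
protocol families (block/rebound; pre-exposure at 0.3/1/3 mM × 1–64 s;
wash-off at 1–32 s after 1 mM/16 s exposure) with a manifest pairing each
variant to its control and recording seeds and parameters; files are
byte-identical across runs with the same seed.

## Problem sizes used in the tests

The default verification suite runs the deterministic protocols at 2–5 ms
output intervals (propagation accuracy does not depend on this), uses
5000 channels for the headline ensemble-vs-propagator comparison and
150–2000 channels for the remaining stochastic properties, and generates
test batteries at 500–1000 Hz sampling with three-point grids per axis.
These sizes were chosen to probe each property well past its noise floor;
the full-resolution study conditions (5 kHz, 64 s exposures) remain the
library defaults.

## Known limitations

* Rates are voltage-independent; only the driving force enters the
  current. Voltage protocols (ramps, steps) are out of scope.
* Elements have exactly two configurations; multi-state gates are not
  representable.
* Model parameters are taken as given — there is deliberately no fitting
  machinery, matching how the parameter set was originally obtained
  (manual adjustment, not optimization).
* The peak conducting probability after the strongest pre-exposure
  (3 mM/16 s) is ≈0.53 in this parameterization; the ~0.9 open
  probability sometimes assumed when scaling experimental data is a
  convention, not a model output, so the suite reports rather than
  enforces proximity to it.
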