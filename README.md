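# otopkin

Kinetic modeling of Zn²⁺ potentiation and block of OTOP proton channels.

OTOP (otopetrin) channels are proton-selective ion channels; the murine
OTOP3 channel is gated by extracellular acid and, strikingly, by Zn²⁺,
which both *blocks* the current while present and *potentiates* it — up to
ten-fold — after it is removed. `otopkin` implements a coupled
binary-element Markov model of this behavior, together with everything
needed to exercise it end to end without experimental data: Q-matrix
simulation of solution-exchange protocols, an exact stochastic
single-channel ensemble, the trace quantifications used for whole-cell
recordings (fold potentiation, latency to peak, fractional inhibition,
Hill dose–response fits), and a synthetic patch-clamp recording generator.

It is intended for ion-channel biophysicists who want to explore, extend
or refit this class of allosteric gating model, and as a worked example of
building thermodynamically consistent multi-site gating schemes.

## The model

The channel is a set of *binary elements*: a pore gate (closed/open,
intrinsic rates k_o = 0.02 s⁻¹, k_c = 25 s⁻¹), a proton activating site
(k_on = 5×10⁴ M⁻¹s⁻¹, k_off = 1 s⁻¹), a Zn²⁺ activating site
(35 M⁻¹s⁻¹, 1 s⁻¹) and an independent fast Zn²⁺ blocking site
(5×10⁴ M⁻¹s⁻¹, 20 s⁻¹) that abolishes current when occupied. Elements
interact through state-dependent changes ΔΔG‡ of each other's transition
barriers, each multiplying a rate by exp(−ΔΔG‡/RT) with RT = 0.593
kcal/mol: proton binding lowers the pore-opening barrier by 4 kcal/mol,
Zn²⁺ binding at the activating site lowers opening by 3 and raises closing
by 3, and the open pore reciprocally stabilizes both bound ligands (the
reciprocal barrier changes +3 and +1 kcal/mol are derived from
thermodynamic-cycle closure). States with both activating sites occupied
are destabilized by +6 kcal/mol, implementing H⁺/Zn²⁺ competition for a
shared site — 14 free parameters in all. The 2⁴ = 16 configuration states
form a hypercube whose generator matrix Q is built per solution condition;
probabilities evolve as dp/dt = pQ and per-channel current is
γ·(V−E_rev)·P(open ∧ unblocked) with γ = 1 pS, −80 mV at pH 5.5 and 0 mV
at pH 7.4.

## Worked example

```python
from otopkin import (block_rebound_protocol, current_trace,
                     otop3_zn_model, run_protocol)

model = otop3_zn_model()
protocol = block_rebound_protocol(zn_molar=1e-3, sample_interval_s=2e-3)
result = run_protocol(model, protocol)
current = current_trace(result, conductance_pS=1.0, n_channels=5000)

t = result.time_s
zn_on, zn_off = protocol.marks["zn_on_s"], protocol.marks["zn_off_s"]
print(result.p_conducting[(t > zn_on - 0.5) & (t < zn_on)].max())  # 0.0853
print(result.p_conducting[t > zn_off].max())                       # 0.3492
print(current.min())                                               # -139.67
```

Applying 1 mM Zn²⁺ during a sustained pH 5.5 stimulus drops the conducting
probability (the blocking site equilibrates at 5/7 ≈ 0.714 occupancy)
while the activating site quietly loads; on washout the block clears in
tens of milliseconds but the activation persists for seconds, so the
conducting probability rebounds from a 0.085 plateau to a 0.349 peak —
a four-fold rebound, ≈140 pA inward for 5000 one-pS channels at −80 mV.

The `examples/` directory holds one short script per capability
(equilibria, rebound, pre-exposure grids, stochastic-vs-deterministic
cross-checks, Hill fitting, synthetic batteries), each printing the
numbers it computes and what they mean. A thin CLI (`otopkin simulate`,
`gillespie`, `metrics`, `hillfit`, `synth`) exposes the same pipeline for
shell use.

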