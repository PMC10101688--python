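"""Single-channel ensemble simulation versus the mean-field propagator.

Runs an exact Gillespie simulation of 2000 independent channels through a
Zn2+ pre-exposure protocol and compares the conducting fraction with the
deterministic Q-matrix solution at evenly spaced checkpoints.  Agreement
within a few binomial standard errors validates both routes against each
other.
"""

import numpy as np

from otopkin import gillespie_protocol, otop3_zn_model, pre_exposure_protocol, run_protocol

model = otop3_zn_model()
protocol = pre_exposure_protocol(1e-3, 8.0, sample_interval_s=0.02)
n = 2000

occ = gillespie_protocol(model, protocol, n_channels=n, seed=7)
det = run_protocol(model, protocol)

idx = np.linspace(0, occ.time_s.size - 1, 10).astype(int)
print(f"{'t (s)':>7} {'ensemble':>9} {'mean-field':>11} {'z-score':>8}")
for i in idx:
    p = det.p_conducting[i]
    f = occ.conducting_fraction[i]
    se = max(np.sqrt(p * (1 - p) / n), 1e-12)
    print(f"{occ.time_s[i]:>7.2f} {f:>9.4f} {p:>11.4f} {(f - p) / se:>8.2f}")
print(
    "\n|z| values of order 1 show the stochastic ensemble fluctuating\n"
    "around the deterministic solution at the expected 1/sqrt(n) scale."
)
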