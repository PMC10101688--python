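"""Dose and time dependence of Zn2+ pre-exposure potentiation.

Zn2+ applied at pH 7.4 (where the channel is shut and carries no current)
loads the activating site; the subsequent pH 5.5 stimulus then evokes a
larger, faster current.  This script tabulates fold potentiation (peak
current relative to the paired no-Zn control) and latency to peak over a
concentration x exposure-duration grid.
"""

from otopkin import otop3_zn_model, timecourse_table

model = otop3_zn_model()
table = timecourse_table(
    model,
    mode="pre_exposure",
    durations_s=(1.0, 4.0, 16.0),
    concentrations_molar=(0.3e-3, 1e-3, 3e-3),
    sample_interval_s=2e-3,
)
table["zn_mM"] = table.zn_molar * 1e3
print(table[["duration_s", "zn_mM", "fold_potentiation", "time_to_peak_s"]]
      .to_string(index=False, float_format=lambda x: f"{x:.3f}"))
print(
    "\nFold potentiation grows with both [Zn2+] and exposure duration;\n"
    "a latency of 8.000 s means the current was still rising at the cap\n"
    "(slow proton-driven activation), while potentiated channels peak\n"
    "within the first seconds of the stimulus."
)
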