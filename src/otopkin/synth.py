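"""Synthetic whole-cell recordings and dose-response datasets.

Emulates the statistical structure of the patch-clamp experiments so the
metrics pipeline is fully testable without experimental data: many-channel
current scaling, 5 kHz sampling, low-pass-filtered Gaussian recording
noise (the acquisition chain's 1 kHz hardware filter is approximated by a
4-pole digital Bessel low-pass applied to the noise), optional finite
solution-exchange time constant, and Hill-shaped dose-response tables with
truncated Gaussian noise.

Not emulated: series-resistance and capacitance artifacts, leak drift and
rundown (an optional linear leak exists for robustness testing only),
liquid-junction potentials, desensitization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import bessel, lfilter
from scipy.stats import truncnorm

from .errors import ConfigurationError, InvalidParameterError
from .metrics import Trace, hill_remaining_fraction
from .model import ChannelModel
from .protocol import (
    Protocol,
    block_rebound_protocol,
    current_trace,
    pre_exposure_protocol,
    run_protocol,
    wash_off_protocol,
    with_exchange_tau,
)
from .stochastic import gillespie_protocol, occupancy_to_current


@dataclass(frozen=True)
class SynthConfig:
    """Recording-emulation parameters.

    Defaults reproduce the acquisition conditions of the experiments:
    5 kHz sampling, 1 kHz low-pass, several thousand channels per cell.
    ``mode`` selects the channel-current source: ``"deterministic"`` scales
    the mean-field conducting probability by ``n_channels`` (no channel
    noise), ``"stochastic"`` draws an exact Gillespie ensemble.
    """

    n_channels: int = 5000
    noise_sigma_pA: float = 1.0
    sampling_hz: float = 5000.0
    lowpass_hz: float = 1000.0
    exchange_tau_s: float = 0.0
    seed: int = 0
    mode: str = "deterministic"
    conductance_pS: float = 1.0
    leak_pA_per_s: float = 0.0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise InvalidParameterError("n_channels must be >= 1")
        if self.noise_sigma_pA < 0:
            raise InvalidParameterError("noise sigma must be >= 0")
        if not 0 < self.lowpass_hz < self.sampling_hz / 2:
            raise ConfigurationError(
                "low-pass cutoff must lie below the Nyquist frequency"
            )
        if self.mode not in ("deterministic", "stochastic"):
            raise ConfigurationError("mode must be 'deterministic' or 'stochastic'")


def _filtered_noise(
    n: int, sigma: float, sampling_hz: float, cutoff_hz: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gaussian noise of standard deviation ``sigma`` before filtering,
    shaped by a 4-pole Bessel low-pass (zero-phase not required: the
    hardware filter is causal too)."""
    white = rng.normal(0.0, sigma, size=n)
    if sigma == 0:
        return white
    b, a = bessel(4, cutoff_hz, btype="low", fs=sampling_hz)
    return lfilter(b, a, white)


def generate_trace(
    model: ChannelModel, protocol: Protocol, config: SynthConfig
) -> Trace:
    """One synthetic recording of a protocol.

    The protocol is resampled at the recording rate; channel current comes
    from the deterministic mean (times ``n_channels``) or a Gillespie
    ensemble according to ``config.mode``, and filtered recording noise is
    added on top.  Epoch annotations and generation parameters are carried
    in the trace for the metrics stage.  Seeded and reproducible.
    """
    proto = replace(protocol, sample_interval_s=1.0 / config.sampling_hz)
    proto = with_exchange_tau(proto, config.exchange_tau_s)
    rng = np.random.default_rng(config.seed)
    if config.mode == "deterministic":
        result = run_protocol(model, proto)
        mean = current_trace(result, config.conductance_pS, config.n_channels)
    else:
        occ = gillespie_protocol(
            model, proto, config.n_channels,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        mean = occupancy_to_current(occ, config.conductance_pS)
    noise = _filtered_noise(
        mean.size, config.noise_sigma_pA, config.sampling_hz,
        config.lowpass_hz, rng,
    )
    current = mean + noise
    if config.leak_pA_per_s:
        current = current + config.leak_pA_per_s * np.arange(mean.size) / config.sampling_hz
    annotations = dict(protocol.marks)
    annotations.update(
        {
            "seed": config.seed,
            "noise_sigma_pA": config.noise_sigma_pA,
            "n_channels": config.n_channels,
            "mode": config.mode,
            "epochs": [
                {
                    "duration_s": e.duration_s,
                    "pH": e.pH,
                    "zn_molar": e.zn_molar,
                    "driving_mV": e.resolved_driving(),
                }
                for e in protocol.epochs
            ],
        }
    )
    return Trace(config.sampling_hz, current, annotations)


def generate_dose_response(
    ic50_molar: float,
    hill_n: float,
    concentrations_molar,
    sigma: float = 0.0,
    replicates: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Remaining-current fractions from the Hill inhibition curve plus
    Gaussian noise truncated to [0, 1]; tidy table with one row per
    (concentration, replicate)."""
    if not (ic50_molar > 0 and hill_n > 0):
        raise InvalidParameterError("IC50 and Hill coefficient must be positive")
    conc = np.asarray(concentrations_molar, dtype=float)
    rng = np.random.default_rng(seed)
    truth = hill_remaining_fraction(conc, ic50_molar, hill_n)
    rows = []
    for rep in range(replicates):
        if sigma > 0:
            a = (0.0 - truth) / sigma
            b = (1.0 - truth) / sigma
            values = truncnorm.rvs(a, b, loc=truth, scale=sigma, random_state=rng)
        else:
            values = truth
        for c, f in zip(conc, values):
            rows.append(
                {"concentration_M": c, "replicate": rep, "remaining_fraction": f}
            )
    return pd.DataFrame(rows)


@dataclass
class BatteryEntry:
    """One generated fixture: protocol family, parameters and file names."""

    name: str
    family: str
    zn_molar: float
    duration_s: float
    control: str | None
    trace_path: str
    params: dict = field(default_factory=dict)


def generate_experiment_battery(
    model: ChannelModel,
    out_dir,
    seed: int = 0,
    config: SynthConfig | None = None,
    *,
    pre_exposure_durations_s=(1.0, 4.0, 16.0, 64.0),
    pre_exposure_zn_molar=(0.3e-3, 1e-3, 3e-3),
    wash_off_durations_s=(1.0, 8.0, 32.0),
) -> dict:
    """Generate the full synthetic-experiment battery into ``out_dir``.

    Emits control + Zn-variant trace files for the block/rebound design,
    the pre-exposure concentration x duration grid, and the wash-off grid,
    plus a JSON-serializable manifest pairing each variant with its no-Zn
    control and recording its generating parameters and seed.  Byte-stable
    across runs with the same seed.
    """
    from .io import write_trace  # local import to avoid a cycle

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = config or SynthConfig()
    rng = np.random.default_rng(seed)
    entries: list[BatteryEntry] = []

    def emit(name, family, protocol, zn, duration, control):
        cfg = replace(base, seed=int(rng.integers(0, 2**31 - 1)))
        trace = generate_trace(model, protocol, cfg)
        path = out / f"{name}.csv"
        write_trace(trace, path)
        entries.append(
            BatteryEntry(
                name=name,
                family=family,
                zn_molar=zn,
                duration_s=duration,
                control=control,
                trace_path=path.name,
                params={"seed": cfg.seed, "mode": cfg.mode,
                        "n_channels": cfg.n_channels,
                        "noise_sigma_pA": cfg.noise_sigma_pA},
            )
        )

    dt = 1.0 / base.sampling_hz
    # block / rebound: Zn applied during a sustained acid stimulus
    emit("rebound_control", "rebound",
         block_rebound_protocol(zn_molar=0.0, sample_interval_s=dt),
         0.0, 0.0, None)
    emit("rebound_zn1mM", "rebound",
         block_rebound_protocol(zn_molar=1e-3, sample_interval_s=dt),
         1e-3, 0.0, "rebound_control")
    # pre-exposure grid with one control per exposure duration
    for dur in pre_exposure_durations_s:
        ctrl_name = f"preexp_control_{dur:g}s"
        emit(ctrl_name, "pre_exposure",
             pre_exposure_protocol(0.0, dur, sample_interval_s=dt),
             0.0, dur, None)
        for zn in pre_exposure_zn_molar:
            emit(f"preexp_zn{zn * 1e3:g}mM_{dur:g}s", "pre_exposure",
                 pre_exposure_protocol(zn, dur, sample_interval_s=dt),
                 zn, dur, ctrl_name)
    # wash-off grid, fixed 1 mM / 16 s exposure
    for wash in wash_off_durations_s:
        ctrl_name = f"wash_control_{wash:g}s"
        emit(ctrl_name, "wash_off",
             wash_off_protocol(wash, zn_molar=0.0, sample_interval_s=dt),
             0.0, wash, None)
        emit(f"wash_zn1mM_{wash:g}s", "wash_off",
             wash_off_protocol(wash, zn_molar=1e-3, sample_interval_s=dt),
             1e-3, wash, ctrl_name)

    manifest = {
        "seed": seed,
        "config": {
            "n_channels": base.n_channels,
            "noise_sigma_pA": base.noise_sigma_pA,
            "sampling_hz": base.sampling_hz,
            "lowpass_hz": base.lowpass_hz,
            "mode": base.mode,
            "conductance_pS": base.conductance_pS,
        },
        "entries": [vars(e) for e in entries],
    }
    import json

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
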