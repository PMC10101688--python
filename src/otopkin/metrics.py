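"""Quantification of current traces.

Implements the measures used to summarize whole-cell recordings: peak
inward current, fold potentiation relative to a paired control, latency to
peak with a scoring cap, fractional inhibition during blocker application,
Hill dose-response fits, and model time-course tables over pre-exposure /
wash-off grids.

Sign convention: inward current is negative; "peak" always refers to the
most negative excursion and its magnitude is reported as a positive pA
value.  Tie-break everywhere: the earliest extremum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import DataError, FitError, InvalidParameterError
from .model import ChannelModel
from .protocol import (
    Protocol,
    current_trace,
    pre_exposure_protocol,
    run_protocol,
    wash_off_protocol,
)


@dataclass
class Trace:
    """A sampled current recording.

    ``annotations`` carries protocol landmarks in seconds from the first
    sample (keys used here: ``stimulus_onset_s``, ``zn_on_s``, ``zn_off_s``)
    plus free-form provenance (seed, noise sigma, generating parameters).
    """

    sampling_hz: float
    current_pA: np.ndarray
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.current_pA = np.asarray(self.current_pA, dtype=float)
        if self.sampling_hz <= 0:
            raise DataError("sampling rate must be positive")
        if self.current_pA.size < 2:
            raise DataError("a trace needs at least two samples")
        if not np.all(np.isfinite(self.current_pA)):
            raise DataError("trace contains non-finite samples")

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.current_pA.size) / self.sampling_hz

    @property
    def duration_s(self) -> float:
        return (self.current_pA.size - 1) / self.sampling_hz


def _smooth(values: np.ndarray, sampling_hz: float, smooth_s: float) -> np.ndarray:
    if smooth_s <= 0:
        return values
    n = max(1, int(round(smooth_s * sampling_hz)))
    if n == 1:
        return values
    kernel = np.ones(n) / n
    # reflect-pad so the running mean is unbiased at the edges
    padded = np.concatenate([values[n - 1:0:-1], values, values[-2:-n - 1:-1]])
    sm = np.convolve(padded, kernel, mode="same")
    return sm[n - 1: n - 1 + values.size]


def _window_slice(trace: Trace, window: tuple[float, float]) -> slice:
    t0, t1 = window
    if t1 <= t0:
        raise DataError("window must satisfy start < end")
    i0 = int(np.ceil(t0 * trace.sampling_hz - 1e-9))
    i1 = int(np.floor(t1 * trace.sampling_hz + 1e-9)) + 1
    i0 = max(i0, 0)
    i1 = min(i1, trace.current_pA.size)
    if i1 - i0 < 1:
        raise DataError("analysis window contains no samples")
    return slice(i0, i1)


def peak_inward(
    trace: Trace,
    window: tuple[float, float] | None = None,
    smooth_s: float = 0.0,
) -> tuple[float, float]:
    """Magnitude (pA, positive) and time (s) of the most negative current
    in the window; earliest sample on ties.  ``smooth_s`` applies a moving
    average before peak picking (useful for noisy traces; leave 0 for
    noiseless model output)."""
    if window is None:
        window = (0.0, trace.duration_s)
    sl = _window_slice(trace, window)
    values = _smooth(trace.current_pA, trace.sampling_hz, smooth_s)[sl]
    k = int(np.argmin(values))  # argmin returns the first minimum on ties
    t = (sl.start + k) / trace.sampling_hz
    return float(-values[k]), float(t)


def fold_potentiation(
    test: Trace,
    control: Trace,
    window: tuple[float, float] | None = None,
    smooth_s: float = 0.0,
) -> float:
    """Ratio of the test trace's peak inward current to the paired
    control's, over the same analysis window."""
    peak_test, _ = peak_inward(test, window, smooth_s)
    peak_ctrl, _ = peak_inward(control, window, smooth_s)
    if peak_ctrl == 0:
        raise DataError("control peak is zero; fold potentiation undefined")
    return peak_test / peak_ctrl


def time_to_peak(
    trace: Trace,
    onset_s: float,
    cap_s: float = 8.0,
    smooth_s: float = 0.0,
) -> float:
    """Latency from stimulus onset to the earliest peak of the inward
    current, scored as ``cap_s`` when no peak is reached within the cap
    (current still growing at the cap)."""
    if onset_s > trace.duration_s:
        raise DataError("stimulus onset lies after the end of the trace")
    end = min(onset_s + cap_s, trace.duration_s)
    sl = _window_slice(trace, (onset_s, end))
    values = _smooth(trace.current_pA, trace.sampling_hz, smooth_s)[sl]
    k = int(np.argmin(values))
    latency = (sl.start + k) / trace.sampling_hz - onset_s
    if k == values.size - 1 and latency > 0:
        # extremum sits on the window edge: the peak was not attained
        return cap_s
    return min(latency, cap_s)


def fractional_inhibition(
    trace: Trace,
    t_before: float,
    t_during: float,
    avg_s: float = 0.05,
) -> float:
    """``1 - I(t_during) / I(t_before)`` with each current taken as a short
    local average (default 50 ms) centred on the requested time."""
    if t_during <= t_before:
        raise DataError("t_during must follow t_before")

    def local_mean(t: float) -> float:
        sl = _window_slice(trace, (t - avg_s / 2, t + avg_s / 2))
        return float(trace.current_pA[sl].mean())

    i_before = local_mean(t_before)
    if i_before == 0:
        raise DataError("current before blocker application is zero")
    return 1.0 - local_mean(t_during) / i_before


@dataclass(frozen=True)
class HillFit:
    """Result of a Hill dose-inhibition fit:
    ``f([Zn]) = 1 / (1 + ([Zn]/IC50)**n)``."""

    ic50_molar: float
    hill_n: float
    residual_norm: float

    def __post_init__(self) -> None:
        if not (self.ic50_molar > 0 and self.hill_n > 0):
            raise FitError("Hill fit returned non-positive parameters")


def hill_remaining_fraction(conc_molar, ic50_molar: float, hill_n: float):
    """Remaining-current fraction of the Hill inhibition curve."""
    conc = np.asarray(conc_molar, dtype=float)
    return 1.0 / (1.0 + (conc / ic50_molar) ** hill_n)


def hill_fit(concentrations_molar, remaining_fraction) -> HillFit:
    """Least-squares Hill fit of remaining current vs blocker concentration.

    Fits in log-parameter space (guaranteeing positivity) from a neutral
    initial guess: IC50 at the geometric mean of the tested concentrations
    and a Hill coefficient of 1.  Floor and ceiling are fixed at 0 and 1
    (inhibition saturating at complete block).
    """
    conc = np.asarray(concentrations_molar, dtype=float)
    frac = np.asarray(remaining_fraction, dtype=float)
    if conc.size < 3:
        raise DataError("Hill fit needs at least three concentrations")
    if np.any(conc <= 0):
        raise DataError("concentrations must be positive")
    if np.any((frac < -1e-9) | (frac > 1 + 1e-9)):
        raise DataError("remaining fractions must lie in [0, 1]")

    def residuals(theta):
        ic50, n = np.exp(theta)
        return hill_remaining_fraction(conc, ic50, n) - frac

    x0 = np.array([np.mean(np.log(conc)), 0.0])
    sol = least_squares(
        residuals, x0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15
    )
    if not sol.success:
        raise FitError(f"Hill fit did not converge: {sol.message}")
    ic50, n = np.exp(sol.x)
    return HillFit(float(ic50), float(n), float(np.linalg.norm(sol.fun)))


def timecourse_table(
    model: ChannelModel,
    *,
    mode: str = "pre_exposure",
    durations_s=(1.0, 4.0, 16.0),
    concentrations_molar=(0.3e-3, 1e-3, 3e-3),
    stim_s: float = 8.0,
    cap_s: float = 8.0,
    sample_interval_s: float = 1e-3,
    conductance_pS: float = 1.0,
    n_channels: int = 1,
) -> pd.DataFrame:
    """Deterministic model summaries over a pre-exposure or wash-off grid.

    One simulation per (duration, concentration) cell plus the shared no-Zn
    control; returns a tidy table with columns ``duration_s``, ``zn_molar``,
    ``fold_potentiation`` and ``time_to_peak_s``, the model's counterpart of
    the experimental dose/duration time-course summaries.
    """
    if mode not in ("pre_exposure", "wash_off"):
        raise InvalidParameterError("mode must be 'pre_exposure' or 'wash_off'")

    def build(duration: float, zn: float) -> Protocol:
        if mode == "pre_exposure":
            return pre_exposure_protocol(
                zn, duration, stim_s=stim_s, sample_interval_s=sample_interval_s
            )
        return wash_off_protocol(
            duration, zn_molar=zn, stim_s=stim_s,
            sample_interval_s=sample_interval_s,
        )

    def simulate(protocol: Protocol) -> Trace:
        result = run_protocol(model, protocol)
        current = current_trace(result, conductance_pS, n_channels)
        return Trace(
            1.0 / sample_interval_s, current, dict(protocol.marks)
        )

    rows = []
    control_cache: dict[float, Trace] = {}
    for duration in durations_s:
        for zn in concentrations_molar:
            test = simulate(build(duration, zn))
            onset = test.annotations["stimulus_onset_s"]
            window = (onset, onset + stim_s)
            # control shares the protocol timing but carries no Zn
            key = round(onset, 12)
            ctrl = control_cache.get(key)
            if ctrl is None:
                ctrl = simulate(build(duration, 0.0))
                control_cache[key] = ctrl
            rows.append(
                {
                    "duration_s": duration,
                    "zn_molar": zn,
                    "fold_potentiation": fold_potentiation(test, ctrl, window),
                    "time_to_peak_s": time_to_peak(test, onset, cap_s),
                }
            )
    return pd.DataFrame(rows)
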