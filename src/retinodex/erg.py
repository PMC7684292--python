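"""Flash-ERG waveform quantification.

The scotopic flash ERG is a biphasic corneal potential: an initial
negative a-wave (photoreceptor response) followed by a positive b-wave
(bipolar / Muller glial response).  Amplitudes follow the ISCEV
conventions — a-wave from the pre-flash baseline to the trough, b-wave
from the trough to the subsequent peak — and the 30 Hz flicker response is
the peak-to-trough of the cycle-averaged trace.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import signal as _signal

from .errors import InputError

#: ISCEV-style search windows (ms after the flash)
A_WAVE_WINDOW_MS = (0.0, 50.0)
B_WAVE_MAX_MS = 150.0
BASELINE_MS = 20.0


@dataclass
class ERGTrace:
    """Uniformly sampled time-voltage waveform, flash at t = 0."""

    time_ms: np.ndarray
    voltage_uv: np.ndarray
    flash_intensity: float
    protocol: Literal["scotopic_series", "iscev_flash", "flicker_30hz"] = \
        "scotopic_series"

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.voltage_uv = np.asarray(self.voltage_uv, dtype=float)
        if self.time_ms.shape != self.voltage_uv.shape or self.time_ms.ndim != 1:
            raise InputError("time and voltage must be matching 1D arrays")
        dt = np.diff(self.time_ms)
        if dt.size == 0 or np.any(dt <= 0) or not np.allclose(dt, dt[0]):
            raise InputError("time must be strictly increasing and uniform")
        if self.time_ms[0] > -BASELINE_MS:
            raise InputError(
                f"trace must include >= {BASELINE_MS:.0f} ms pre-flash baseline")

    @property
    def sampling_rate_hz(self) -> float:
        return 1000.0 / float(self.time_ms[1] - self.time_ms[0])


@dataclass
class ERGAmplitudes:
    """Baseline-referenced amplitudes (uV) and implicit times (ms)."""

    a_amp_uv: float
    b_amp_uv: float
    a_time_ms: float | None
    b_time_ms: float | None
    baseline_uv: float


@dataclass
class IntensitySeries:
    """Per-flash-intensity amplitudes, intensities strictly increasing."""

    intensities: np.ndarray
    amplitudes: list[ERGAmplitudes]
    group: str = ""

    def a_amps(self) -> np.ndarray:
        return np.array([a.a_amp_uv for a in self.amplitudes])

    def b_amps(self) -> np.ndarray:
        return np.array([a.b_amp_uv for a in self.amplitudes])


def measure_amplitudes(t: ERGTrace, *, smooth_ms: float = 1.5) -> ERGAmplitudes:
    """ISCEV-convention a/b amplitudes and implicit times of one trace.

    Baseline is the mean over [-20, 0) ms.  The a-wave is the deflection
    from baseline to the minimum in (0, 50] ms, clamped to 0 unless it
    exceeds twice the baseline noise SD (so a pure positive lobe reports
    a_amp 0 with the trough taken at baseline).  The b-wave is the maximum
    in (trough, 150] ms minus the trough voltage.  Adding any constant
    offset to the trace leaves both amplitudes unchanged.

    Before the extrema are located the trace is band-limited by a
    ``smooth_ms`` moving average (clinical ERG amplifiers low-pass around
    300 Hz); without it, picking extrema off raw noise biases both
    amplitudes upward.  Set ``smooth_ms=0`` to measure the raw trace.
    """
    time = t.time_ms
    v = t.voltage_uv
    if smooth_ms > 0:
        n = int(round(smooth_ms * t.sampling_rate_hz / 1000.0))
        if n > 1:
            from scipy.ndimage import uniform_filter1d

            v = uniform_filter1d(v, n, mode="nearest")
    base_mask = (time >= -BASELINE_MS) & (time < 0)
    if not base_mask.any():
        raise InputError("no baseline samples in [-20, 0) ms")
    baseline = float(v[base_mask].mean())
    noise_sd = float(v[base_mask].std())

    a_mask = (time > A_WAVE_WINDOW_MS[0]) & (time <= A_WAVE_WINDOW_MS[1])
    if not a_mask.any():
        raise InputError("no post-flash samples")
    a_idx = np.flatnonzero(a_mask)[np.argmin(v[a_mask])]
    deflection = baseline - float(v[a_idx])
    if deflection > 2.0 * noise_sd and deflection > 0:
        a_amp = deflection
        a_time = float(time[a_idx])
        trough_v = float(v[a_idx])
        b_start = a_time
    else:
        a_amp = 0.0
        a_time = None
        trough_v = baseline
        b_start = 0.0

    b_mask = (time > b_start) & (time <= B_WAVE_MAX_MS)
    if not b_mask.any():
        raise InputError("no samples in the b-wave window")
    b_idx = np.flatnonzero(b_mask)[np.argmax(v[b_mask])]
    b_amp = max(float(v[b_idx]) - trough_v, 0.0)
    b_time = float(time[b_idx]) if b_amp > 0 else None
    return ERGAmplitudes(a_amp_uv=a_amp, b_amp_uv=b_amp, a_time_ms=a_time,
                         b_time_ms=b_time, baseline_uv=baseline)


def build_intensity_series(
    traces: Sequence[ERGTrace], group: str = ""
) -> IntensitySeries:
    """Amplitudes per flash intensity, sorted ascending; duplicates refused."""
    if len(traces) == 0:
        raise InputError("need at least one trace")
    intens = np.array([tr.flash_intensity for tr in traces], dtype=float)
    if np.unique(intens).size != intens.size:
        raise InputError("duplicate flash intensities in series")
    order = np.argsort(intens)
    amps = [measure_amplitudes(traces[i]) for i in order]
    return IntensitySeries(intensities=intens[order], amplitudes=amps,
                           group=group)


def flicker_amplitude(t: ERGTrace, stim_hz: float) -> float:
    """Peak-to-trough of the stimulus-period-folded, cycle-averaged trace.

    The trace is folded into phase bins of one stimulus period and averaged
    across cycles; non-stimulus-locked components average out as the cycle
    count grows.  Requires >= 5 complete cycles.
    """
    if stim_hz <= 0:
        raise InputError("stimulus frequency must be positive")
    period_ms = 1000.0 / stim_hz
    span = float(t.time_ms[-1] - t.time_ms[0])
    n_cycles = int(span / period_ms)
    if n_cycles < 5:
        raise InputError(
            f"trace spans only {n_cycles} stimulus cycles (need >= 5)")
    n_bins = max(int(round(t.sampling_rate_hz / stim_hz)), 4)
    phase = np.mod(t.time_ms - t.time_ms[0], period_ms) / period_ms
    bins = np.minimum((phase * n_bins).astype(int), n_bins - 1)
    folded = np.bincount(bins, weights=t.voltage_uv, minlength=n_bins)
    counts = np.bincount(bins, minlength=n_bins)
    cycle = folded / np.maximum(counts, 1)
    return float(cycle.max() - cycle.min())


def notch_filter(t: ERGTrace, freq_hz: float = 60.0, q: float = 30.0) -> ERGTrace:
    """Opt-in mains-interference notch (off by default; amplifier-level
    filtering is otherwise left untouched)."""
    b, a = _signal.iirnotch(freq_hz, q, fs=t.sampling_rate_hz)
    return ERGTrace(time_ms=t.time_ms,
                    voltage_uv=_signal.filtfilt(b, a, t.voltage_uv),
                    flash_intensity=t.flash_intensity, protocol=t.protocol)
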