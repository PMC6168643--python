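"""In vitro sweep analysis: PSP/PSC amplitudes, onset latency, rise and
decay kinetics, short-term adaptation, excitation/inhibition ratios,
connection detection, and firing-pattern / IPSP-class classification.

Sign convention: all kinetic measures operate on the rectified deflection
from baseline (the sign of the largest deflection defines the response
polarity), so they are invariant to amplitude scaling, baseline offset and
inversion.  Crossing times are obtained by linear interpolation between
samples, which keeps kinetics accurate without pre-smoothing; an optional
moving-average smoother is available for noisy averaged sweeps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .containers import SweepSet

__all__ = [
    "KineticsResult",
    "ConnectionResult",
    "FiringPattern",
    "mean_response",
    "measure_amplitude",
    "onset_latency",
    "rise_and_halfwidth",
    "pulse_amplitudes",
    "adaptation_ratio",
    "ei_ratio",
    "ei_ratio_per_cell",
    "classify_ipsp",
    "detect_connection",
    "classify_firing_pattern",
    "analyze_sweep_set",
]

# boundaries between fast-spiking-like and neurogliaform-like IPSP kinetics:
# midpoints of the two group means (rise 5.6 vs 22.3 ms, half-width 46.3 vs
# 118.6 ms)
RISE_BOUNDARY_MS = (5.6 + 22.3) / 2.0
HALFWIDTH_BOUNDARY_MS = (46.3 + 118.6) / 2.0


@dataclass
class KineticsResult:
    """Kinetic and amplitude measurements of one averaged response."""

    amplitude: Optional[float] = None  # mV or pA, signed
    onset_latency_ms: Optional[float] = None
    rise_10_90_ms: Optional[float] = None
    decay_half_width_ms: Optional[float] = None
    adaptation_ratio: Optional[float] = None
    ei_ratio: Optional[float] = None
    ipsp_class: Optional[str] = None  # 'NPY_like' | 'FS_like' | 'mixed'


@dataclass
class ConnectionResult:
    connected: bool
    unitary_amplitude: float  # mV
    detection_z: float


@dataclass
class FiringPattern:
    peak_rate: float  # spikes/s
    spike_width_ms: float
    adaptation_index: float  # last ISI / first ISI
    late_spiking: bool
    label: str  # 'FS' | 'NGF_like' | 'adapting_other'


# ---------------------------------------------------------------------------
# averaging and amplitudes
# ---------------------------------------------------------------------------

def mean_response(sweeps: SweepSet,
                  baseline_window: Optional[tuple[float, float]] = None) -> np.ndarray:
    """Point-wise sweep average, baseline-subtracted over a pre-pulse window.

    The baseline window defaults to everything before the first pulse.
    """
    m = sweeps.sweeps.mean(axis=0)
    if baseline_window is None:
        if sweeps.pulse_times.size == 0:
            raise ValueError("no pulse times and no explicit baseline window")
        baseline_window = (0.0, float(sweeps.pulse_times[0]))
    lo = int(round(baseline_window[0] * sweeps.fs))
    hi = int(round(baseline_window[1] * sweeps.fs))
    if hi <= lo:
        raise ValueError("empty baseline window")
    return m - m[lo:hi].mean()


def measure_amplitude(mean: np.ndarray, fs: float,
                      window: tuple[float, float]) -> float:
    """Signed extremum relative to baseline within ``window`` (s).

    Expects a baseline-subtracted mean trace (see :func:`mean_response`).
    """
    lo = int(round(window[0] * fs))
    hi = int(round(window[1] * fs))
    if lo < 0 or hi > mean.size or hi <= lo:
        raise ValueError("amplitude window outside the sweep")
    seg = mean[lo:hi]
    return float(seg[np.argmax(np.abs(seg))])


def _interp_crossing(t: np.ndarray, y: np.ndarray, i: int, level: float) -> float:
    """Linear interpolation of the time where y crosses `level` between
    samples i-1 and i."""
    if i == 0 or y[i] == y[i - 1]:
        return float(t[i])
    return float(t[i - 1] + (level - y[i - 1]) * (t[i] - t[i - 1]) / (y[i] - y[i - 1]))


def onset_latency(mean: np.ndarray, fs: float, pulse_time: float,
                  min_amplitude: float = 10.0,
                  window_ms: float = 20.0) -> Optional[float]:
    """Onset latency (ms): start of the 10-90% rise of the mean response.

    Measured from ``pulse_time`` to the 10% point of the rise toward the
    peak inside the first ``window_ms``.  Responses whose amplitude does
    not exceed ``min_amplitude`` (10 pA by default, the inclusion rule for
    latency analysis) return ``None``.  A non-monotonic rise yields the
    earliest qualifying 10% crossing, with a warning.
    """
    i0 = int(round(pulse_time * fs))
    i1 = min(mean.size, i0 + int(round(window_ms / 1000.0 * fs)))
    seg = mean[i0:i1] - mean[i0]
    if seg.size < 3:
        raise ValueError("analysis window outside the sweep")
    pk = int(np.argmax(np.abs(seg)))
    amp = seg[pk]
    if abs(amp) <= min_amplitude:
        return None
    y = seg * np.sign(amp)
    level = 0.1 * abs(amp)
    above = y[:pk + 1] >= level
    idxs = np.flatnonzero(above)
    if idxs.size == 0:
        return None
    i = int(idxs[0])
    # non-monotonic rise: crossings back below 10% after the first one
    if np.any(y[i:pk + 1] < level):
        warnings.warn("non-monotonic rise; using earliest 10% crossing",
                      UserWarning)
    t = np.arange(seg.size) / fs * 1000.0
    return _interp_crossing(t, y, i, level)


def rise_and_halfwidth(mean: np.ndarray, fs: float,
                       window: Optional[tuple[float, float]] = None,
                       smooth_ms: float = 0.0) -> tuple[float, float]:
    """10-90% rise time and 50% decay half-width of a response, in ms.

    Operates on the rectified deflection from baseline, so the result is
    invariant to amplitude scale, baseline offset and sign.  Crossing
    times are linearly interpolated.  ``smooth_ms`` applies a moving
    average before measurement (useful on noisy averages; off by default
    because interpolation alone is sub-sample accurate on clean means).
    Raises when the peak sits at the trace edge (truncated response).
    """
    x = np.asarray(mean, dtype=float)
    if window is not None:
        lo = int(round(window[0] * fs))
        hi = int(round(window[1] * fs))
        x = x[lo:hi]
    if smooth_ms > 0:
        n = max(1, int(round(smooth_ms / 1000.0 * fs)))
        x = np.convolve(x, np.ones(n) / n, mode="same")
    # offset invariance: re-reference to the local pre-response level
    x = x - np.median(x[:max(3, x.size // 50)])
    pk = int(np.argmax(np.abs(x)))
    if pk == 0 or pk == x.size - 1:
        raise ValueError("response peak at trace edge")
    y = x * np.sign(x[pk])
    peak = y[pk]
    t = np.arange(y.size) / fs * 1000.0

    def last_rise_crossing(level: float) -> float:
        below = np.flatnonzero(y[:pk + 1] < level)
        if below.size == 0:
            raise ValueError("rising phase does not span the crossing level")
        i = int(below[-1]) + 1
        return _interp_crossing(t, y, i, level)

    t10 = last_rise_crossing(0.1 * peak)
    t90 = last_rise_crossing(0.9 * peak)
    t50a = last_rise_crossing(0.5 * peak)

    after = np.flatnonzero(y[pk:] < 0.5 * peak)
    if after.size == 0:
        raise ValueError("response does not decay below 50% within the trace")
    j = pk + int(after[0])
    t50b = _interp_crossing(t, y, j, 0.5 * peak)
    return t90 - t10, t50b - t50a


def pulse_amplitudes(mean: np.ndarray, fs: float, pulse_times: np.ndarray,
                     window: Optional[float] = None) -> np.ndarray:
    """Per-pulse response amplitudes along a train, local-baseline corrected.

    For each pulse the amplitude is the extremal deflection within the
    inter-pulse interval minus the trace value at that pulse's onset
    (which removes most of the residual decay of the preceding response).
    ``window`` (s) overrides the measurement span per pulse.
    """
    pulse_times = np.asarray(pulse_times, dtype=float)
    if pulse_times.size == 0:
        raise ValueError("no pulse times")
    if window is None:
        ipis = np.diff(pulse_times)
        window = float(ipis.min()) if ipis.size else (mean.size / fs
                                                      - pulse_times[-1])
    amps = []
    for pt in pulse_times:
        i0 = int(round(pt * fs))
        i1 = min(mean.size, i0 + int(round(window * fs)))
        seg = mean[i0:i1] - mean[i0]
        amps.append(float(seg[np.argmax(np.abs(seg))]))
    return np.asarray(amps)


def adaptation_ratio(amplitudes: Sequence[float]) -> float:
    """Short-term plasticity index of a pulse train: last / first amplitude.

    Values < 1 indicate synaptic depression, > 1 facilitation.
    """
    amps = np.asarray(amplitudes, dtype=float)
    if amps.size < 2:
        raise ValueError("need at least 2 pulse amplitudes")
    if amps[0] == 0:
        raise ValueError("first pulse amplitude is zero")
    return float(amps[-1] / amps[0])


def ei_ratio(epsc: float, ipsc: float) -> float:
    """|EPSC| / |IPSC| for one cell."""
    if ipsc == 0:
        raise ValueError("zero inhibitory current")
    if epsc == 0:
        raise ValueError("zero excitatory current")
    return abs(epsc) / abs(ipsc)


def ei_ratio_per_cell(epscs: Sequence[float], ipscs: Sequence[float]) -> float:
    """Population E/I summary: mean of per-cell ratios.

    Computed per cell first and then averaged; this is not the same number
    as the ratio of the group-mean currents, and the per-cell mean is the
    documented summary.
    """
    ratios = [ei_ratio(e, i) for e, i in zip(epscs, ipscs, strict=True)]
    return float(np.mean(ratios))


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_ipsp(rise_10_90_ms: float, decay_half_width_ms: float,
                  rise_boundary: float = RISE_BOUNDARY_MS,
                  halfwidth_boundary: float = HALFWIDTH_BOUNDARY_MS,
                  ) -> Optional[str]:
    """Classify an IPSP by its kinetics.

    ``FS_like``: fast rise and fast decay (fast-spiking, parvalbumin-type
    GABA_A inhibition).  ``NPY_like``: slow rise and slow decay
    (neurogliaform-type slow inhibition).  ``mixed``: fast rise with slow
    decay, consistent with co-innervation.  A slow rise with a fast decay
    has no physiological reading under this scheme and returns ``None``
    with a warning.  Boundaries default to the midpoints of the two
    empirical group means and are configurable.
    """
    fast_rise = rise_10_90_ms < rise_boundary
    fast_decay = decay_half_width_ms < halfwidth_boundary
    if fast_rise and fast_decay:
        return "FS_like"
    if not fast_rise and not fast_decay:
        return "NPY_like"
    if fast_rise and not fast_decay:
        return "mixed"
    warnings.warn("slow rise with fast decay: unclassifiable IPSP kinetics",
                  UserWarning)
    return None


def detect_connection(sweeps: SweepSet, z_threshold: float = 3.0,
                      response_window: float = 0.1,
                      expected_sign: Optional[int] = None) -> ConnectionResult:
    """Statistical test for a synaptic connection in a paired recording.

    Per trial, the mean deflection in the ``response_window`` (100 ms)
    after the last presynaptic spike of the burst is compared with the
    pre-burst baseline; the decision statistic is the across-trial mean
    of that deflection divided by its standard error.  Connected iff
    |z| > ``z_threshold`` (or a one-sided test when ``expected_sign`` is
    given).  The unitary amplitude is the extremal deflection of the
    averaged response after the first presynaptic spike.
    """
    if sweeps.n_sweeps < 10:
        raise ValueError("need at least 10 trials for connection detection")
    fs = sweeps.fs
    first, last = float(sweeps.pulse_times[0]), float(sweeps.pulse_times[-1])
    b_hi = int(round(first * fs))
    r_lo = int(round(last * fs))
    r_hi = min(sweeps.sweeps.shape[1], r_lo + int(round(response_window * fs)))
    if b_hi < 2 or r_hi - r_lo < 2:
        raise ValueError("baseline or response window too short")
    d = sweeps.sweeps[:, r_lo:r_hi].mean(axis=1) - sweeps.sweeps[:, :b_hi].mean(axis=1)
    sem = d.std(ddof=1) / np.sqrt(d.size)
    z = float(d.mean() / sem) if sem > 0 else 0.0
    if expected_sign is None:
        connected = abs(z) > z_threshold
    else:
        connected = z * np.sign(expected_sign) > z_threshold
    m = mean_response(sweeps)
    amp = measure_amplitude(m, fs, (first, min(sweeps.duration,
                                               last + response_window)))
    return ConnectionResult(connected=bool(connected), unitary_amplitude=amp,
                            detection_z=z)


def _spike_peaks(trace: np.ndarray, fs: float, threshold: float) -> np.ndarray:
    min_dist = max(1, int(round(0.0003 * fs)))
    peaks, _ = signal.find_peaks(trace, height=threshold, distance=min_dist)
    return peaks


def _spike_fwhm(trace: np.ndarray, fs: float, peak: int, baseline: float) -> float:
    half = baseline + 0.5 * (trace[peak] - baseline)
    t = np.arange(trace.size) / fs * 1000.0
    left = np.flatnonzero(trace[:peak + 1] < half)
    right = np.flatnonzero(trace[peak:] < half)
    if left.size == 0 or right.size == 0:
        raise ValueError("spike does not return to half height")
    i = int(left[-1]) + 1
    j = peak + int(right[0])
    return _interp_crossing(t, trace, j, half) - _interp_crossing(t, trace, i, half)


def classify_firing_pattern(supra: np.ndarray, just_supra: np.ndarray, fs: float,
                            step_start: float, step_duration: float,
                            spike_threshold: float = -20.0,
                            rate_threshold: float = 100.0,
                            width_threshold: float = 0.4,
                            weak_adaptation_max: float = 2.0,
                            late_fraction: float = 0.5) -> FiringPattern:
    """Classify a neuron's firing pattern from current-step responses.

    ``supra`` is the response to a clearly supra-threshold step (used for
    peak rate, spike width and the adaptation index = last ISI / first
    ISI); ``just_supra`` the response to a just-past-threshold step (used
    for the late-spiking test: first spike later than ``late_fraction`` of
    the step).  Fast-spiking (FS): peak rate > 100 spikes/s and width
    < 0.4 ms.  Neurogliaform-like (NGF_like): weakly adapting
    (index < 2) and late spiking.  Everything else: ``adapting_other``.
    """
    peaks = _spike_peaks(supra, fs, spike_threshold)
    if peaks.size == 0:
        raise ValueError("no spikes on the supra-threshold step")
    spike_t = peaks / fs
    if peaks.size >= 2:
        isis = np.diff(spike_t)
        peak_rate = float(1.0 / isis.min())
        adaptation_index = float(isis[-1] / isis[0])
    else:
        peak_rate = 1.0 / step_duration
        adaptation_index = 1.0
    base = float(np.median(supra[int(round(step_start * fs)):
                                 int(round((step_start + step_duration) * fs))]))
    width = float(np.mean([_spike_fwhm(supra, fs, p, base) for p in peaks]))

    jp = _spike_peaks(just_supra, fs, spike_threshold)
    if jp.size:
        first_latency = jp[0] / fs - step_start
        late = first_latency > late_fraction * step_duration
    else:
        late = False

    if peak_rate > rate_threshold and width < width_threshold:
        label = "FS"
    elif adaptation_index < weak_adaptation_max and late:
        label = "NGF_like"
    else:
        label = "adapting_other"
    return FiringPattern(peak_rate=peak_rate, spike_width_ms=width,
                         adaptation_index=adaptation_index, late_spiking=bool(late),
                         label=label)


# ---------------------------------------------------------------------------
# per-cell driver
# ---------------------------------------------------------------------------

def analyze_sweep_set(sweeps: SweepSet, min_latency_amplitude: float = 10.0,
                      classify: bool = False,
                      smooth_ms: float = 0.0) -> KineticsResult:
    """Measure amplitude, latency, kinetics and adaptation of one sweep set.

    ``classify=True`` additionally assigns the IPSP kinetic class (for
    current-clamp inhibitory responses).
    """
    m = mean_response(sweeps)
    first = float(sweeps.pulse_times[0])
    res = KineticsResult()
    amps = pulse_amplitudes(m, sweeps.fs, sweeps.pulse_times)
    res.amplitude = float(amps[0])
    res.onset_latency_ms = onset_latency(m, sweeps.fs, first,
                                         min_amplitude=min_latency_amplitude)
    try:
        ipi = (np.diff(sweeps.pulse_times).min()
               if sweeps.pulse_times.size > 1 else sweeps.duration - first)
        # include the pre-pulse baseline so re-referencing sees quiescence
        rise, hw = rise_and_halfwidth(m, sweeps.fs, window=(0.0, first + ipi),
                                      smooth_ms=smooth_ms)
        res.rise_10_90_ms = rise
        res.decay_half_width_ms = hw
    except ValueError:
        pass
    if amps.size >= 2:
        res.adaptation_ratio = adaptation_ratio(amps)
    if classify and res.rise_10_90_ms is not None:
        res.ipsp_class = classify_ipsp(res.rise_10_90_ms, res.decay_half_width_ms)
    return res
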