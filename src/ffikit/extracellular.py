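"""In vivo spike pipeline: filtering, event detection, unit isolation,
cell typing, peri-stimulus time histograms and per-unit response metrics.

The measurement rules implemented here:

* band-pass filtering of the raw trace (0.3-5 kHz analysis band,
  zero-phase Butterworth)
* amplitude-threshold event detection at a signal-to-noise ratio of 4,
  with a robust (median-based) noise-SD estimate
* single/multi-unit labeling from the inter-spike-interval distribution
  (multiunit iff more than 0.1% of ISIs are shorter than 2 ms)
* peak-to-trough spike widths; putative interneurons have widths < 0.4 ms
* modulation index MI = (FR_post - FR_pre) / (FR_post + FR_pre) with the
  pre rate over the 1 s before the stimulus and the post rate over
  0-0.1 s after; MI = -1 is complete silencing
* excitation flag: any 5 ms PSTH bin in the 30 ms after the stimulus
  exceeding the baseline mean by 4 baseline SDs
* response latency from the 1 ms-binned PSTH peak; jitter and spike
  probability from the first spike per trial in the 2-20 ms window
* inhibition duration: time between the trial-averaged rate falling below
  50% of baseline and recovering back to 50%
* late-response quartile sort on the 200-500 ms window
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .containers import RecordingSession

__all__ = [
    "SpikeTrain",
    "Psth",
    "ModulationResult",
    "bandpass",
    "estimate_noise_sd",
    "detect_events",
    "classify_isolation",
    "spike_width",
    "classify_cell_type",
    "build_psth",
    "normalize_psth",
    "modulation_index",
    "detect_excitation",
    "response_latency",
    "inhibition_duration",
    "late_response_sort",
    "analyze_unit",
]


@dataclass
class SpikeTrain:
    """Detected (or planted) events of one unit, with optional labels."""

    unit_id: str
    event_times: np.ndarray  # s, sorted
    waveforms: Optional[np.ndarray] = None  # (n_events, n_samples)
    fs: Optional[float] = None
    width_ms: Optional[float] = None
    isolation: Optional[str] = None  # 'single' | 'multi'
    cell_type: Optional[str] = None  # 'PC' | 'IN'

    def __post_init__(self) -> None:
        t = np.asarray(self.event_times, dtype=float)
        if np.any(np.diff(t) < 0):
            t = np.sort(t)
        self.event_times = t

    @property
    def n_events(self) -> int:
        return self.event_times.size


@dataclass
class Psth:
    """Trial-averaged binned firing rate aligned to stimulus onset."""

    bin_edges: np.ndarray  # s relative to stimulus, len n_bins + 1
    rates: np.ndarray  # spikes/s per bin
    n_trials: int
    baseline_window: tuple[float, float] = (-1.0, 0.0)
    normalized: bool = False

    @property
    def binsize(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def baseline_rate(self) -> float:
        lo, hi = self.baseline_window
        mask = (self.bin_edges[:-1] >= lo) & (self.bin_edges[1:] <= hi)
        if not mask.any():
            raise ValueError("no PSTH bins inside the baseline window")
        return float(self.rates[mask].mean())


@dataclass
class ModulationResult:
    """Per-unit stimulus-response metrics."""

    unit_id: str = ""
    MI: Optional[float] = None
    FR_pre: float = 0.0
    FR_post: float = 0.0
    excited: Optional[bool] = None
    excitation_bins: list = field(default_factory=list)
    latency_ms: Optional[float] = None
    jitter_ms: Optional[float] = None
    spike_probability: Optional[float] = None
    inhibition_duration_ms: Optional[float] = None
    late_class: Optional[str] = None


# ---------------------------------------------------------------------------
# filtering and detection
# ---------------------------------------------------------------------------

def bandpass(trace: np.ndarray, fs: float, low: float = 300.0,
             high: float = 5000.0, order: int = 3) -> np.ndarray:
    """Zero-phase Butterworth band-pass (default 0.3-5 kHz analysis band)."""
    if not (0 < low < high < fs / 2):
        raise ValueError(f"invalid band edges ({low}, {high}) for fs={fs}")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(trace, dtype=float))


def estimate_noise_sd(x: np.ndarray) -> float:
    """Robust noise SD, ``median(|x|) / 0.6745`` (insensitive to spikes)."""
    return float(np.median(np.abs(x)) / 0.6745)


def detect_events(filtered: np.ndarray, fs: float, snr_threshold: float = 4.0,
                  dead_time_ms: float = 1.0, polarity: int = -1,
                  snippet_ms: tuple[float, float] = (1.0, 2.0),
                  unit_id: str = "u0") -> SpikeTrain:
    """Amplitude-threshold event detection on a filtered trace.

    Events are crossings of ``snr_threshold`` times the robust noise SD
    (negative-going by default, the extracellular convention), separated by
    at least ``dead_time_ms``, each aligned to its peak and returned with a
    waveform snippet spanning ``snippet_ms`` (before, after) the peak.
    """
    x = np.asarray(filtered, dtype=float) * (1 if polarity > 0 else -1)
    sd = estimate_noise_sd(x)
    if sd == 0:
        return SpikeTrain(unit_id, np.empty(0), np.empty((0, 0)), fs)
    thr = snr_threshold * sd
    above = x > thr
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    dead = int(round(dead_time_ms / 1000.0 * fs))
    pre = int(round(snippet_ms[0] / 1000.0 * fs))
    post = int(round(snippet_ms[1] / 1000.0 * fs))

    peaks: list[int] = []
    last = -np.inf
    for c in crossings:
        if c - last < dead:
            continue
        stop = min(c + dead, x.size)
        pk = c + int(np.argmax(x[c:stop]))
        peaks.append(pk)
        last = pk

    times, snips = [], []
    for pk in peaks:
        if pk - pre < 0 or pk + post > x.size:
            continue
        times.append(pk / fs)
        snips.append(filtered[pk - pre:pk + post])
    waveforms = np.asarray(snips) if snips else np.empty((0, pre + post))
    return SpikeTrain(unit_id, np.asarray(times), waveforms, fs)


# ---------------------------------------------------------------------------
# unit labels
# ---------------------------------------------------------------------------

def classify_isolation(train: SpikeTrain, isi_ms: float = 2.0,
                       frac_threshold: float = 0.001) -> str:
    """Single/multi-unit label from the ISI distribution.

    Multi-unit iff the fraction of inter-spike intervals below ``isi_ms``
    exceeds ``frac_threshold`` (strictly greater, so exactly 0.1% remains
    single).  Requires at least 2 events; fewer than ~100 makes the
    fraction statistically weak and triggers a warning.
    """
    if train.n_events < 2:
        raise ValueError("isolation undefined for fewer than 2 events")
    if train.n_events < 100:
        warnings.warn("fewer than 100 events: ISI fraction is unreliable",
                      UserWarning)
    isis = np.diff(train.event_times) * 1000.0
    frac = float(np.mean(isis < isi_ms))
    return "multi" if frac > frac_threshold else "single"


def spike_width(waveform: np.ndarray, fs: float) -> float:
    """Peak-to-trough spike width in ms.

    The main extremum (largest absolute deflection) is taken as the spike
    peak; the width is the time to the subsequent opposite-polarity
    extremum.  A snippet with no such extremum (e.g. a monotonic tail)
    raises ``ValueError`` rather than returning a silently wrong sign.
    """
    w = np.asarray(waveform, dtype=float)
    if w.size < 3:
        raise ValueError("waveform too short")
    pk = int(np.argmax(np.abs(w)))
    s = np.sign(w[pk])
    tail = -s * w[pk + 1:]
    if tail.size == 0:
        raise ValueError("spike peak at snippet edge; no trough")
    tr = int(np.argmax(tail))
    if tail[tr] <= 0 or tr == tail.size - 1:
        raise ValueError("no opposite-polarity extremum after the peak")
    return (tr + 1) / fs * 1000.0


def classify_cell_type(width_ms: float, threshold_ms: float = 0.4) -> str:
    """Putative interneuron iff the peak-to-trough width is < 0.4 ms."""
    return "IN" if width_ms < threshold_ms else "PC"


# ---------------------------------------------------------------------------
# PSTHs
# ---------------------------------------------------------------------------

def _valid_stims(stim_times: np.ndarray, window: tuple[float, float],
                 t_stop: Optional[float]) -> np.ndarray:
    stims = np.asarray(stim_times, dtype=float)
    ok = stims + window[0] >= 0
    if t_stop is not None:
        ok &= stims + window[1] <= t_stop
    return stims[ok]


def build_psth(train: SpikeTrain | np.ndarray, stim_times: np.ndarray,
               window: tuple[float, float] = (-1.0, 0.5),
               binsize: float = 0.01,
               t_stop: Optional[float] = None) -> Psth:
    """Trial-averaged peri-stimulus time histogram in spikes/s.

    Stimuli whose window extends before the recording start (or past
    ``t_stop`` when given) are dropped.  Bins are half-open
    ``[edge, edge + binsize)``.
    """
    events = train.event_times if isinstance(train, SpikeTrain) else np.asarray(train)
    stims = _valid_stims(stim_times, window, t_stop)
    if stims.size == 0:
        raise ValueError("no stimuli with a complete analysis window")
    n_bins = int(round((window[1] - window[0]) / binsize))
    edges = window[0] + np.arange(n_bins + 1) * binsize
    counts = np.zeros(n_bins)
    for s in stims:
        rel = events[np.searchsorted(events, s + edges[0]):
                     np.searchsorted(events, s + edges[-1])] - s
        counts += np.histogram(rel, bins=edges)[0]
    rates = counts / (stims.size * binsize)
    baseline = (max(window[0], -2.0), 0.0)
    return Psth(edges, rates, n_trials=int(stims.size), baseline_window=baseline)


def normalize_psth(psth: Psth, baseline: tuple[float, float] = (-2.0, 0.0)) -> Psth:
    """Divide all bins by the mean pre-stimulus rate (baseline average = 1).

    The normalization window defaults to the 2 s before the stimulus,
    clipped to the bins the PSTH actually covers.  A unit with zero
    baseline rate cannot be normalized and raises ``ValueError`` (such
    units are excluded from normalized population displays).
    """
    lo = max(baseline[0], float(psth.bin_edges[0]))
    mask = (psth.bin_edges[:-1] >= lo) & (psth.bin_edges[1:] <= baseline[1])
    if not mask.any():
        raise ValueError("no PSTH bins inside the normalization window")
    base = float(psth.rates[mask].mean())
    if base <= 0:
        raise ValueError("zero baseline rate: unit cannot be normalized")
    return Psth(psth.bin_edges.copy(), psth.rates / base, psth.n_trials,
                baseline_window=(lo, baseline[1]), normalized=True)


# ---------------------------------------------------------------------------
# response metrics
# ---------------------------------------------------------------------------

def modulation_index(train: SpikeTrain | np.ndarray, stim_times: np.ndarray,
                     pre_window: float = 1.0, post_window: float = 0.1,
                     t_stop: Optional[float] = None,
                     unit_id: str = "") -> ModulationResult:
    """Stimulus modulation index from trial-averaged rates.

    ``MI = (FR_post - FR_pre) / (FR_post + FR_pre)`` with ``FR_pre`` the
    mean rate over the ``pre_window`` s before each stimulus and
    ``FR_post`` the mean rate over ``post_window`` s after.  -1 is
    complete suppression; values near +1 indicate strong activation.  For
    bursty excited units the index can still be negative even when the
    cell is initially excited (a documented property of the metric; the
    separate excitation flag captures such units).

    When both rates are zero the MI is undefined and returned as ``None``.
    """
    events = train.event_times if isinstance(train, SpikeTrain) else np.asarray(train)
    stims = _valid_stims(stim_times, (-pre_window, post_window), t_stop)
    if stims.size == 0:
        raise ValueError("no stimuli with complete pre/post windows")
    pre_counts = (np.searchsorted(events, stims)
                  - np.searchsorted(events, stims - pre_window))
    post_counts = (np.searchsorted(events, stims + post_window)
                   - np.searchsorted(events, stims))
    fr_pre = pre_counts.sum() / (stims.size * pre_window)
    fr_post = post_counts.sum() / (stims.size * post_window)
    if fr_pre + fr_post == 0:
        warnings.warn("MI undefined: no spikes in either window", UserWarning)
        mi = None
    else:
        mi = (fr_post - fr_pre) / (fr_post + fr_pre)
    return ModulationResult(unit_id=unit_id, MI=mi, FR_pre=float(fr_pre),
                            FR_post=float(fr_post))


def detect_excitation(psth: Psth, response_window: tuple[float, float] = (0.0, 0.03),
                      n_sd: float = 4.0) -> tuple[bool, list[float]]:
    """Excitation flag from a 5 ms-binned PSTH.

    Excited iff any bin inside the 30 ms after the stimulus has a rate
    greater than the baseline mean plus ``n_sd`` baseline SDs.  Baseline
    mean and SD are computed across the pre-stimulus bins of the same
    PSTH.  Returns ``(excited, start times of supra-threshold bins)``.
    """
    starts = psth.bin_edges[:-1]
    base = psth.rates[starts < 0]
    if base.size < 2:
        raise ValueError("need pre-stimulus bins to estimate the baseline")
    mu = float(base.mean())
    sd = float(base.std(ddof=1))
    post = (starts >= response_window[0]) & (psth.bin_edges[1:] <= response_window[1])
    if sd == 0 and mu == 0:
        # degenerate silent baseline: any post-stimulus spiking counts
        warnings.warn("zero-mean, zero-variance baseline; excitation test "
                      "degenerates to any post-stimulus activity", UserWarning)
        hot = post & (psth.rates > 0)
    else:
        hot = post & (psth.rates > mu + n_sd * sd)
    return bool(hot.any()), [float(s) for s in starts[hot]]


def response_latency(train: SpikeTrain | np.ndarray, stim_times: np.ndarray,
                     peak_window: tuple[float, float] = (0.0, 0.03),
                     first_spike_window: tuple[float, float] = (0.002, 0.02),
                     binsize: float = 0.001,
                     t_stop: Optional[float] = None,
                     ) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """Latency, temporal jitter and spike probability of an excited unit.

    Latency (ms) is the time of the peak of the 1 ms-binned PSTH after the
    stimulus; jitter is the SD of the first spike per trial in the
    2-20 ms window; spike probability is the fraction of trials with at
    least one spike in that window.  All three are ``None`` when the unit
    emits no post-stimulus spikes in the peak window.
    """
    events = train.event_times if isinstance(train, SpikeTrain) else np.asarray(train)
    stims = _valid_stims(stim_times, peak_window, t_stop)
    if stims.size == 0:
        raise ValueError("no stimuli available")
    psth = build_psth(events, stims, window=peak_window, binsize=binsize,
                      t_stop=t_stop)
    if psth.rates.sum() == 0:
        return None, None, None
    latency = float(psth.bin_centers[np.argmax(psth.rates)] * 1000.0)

    firsts = []
    hit = 0
    for s in stims:
        lo = np.searchsorted(events, s + first_spike_window[0], side="right")
        hi = np.searchsorted(events, s + first_spike_window[1], side="right")
        if hi > lo:
            hit += 1
            firsts.append(events[lo] - s)
    prob = hit / stims.size
    if len(firsts) >= 2:
        jitter = float(np.std(firsts, ddof=1) * 1000.0)
    elif len(firsts) == 1:
        jitter = None
    else:
        jitter = None
    return latency, jitter, float(prob)


def _smooth_same(x: np.ndarray, nbins: int) -> np.ndarray:
    if nbins <= 1:
        return x
    kernel = np.ones(nbins)
    return np.convolve(x, kernel, mode="same") / np.convolve(
        np.ones_like(x), kernel, mode="same")


def inhibition_duration(psth: Psth, baseline_rate: Optional[float] = None,
                        smooth_bins: int = 3, sustain_bins: int = 2,
                        level: float = 0.5) -> Optional[float]:
    """Duration of stimulus-evoked spike suppression, in ms.

    Measured on the (lightly smoothed) trial-averaged PSTH as the time
    elapsed between the rate first falling below ``level`` (50%) of the
    baseline rate after the stimulus and recovering back above it.  Raw
    bins of low-rate units cross the threshold spuriously, so the PSTH is
    smoothed with a ``smooth_bins``-bin moving average and recovery
    requires ``sustain_bins`` consecutive bins at or above threshold.
    Returns ``None`` when the rate never falls below threshold (or never
    recovers within the PSTH window).
    """
    if baseline_rate is None:
        baseline_rate = psth.baseline_rate()
    if baseline_rate <= 0:
        raise ValueError("baseline rate must be > 0")
    sm = _smooth_same(psth.rates, smooth_bins)
    thr = level * baseline_rate
    starts = psth.bin_edges[:-1]
    post = np.flatnonzero(starts >= 0)
    below = sm[post] < thr
    if not below.any():
        return None
    i_down = int(np.argmax(below))
    at_or_above = ~below
    for i in range(i_down + 1, post.size - sustain_bins + 1):
        if at_or_above[i:i + sustain_bins].all():
            return float((starts[post[i]] - starts[post[i_down]]) * 1000.0)
    return None


def late_response_sort(psths: Sequence[Psth], unit_ids: Optional[Sequence] = None,
                       window: tuple[float, float] = (0.2, 0.5)) -> list[str]:
    """Quartile sort of late (200-500 ms) responses across a population.

    Units are ranked by their mean (normalized) rate in the window; the
    top quartile is labeled ``late_excited``, the bottom quartile
    ``late_inhibited``, the rest ``middle``.  Quartiles are taken by rank
    (n // 4 units each) with a stable sort, so ties keep input order.
    """
    n = len(psths)
    if n < 4:
        raise ValueError("need at least 4 units for a quartile sort")
    late = []
    for p in psths:
        mask = (p.bin_edges[:-1] >= window[0]) & (p.bin_edges[1:] <= window[1])
        if not mask.any():
            raise ValueError("PSTH does not cover the late-response window")
        late.append(float(p.rates[mask].mean()))
    late_arr = np.asarray(late)
    if np.allclose(late_arr, late_arr[0]):
        warnings.warn("all late-response rates identical; quartile labels are "
                      "degenerate", UserWarning)
    order = np.argsort(late_arr, kind="stable")
    k = n // 4
    labels = ["middle"] * n
    for i in order[:k]:
        labels[i] = "late_inhibited"
    for i in order[n - k:]:
        labels[i] = "late_excited"
    return labels


# ---------------------------------------------------------------------------
# per-unit driver
# ---------------------------------------------------------------------------

def analyze_unit(train: SpikeTrain, session: RecordingSession,
                 pre_window: float = 1.0, post_window: float = 0.1,
                 excitation_binsize: float = 0.005,
                 excitation_window: tuple[float, float] = (0.0, 0.03),
                 excitation_sd: float = 4.0,
                 duration_binsize: float = 0.01,
                 duration_window: tuple[float, float] = (-1.0, 2.0),
                 width_threshold: float = 0.4) -> ModulationResult:
    """Compute the full per-unit response-metric bundle for one spike train.

    Fills MI/rates, the excitation flag, latency/jitter/probability (for
    excited units) and the inhibition duration; the late class is assigned
    at population level by :func:`late_response_sort`.
    """
    t_stop = session.duration
    res = modulation_index(train, session.stim_times, pre_window, post_window,
                           t_stop=t_stop, unit_id=train.unit_id)
    psth5 = build_psth(train, session.stim_times,
                       window=(-pre_window, excitation_window[1]),
                       binsize=excitation_binsize, t_stop=t_stop)
    res.excited, res.excitation_bins = detect_excitation(
        psth5, excitation_window, excitation_sd)
    if res.excited:
        res.latency_ms, res.jitter_ms, res.spike_probability = response_latency(
            train, session.stim_times, t_stop=t_stop)
    psth10 = build_psth(train, session.stim_times, window=duration_window,
                        binsize=duration_binsize, t_stop=t_stop)
    if res.FR_pre > 0:
        res.inhibition_duration_ms = inhibition_duration(psth10)
    return res
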