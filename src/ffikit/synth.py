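"""Synthetic extracellular sessions and intracellular sweep sets with ground truth.

The generators emulate the statistical structure of optogenetic
claustrocortical feedforward-inhibition experiments: Poisson-like spike
trains with stimulus-locked suppression, biphasic excitation-inhibition,
rebound and flat-control rate profiles; biphasic extracellular spike
waveforms with controllable peak-to-trough width; and postsynaptic
potential/current sweeps built from difference-of-exponential kernels with
geometric short-term depression across pulse trains.

Every generator is deterministic under a fixed ``(config, seed)`` pair: a
single :class:`numpy.random.SeedSequence` is spawned per call, one child
stream per unit (in list order) followed by one stream for the additive
noise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .containers import GroundTruth, RecordingSession, SessionMetadata, SweepSet

__all__ = [
    "RateProfile",
    "UnitSpec",
    "PspKernel",
    "DepressionSpec",
    "profile_preset",
    "spike_template",
    "gen_spike_times",
    "gen_extracellular_session",
    "gen_sweep_set",
    "gen_paired_recording",
    "kernel_from_kinetics",
    "render_spike_train_trace",
]

PRESET_NAMES = (
    "pc_suppressed",
    "in_biphasic",
    "control_flat",
    "md_excited",
    "pv_opto",
    "npy_opto",
)


# ---------------------------------------------------------------------------
# rate profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateProfile:
    """Trial-periodic firing-rate profile relative to stimulus onset.

    Parameters
    ----------
    baseline_rate : float
        Stationary rate away from the stimulus, spikes/s.
    segments : sequence of (t_start, t_end, multiplier)
        Non-overlapping stimulus-relative epochs (s) whose rate is
        ``baseline_rate * multiplier``.
    recovery_tau : float, optional
        If set, the unit is fully silenced at stimulus onset and the rate
        recovers exponentially, ``r(t) = r0 * (1 - exp(-t / tau))`` for
        t >= 0 (stimulus-relative).  Models the slow recovery from
        feedforward inhibition.
    """

    baseline_rate: float
    segments: tuple[tuple[float, float, float], ...] = ()
    recovery_tau: Optional[float] = None

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        segs = tuple(tuple(map(float, s)) for s in self.segments)
        object.__setattr__(self, "segments", segs)
        for t0, t1, m in segs:
            if m < 0:
                raise ValueError("segment multipliers must be >= 0")
            if t1 <= t0:
                raise ValueError("segment end must exceed start")
        for (a0, a1, _), (b0, b1, _) in zip(segs, segs[1:]):
            if b0 < a1:
                raise ValueError("segments must be sorted and non-overlapping")
        if self.recovery_tau is not None and self.recovery_tau <= 0:
            raise ValueError("recovery_tau must be > 0")

    def rate(self, t_rel: np.ndarray) -> np.ndarray:
        """Instantaneous rate at stimulus-relative times ``t_rel`` (s)."""
        t = np.asarray(t_rel, dtype=float)
        r = np.full(t.shape, self.baseline_rate, dtype=float)
        for t0, t1, m in self.segments:
            r[(t >= t0) & (t < t1)] *= m
        if self.recovery_tau is not None:
            post = t >= 0
            r[post] *= 1.0 - np.exp(-t[post] / self.recovery_tau)
        return r

    @property
    def max_rate(self) -> float:
        m = max((s[2] for s in self.segments), default=1.0)
        return self.baseline_rate * max(1.0, m)

    def expected_mi(self, pre_window: float = 1.0, post_window: float = 0.1,
                    stim_period: float = 5.0) -> float:
        """Closed-form modulation index of the configured profile.

        Mean rates over the pre/post analysis windows are obtained by
        numerical integration of ``rate``; MI = (post - pre)/(post + pre).
        """
        # the pre-window of trial k is the tail of trial k-1, i.e. lags
        # [period - pre, period) of the periodic profile
        tp = np.linspace(stim_period - pre_window, stim_period, 20001)[:-1]
        fr_pre = float(np.mean(self.rate(tp)))
        ta = np.linspace(0.0, post_window, 20001)[:-1]
        fr_post = float(np.mean(self.rate(ta)))
        if fr_pre + fr_post == 0:
            raise ValueError("MI undefined: zero rate in both windows")
        return (fr_post - fr_pre) / (fr_post + fr_pre)

    def half_recovery_time(self) -> Optional[float]:
        """Analytic time at which an exponential recovery crosses 50% of
        baseline: ``tau * ln 2``.  ``None`` when there is no recovery epoch."""
        if self.recovery_tau is None:
            return None
        return self.recovery_tau * math.log(2.0)


def profile_preset(name: str, baseline_rate: float = 10.0,
                   recovery_tau: Optional[float] = None) -> RateProfile:
    """Named rate profiles mirroring the recorded response classes.

    ``pc_suppressed``
        Principal cell under claustrum-driven feedforward inhibition: full
        silencing at stimulus onset, exponential recovery (default tau
        0.352 s, the value implied by the ~244 ms half-recovery of the
        claustrum condition).
    ``in_biphasic``
        Interneuron with short-latency excitation (7-15 ms epoch, 5x) then
        suppression to 10% of baseline out to 150 ms.
    ``control_flat``
        Fluorophore-only control: no stimulus-locked modulation.
    ``md_excited``
        Mediodorsal-thalamus-like net excitation: 1.469x for 0-100 ms
        (closed-form MI ~ 0.19).
    ``pv_opto`` / ``npy_opto``
        Direct fast-spiking / neurogliaform interneuron activation:
        silencing with short (0.1717 s) or long (0.346 s) recovery tau.
    """
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    if name == "control_flat":
        return RateProfile(baseline_rate)
    if name == "pc_suppressed":
        return RateProfile(baseline_rate, recovery_tau=recovery_tau or 0.352)
    if name == "pv_opto":
        return RateProfile(baseline_rate, recovery_tau=recovery_tau or 0.1717)
    if name == "npy_opto":
        return RateProfile(baseline_rate, recovery_tau=recovery_tau or 0.346)
    if name == "md_excited":
        return RateProfile(baseline_rate, segments=((0.0, 0.1, 1.469),))
    # in_biphasic
    return RateProfile(
        baseline_rate,
        segments=((0.007, 0.015, 5.0), (0.015, 0.15, 0.1)),
    )


# ---------------------------------------------------------------------------
# extracellular units
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnitSpec:
    """Ground-truth description of one simulated unit.

    ``waveform_width`` is the peak-to-trough interval in ms (the quantity
    the extracellular cell-type classifier thresholds at 0.4 ms);
    ``snr`` is waveform amplitude / noise SD.  When ``waveform_amplitude``
    is None it is derived as ``snr * noise_sd`` at render time.
    """

    unit_id: str
    profile: RateProfile
    waveform_width: float = 0.7  # ms
    waveform_amplitude: Optional[float] = None
    refractory: float = 2.0  # ms
    is_multiunit: bool = False
    snr: float = 8.0

    def __post_init__(self) -> None:
        if self.waveform_width <= 0:
            raise ValueError("waveform_width must be > 0")
        if self.refractory < 0:
            raise ValueError("refractory must be >= 0")
        if self.snr <= 0:
            raise ValueError("snr must be > 0")


def spike_template(width_ms: float, amplitude: float, fs: float) -> tuple[np.ndarray, int]:
    """Biphasic extracellular spike template (difference of Gaussians).

    The negative lobe (detection polarity) peaks at the returned index and
    the positive lobe peaks ``width_ms`` later, so the planted
    peak-to-trough width is exact up to sample quantization.  ``amplitude``
    is the magnitude of the negative peak.

    Returns ``(template, peak_index)``.
    """
    w = width_ms / 1000.0
    s1, s2 = w / 5.0, w / 3.0
    t = np.arange(round(-3 * s1 * fs), round((w + 3 * s2) * fs) + 1) / fs
    tem = -np.exp(-0.5 * (t / s1) ** 2) + 0.4 * np.exp(-0.5 * ((t - w) / s2) ** 2)
    tem *= amplitude / np.abs(tem).max()
    return tem, int(np.argmin(tem))


def _enforce_refractory(times: np.ndarray, refractory_s: float) -> np.ndarray:
    """Greedy deletion of events closer than the refractory period."""
    if times.size < 2 or refractory_s <= 0:
        return times
    kept = [times[0]]
    last = times[0]
    for t in times[1:]:
        if t - last >= refractory_s:
            kept.append(t)
            last = t
    return np.asarray(kept)


def gen_spike_times(profile: RateProfile, n_trials: int, stim_period: float,
                    refractory_ms: float = 2.0,
                    rng: Optional[np.random.Generator] = None,
                    seed: Optional[int] = None) -> np.ndarray:
    """Inhomogeneous-Poisson spike times over ``n_trials`` stimulus periods.

    Spikes are drawn by thinning a homogeneous Poisson process at the
    profile's maximal rate, then events closer than the refractory period
    are deleted (for rate * refractory << 1 this distorts the rate
    negligibly).  Stimuli occur at ``k * stim_period`` for k = 0..n-1.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    total = n_trials * stim_period
    rmax = profile.max_rate
    if rmax == 0:
        return np.empty(0)
    n = rng.poisson(rmax * total)
    t = np.sort(rng.uniform(0.0, total, n))
    accept = rng.uniform(0.0, 1.0, n) < profile.rate(t % stim_period) / rmax
    return _enforce_refractory(t[accept], refractory_ms / 1000.0)


def gen_extracellular_session(
    units: Sequence[UnitSpec],
    n_trials: int = 200,
    stim_period: float = 5.0,
    fs: float = 25_000.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    metadata: Optional[SessionMetadata] = None,
    render_trace: bool = True,
) -> tuple[RecordingSession, GroundTruth]:
    """Generate one extracellular session (trace + stimulus times) with truth.

    Emulates the in vivo protocol: one brief optical pulse per
    ``stim_period`` (default 5 s, i.e. 0.2 Hz) sampled at 25 kHz.  Each
    unit's spikes follow its :class:`RateProfile` and are rendered as
    biphasic templates of the configured width and amplitude on top of
    white Gaussian noise.  With ``render_trace=False`` only spike times are
    generated (a detection-free session).
    """
    if not units:
        raise ValueError("units must be non-empty")
    if render_trace and fs < 10_000:
        raise ValueError("fs must be >= 10 kHz for waveform rendering")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    for u in units:
        # template support must fit inside the refractory period so that
        # rendered spikes of one unit never overlap
        support_ms = 0.6 * u.waveform_width + u.waveform_width + u.waveform_width
        if render_trace and support_ms > u.refractory:
            raise ValueError(
                f"unit {u.unit_id!r}: waveform support {support_ms:.2f} ms exceeds "
                f"refractory period {u.refractory:.2f} ms"
            )

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(units) + 1)
    n_samples = int(round(n_trials * stim_period * fs))
    stim_times = np.arange(n_trials) * stim_period

    spike_times: dict = {}
    for u, child in zip(units, children[:-1]):
        spike_times[u.unit_id] = gen_spike_times(
            u.profile, n_trials, stim_period, u.refractory,
            rng=np.random.default_rng(child),
        )

    trace = None
    clean = None
    if render_trace:
        clean = np.zeros(n_samples, dtype=np.float64)
        for u in units:
            amp = u.waveform_amplitude
            if amp is None:
                amp = u.snr * noise_sd
            tem, pk = spike_template(u.waveform_width, amp, fs)
            idx = np.round(spike_times[u.unit_id] * fs).astype(int)
            for i in idx:
                lo = i - pk
                hi = lo + tem.size
                if lo < 0 or hi > n_samples:
                    continue
                clean[lo:hi] += tem
        noise_rng = np.random.default_rng(children[-1])
        trace = clean + noise_rng.normal(0.0, noise_sd, n_samples)

    session = RecordingSession(
        trace=trace, fs=fs, stim_times=stim_times,
        metadata=metadata or SessionMetadata(),
    )
    truth = GroundTruth(
        spike_times=spike_times,
        clean=None if clean is None else clean.astype(np.float32),
        params={
            "n_trials": n_trials, "stim_period": stim_period, "fs": fs,
            "noise_sd": noise_sd,
            "units": [
                {
                    "unit_id": u.unit_id,
                    "baseline_rate": u.profile.baseline_rate,
                    "segments": list(u.profile.segments),
                    "recovery_tau": u.profile.recovery_tau,
                    "waveform_width": u.waveform_width,
                    "waveform_amplitude": u.waveform_amplitude,
                    "refractory": u.refractory,
                    "snr": u.snr,
                }
                for u in units
            ],
        },
        seed=seed,
    )
    return session, truth


# ---------------------------------------------------------------------------
# intracellular kernels and sweeps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PspKernel:
    """Difference-of-exponentials postsynaptic potential/current kernel.

    ``k(t) = A * (exp(-t/tau_decay) - exp(-t/tau_rise))`` for t >= 0,
    rescaled so the peak equals ``amplitude`` (a magnitude; ``sign``
    selects the deflection direction: excitatory -> positive, inhibitory
    -> negative in the rendered sweep).  Time constants in ms.
    """

    amplitude: float
    tau_rise: float
    tau_decay: float
    onset_delay: float = 0.0  # ms
    sign: str = "excitatory"

    def __post_init__(self) -> None:
        if not (self.tau_decay > self.tau_rise > 0):
            raise ValueError("require tau_decay > tau_rise > 0")
        if self.sign not in ("excitatory", "inhibitory"):
            raise ValueError("sign must be 'excitatory' or 'inhibitory'")

    @property
    def peak_time(self) -> float:
        """Time-to-peak after onset, ms."""
        tr, td = self.tau_rise, self.tau_decay
        return tr * td / (td - tr) * math.log(td / tr)

    def evaluate(self, t_ms: np.ndarray) -> np.ndarray:
        """Kernel value at times ``t_ms`` (ms) after the pulse."""
        t = np.asarray(t_ms, dtype=float) - self.onset_delay
        tp = self.peak_time
        norm = math.exp(-tp / self.tau_decay) - math.exp(-tp / self.tau_rise)
        out = np.where(
            t >= 0,
            np.exp(-np.maximum(t, 0) / self.tau_decay)
            - np.exp(-np.maximum(t, 0) / self.tau_rise),
            0.0,
        ) / norm * self.amplitude
        if self.sign == "inhibitory":
            out = -out
        return out


@dataclass(frozen=True)
class DepressionSpec:
    """Geometric short-term depression across a fixed-frequency pulse train.

    Pulse k (1-based) has amplitude ``A1 * retention**(k-1)``.
    """

    n_pulses: int = 5
    frequency: float = 20.0  # Hz
    retention: float = 0.853

    def __post_init__(self) -> None:
        if self.n_pulses < 1:
            raise ValueError("n_pulses must be >= 1")
        if self.frequency <= 0:
            raise ValueError("frequency must be > 0")
        if not (0 < self.retention <= 1):
            raise ValueError("retention must be in (0, 1]")

    @property
    def amplitudes(self) -> np.ndarray:
        return self.retention ** np.arange(self.n_pulses)


def gen_sweep_set(
    kernel: PspKernel,
    depression: Optional[DepressionSpec] = None,
    n_sweeps: int = 10,
    fs: float = 10_000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    pre_time: float = 0.1,
    tail: float = 0.5,
    mode: str = "current_clamp",
) -> tuple[SweepSet, GroundTruth]:
    """Generate stimulus-aligned sweeps: summed PSP kernels plus noise.

    A single pulse at ``pre_time`` s, or a train from ``depression``
    (``n_pulses`` at ``frequency`` Hz with geometric amplitude scaling).
    Each sweep is the noise-free waveform plus white Gaussian noise; the
    noise-free component is identical across sweeps and stored in the
    ground truth.
    """
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    if depression is None:
        pulse_times = np.array([pre_time])
        amps = np.array([1.0])
        ipi = np.inf
    else:
        ipi = 1.0 / depression.frequency
        pulse_times = pre_time + np.arange(depression.n_pulses) * ipi
        amps = depression.amplitudes
        support_ms = kernel.onset_delay + kernel.peak_time + 4.6 * kernel.tau_decay
        if support_ms / 1000.0 > ipi + tail:
            warnings.warn(
                "PSP kernel support exceeds the inter-pulse interval plus the "
                "sweep tail; responses will overlap strongly", UserWarning,
            )
    duration = pulse_times[-1] + tail
    n_samples = int(round(duration * fs))
    t_ms = np.arange(n_samples) / fs * 1000.0
    clean = np.zeros(n_samples)
    for pt, a in zip(pulse_times, amps):
        clean += a * kernel.evaluate(t_ms - pt * 1000.0)

    rng = np.random.default_rng(seed)
    sweeps = clean[None, :] + rng.normal(0.0, noise_sd, (n_sweeps, n_samples))
    sweep_set = SweepSet(sweeps=sweeps, fs=fs, pulse_times=pulse_times, mode=mode)
    truth = GroundTruth(
        clean=clean,
        params={
            "kernel": {
                "amplitude": kernel.amplitude, "tau_rise": kernel.tau_rise,
                "tau_decay": kernel.tau_decay, "onset_delay": kernel.onset_delay,
                "sign": kernel.sign,
            },
            "depression": None if depression is None else {
                "n_pulses": depression.n_pulses,
                "frequency": depression.frequency,
                "retention": depression.retention,
            },
            "n_sweeps": n_sweeps, "fs": fs, "noise_sd": noise_sd,
            "pre_time": pre_time, "tail": tail, "mode": mode,
        },
        seed=seed,
    )
    return sweep_set, truth


def gen_paired_recording(
    connected: bool,
    kernel: PspKernel,
    burst: Optional[DepressionSpec] = None,
    n_trials: int = 20,
    noise_sd: float = 0.1,
    seed: int = 0,
    fs: float = 10_000.0,
) -> tuple[SweepSet, GroundTruth]:
    """Simulated paired recording: presynaptic burst, postsynaptic sweeps.

    Emulates the connectivity protocol in which 50 Hz bursts of presynaptic
    spikes are driven while the postsynaptic membrane potential is
    recorded.  ``connected=False`` yields pure-noise sweeps with the same
    pulse bookkeeping (the null condition for the connection detector).
    """
    if burst is None:
        burst = DepressionSpec(n_pulses=5, frequency=50.0, retention=1.0)
    eff_kernel = kernel if connected else replace(kernel, amplitude=0.0)
    sweep_set, truth = gen_sweep_set(
        eff_kernel, depression=burst, n_sweeps=n_trials, fs=fs,
        noise_sd=noise_sd, seed=seed, tail=0.5,
    )
    truth.params["connected"] = connected
    return sweep_set, truth


# ---------------------------------------------------------------------------
# kernel design helpers
# ---------------------------------------------------------------------------

def _shape_metrics(tau_rise: float, tau_decay: float) -> tuple[float, float]:
    # 10-90% rise time and half-width of the unit difference-of-exponentials
    # kernel, from a dense grid (generator-side design tool)
    k = PspKernel(1.0, tau_rise, tau_decay)
    t = np.linspace(0.0, k.peak_time + 8.0 * tau_decay, 200_001)
    y = k.evaluate(t)
    pk = int(np.argmax(y))
    ymax = y[pk]

    def crossing(level: float, lo: int, hi: int, rising: bool) -> float:
        seg = y[lo:hi]
        if rising:
            i = int(np.searchsorted(seg, level))
        else:
            i = int(np.searchsorted(-seg, -level))
        i = min(max(i, 1), seg.size - 1)
        x0, x1 = t[lo + i - 1], t[lo + i]
        y0, y1 = seg[i - 1], seg[i]
        if y1 == y0:
            return x0
        return x0 + (level - y0) * (x1 - x0) / (y1 - y0)

    t10 = crossing(0.1 * ymax, 0, pk + 1, True)
    t90 = crossing(0.9 * ymax, 0, pk + 1, True)
    t50a = crossing(0.5 * ymax, 0, pk + 1, True)
    t50b = crossing(0.5 * ymax, pk, y.size, False)
    return t90 - t10, t50b - t50a


def kernel_from_kinetics(rise_10_90: float, half_width: float,
                         amplitude: float = 1.0, sign: str = "inhibitory",
                         onset_delay: float = 0.0) -> PspKernel:
    """Solve for (tau_rise, tau_decay) giving target kinetics (ms).

    Used to build IPSP fixtures whose measured 10-90% rise time and decay
    half-width equal specified group means (e.g. fast-spiking-like
    5.6/46.3 ms or neurogliaform-like 22.3/118.6 ms).
    """

    def residual(logp):
        tr, td = np.exp(logp)
        if td <= tr:
            return [1e3, 1e3]
        r, h = _shape_metrics(tr, td)
        return [math.log(r / rise_10_90), math.log(h / half_width)]

    x0 = np.log([rise_10_90 / 1.7, half_width / 1.2])
    sol = optimize.least_squares(residual, x0, xtol=1e-12, ftol=1e-12)
    tr, td = np.exp(sol.x)
    return PspKernel(amplitude, float(tr), float(td), onset_delay=onset_delay,
                     sign=sign)


# ---------------------------------------------------------------------------
# firing-pattern fixture
# ---------------------------------------------------------------------------

def render_spike_train_trace(
    spike_times: Sequence[float],
    spike_width_ms: float,
    fs: float,
    duration: float,
    baseline: float = -60.0,
    step: Optional[tuple[float, float, float]] = None,
    spike_peak: float = 20.0,
) -> np.ndarray:
    """Render a current-clamp-like trace with Gaussian action potentials.

    Each spike is a Gaussian bump whose full width at half maximum equals
    ``spike_width_ms`` (the ground truth for intracellular spike-width
    measurement).  ``step`` is an optional ``(start_s, duration_s,
    plateau_mV)`` depolarizing current-step plateau.
    """
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    v = np.full(n, baseline)
    plateau = baseline
    if step is not None:
        s0, sd, level = step
        v[(t >= s0) & (t < s0 + sd)] = level
        plateau = level
    sigma = spike_width_ms / 1000.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    for st in spike_times:
        v += (spike_peak - plateau) * np.exp(-0.5 * ((t - st) / sigma) ** 2)
    return v
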