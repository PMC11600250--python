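"""Ground-truthed synthetic extracellular recordings and calcium traces.

Emulates the style of benchmark data used for spike-sorter evaluation:
a handful of source neurons, each with a fixed extracellular waveform
template, firing as independent Poisson processes with a refractory dead
time, superimposed on white Gaussian background noise.  Two size classes
("small" ≈ 100 000 spikes, "large" ≈ 1 100 000 spikes) mirror the scale
split commonly used when benchmarking sorters on simulated data.

Templates are biphasic trough-then-rebound shapes (difference of two
Gaussian lobes) — the trough-dominated morphology typical of extracellular
somatic spikes recorded by planar microelectrodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SpikeTemplate",
    "SimulationConfig",
    "GroundTruth",
    "RawRecording",
    "CalciumTrace",
    "make_templates",
    "simulate_recording",
    "make_benchmark_suite",
    "simulate_calcium_trace",
    "BENCHMARK_SPIKE_COUNTS",
]

#: Target total spike counts per size class (before any scale factor).
BENCHMARK_SPIKE_COUNTS = {"small": 100_000, "large": 1_100_000}


@dataclass
class SpikeTemplate:
    """Extracellular waveform of one source neuron.

    Attributes
    ----------
    neuron_id : int
        Integer label of the source neuron.
    waveform : ndarray
        Voltage samples (µV) at the recording sampling rate; the global
        minimum is the trough.
    peak_amplitude : float
        Trough amplitude in µV (negative by convention).
    """

    neuron_id: int
    waveform: np.ndarray
    peak_amplitude: float

    @property
    def trough_index(self) -> int:
        return int(np.argmin(self.waveform))


@dataclass
class SimulationConfig:
    """Parameters of one synthetic recording.

    ``firing_rates`` may be a scalar (applied to every neuron) or a
    per-neuron sequence in Hz.  If ``target_spike_count`` is given the
    duration is solved as ``target / sum(rates)`` so the expected total
    number of inserted spikes matches the target.
    """

    n_neurons: int = 5
    firing_rates: float | Sequence[float] = 20.0
    duration: float | None = None
    sampling_rate: float = 20_000.0
    noise_sd: float = 10.0
    refractory: float = 0.002
    target_spike_count: int | None = None
    seed: int = 0
    #: Within-unit waveform variability: per-spike time-base stretch
    #: (sd of a clipped normal around 1) and amplitude attenuation
    #: (uniform factor range), emulating burst-related spike-shape
    #: modulation.  Both default to "off" so a unit's spikes reproduce
    #: its template exactly.
    width_jitter_sd: float = 0.0
    amp_jitter_range: tuple[float, float] = (1.0, 1.0)

    def rates_array(self) -> np.ndarray:
        rates = np.broadcast_to(
            np.asarray(self.firing_rates, dtype=float), (self.n_neurons,)
        ).copy()
        if np.any(rates < 0):
            raise ValueError("firing_rates must be >= 0")
        return rates

    def resolved_duration(self) -> float:
        if self.target_spike_count is not None:
            total = self.rates_array().sum()
            if total <= 0:
                raise ValueError(
                    "target_spike_count requires a positive total firing rate"
                )
            return self.target_spike_count / total
        if self.duration is None:
            raise ValueError("either duration or target_spike_count must be set")
        return self.duration

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.refractory < 0:
            raise ValueError("refractory must be >= 0")
        if self.resolved_duration() <= 0:
            raise ValueError("duration must be > 0")
        self.rates_array()


@dataclass
class GroundTruth:
    """Simulator-emitted spike times (trough sample indices) and labels."""

    spike_times: np.ndarray
    neuron_labels: np.ndarray
    n_neurons: int

    def __len__(self) -> int:
        return len(self.spike_times)


@dataclass
class RawRecording:
    """Single-channel extracellular voltage recording."""

    samples: np.ndarray
    sampling_rate: float
    channel_id: str = "sim"

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate


@dataclass
class CalciumTrace:
    """Per-frame fluorescence time series of one ROI."""

    intensities: np.ndarray
    frame_interval: float
    roi_id: str = "roi0"

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.intensities)) * self.frame_interval

    @property
    def duration(self) -> float:
        return len(self.intensities) * self.frame_interval


def _shape_feature(shape: np.ndarray) -> np.ndarray:
    """Unit-norm gradient feature of a trough-aligned 64-sample window.

    Mirrors the sorting front end (min-max scale then first difference)
    so template distinctness is enforced in the space where clustering
    actually happens.
    """
    w = np.concatenate([shape, np.zeros(64)])
    k = int(np.argmin(w))
    win = w[k - 20 : k + 44] if k >= 20 else w[:64]
    g = np.diff((win - win.min()) / (win.max() - win.min()))
    return g / np.linalg.norm(g)


def _shape_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Distance between two spike shapes in normalized-gradient space."""
    return float(np.linalg.norm(_shape_feature(a) - _shape_feature(b)))


def make_templates(
    n_neurons: int,
    template_length: int = 64,
    amplitude_range: tuple[float, float] = (-75.0, -120.0),
    rng_seed: int = 0,
    min_shape_distance: float = 0.7,
) -> list[SpikeTemplate]:
    """Build biphasic spike templates, one per source neuron.

    Each template is a difference of two Gaussian lobes: a dominant
    negative trough at 35 % of the template length and a smaller positive
    rebound after it.  Lobe widths, rebound delay and rebound fraction are
    drawn per neuron; the trough amplitude is drawn uniformly inside
    ``amplitude_range`` (µV, negative).  Sortable units must be distinct
    in the representation the sorters see, so candidate draws are
    rejection-sampled until each new template is at least
    ``min_shape_distance`` away from every accepted one in unit-norm
    normalized-gradient feature space; if the budget of redraws is
    exhausted the most distant candidate seen is kept.

    Parameters
    ----------
    n_neurons : int
        Number of templates (source neurons).
    template_length : int
        Samples per template, at least 64.
    amplitude_range : (float, float)
        Interval of trough amplitudes in µV; order-insensitive, both
        entries must be negative.
    rng_seed : int
        Seed; identical seeds yield identical template banks.
    min_shape_distance : float
        Minimum pairwise normalized waveform distance between units.
    """
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    if template_length < 64:
        raise ValueError("template_length must be >= 64")
    lo, hi = sorted(float(a) for a in amplitude_range)
    if hi > 0:
        raise ValueError("trough amplitudes must be negative (µV)")
    rng = np.random.default_rng(rng_seed)
    t = np.arange(template_length, dtype=float)
    trough_center = 0.35 * template_length

    def draw_shape() -> np.ndarray:
        trough_width = rng.uniform(2.0, 6.5)
        rebound_delay = rng.uniform(1.8, 4.5) * trough_width
        rebound_width = trough_width * rng.uniform(1.2, 3.5)
        rebound_frac = rng.uniform(0.1, 0.6)
        shape = -np.exp(-((t - trough_center) ** 2) / (2 * trough_width**2))
        shape += rebound_frac * np.exp(
            -((t - trough_center - rebound_delay) ** 2) / (2 * rebound_width**2)
        )
        return shape / -shape.min()  # trough exactly -1

    templates = []
    accepted_shapes: list[np.ndarray] = []
    for nid in range(n_neurons):
        best, best_dist = None, -1.0
        for _ in range(1000):
            cand = draw_shape()
            dist = min(
                (_shape_distance(cand, s) for s in accepted_shapes), default=np.inf
            )
            if dist > best_dist:
                best, best_dist = cand, dist
            if dist >= min_shape_distance:
                break
        accepted_shapes.append(best)
        amp = rng.uniform(lo, hi)
        templates.append(
            SpikeTemplate(neuron_id=nid, waveform=best * -amp, peak_amplitude=amp)
        )
    return templates


def _poisson_train(
    rate: float, duration: float, refractory: float, rng: np.random.Generator
) -> np.ndarray:
    """Spike times (s) of a Poisson process thinned by a refractory dead time.

    The driving intensity is dead-time corrected, λ' = λ/(1−λτ), so the
    observed rate after thinning matches the configured rate.
    """
    if rate <= 0:
        return np.empty(0)
    lam = rate / max(1.0 - rate * refractory, 1e-9)
    # generate in one vectorized pass with ~6 sd headroom, then thin
    n_expect = lam * duration
    n_draw = int(n_expect + 6 * np.sqrt(n_expect) + 10)
    isis = rng.exponential(1.0 / lam, size=n_draw)
    times = np.cumsum(isis)
    while times[-1] < duration:  # pragma: no cover - headroom almost always enough
        extra = rng.exponential(1.0 / lam, size=n_draw // 2 + 10)
        times = np.concatenate([times, times[-1] + np.cumsum(extra)])
    times = times[times < duration]
    if refractory > 0 and len(times) > 1:
        kept = [times[0]]
        last = times[0]
        for ti in times[1:]:
            if ti - last >= refractory:
                kept.append(ti)
                last = ti
        times = np.asarray(kept)
    return times


def simulate_recording(
    templates: Sequence[SpikeTemplate], config: SimulationConfig
) -> tuple[RawRecording, GroundTruth]:
    """Synthesize one recording: Gaussian noise plus template insertions.

    Each neuron fires as an independent refractory-thinned Poisson
    process; its template is added (linear superposition, collisions
    allowed) with the trough landing on the spike's sample index.  Spikes
    whose full waveform would not fit inside the recording are skipped.

    Returns
    -------
    (RawRecording, GroundTruth)
        The voltage trace and every inserted spike (trough sample index,
        neuron label), sorted by time.
    """
    if len(templates) == 0:
        raise ValueError("templates must be non-empty")
    config.validate()
    if len(templates) != config.n_neurons:
        raise ValueError(
            f"got {len(templates)} templates for n_neurons={config.n_neurons}"
        )
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    duration = config.resolved_duration()
    n = int(round(duration * fs))
    rates = config.rates_array()

    signal = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 else np.zeros(n)

    jitter = config.width_jitter_sd > 0 or config.amp_jitter_range != (1.0, 1.0)
    a_lo, a_hi = config.amp_jitter_range

    all_times: list[np.ndarray] = []
    all_labels: list[np.ndarray] = []
    for tmpl, rate in zip(templates, rates):
        times_s = _poisson_train(rate, duration, config.refractory, rng)
        w0 = tmpl.waveform
        k0 = tmpl.trough_index
        t_base = np.arange(len(w0), dtype=float)
        kept = []
        for ts in times_s:
            idx = int(round(ts * fs))
            if jitter:
                stretch = float(np.clip(rng.normal(1.0, config.width_jitter_sd),
                                        0.8, 1.25)) if config.width_jitter_sd > 0 else 1.0
                ampf = rng.uniform(a_lo, a_hi)
                w = np.interp((t_base - k0) / stretch + k0, t_base, w0,
                              left=0.0, right=0.0) * ampf
                k = int(np.argmin(w))
            else:
                w, k = w0, k0
            start = idx - k
            stop = start + len(w)
            if start < 0 or stop > n:
                continue
            signal[start:stop] += w
            kept.append(idx)
        all_times.append(np.asarray(kept, dtype=np.int64))
        all_labels.append(np.full(len(kept), tmpl.neuron_id, dtype=np.int64))

    times = np.concatenate(all_times) if all_times else np.empty(0, dtype=np.int64)
    labels = np.concatenate(all_labels) if all_labels else np.empty(0, dtype=np.int64)
    order = np.argsort(times, kind="stable")
    truth = GroundTruth(
        spike_times=times[order], neuron_labels=labels[order], n_neurons=len(templates)
    )
    rec = RawRecording(samples=signal, sampling_rate=fs)
    return rec, truth


#: Per-neuron firing rates (Hz) of the five benchmark units.  Cultured
#: hippocampal neurons fire at strongly heterogeneous rates (roughly
#: log-spread), so the benchmark clusters are deliberately imbalanced;
#: the total (60 Hz) keeps the spike-collision fraction moderate.
BENCHMARK_FIRING_RATES = (2.0, 4.0, 8.0, 16.0, 30.0)


def make_benchmark_suite(
    size_class: str,
    n_sets: int = 10,
    scale_factor: float = 1.0,
    rng_seed: int = 0,
    n_neurons: int = 5,
    firing_rates: Sequence[float] | float = BENCHMARK_FIRING_RATES,
    noise_sd: float = 10.0,
    amplitude_range: tuple[float, float] = (-75.0, -120.0),
    width_jitter_sd: float = 0.05,
    amp_jitter_range: tuple[float, float] = (0.85, 1.0),
) -> list[tuple[RawRecording, GroundTruth]]:
    """Generate ``n_sets`` independent ground-truthed benchmark recordings.

    ``size_class`` selects the target spike count (``"small"`` → 100 000,
    ``"large"`` → 1 100 000) which is multiplied by ``scale_factor``; each
    set gets its own template bank and noise realization from seeds derived
    deterministically from ``rng_seed``.
    """
    if size_class not in BENCHMARK_SPIKE_COUNTS:
        raise ValueError(f"unknown size_class {size_class!r}; use 'small' or 'large'")
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    if not (0 < scale_factor <= 1):
        raise ValueError("scale_factor must be in (0, 1]")
    target = int(round(BENCHMARK_SPIKE_COUNTS[size_class] * scale_factor))
    ss = np.random.SeedSequence(rng_seed)
    seeds = ss.generate_state(2 * n_sets).astype(np.int64) % (2**31)
    suite = []
    for i in range(n_sets):
        templates = make_templates(
            n_neurons, 64, amplitude_range, rng_seed=int(seeds[2 * i])
        )
        config = SimulationConfig(
            n_neurons=n_neurons,
            firing_rates=firing_rates,
            noise_sd=noise_sd,
            target_spike_count=target,
            seed=int(seeds[2 * i + 1]),
            width_jitter_sd=width_jitter_sd,
            amp_jitter_range=amp_jitter_range,
        )
        suite.append(simulate_recording(templates, config))
    return suite


def simulate_calcium_trace(
    truth: GroundTruth,
    frame_interval: float = 0.0125,
    kernel_tau: float = 0.5,
    bleach_coeffs: Sequence[float] = (0.0,),
    noise_sd: float = 0.0,
    rng_seed: int = 0,
    sampling_rate: float = 20_000.0,
    n_frames: int | None = None,
) -> CalciumTrace:
    """Synthesize a fluorescence trace coupled to a ground-truth spike train.

    The trace is a bleach polynomial (coefficients in increasing degree,
    evaluated on time in seconds) plus one unit-amplitude exponential-decay
    kernel per spike (decay constant ``kernel_tau``), sampled every
    ``frame_interval`` seconds, plus white Gaussian noise.  Spike sample
    indices in ``truth`` are converted to seconds via ``sampling_rate``.
    An empty ground truth is allowed and yields bleach + noise only.
    """
    if frame_interval <= 0:
        raise ValueError("frame_interval must be > 0")
    if kernel_tau <= 0:
        raise ValueError("kernel_tau must be > 0")
    spike_s = np.asarray(truth.spike_times, dtype=float) / sampling_rate
    if n_frames is None:
        span = spike_s.max() + 5 * kernel_tau if len(spike_s) else 1.0
        n_frames = int(np.ceil(span / frame_interval)) + 1
    t = np.arange(n_frames) * frame_interval
    trace = np.polynomial.polynomial.polyval(t, np.asarray(bleach_coeffs, dtype=float))
    for ts in spike_s:
        dt = t - ts
        mask = dt >= 0
        trace[mask] += np.exp(-dt[mask] / kernel_tau)
    if noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        trace = trace + rng.normal(0.0, noise_sd, size=n_frames)
    return CalciumTrace(intensities=trace, frame_interval=frame_interval)
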