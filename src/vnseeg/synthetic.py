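"""Synthetic VNS-iEEG recordings with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: 1/f-spectrum background noise on every electrode, a 2 x 2
(stimulation frequency x amplitude) block design with ~30 trials per
condition, biphasic pulse-train artifacts that bleed onto every neural
channel, a clean pulse train on an auxiliary sync channel, optional bad
channels and ictal intervals, and -- on electrodes belonging to planted
spatial clusters -- a condition-dependent shift of band-limited amplitude
inside a fixed post-onset window.

Planted effect sizes are expressed on the z-scale of the downstream
single-trial normalization (baseline-mean / full-epoch-SD).  For Gaussian
band-limited noise the analytic envelope is Rayleigh distributed, so
multiplying the in-band component by a gain g inside the effect window
shifts the mean envelope by (g - 1)*sqrt(pi/(4 - pi)) envelope-SD units.
``calibrated_gain_solver`` refines this first-order rule for the full
measurement chain (band-filter leakage of the 1/f background and the
epoch-SD inflation caused by the effect itself); see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocess import ROI_LABELS, BandSpec, RawRecording

#: canonical presentation order of the 2 x 2 conditions
CONDITION_ORDER = (("low", "low"), ("low", "high"), ("high", "low"), ("high", "high"))

#: envelope-SD units of mean-envelope shift per unit of multiplicative gain
#: (Rayleigh: mean = sigma*sqrt(pi/2), sd = sigma*sqrt((4-pi)/2))
_RAYLEIGH_SHIFT = float(np.sqrt((4 - np.pi) / np.pi))


@dataclass(frozen=True)
class StimProtocol:
    """Stimulation-train parameters for one VNS modality.

    iVNS and taVNS-matched use the rapid duty cycle (2 s linear ramp up,
    7 s plateau, 2 s ramp down, then rest); taVNS-short delivers a burst of
    15 pulses with no ramp.
    """

    modality: str  # 'iVNS' | 'taVNS-matched' | 'taVNS-short'
    pulse_frequency: float  # Hz
    amplitude_level: str  # 'high' | 'low'
    amplitude: float  # mA
    pulse_width_us: float = 250.0
    ramp_duration: float = 2.0
    plateau_duration: float = 7.0
    inter_train_interval: float = 8.0
    n_pulses_per_burst: int | None = None

    def __post_init__(self) -> None:
        if self.modality not in ("iVNS", "taVNS-matched", "taVNS-short"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.amplitude_level not in ("high", "low"):
            raise ValueError("amplitude_level must be 'high' or 'low'")
        if self.modality == "taVNS-short":
            if self.ramp_duration != 0:
                raise ValueError("taVNS-short bursts have no ramp")
            if self.n_pulses_per_burst is None or self.n_pulses_per_burst < 1:
                raise ValueError("taVNS-short requires n_pulses_per_burst >= 1")
        else:
            if self.ramp_duration != 2.0 or self.plateau_duration != 7.0:
                raise ValueError(
                    "iVNS/taVNS-matched use the fixed duty cycle "
                    "(2 s ramp, 7 s plateau, 2 s ramp)"
                )

    @property
    def train_duration(self) -> float:
        """Active stimulation duration of one train (s)."""
        if self.modality == "taVNS-short":
            return self.n_pulses_per_burst / self.pulse_frequency
        return 2 * self.ramp_duration + self.plateau_duration

    @classmethod
    def ivns(cls, pulse_frequency: float = 30.0, amplitude: float = 1.0,
             amplitude_level: str = "high") -> "StimProtocol":
        return cls("iVNS", pulse_frequency, amplitude_level, amplitude)

    @classmethod
    def tavns_matched(cls, pulse_frequency: float = 30.0, amplitude: float = 1.0,
                      amplitude_level: str = "high") -> "StimProtocol":
        return cls("taVNS-matched", pulse_frequency, amplitude_level, amplitude)

    @classmethod
    def tavns_short(cls, pulse_frequency: float = 25.0, amplitude: float = 1.0,
                    amplitude_level: str = "high", n_pulses: int = 15) -> "StimProtocol":
        return cls(
            "taVNS-short", pulse_frequency, amplitude_level, amplitude,
            ramp_duration=0.0, plateau_duration=0.0, inter_train_interval=8.0,
            n_pulses_per_burst=n_pulses,
        )


@dataclass
class GroundTruth:
    """What the generator planted, for parameter-recovery tests."""

    cluster_assignment: np.ndarray  # per-electrode integer label, 1-based
    effect_window: tuple[float, float]  # s relative to onset
    effect_sizes: dict[tuple[str, str], tuple[float, ...]]  # (freq, amp) level -> per-cluster z-shift
    event_onsets: np.ndarray  # sample indices of train onsets
    pulse_times: np.ndarray  # sample indices of every pulse center
    events: pd.DataFrame | None = None  # one row per trial


def _default_effect_sizes() -> dict[tuple[str, str], tuple[float, float]]:
    # cluster 1 mirrors the observed pattern: high-frequency stimulation
    # raises low-frequency amplitude (~+0.28 z at high amplitude), low
    # frequency lowers it (~-0.25 z); cluster 2 responds with the opposite
    # sign at half magnitude
    return {
        ("low", "low"): (-0.12, 0.06),
        ("low", "high"): (-0.25, 0.12),
        ("high", "low"): (0.14, -0.07),
        ("high", "high"): (0.28, -0.14),
    }


@dataclass
class SynthConfig:
    """Knobs of the synthetic-recording generator.

    ``effect_sizes`` maps a (frequency_level, amplitude_level) condition to
    the per-cluster planted z-shift; electrodes are split into
    ``n_clusters`` contiguous groups.  The seed fully determines the output.
    """

    n_channels: int = 24
    sampling_rate: float = 4000.0
    n_trials_per_condition: int = 30
    noise_exponent: float = 1.5
    noise_sd: float = 20.0  # broadband background SD, microvolts
    effect_band: BandSpec = field(default_factory=lambda: BandSpec("theta", 4.0, 8.0))
    effect_window: tuple[float, float] = (2.0, 6.0)
    effect_sizes: dict[tuple[str, str], tuple[float, ...]] = field(
        default_factory=_default_effect_sizes
    )
    n_clusters: int = 2
    seed: int = 0
    bad_channel_fraction: float = 0.0
    ictal_segments: tuple[tuple[int, float, float], ...] = ()  # (channel, start_s, end_s)
    artifact_amplitude_uv: float = 500.0
    epoch_window: tuple[float, float] = (-4.0, 11.0)

    def __post_init__(self) -> None:
        if self.n_trials_per_condition < 1:
            raise ValueError("n_trials_per_condition must be >= 1")
        if not (0.5 <= self.effect_band.f_lo and self.effect_band.f_hi <= 20.0):
            raise ValueError("effect_band must lie within the 0.5-20 Hz analysis range")
        if self.n_channels < self.n_clusters:
            raise ValueError("need at least one channel per planted cluster")

    def cluster_assignment(self) -> np.ndarray:
        """Contiguous 1-based electrode-to-cluster split."""
        return (
            np.floor(np.arange(self.n_channels) * self.n_clusters / self.n_channels)
            .astype(int) + 1
        )


# ---------------------------------------------------------------------------
# pulse trains
# ---------------------------------------------------------------------------

def generate_pulse_train(
    protocol: StimProtocol, sampling_rate: float
) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize one stimulation train of biphasic square pulses.

    Returns (waveform, pulse_times).  Each pulse is a positive lobe followed
    by an equal negative lobe (each ``pulse_width_us`` long); pulse_times
    mark the center of each pulse (the lobe boundary).  For the rapid duty
    cycle each pulse is scaled by the ramp/plateau/ramp trapezoid evaluated
    at its center; taVNS-short bursts have a rectangular envelope.
    """
    fs = sampling_rate
    f = protocol.pulse_frequency
    if fs < 4 * f:
        raise ValueError(f"sampling rate {fs} Hz too low for {f} Hz pulses (need >= {4 * f})")
    lobe = int(round(protocol.pulse_width_us * 1e-6 * fs))
    if lobe < 1:
        min_fs = int(np.ceil(1e6 / protocol.pulse_width_us))
        raise ValueError(
            f"pulse width {protocol.pulse_width_us} us is shorter than one sample "
            f"at {fs} Hz; need sampling rate >= {min_fs} Hz"
        )

    if protocol.modality == "taVNS-short":
        n_pulses = protocol.n_pulses_per_burst
        duration = n_pulses / f
        def envelope(t: np.ndarray) -> np.ndarray:
            return np.ones_like(t)
    else:
        r, p = protocol.ramp_duration, protocol.plateau_duration
        duration = 2 * r + p
        n_pulses = int(round(duration * f))
        def envelope(t: np.ndarray) -> np.ndarray:
            up = np.clip(t / r, 0.0, 1.0)
            down = np.clip((duration - t) / r, 0.0, 1.0)
            return np.minimum(up, down)

    centers_s = (np.arange(n_pulses) + 0.5) / f
    env = envelope(centers_s) * protocol.amplitude
    n = int(round(duration * fs))
    wave = np.zeros(n)
    centers = np.round(centers_s * fs).astype(int)
    for c, a in zip(centers, env):
        wave[max(0, c - lobe) : c] += a
        wave[c : min(n, c + lobe)] -= a
    return wave, centers


# ---------------------------------------------------------------------------
# full recordings
# ---------------------------------------------------------------------------

def _one_over_f_noise(
    rng: np.random.Generator, n_samples: int, sampling_rate: float,
    exponent: float, sd: float, band: BandSpec | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Spectrally shaped Gaussian noise with power ~ 1/f^exponent, given SD.

    If ``band`` is given, also returns the in-band component of the same
    realization (brick-wall spectral split on the shared FFT).
    """
    from scipy import fft as sfft

    # synthesize on a 5-smooth length and crop: much faster FFTs
    n_fast = sfft.next_fast_len(n_samples)
    white = rng.standard_normal(n_fast)
    spec = sfft.rfft(white)
    freqs = sfft.rfftfreq(n_fast, d=1.0 / sampling_rate)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    spec *= shape
    x = sfft.irfft(spec, n=n_fast)[:n_samples]
    scale = sd / x.std()
    x *= scale
    if band is None:
        return x, None
    mask = (freqs >= band.f_lo) & (freqs <= band.f_hi)
    spec[~mask] = 0.0
    xb = sfft.irfft(spec, n=n_fast)[:n_samples] * scale
    return x, xb


def trial_schedule(
    config: SynthConfig, protocol: StimProtocol
) -> tuple[pd.DataFrame, float]:
    """Blocked trial order in canonical condition order.

    Returns (events, period_s); events has columns onset_s, modality,
    frequency_level, amplitude_level, frequency_hz, amplitude_ma.
    """
    freq_hz = {"high": protocol.pulse_frequency, "low": 10.0}
    if protocol.modality == "taVNS-short":
        epoch_pre = 2.0
    else:
        epoch_pre = -config.epoch_window[0]
    period = protocol.train_duration + protocol.inter_train_interval
    pre_pad = epoch_pre + 1.0
    rows = []
    i = 0
    for f_lvl, a_lvl in CONDITION_ORDER:
        for _ in range(config.n_trials_per_condition):
            rows.append(
                {
                    "onset_s": pre_pad + i * period,
                    "modality": protocol.modality,
                    "frequency_level": f_lvl,
                    "amplitude_level": a_lvl,
                    "frequency_hz": freq_hz[f_lvl],
                    "amplitude_ma": protocol.amplitude * (1.0 if a_lvl == "high" else 0.5),
                }
            )
            i += 1
    return pd.DataFrame(rows), period


def gain_for_z_shift(dz: float) -> float:
    """First-order in-band gain for a z-shift of ``dz`` (pure in-band noise)."""
    g = 1.0 + dz * _RAYLEIGH_SHIFT
    if g <= 0:
        raise ValueError(f"z-shift {dz} too negative to realize by gain modulation")
    return g


def calibrated_gain_solver(
    config: "SynthConfig", analysis_rate: float = 512.0
):
    """Build a solver mapping target z-shift -> in-band gain, pipeline-aware.

    The downstream analysis measures the Hilbert envelope after a 3rd-order
    Butterworth band-pass applied forward-backward, so the envelope mixes
    the modulated in-band noise with unmodulated out-of-band leakage of the
    1/f background (weight lambda), and the single-trial normalization
    divides by the full-epoch SD, which itself grows with the planted
    effect.  Both are accounted for analytically: with in-window variance
    v_w = g^2 + lambda and baseline variance v_b = 1 + lambda (in units of
    the filtered in-band power), the Rayleigh envelope has mean
    sqrt(pi*v/2) and variance (4-pi)*v/2, and the realized shift is
    (mu_w - mu_b) / S with S the mixture SD over the epoch.  The gain is
    solved by root finding.
    """
    from scipy.optimize import brentq
    from scipy.signal import butter, sosfreqz

    band = config.effect_band
    f = np.linspace(0.02, analysis_rate / 2 * 0.999, 8192)
    sos = butter(
        3, [band.f_lo, band.f_hi], btype="bandpass", fs=analysis_rate, output="sos"
    )
    _, h = sosfreqz(sos, worN=f, fs=analysis_rate)
    power_gain = np.abs(h) ** 4  # forward-backward: |H|^2 amplitude response
    spectrum = f ** (-config.noise_exponent)
    inband = (f >= band.f_lo) & (f <= band.f_hi)
    v_mod = np.trapezoid(spectrum * power_gain * inband, f)
    lam = np.trapezoid(spectrum * power_gain * ~inband, f) / v_mod
    t0, t1 = config.epoch_window
    w0, w1 = config.effect_window
    p = (w1 - w0) / (t1 - t0)

    def realized(g: float) -> float:
        v_b = 1.0 + lam
        v_w = g * g + lam
        mu_b = np.sqrt(np.pi * v_b / 2.0)
        mu_w = np.sqrt(np.pi * v_w / 2.0)
        s2 = (
            (1 - p) * (4 - np.pi) / 2.0 * v_b
            + p * (4 - np.pi) / 2.0 * v_w
            + p * (1 - p) * (mu_w - mu_b) ** 2
        )
        return (mu_w - mu_b) / np.sqrt(s2)

    def solve(dz: float) -> float:
        if dz == 0:
            return 1.0
        return float(brentq(lambda g: realized(g) - dz, 1e-3, 1e3))

    return solve


def generate_recording(
    config: SynthConfig, protocol: StimProtocol
) -> tuple[RawRecording, GroundTruth]:
    """Generate a full raw recording plus ground truth.

    Channels carry 1/f background noise; electrodes of each planted cluster
    additionally have their in-band (effect_band) component gain-modulated
    inside the effect window on every trial, by an amount set per condition
    from ``config.effect_sizes``.  The pulse-artifact train is added to every
    channel with a random per-channel gain in [0.05, 0.5] of the aux
    amplitude; the aux channel carries the clean train plus weak noise.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    events, period = trial_schedule(config, protocol)
    post_pad = max(config.epoch_window[1] - protocol.train_duration, 0.0) + 1.0
    total_s = float(events.onset_s.iloc[-1]) + protocol.train_duration + post_pad
    n_samples = int(round(total_s * fs))
    onsets = np.round(events.onset_s.to_numpy() * fs).astype(int)

    assignment = config.cluster_assignment()
    gain_of = calibrated_gain_solver(config)
    gains_by_cond = {
        cond: tuple(gain_of(d) for d in dz)
        for cond, dz in config.effect_sizes.items()
    }

    # effect gain profile per trial (same for all electrodes of a cluster,
    # scaled by the condition's planted z-shift); 100 ms cosine taper
    w0, w1 = config.effect_window
    win_len = int(round((w1 - w0) * fs))
    taper = np.ones(win_len)
    edge = min(int(round(0.1 * fs)), win_len // 2)
    if edge > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(edge) / edge))
        taper[:edge] = ramp
        taper[-edge:] = ramp[::-1]

    signal = np.empty((config.n_channels, n_samples))
    for ch in range(config.n_channels):
        x, band_part = _one_over_f_noise(
            rng, n_samples, fs, config.noise_exponent, config.noise_sd,
            band=config.effect_band,
        )
        cl = assignment[ch] - 1
        for onset, f_lvl, a_lvl in zip(
            onsets, events.frequency_level, events.amplitude_level
        ):
            g = gains_by_cond[(f_lvl, a_lvl)][cl]
            if g == 1.0:
                continue
            a = onset + int(round(w0 * fs))
            b = a + win_len
            if a < 0 or b > n_samples:
                continue
            x[a:b] += (g - 1.0) * taper * band_part[a:b]
        signal[ch] = x

    # stimulation artifact: clean train on aux, scaled bleed on every channel
    aux = np.zeros(n_samples)
    all_pulses = []
    freq_hz = {"high": protocol.pulse_frequency, "low": 10.0}
    for onset, f_lvl, a_lvl in zip(onsets, events.frequency_level, events.amplitude_level):
        p = replace(
            protocol,
            pulse_frequency=freq_hz[f_lvl],
            amplitude_level=a_lvl,
            amplitude=protocol.amplitude * (1.0 if a_lvl == "high" else 0.5),
        )
        wave, centers = generate_pulse_train(p, fs)
        wave = wave * (config.artifact_amplitude_uv / max(protocol.amplitude, 1e-12))
        end = min(n_samples, onset + len(wave))
        aux[onset:end] += wave[: end - onset]
        all_pulses.append(centers + onset)
    pulse_times = np.concatenate(all_pulses) if all_pulses else np.array([], dtype=int)
    gains = rng.uniform(0.05, 0.5, size=config.n_channels)
    signal += gains[:, None] * aux[None, :]
    aux = aux + rng.normal(0.0, config.artifact_amplitude_uv / 20.0, size=n_samples)

    channel_ids = [f"ch{idx:03d}" for idx in range(config.n_channels)]
    rois = [ROI_LABELS[idx % len(ROI_LABELS)] for idx in range(config.n_channels)]

    n_bad = int(round(config.bad_channel_fraction * config.n_channels))
    bad = set()
    if n_bad > 0:
        for idx in rng.choice(config.n_channels, size=n_bad, replace=False):
            signal[idx] = rng.normal(0.0, 5.0 * config.noise_sd, size=n_samples)
            bad.add(channel_ids[idx])

    ictal: dict[str, list[tuple[int, int]]] = {}
    for ch_idx, start_s, end_s in config.ictal_segments:
        ictal.setdefault(channel_ids[ch_idx], []).append(
            (int(round(start_s * fs)), int(round(end_s * fs)))
        )

    events = events.assign(onset_sample=onsets)
    rec = RawRecording(
        signal=signal, sampling_rate=fs, aux=aux,
        channel_ids=channel_ids, roi_labels=rois,
        bad_channels=bad, ictal_intervals=ictal,
    )
    truth = GroundTruth(
        cluster_assignment=assignment,
        effect_window=config.effect_window,
        effect_sizes=dict(config.effect_sizes),
        event_onsets=onsets,
        pulse_times=np.sort(pulse_times),
        events=events,
    )
    return rec, truth


# ---------------------------------------------------------------------------
# fast path: pre-epoched z-scale trial tensors
# ---------------------------------------------------------------------------

def generate_trial_tensor(config: SynthConfig):
    """Directly generate a z-scale trial tensor, bypassing signal synthesis.

    Unit-SD Gaussian noise per electrode x time x trial, with the planted
    per-condition mean shift added inside the effect window for electrodes
    of each cluster.  Labels are balanced across the 2 x 2 design and
    blocked in canonical condition order.
    """
    from .epochs import TrialTensor

    rng = np.random.default_rng(config.seed)
    t0, t1 = config.epoch_window
    rate = 100.0
    n_t = int(round((t1 - t0) * rate))
    time_axis = t0 + np.arange(n_t) / rate
    n_trials = 4 * config.n_trials_per_condition
    f_lvl = np.repeat([c[0] for c in CONDITION_ORDER], config.n_trials_per_condition)
    a_lvl = np.repeat([c[1] for c in CONDITION_ORDER], config.n_trials_per_condition)

    z = rng.standard_normal((config.n_channels, n_t, n_trials))
    assignment = config.cluster_assignment()
    w = (time_axis >= config.effect_window[0]) & (time_axis < config.effect_window[1])
    for tr in range(n_trials):
        dz = config.effect_sizes[(f_lvl[tr], a_lvl[tr])]
        for ch in range(config.n_channels):
            d = dz[assignment[ch] - 1]
            if d:
                z[ch, w, tr] += d

    labels = pd.DataFrame({"frequency_level": f_lvl, "amplitude_level": a_lvl})
    tensor = TrialTensor(
        z=z, time_axis=time_axis, condition=labels,
        band=config.effect_band, modality="iVNS",
        channel_ids=[f"ch{idx:03d}" for idx in range(config.n_channels)],
    )
    truth = GroundTruth(
        cluster_assignment=assignment,
        effect_window=config.effect_window,
        effect_sizes=dict(config.effect_sizes),
        event_onsets=np.array([], dtype=int),
        pulse_times=np.array([], dtype=int),
        events=labels,
    )
    return tensor, truth
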