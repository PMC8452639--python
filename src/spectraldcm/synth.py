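"""Synthetic electrophysiology with known ground truth.

Generates the three kinds of input the analysis pipeline consumes:

* **Synaptic-event traces** emulating whole-cell voltage-clamp recordings of
  spontaneous EPSCs/IPSCs: Poisson event timing, log-normal amplitudes,
  bi-exponential kernels, Gaussian baseline noise.  Condition effects encode
  the NMDAR-antibody phenotype — EPSCs become sparser (longer interevent
  intervals), smaller and faster-decaying, IPSCs are unchanged, and the
  7-day condition is more severe than 48 h.
* **Field recordings** emulating hippocampal LFP/EEG: 1/f-type background,
  suprathreshold interictal transients, and ictal epochs with multiplied
  spike rates and added 12-30 Hz band-limited (beta) oscillation.
* **State spectra**: noisy log-domain observations of canonical-microcircuit
  power spectra at known parameter triplets, standing in for the empirically
  measured control / interictal / ictal spectra.

Every generator is a pure function of its configuration including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .cmc import CMCParameters, SpectralDensity, predict_psd, stability
from .ephys import TraceRecording

__all__ = [
    "SynapticTraceConfig",
    "ConditionEffects",
    "FieldTraceConfig",
    "GroundTruth",
    "CONDITION_EFFECTS",
    "sample_event_train",
    "biexp_kernel",
    "render_synaptic_trace",
    "make_condition_config",
    "render_field_trace",
    "generate_state_psd_data",
    "NOMINAL_CONTRAST_RATIOS",
    "DEFAULT_ICTO_SHIFTS",
    "default_state_lambdas",
    "default_state_params",
]


@dataclass(frozen=True)
class SynapticTraceConfig:
    """Configuration of a synthetic voltage-clamp trace.

    Defaults describe a control-condition sEPSC recording: 2 events/s with
    median amplitude 15 pA, 1/8 log-sd, 0.8/8 ms rise/decay, 2 pA baseline
    noise, inward (negative) polarity.
    """

    duration: float = 60.0          # s
    sampling_rate: float = 10_000.0  # Hz
    event_rate: float = 2.0         # events/s
    amp_median: float = 15.0        # pA
    amp_log_sd: float = 0.35
    tau_rise: float = 0.8           # ms
    tau_decay: float = 8.0          # ms
    noise_sd: float = 2.0           # pA
    polarity: str = "inward"
    seed: int = 0

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.sampling_rate < 1000.0:
            raise ValueError("sampling_rate must be at least 1000 Hz")
        if self.event_rate < 0:
            raise ValueError("event_rate must be non-negative")
        if not 0 <= self.tau_rise < self.tau_decay:
            raise ValueError("need 0 <= tau_rise < tau_decay")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.polarity not in ("inward", "outward"):
            raise ValueError("polarity must be 'inward' or 'outward'")


@dataclass(frozen=True)
class ConditionEffects:
    """Multiplicative condition effects on synaptic transmission.

    The NMDAR-antibody conditions reduce EPSC rate, amplitude and decay time
    (rate even further at 7 days); IPSCs are unaffected in every condition.
    """

    condition: str                 # 'control' | 'nmdar_48h' | 'nmdar_7d'
    rate_mult: float = 1.0
    amp_mult: float = 1.0
    decay_mult: float = 1.0
    amp_logsd_mult: float = 1.0    # < 1: more homogeneous amplitudes
    applies_to: str = "EPSC"       # 'EPSC' | 'IPSC'

    def __post_init__(self):
        if self.condition not in ("control", "nmdar_48h", "nmdar_7d"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.applies_to not in ("EPSC", "IPSC"):
            raise ValueError("applies_to must be 'EPSC' or 'IPSC'")
        if min(self.rate_mult, self.amp_mult, self.decay_mult,
               self.amp_logsd_mult) <= 0:
            raise ValueError("multipliers must be positive")
        if self.applies_to == "IPSC" and (
            self.rate_mult != 1 or self.amp_mult != 1 or self.decay_mult != 1
            or self.amp_logsd_mult != 1
        ):
            raise ValueError("IPSC multipliers are 1 in every condition")
        if self.applies_to == "EPSC" and self.condition != "control":
            if not (self.rate_mult < 1 and self.amp_mult < 1 and self.decay_mult < 1):
                raise ValueError(
                    "NMDAR conditions reduce EPSC rate, amplitude and decay"
                )


#: Default condition effects.  Magnitudes preserve the observed effect
#: directions (fewer, smaller, faster and more homogeneous EPSCs; 7 d
#: sparser than 48 h; IPSCs unchanged); they are generator conventions, not
#: fitted estimates.
CONDITION_EFFECTS: dict[tuple[str, str], ConditionEffects] = {
    ("control", "EPSC"): ConditionEffects("control", applies_to="EPSC"),
    ("control", "IPSC"): ConditionEffects("control", applies_to="IPSC"),
    ("nmdar_48h", "EPSC"): ConditionEffects(
        "nmdar_48h", rate_mult=0.6, amp_mult=0.8, decay_mult=0.7,
        amp_logsd_mult=0.85, applies_to="EPSC",
    ),
    ("nmdar_48h", "IPSC"): ConditionEffects("nmdar_48h", applies_to="IPSC"),
    ("nmdar_7d", "EPSC"): ConditionEffects(
        "nmdar_7d", rate_mult=0.45, amp_mult=0.7, decay_mult=0.7,
        amp_logsd_mult=0.8, applies_to="EPSC",
    ),
    ("nmdar_7d", "IPSC"): ConditionEffects("nmdar_7d", applies_to="IPSC"),
}


@dataclass(frozen=True)
class FieldTraceConfig:
    """Configuration of a synthetic field (LFP/EEG) recording."""

    duration: float = 120.0
    sampling_rate: float = 1000.0
    background_exponent: float = 1.5   # beta of the 1/f^beta background
    background_scale: float = 20.0     # target background RMS, uV
    spike_rate: float = 0.5            # interictal transients per second
    spike_amp_factor: float = 8.0      # multiples of background RMS
    spike_tau_rise: float = 2.0        # ms
    spike_tau_decay: float = 20.0      # ms
    ictal_epochs: tuple = ()           # (start s, end s, beta_amp uV, rate mult)
    seed: int = 0

    def __post_init__(self):
        if self.duration <= 0 or self.sampling_rate < 200:
            raise ValueError("invalid duration or sampling rate")
        if self.spike_rate < 0 or self.background_scale < 0:
            raise ValueError("rates and scales must be non-negative")
        if self.spike_tau_rise >= self.spike_tau_decay:
            raise ValueError("spike_tau_rise must be below spike_tau_decay")
        epochs = tuple(tuple(e) for e in self.ictal_epochs)
        object.__setattr__(self, "ictal_epochs", epochs)
        prev_end = -np.inf
        for start, end, beta_amp, rate_mult in sorted(epochs):
            if not 0 <= start < end <= self.duration:
                raise ValueError("ictal epochs must lie within the recording")
            if start < prev_end:
                raise ValueError("ictal epochs must not overlap")
            if beta_amp < 0 or rate_mult < 0:
                raise ValueError("epoch amplitude and rate multiplier must be >= 0")
            prev_end = end


@dataclass(frozen=True)
class GroundTruth:
    """Event times/amplitudes and labelled epochs behind a synthetic trace."""

    event_times: np.ndarray
    event_amps: np.ndarray
    epoch_labels: tuple = ()

    def __post_init__(self):
        times = np.asarray(self.event_times, dtype=float)
        amps = np.asarray(self.event_amps, dtype=float)
        object.__setattr__(self, "event_times", times)
        object.__setattr__(self, "event_amps", amps)
        if times.size and np.any(np.diff(times) < 0):
            raise ValueError("event times must be sorted")

    def to_dict(self) -> dict:
        return {
            "event_times": self.event_times.tolist(),
            "event_amps": self.event_amps.tolist(),
            "epoch_labels": [list(e) for e in self.epoch_labels],
        }


def sample_event_train(rate: float, duration: float, seed: int | None = None):
    """Event times of a homogeneous Poisson process on [0, duration)."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration, n))


def biexp_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Time (ms) from kernel onset to its peak; 0 in the mono-exponential limit."""
    if tau_rise <= 0:
        return 0.0
    return (
        tau_rise * tau_decay / (tau_decay - tau_rise) * np.log(tau_decay / tau_rise)
    )


def biexp_kernel(t: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Unit-peak bi-exponential kernel exp(-t/tau_d) - exp(-t/tau_r), t >= 0 ms.

    In the tau_rise -> 0 limit the kernel is a mono-exponential decay."""
    t = np.asarray(t, dtype=float)
    if tau_rise <= 0:
        w = np.exp(-t / tau_decay)
    else:
        w = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
        t_peak = (
            tau_rise * tau_decay / (tau_decay - tau_rise)
            * np.log(tau_decay / tau_rise)
        )
        peak = np.exp(-t_peak / tau_decay) - np.exp(-t_peak / tau_rise)
        w = w / peak
    w[t < 0] = 0.0
    return w


def render_synaptic_trace(config: SynapticTraceConfig):
    """Render a synaptic-event trace; returns (TraceRecording, GroundTruth).

    The trace is a sum of unit-peak bi-exponential kernels scaled by
    log-normal amplitudes (median ``amp_median``, log-sd ``amp_log_sd``) at
    Poisson event times, plus white Gaussian baseline noise; inward polarity
    flips the sign.
    """
    fs = config.sampling_rate
    n = int(round(config.duration * fs))
    kernel_len_s = (config.tau_decay * 8.0 + config.tau_rise) / 1000.0
    if kernel_len_s >= config.duration:
        raise ValueError("event kernel is longer than the trace")
    rng = np.random.default_rng(config.seed)
    n_ev = rng.poisson(config.event_rate * config.duration)
    times = np.sort(rng.uniform(0.0, config.duration, n_ev))
    amps = np.exp(rng.normal(np.log(config.amp_median), config.amp_log_sd, n_ev))

    t_k = np.arange(int(round(kernel_len_s * fs))) / fs * 1000.0  # ms
    kernel = biexp_kernel(t_k, config.tau_rise, config.tau_decay)
    x = np.zeros(n + kernel.size)
    for t0, a in zip(times, amps):
        i0 = int(round(t0 * fs))
        x[i0: i0 + kernel.size] += a * kernel
    x = x[:n]
    if config.noise_sd > 0:
        x = x + rng.normal(0.0, config.noise_sd, n)
    if config.polarity == "inward":
        x = -x
    trace = TraceRecording(samples=x, sampling_rate=fs, units="pA")
    # ground-truth times refer to event PEAKS (what detectors report)
    t_peak = biexp_peak_time(config.tau_rise, config.tau_decay) / 1000.0
    return trace, GroundTruth(event_times=times + t_peak, event_amps=amps)


def make_condition_config(
    base: SynapticTraceConfig, effects: ConditionEffects
) -> SynapticTraceConfig:
    """Apply condition multipliers to rate, amplitude, decay and dispersion."""
    return replace(
        base,
        event_rate=base.event_rate * effects.rate_mult,
        amp_median=base.amp_median * effects.amp_mult,
        tau_decay=base.tau_decay * effects.decay_mult,
        amp_log_sd=base.amp_log_sd * effects.amp_logsd_mult,
    )


def _one_over_f_background(
    n: int, fs: float, beta: float, rms: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian background spectrally shaped to 1/f^beta, scaled to target RMS."""
    w = rng.standard_normal(n)
    W = np.fft.rfft(w)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(f)
    nz = f > 0
    shape[nz] = f[nz] ** (-beta / 2.0)
    W *= shape
    x = np.fft.irfft(W, n)
    cur = np.sqrt(np.mean(x**2))
    return x * (rms / cur) if cur > 0 else x


def _band_limited_noise(
    n: int, fs: float, lo: float, hi: float, rms: float, rng: np.random.Generator
) -> np.ndarray:
    w = rng.standard_normal(n)
    W = np.fft.rfft(w)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    W[(f < lo) | (f > hi)] = 0.0
    x = np.fft.irfft(W, n)
    cur = np.sqrt(np.mean(x**2))
    return x * (rms / cur) if cur > 0 else x


def render_field_trace(config: FieldTraceConfig):
    """Render a field recording; returns (TraceRecording, GroundTruth).

    Background: 1/f^beta Gaussian noise at the configured RMS.  Interictal
    transients: bi-exponential spikes of amplitude ``spike_amp_factor`` times
    the background RMS at Poisson times.  Within each ictal epoch the spike
    rate is multiplied and a 12-30 Hz band-limited oscillation of RMS
    ``beta_amp`` is added.
    """
    fs = config.sampling_rate
    n = int(round(config.duration * fs))
    rng = np.random.default_rng(config.seed)
    x = _one_over_f_background(
        n, fs, config.background_exponent, config.background_scale, rng
    )

    # piecewise-constant spike rate: baseline outside epochs, multiplied inside
    epochs = sorted(config.ictal_epochs)
    times = []
    bounds = []
    prev = 0.0
    for start, end, beta_amp, rate_mult in epochs:
        bounds.append((prev, start, config.spike_rate))
        bounds.append((start, end, config.spike_rate * rate_mult))
        prev = end
    bounds.append((prev, config.duration, config.spike_rate))
    for lo, hi, rate in bounds:
        if hi > lo and rate > 0:
            k = rng.poisson(rate * (hi - lo))
            times.extend(rng.uniform(lo, hi, k))
    times = np.sort(np.asarray(times, dtype=float))

    t_k = (
        np.arange(int(round((config.spike_tau_decay * 8.0) / 1000.0 * fs)))
        / fs * 1000.0
    )
    kernel = biexp_kernel(t_k, config.spike_tau_rise, config.spike_tau_decay)
    amp = config.spike_amp_factor * config.background_scale
    pad = np.zeros(n + kernel.size)
    for t0 in times:
        i0 = int(round(t0 * fs))
        pad[i0: i0 + kernel.size] += amp * kernel
    x = x + pad[:n]

    labels = []
    for start, end, beta_amp, rate_mult in epochs:
        i0, i1 = int(round(start * fs)), int(round(end * fs))
        if beta_amp > 0:
            osc = _band_limited_noise(i1 - i0, fs, 12.0, 30.0, beta_amp, rng)
            x[i0:i1] = x[i0:i1] + osc
        labels.append((start, end, "ictal"))

    trace = TraceRecording(samples=x, sampling_rate=fs, units="uV")
    t_peak = biexp_peak_time(config.spike_tau_rise, config.spike_tau_decay) / 1000.0
    truth = GroundTruth(
        event_times=times + t_peak,  # peak-referenced, see render_synaptic_trace
        event_amps=np.full(times.size, amp),
        epoch_labels=tuple(labels),
    )
    return trace, truth


#: Nominal microscale feature ratios of the default nmdar_48h EPSC condition
#: (amplitude x0.8, half-life x0.7, CDF slope x 1/(0.8*0.85)); the slope
#: ratio follows from amplitude scaling and the homogeneity increase.
NOMINAL_CONTRAST_RATIOS = {
    "amplitude": 0.8,
    "half_life": 0.7,
    "slope": 1.0 / (0.8 * 0.85),
}

#: Ictogenesis direction of the default state triplet: reduced inhibitory
#: self-modulation and increased deep-pyramidal drive onto interneurons —
#: an excitation/inhibition balance shift within the deep oscillator pair.
DEFAULT_ICTO_SHIFTS = {"gamma8": -0.15, "gamma2": 0.10}


def default_state_lambdas() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Log-scaling vectors of the documented default state triplet.

    * control: the baseline circuit (lambda = 0);
    * interictal: the NMDAR-antibody effect — deep-pair couplings scaled by
      the nominal EPSC amplitude ratio and deep-pair sigmoid slopes by the
      nominal CDF-slope ratio (the winning prior-placement structure);
    * ictal: interictal plus the ictogenesis shifts.

    Returns (lambda_control, lambda_interictal, lambda_ictal); all three
    parameterize stable circuits, the ictal one near-critically so.
    """
    from .cmc import GAMMA_TARGETS
    from .inversion import PARAM_NAMES

    lam0 = np.zeros(18)
    d_gamma = np.log(NOMINAL_CONTRAST_RATIOS["amplitude"])
    d_sigma = np.log(NOMINAL_CONTRAST_RATIOS["slope"])
    depi = np.zeros(18)
    for i, name in enumerate(PARAM_NAMES):
        if name.startswith("gamma") and GAMMA_TARGETS[int(name[5:]) - 1] in ("ii", "dp"):
            depi[i] = d_gamma
        elif name in ("sigma_ii", "sigma_dp"):
            depi[i] = d_sigma
    dicto = np.zeros(18)
    for name, shift in DEFAULT_ICTO_SHIFTS.items():
        dicto[PARAM_NAMES.index(name)] = shift
    return lam0, depi, lam0 + depi + dicto


def default_state_params(
    base: CMCParameters | None = None,
) -> tuple[CMCParameters, CMCParameters, CMCParameters]:
    """Parameter sets of the default control/interictal/ictal triplet."""
    base = base or CMCParameters()
    lam0, lam1, lam2 = default_state_lambdas()
    return (
        base.with_scaling(lam0),
        base.with_scaling(lam1),
        base.with_scaling(lam2),
    )


def generate_state_psd_data(
    params_triplet: Sequence[CMCParameters],
    log_noise_sd: float,
    freqs: np.ndarray,
    seed: int | None = None,
) -> list[SpectralDensity]:
    """Noisy "observed" spectra for a triplet of circuit states.

    The observed log-PSD is the model log-PSD plus independent Gaussian
    noise of standard deviation ``log_noise_sd`` per frequency, per state —
    a stand-in for empirically measured control / interictal / ictal spectra
    with known generating parameters.
    """
    if len(params_triplet) != 3:
        raise ValueError("expected exactly three parameter sets")
    if log_noise_sd < 0:
        raise ValueError("log_noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    out = []
    for params in params_triplet:
        log_psd = np.log(predict_psd(params, freqs).values)  # raises if unstable
        noisy = log_psd + rng.normal(0.0, log_noise_sd, log_psd.size)
        out.append(SpectralDensity(freqs=np.asarray(freqs, float), values=np.exp(noisy)))
    return out
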