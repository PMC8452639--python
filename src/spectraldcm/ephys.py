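"""Operational electrophysiology metrics.

Implements the signal measures used to quantify epileptiform activity in
field recordings and synaptic function in patch-clamp recordings:

* interictal event detection by a 4x-RMS amplitude threshold with a 15 ms
  interevent-interval refractory rule;
* coastline (per-window total variation) of EEG/LFP traces;
* band power over the eight standard analysis bands (1-4 ... 120-180 Hz);
* six per-second segment metrics (power, coastline, intermittency, coherence,
  asymmetry, spikiness) and nearest-neighbour segment classification against
  a labelled library;
* synaptic feature extraction from voltage-clamp traces: mean event
  amplitude, interevent intervals, mono-exponential decay constant and
  half-life, and the midpoint slope of a logistic fit to the cumulative
  amplitude distribution (a homogeneity index).

The segment-metric formulas are reconstructions: the original analysis used
external classifier software whose exact definitions are not published; the
definitions used here are stated in each docstring and in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, signal, stats

__all__ = [
    "DEFAULT_BANDS",
    "TraceRecording",
    "DetectedEventSet",
    "BandPowerTable",
    "SegmentMetrics",
    "SynapticFeatureSet",
    "InsufficientEventsError",
    "rms",
    "detect_events",
    "interevent_intervals",
    "coastline",
    "band_power",
    "segment_metrics",
    "classify_segment",
    "extract_synaptic_features",
]

#: The eight standard analysis bands (Hz).
DEFAULT_BANDS: tuple[tuple[float, float], ...] = (
    (1, 4), (4, 8), (8, 12), (12, 30), (30, 50), (50, 70), (70, 120), (120, 180),
)

#: Welch settings used throughout: 2 s Hann windows, 50% overlap.
WELCH_WINDOW_S = 2.0
WELCH_OVERLAP = 0.5

#: Cap on the logistic midpoint slope for degenerate (step-like) amplitude CDFs.
SIGMOID_SLOPE_CAP = 1e6


class InsufficientEventsError(ValueError):
    """Raised when a feature extraction needs more detected events."""


@dataclass(frozen=True)
class TraceRecording:
    """A uniformly sampled single-channel recording."""

    samples: np.ndarray
    sampling_rate: float
    units: str = "a.u."

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if samples.size and not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate


@dataclass(frozen=True)
class DetectedEventSet:
    """Events found by threshold crossing, after the refractory rule."""

    times: np.ndarray
    peak_amplitudes: np.ndarray
    threshold_used: float
    rms: float

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(
            self, "peak_amplitudes", np.asarray(self.peak_amplitudes, dtype=float)
        )

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class BandPowerTable:
    bands: tuple[tuple[float, float], ...]
    power: np.ndarray
    total_power: float

    def as_dict(self) -> dict[str, float]:
        return {f"{lo:g}-{hi:g}Hz": float(p) for (lo, hi), p in zip(self.bands, self.power)}


@dataclass(frozen=True)
class SegmentMetrics:
    """Six scalar metrics of a one-second segment."""

    power: float
    coastline: float
    intermittency: float
    coherence: float
    asymmetry: float
    spikiness: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.power, self.coastline, self.intermittency,
             self.coherence, self.asymmetry, self.spikiness]
        )


@dataclass(frozen=True)
class SynapticFeatureSet:
    """Summary features of synaptic events in a voltage-clamp trace."""

    mean_amplitude: float          # pA
    ieis: np.ndarray               # ms
    decay_tau: float               # ms
    half_life: float               # ms  (= decay_tau * ln 2)
    sigmoid_midpoint_slope: float  # 1/pA
    n_events: int
    slope_capped: bool = False

    def as_dict(self) -> dict:
        return {
            "mean_amplitude": self.mean_amplitude,
            "mean_iei_ms": float(np.mean(self.ieis)) if len(self.ieis) else float("nan"),
            "decay_tau_ms": self.decay_tau,
            "half_life_ms": self.half_life,
            "sigmoid_midpoint_slope": self.sigmoid_midpoint_slope,
            "n_events": self.n_events,
        }


def rms(trace: TraceRecording) -> float:
    """Root-mean-square amplitude of the mean-subtracted recording."""
    x = trace.samples
    if x.size == 0:
        raise ValueError("cannot compute RMS of an empty trace")
    return float(np.sqrt(np.mean((x - x.mean()) ** 2)))


def detect_events(
    trace: TraceRecording,
    threshold_factor: float = 4.0,
    min_iei: float = 15.0,
    polarity: str | None = None,
) -> DetectedEventSet:
    """Detect epileptiform/synaptic events by amplitude threshold.

    Samples deviating from the mean by more than ``threshold_factor`` times
    the whole-recording RMS are grouped into contiguous suprathreshold runs;
    each run contributes one event at its absolute-peak sample.  Events are
    then scanned in time order and any event closer than ``min_iei`` (ms) to
    the previously kept event is discarded (the earlier event wins).

    ``polarity`` restricts detection to deflections of one sign: ``"inward"``
    (negative) or ``"outward"`` (positive); ``None`` detects both.
    """
    x = trace.samples
    if x.size == 0:
        return DetectedEventSet(np.empty(0), np.empty(0), 0.0, 0.0)
    mu = x.mean()
    dev = x - mu
    r = float(np.sqrt(np.mean(dev**2)))
    thr = threshold_factor * r
    if polarity is None:
        supra = np.abs(dev) > thr
    elif polarity == "inward":
        supra = dev < -thr
    elif polarity == "outward":
        supra = dev > thr
    else:
        raise ValueError("polarity must be 'inward', 'outward' or None")
    if r == 0 or not supra.any():
        return DetectedEventSet(np.empty(0), np.empty(0), thr, r)
    # contiguous runs of suprathreshold samples
    edges = np.diff(supra.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if supra[0]:
        starts = np.r_[0, starts]
    if supra[-1]:
        ends = np.r_[ends, supra.size]
    peak_idx = np.array(
        [s + np.argmax(np.abs(dev[s:e])) for s, e in zip(starts, ends)], dtype=int
    )
    times = peak_idx / trace.sampling_rate
    amps = dev[peak_idx]
    # refractory rule: keep the earlier event of any violating pair
    min_dt = min_iei / 1000.0
    keep = []
    last_kept = -np.inf
    for i, t in enumerate(times):
        if t - last_kept >= min_dt:
            keep.append(i)
            last_kept = t
    keep = np.asarray(keep, dtype=int)
    return DetectedEventSet(times[keep], amps[keep], thr, r)


def interevent_intervals(events: DetectedEventSet) -> np.ndarray:
    """Successive event-time differences in ms (empty for < 2 events)."""
    if len(events) < 2:
        return np.empty(0)
    return np.diff(events.times) * 1000.0


def coastline(trace: TraceRecording, window: float = 1.0) -> np.ndarray:
    """Per-window coastline: sum of absolute successive sample differences.

    Non-overlapping windows of ``window`` seconds; a trailing partial window
    is dropped.
    """
    n_win = int(round(window * trace.sampling_rate))
    if n_win < 2:
        raise ValueError("window must span at least 2 samples")
    x = trace.samples
    n_full = x.size // n_win
    out = np.empty(n_full)
    for k in range(n_full):
        seg = x[k * n_win: (k + 1) * n_win]
        out[k] = np.sum(np.abs(np.diff(seg)))
    return out


def _welch_psd(trace: TraceRecording, window_s: float = WELCH_WINDOW_S):
    nper = int(round(window_s * trace.sampling_rate))
    nper = min(nper, trace.samples.size)
    return signal.welch(
        trace.samples,
        fs=trace.sampling_rate,
        window="hann",
        nperseg=nper,
        noverlap=int(nper * WELCH_OVERLAP),
        detrend="constant",
    )


def band_power(
    trace: TraceRecording,
    bands: Sequence[tuple[float, float]] = DEFAULT_BANDS,
) -> BandPowerTable:
    """Welch band power (2 s Hann windows, 50% overlap) integrated per band."""
    if trace.duration < 2.0:
        raise ValueError("band power needs at least 2 s of signal")
    nyq = trace.sampling_rate / 2.0
    for lo, hi in bands:
        if hi > nyq:
            raise ValueError(f"band {lo}-{hi} Hz exceeds the Nyquist frequency {nyq} Hz")
        if lo >= hi:
            raise ValueError("band edges must satisfy low < high")
    f, p = _welch_psd(trace)
    df = f[1] - f[0]
    powers = np.array(
        [np.sum(p[(f >= lo) & (f < hi)]) * df for lo, hi in bands]
    )
    total = float(np.sum(p) * df)
    return BandPowerTable(tuple(tuple(b) for b in bands), powers, total)


def segment_metrics(segment: TraceRecording) -> SegmentMetrics:
    """Six scalar metrics of a one-second segment.

    Reconstruction of the classifier metrics (the original definitions are
    in unpublished external software):

    * power - mean squared mean-subtracted amplitude;
    * coastline - total variation of the segment;
    * intermittency - fraction of 100 ms sub-windows whose coastline exceeds
      twice the median sub-window coastline;
    * coherence - maximum of the normalized autocorrelation at lags
      10-500 ms (rhythmicity);
    * asymmetry - sample skewness;
    * spikiness - max absolute deviation from the mean divided by the RMS.
    """
    n = segment.samples.size
    if abs(segment.duration - 1.0) > 0.5 / segment.sampling_rate:
        raise ValueError("segment_metrics expects a one-second segment")
    x = segment.samples - segment.samples.mean()
    r = float(np.sqrt(np.mean(x**2)))
    power = float(np.mean(x**2))
    coast = float(np.sum(np.abs(np.diff(x))))
    # intermittency over 100 ms sub-windows
    n_sub = max(2, int(round(0.1 * segment.sampling_rate)))
    sub_coasts = [
        np.sum(np.abs(np.diff(x[s: s + n_sub])))
        for s in range(0, n - n_sub + 1, n_sub)
    ]
    med = np.median(sub_coasts)
    intermittency = (
        float(np.mean(np.asarray(sub_coasts) > 2.0 * med)) if med > 0 else 0.0
    )
    # coherence: normalized autocorrelation peak in 10-500 ms lags
    if r > 0:
        ac = signal.correlate(x, x, mode="full")[n - 1:]
        ac = ac / ac[0]
        lo = max(1, int(round(0.010 * segment.sampling_rate)))
        hi = min(n - 1, int(round(0.500 * segment.sampling_rate)))
        coherence = float(np.max(ac[lo: hi + 1])) if hi >= lo else 0.0
    else:
        coherence = 0.0
    asymmetry = float(stats.skew(x)) if r > 0 else 0.0
    spikiness = float(np.max(np.abs(x)) / r) if r > 0 else 0.0
    return SegmentMetrics(power, coast, intermittency, coherence, asymmetry, spikiness)


def classify_segment(
    metrics: SegmentMetrics,
    library: Sequence[tuple[SegmentMetrics, str]],
) -> str:
    """Label of the nearest library entry in z-scored 6-metric space.

    Metrics are z-scored against the library; any metric with zero variance
    across the library is dropped from the distance.  Ties break to the first
    occurrence.
    """
    if not library:
        raise ValueError("library must be non-empty")
    lib = np.array([m.as_array() for m, _ in library])
    labels = [lab for _, lab in library]
    mu = lib.mean(axis=0)
    sd = lib.std(axis=0)
    keep = sd > 0
    q = metrics.as_array()
    if not keep.any():  # fully degenerate library: all entries identical
        return labels[0]
    d = np.sum(((lib[:, keep] - q[keep]) / sd[keep]) ** 2, axis=1)
    return labels[int(np.argmin(d))]


def _mean_aligned_event(
    x: np.ndarray, peak_idx: np.ndarray, fs: float, pre_s: float, post_s: float
) -> tuple[np.ndarray, np.ndarray]:
    n_pre = int(round(pre_s * fs))
    n_post = int(round(post_s * fs))
    snippets = []
    for p in peak_idx:
        if p - n_pre < 0 or p + n_post >= x.size:
            continue
        snippets.append(x[p - n_pre: p + n_post + 1])
    if not snippets:
        raise InsufficientEventsError("no events with a full analysis window")
    avg = np.mean(snippets, axis=0)
    t = (np.arange(avg.size) - n_pre) / fs
    return t, avg


def _fit_decay_tau(t_ms: np.ndarray, y: np.ndarray) -> float:
    """Least-squares mono-exponential decay constant from peak to 10% of peak."""
    peak = y[0]
    below = np.flatnonzero(y <= 0.10 * peak)
    end = below[0] if below.size else y.size
    end = max(end, 3)
    tt, yy = t_ms[:end], y[:end]
    pos = yy > 0
    if pos.sum() < 3:
        raise RuntimeError("decay fit failed: too few positive samples")
    # log-linear initialization, then nonlinear refinement
    slope, intercept = np.polyfit(tt[pos], np.log(yy[pos]), 1)
    tau0 = -1.0 / slope if slope < 0 else float(tt[-1])
    try:
        popt, _ = optimize.curve_fit(
            lambda t, a, tau: a * np.exp(-t / tau),
            tt, yy, p0=[peak, max(tau0, 1e-3)], maxfev=10000,
        )
        return float(abs(popt[1]))
    except RuntimeError as e:
        raise RuntimeError(f"decay fit did not converge: {e}") from e


def _fit_amplitude_sigmoid(amps: np.ndarray) -> tuple[float, bool]:
    """Logistic fit F(a) = 1/(1+exp(-s(a - a50))) to the empirical CDF.

    Returns (midpoint slope s in 1/pA, capped flag).  A step-like CDF (all
    amplitudes nearly identical) yields an unbounded slope, reported as the
    documented cap.
    """
    a = np.sort(amps)
    n = a.size
    ecdf = (np.arange(1, n + 1) - 0.5) / n
    spread = a[-1] - a[0]
    if spread <= 1e-12 * max(1.0, abs(a[0])):
        return SIGMOID_SLOPE_CAP, True
    s0 = 4.0 / spread
    try:
        popt, _ = optimize.curve_fit(
            lambda x, s, a50: 1.0 / (1.0 + np.exp(-np.clip(s * (x - a50), -500, 500))),
            a, ecdf, p0=[s0, float(np.median(a))], maxfev=10000,
        )
        s = float(abs(popt[0]))
    except RuntimeError:
        return SIGMOID_SLOPE_CAP, True
    if s > SIGMOID_SLOPE_CAP:
        return SIGMOID_SLOPE_CAP, True
    return s, False


def extract_synaptic_features(
    trace: TraceRecording,
    polarity: str = "inward",
    threshold_factor: float = 4.0,
    min_iei: float = 15.0,
) -> SynapticFeatureSet:
    """Extract synaptic-event features from a voltage-clamp trace.

    Events are detected with the polarity-constrained threshold rule; the
    feature set carries the mean absolute peak amplitude (relative to a local
    pre-event baseline), interevent intervals, the mono-exponential decay
    constant of the peak-aligned average event (fit from the peak down to 10%
    of the peak), its half-life (tau * ln 2), and the logistic midpoint slope
    of the cumulative amplitude distribution.
    """
    events = detect_events(trace, threshold_factor, min_iei, polarity=polarity)
    if len(events) < 5:
        raise InsufficientEventsError(
            f"need at least 5 detected events, found {len(events)}"
        )
    fs = trace.sampling_rate
    x = trace.samples
    sign = -1.0 if polarity == "inward" else 1.0
    peak_idx = np.round(events.times * fs).astype(int)
    # local baseline: median over a 5 ms window ending 2 ms before the peak
    n_bl = max(1, int(round(0.005 * fs)))
    n_gap = int(round(0.002 * fs))
    amps = []
    for p in peak_idx:
        lo = max(0, p - n_gap - n_bl)
        hi = max(lo + 1, p - n_gap)
        baseline = np.median(x[lo:hi])
        amps.append(abs(x[p] - baseline))
    amps = np.asarray(amps)
    # peak-aligned average, rectified to positive-going decay
    t, avg = _mean_aligned_event(sign * (x - np.mean(x)), peak_idx, fs,
                                 pre_s=0.002, post_s=0.080)
    i_peak = int(np.argmax(avg))
    t_ms = (t[i_peak:] - t[i_peak]) * 1000.0
    decay = avg[i_peak:]
    tau = _fit_decay_tau(t_ms, decay)
    slope, capped = _fit_amplitude_sigmoid(amps)
    return SynapticFeatureSet(
        mean_amplitude=float(np.mean(amps)),
        ieis=interevent_intervals(events),
        decay_tau=tau,
        half_life=tau * np.log(2.0),
        sigmoid_midpoint_slope=slope,
        n_events=len(events),
        slope_capped=capped,
    )
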