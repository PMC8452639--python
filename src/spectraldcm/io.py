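"""Plain-text interchange formats.

Traces travel as two-column text (time_s, value) with a one-line header
``# fs=<Hz> units=<pA|uV>``; spectra as two-column CSV (freq, power);
parameter sets, densities, ground truth and model spaces as JSON.  EDF field
recordings can be read when ``mne`` is installed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .cmc import CMCParameters, SpectralDensity
from .ephys import TraceRecording
from .inversion import ParameterDensity
from .synth import GroundTruth

__all__ = [
    "write_trace",
    "read_trace",
    "read_edf_trace",
    "write_psd_csv",
    "read_psd_csv",
    "write_params",
    "read_params",
    "write_density",
    "read_density",
    "write_ground_truth",
    "read_ground_truth",
]


def write_trace(path, trace: TraceRecording) -> None:
    path = Path(path)
    t = trace.times
    with path.open("w") as fh:
        fh.write(f"# fs={trace.sampling_rate:g} units={trace.units}\n")
        np.savetxt(fh, np.column_stack([t, trace.samples]), fmt="%.9g")


def read_trace(path) -> TraceRecording:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing '# fs=... units=...' header")
        meta = dict(
            tok.split("=", 1) for tok in header[1:].split() if "=" in tok
        )
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    return TraceRecording(
        samples=data[:, 1],
        sampling_rate=float(meta["fs"]),
        units=meta.get("units", "a.u."),
    )


def read_edf_trace(path, channel: int = 0) -> TraceRecording:
    """Read one channel of an EDF recording (requires the optional mne extra)."""
    try:
        import mne
    except ImportError as e:
        raise ImportError(
            "EDF support requires mne; install spectraldcm[edf]"
        ) from e
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data()[channel] * 1e6  # volts -> microvolts
    return TraceRecording(samples=data, sampling_rate=float(raw.info["sfreq"]),
                          units="uV")


def write_psd_csv(path, psd: SpectralDensity) -> None:
    np.savetxt(
        Path(path), np.column_stack([psd.freqs, psd.values]),
        delimiter=",", header="freq_hz,power", comments="",
    )


def read_psd_csv(path) -> SpectralDensity:
    data = np.loadtxt(Path(path), delimiter=",", skiprows=1)
    return SpectralDensity(freqs=data[:, 0], values=data[:, 1])


def write_params(path, params: CMCParameters) -> None:
    Path(path).write_text(json.dumps(params.to_dict(), indent=2) + "\n")


def read_params(path) -> CMCParameters:
    return CMCParameters.from_dict(json.loads(Path(path).read_text()))


def write_density(path, density: ParameterDensity) -> None:
    Path(path).write_text(json.dumps(density.to_dict(), indent=2) + "\n")


def read_density(path) -> ParameterDensity:
    return ParameterDensity.from_dict(json.loads(Path(path).read_text()))


def write_ground_truth(path, truth: GroundTruth) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=2) + "\n")


def read_ground_truth(path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        event_times=np.asarray(d["event_times"], float),
        event_amps=np.asarray(d["event_amps"], float),
        epoch_labels=tuple(tuple(e) for e in d.get("epoch_labels", [])),
    )
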