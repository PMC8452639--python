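"""Epileptogenicity x ictogenicity parameter-space analysis.

The fitted parameter vectors of the three brain states define two effect
directions in log-scaling parameter space:

* the **epileptogenesis** vector, interictal minus control — the synaptic
  change produced by NMDAR-antibody exposure;
* the **ictogenesis** vector, ictal minus interictal — the synaptic change
  accompanying the transition into a seizure.

A 2-D grid ``lambda(e, i) = lambda_control + e * delta_epi + i * delta_icto``
is simulated: at each point the predicted spectrum is computed, classified
to the nearest of the three reference state spectra by mean-squared
difference of log-amplitudes, and summarized by a high/low frequency
log-amplitude ratio map and a neighbour-sensitivity map.  The headline
readout is the distance along the ictogenicity axis to the seizure-like
territory — shorter from the interictal (NMDAR-antibody) row than from the
control row when antibody-induced hypoexcitation has moved the circuit into
a more perturbation-sensitive regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import cmc
from .cmc import CMCParameters, SpectralDensity, UnstableModelError

__all__ = [
    "StateTriplet",
    "EffectVectors",
    "GridResult",
    "effect_vectors",
    "pca_states",
    "simulate_grid",
    "classify_grid",
    "ratio_map",
    "sensitivity_map",
    "seizure_onset_distance",
    "STATE_LABELS",
    "SENSITIVITY_FLOOR",
]

STATE_LABELS = ("control-like", "interictal-like", "seizure-like")
UNSTABLE_LABEL = "unstable"

#: Floor applied to neighbour mean-squared differences before log10.
SENSITIVITY_FLOOR = 1e-12


@dataclass(frozen=True)
class StateTriplet:
    """Posterior-mean log-scaling vectors of the three fitted states."""

    lambda_control: np.ndarray
    lambda_interictal: np.ndarray
    lambda_ictal: np.ndarray

    def __post_init__(self):
        arrs = [np.asarray(a, dtype=float) for a in (
            self.lambda_control, self.lambda_interictal, self.lambda_ictal)]
        object.__setattr__(self, "lambda_control", arrs[0])
        object.__setattr__(self, "lambda_interictal", arrs[1])
        object.__setattr__(self, "lambda_ictal", arrs[2])
        if not (arrs[0].shape == arrs[1].shape == arrs[2].shape):
            raise ValueError("state vectors must have equal dimensions")

    def stack(self) -> np.ndarray:
        return np.vstack(
            [self.lambda_control, self.lambda_interictal, self.lambda_ictal]
        )


@dataclass(frozen=True)
class EffectVectors:
    """Epileptogenesis and ictogenesis directions in parameter space."""

    delta_epi: np.ndarray
    delta_icto: np.ndarray

    def __post_init__(self):
        de = np.asarray(self.delta_epi, dtype=float)
        di = np.asarray(self.delta_icto, dtype=float)
        object.__setattr__(self, "delta_epi", de)
        object.__setattr__(self, "delta_icto", di)
        if de.shape != di.shape:
            raise ValueError("effect vectors must have equal dimensions")


@dataclass
class GridResult:
    """Spectra and maps over the epileptogenicity x ictogenicity grid.

    ``spectra[j, k]`` is the predicted PSD at epileptogenicity ``e_values[j]``
    and ictogenicity ``i_values[k]`` (None where the circuit is unstable);
    ``labels`` uses :data:`STATE_LABELS` plus ``"unstable"``.
    """

    e_values: np.ndarray
    i_values: np.ndarray
    freqs: np.ndarray
    spectra: np.ndarray            # object array (n_e, n_i) of PSD vectors/None
    labels: np.ndarray | None = None
    ratio: np.ndarray | None = None
    sensitivity: np.ndarray | None = None
    n_unstable: int = 0

    @property
    def stable_mask(self) -> np.ndarray:
        return np.array(
            [[s is not None for s in row] for row in self.spectra], dtype=bool
        )


def effect_vectors(triplet: StateTriplet) -> EffectVectors:
    """Element-wise state differences: interictal-control, ictal-interictal."""
    return EffectVectors(
        delta_epi=triplet.lambda_interictal - triplet.lambda_control,
        delta_icto=triplet.lambda_ictal - triplet.lambda_interictal,
    )


def pca_states(triplet: StateTriplet):
    """Project the three states onto their first two principal components.

    Three points span at most a plane, so the 2-D projection preserves their
    pairwise distances exactly.  Returns ``(projections (3, 2), singular
    values, effect_angle_deg)`` where the angle is between the projected
    epileptogenesis and ictogenesis vectors.
    """
    X = triplet.stack()
    Xc = X - X.mean(axis=0)
    if np.allclose(Xc, 0):
        raise ValueError("degenerate decomposition: all three states identical")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    proj = (U * s)[:, :2]
    if proj.shape[1] < 2:  # collinear edge case with rank 1
        proj = np.column_stack([proj, np.zeros(3)])
        s = np.r_[s, 0.0]
    d_epi = proj[1] - proj[0]
    d_icto = proj[2] - proj[1]
    denom = np.linalg.norm(d_epi) * np.linalg.norm(d_icto)
    if denom == 0:
        angle = float("nan")
    else:
        cosang = np.clip(d_epi @ d_icto / denom, -1.0, 1.0)
        angle = float(np.degrees(np.arccos(cosang)))
    return proj, s[:2], angle


def simulate_grid(
    lambda_control: np.ndarray,
    effects: EffectVectors,
    base_params: CMCParameters | None = None,
    n_e: int = 21,
    n_i: int = 21,
    range_e: tuple[float, float] = (0.0, 1.0),
    range_i: tuple[float, float] = (0.0, 1.0),
    freqs: np.ndarray | None = None,
) -> GridResult:
    """Predict spectra over the epileptogenicity x ictogenicity grid.

    At grid point (e, i) the circuit is evaluated at
    ``lambda_control + e * delta_epi + i * delta_icto``; unstable points are
    recorded as None and excluded from later classification and maps.
    """
    if n_e < 2 or n_i < 2:
        raise ValueError("grid must be at least 2 x 2")
    base_params = base_params or CMCParameters()
    freqs = np.asarray(
        freqs if freqs is not None else np.arange(1.0, 100.5, 0.5), dtype=float
    )
    lam0 = np.asarray(lambda_control, dtype=float)
    e_values = np.linspace(range_e[0], range_e[1], n_e)
    i_values = np.linspace(range_i[0], range_i[1], n_i)
    spectra = np.empty((n_e, n_i), dtype=object)
    n_unstable = 0
    for j, e in enumerate(e_values):
        for k, i in enumerate(i_values):
            lam = lam0 + e * effects.delta_epi + i * effects.delta_icto
            try:
                spectra[j, k] = cmc.predict_psd(
                    base_params.with_scaling(lam), freqs
                ).values
            except (UnstableModelError, FloatingPointError, OverflowError):
                spectra[j, k] = None
                n_unstable += 1
    return GridResult(
        e_values=e_values, i_values=i_values, freqs=freqs,
        spectra=spectra, n_unstable=n_unstable,
    )


def _log_amplitude(psd_values: np.ndarray) -> np.ndarray:
    # log amplitude = 0.5 * log PSD; the factor cancels nowhere that matters
    # (argmin classification, ratios of means), kept for interpretability
    return 0.5 * np.log(psd_values)


def classify_grid(
    grid: GridResult, references: Sequence[SpectralDensity]
) -> np.ndarray:
    """Label each stable grid point by its nearest reference spectrum.

    Distance is the mean squared difference of log-amplitude spectra on the
    grid's frequency axis; ties break to the lower-index reference.  The
    labels array is also stored on ``grid.labels``.
    """
    if len(references) != len(STATE_LABELS):
        raise ValueError(f"expected {len(STATE_LABELS)} reference spectra")
    ref_logs = []
    for ref in references:
        if ref.freqs.shape != grid.freqs.shape or not np.allclose(
            ref.freqs, grid.freqs
        ):
            raise ValueError("reference spectra must be on the grid frequency axis")
        ref_logs.append(_log_amplitude(ref.values))
    labels = np.empty(grid.spectra.shape, dtype=object)
    for j in range(grid.e_values.size):
        for k in range(grid.i_values.size):
            s = grid.spectra[j, k]
            if s is None:
                labels[j, k] = UNSTABLE_LABEL
                continue
            la = _log_amplitude(s)
            d = [np.mean((la - rl) ** 2) for rl in ref_logs]
            labels[j, k] = STATE_LABELS[int(np.argmin(d))]
    grid.labels = labels
    return labels


def ratio_map(
    grid: GridResult, split_high: float = 20.0, split_low: float = 8.0
) -> np.ndarray:
    """High/low-frequency log-amplitude ratio per grid point.

    Mean log-amplitude above ``split_high`` divided by the mean below
    ``split_low``; NaN at unstable points.  Stored on ``grid.ratio``.
    """
    hi = grid.freqs > split_high
    lo = grid.freqs < split_low
    if not hi.any() or not lo.any():
        raise ValueError("frequency grid does not cover both ratio bands")
    out = np.full(grid.spectra.shape, np.nan)
    for j in range(grid.e_values.size):
        for k in range(grid.i_values.size):
            s = grid.spectra[j, k]
            if s is None:
                continue
            la = _log_amplitude(s)
            out[j, k] = np.mean(la[hi]) / np.mean(la[lo])
    grid.ratio = out
    return out


def sensitivity_map(grid: GridResult) -> np.ndarray:
    """log10 mean-squared difference between ictogenicity neighbours.

    For each epileptogenicity row, the MSE between log-spectra at adjacent
    ictogenicity grid points, floored at :data:`SENSITIVITY_FLOOR` before
    taking log10; NaN where either neighbour is unstable.  Shape
    ``(n_e, n_i - 1)``; stored on ``grid.sensitivity``.
    """
    n_e, n_i = grid.spectra.shape
    if n_i < 2:
        raise ValueError("sensitivity needs at least two ictogenicity points")
    out = np.full((n_e, n_i - 1), np.nan)
    for j in range(n_e):
        for k in range(n_i - 1):
            a, b = grid.spectra[j, k], grid.spectra[j, k + 1]
            if a is None or b is None:
                continue
            mse = float(np.mean((_log_amplitude(a) - _log_amplitude(b)) ** 2))
            out[j, k] = np.log10(max(mse, SENSITIVITY_FLOOR))
    grid.sensitivity = out
    return out


def seizure_onset_distance(grid: GridResult) -> np.ndarray:
    """Smallest ictogenicity value labelled seizure-like, per row (NaN if none).

    Requires :func:`classify_grid` to have run on the grid."""
    if grid.labels is None:
        raise ValueError("grid must be classified first (classify_grid)")
    out = np.full(grid.e_values.size, np.nan)
    for j in range(grid.e_values.size):
        hits = np.flatnonzero(grid.labels[j] == "seizure-like")
        if hits.size:
            out[j] = grid.i_values[hits[0]]
    return out
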