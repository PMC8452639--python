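"""Microscale-informed priors and the 22-model space of prior placements.

Whole-cell patch-clamp contrasts between control-antibody and
NMDAR-antibody conditions are turned into quantitative prior shifts on
population parameters of the canonical microcircuit:

* EPSC amplitude ratio       -> effective coupling strength gamma,
* EPSC half-life ratio       -> synaptic time constant tau,
* amplitude-CDF slope ratio  -> sigmoid slope sigma (response variance).

Shifts are natural logs of the feature ratios, applied additively in the
log-scaling parameter space (population parameters scale proportionally to
the single-cell features).

The model space crosses the seven non-empty subsets of {gamma, tau, sigma}
with three population subsets (superficial pair ss+sp, deep pair ii+dp,
both) and adds a null model without microscale information: 22 models.
The exact composition of the original 22-model space is not published; this
reconstruction contains the named null model, the full model and the
winning {gamma, sigma} x deep-pair model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cmc import GAMMA_TARGETS, POPULATIONS
from .ephys import SynapticFeatureSet
from .inversion import PARAM_NAMES, ParameterDensity

__all__ = [
    "MicroscaleContrast",
    "ModelSpec",
    "ModelSpace",
    "contrast_from_features",
    "shifts_from_contrast",
    "build_model_space",
    "informed_priors",
    "SUPERFICIAL_PAIR",
    "DEEP_PAIR",
]

SUPERFICIAL_PAIR: tuple[str, ...] = ("ss", "sp")
DEEP_PAIR: tuple[str, ...] = ("ii", "dp")

_GROUPS = ("gamma", "tau", "sigma")
_POP_SUBSETS = {
    "superficial": SUPERFICIAL_PAIR,
    "deep": DEEP_PAIR,
    "both": SUPERFICIAL_PAIR + DEEP_PAIR,
}


@dataclass(frozen=True)
class MicroscaleContrast:
    """Feature ratios (NMDAR-antibody / control) from patch-clamp recordings."""

    amplitude_ratio: float
    half_life_ratio: float
    slope_ratio: float

    def __post_init__(self):
        for name in ("amplitude_ratio", "half_life_ratio", "slope_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ModelSpec:
    """One prior-placement specification in the model space."""

    informed_groups: tuple[str, ...]     # subset of ('gamma', 'tau', 'sigma')
    informed_populations: str            # 'superficial' | 'deep' | 'both'
    is_null: bool = False

    def __post_init__(self):
        if self.is_null:
            if self.informed_groups:
                raise ValueError("null model must have no informed groups")
        else:
            if not self.informed_groups:
                raise ValueError("non-null model must inform at least one group")
            for g in self.informed_groups:
                if g not in _GROUPS:
                    raise ValueError(f"unknown parameter group {g!r}")
            if self.informed_populations not in _POP_SUBSETS:
                raise ValueError(
                    f"unknown population subset {self.informed_populations!r}"
                )

    @property
    def name(self) -> str:
        if self.is_null:
            return "null"
        return "+".join(self.informed_groups) + "_x_" + self.informed_populations

    @property
    def populations(self) -> tuple[str, ...]:
        return () if self.is_null else _POP_SUBSETS[self.informed_populations]


@dataclass(frozen=True)
class ModelSpace:
    specs: tuple[ModelSpec, ...]

    def __post_init__(self):
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise ValueError("model specs must be distinct")
        if sum(s.is_null for s in self.specs) != 1:
            raise ValueError("model space must contain exactly one null model")

    def __len__(self) -> int:
        return len(self.specs)

    def __iter__(self):
        return iter(self.specs)

    def to_list(self) -> list[dict]:
        return [
            {
                "name": s.name,
                "informed_groups": list(s.informed_groups),
                "informed_populations": s.informed_populations if not s.is_null else None,
                "is_null": s.is_null,
            }
            for s in self.specs
        ]


def contrast_from_features(
    control: SynapticFeatureSet, nmdar: SynapticFeatureSet
) -> MicroscaleContrast:
    """Element-wise NMDAR/control feature ratios (amplitude, half-life, slope)."""
    for name, val in (
        ("mean_amplitude", control.mean_amplitude),
        ("half_life", control.half_life),
        ("sigmoid_midpoint_slope", control.sigmoid_midpoint_slope),
    ):
        if val == 0:
            raise ValueError(f"control feature {name} is zero; ratio undefined")
    return MicroscaleContrast(
        amplitude_ratio=nmdar.mean_amplitude / control.mean_amplitude,
        half_life_ratio=nmdar.half_life / control.half_life,
        slope_ratio=nmdar.sigmoid_midpoint_slope / control.sigmoid_midpoint_slope,
    )


def shifts_from_contrast(contrast: MicroscaleContrast) -> dict[str, float]:
    """Log shifts per parameter group: gamma <- ln amplitude ratio,
    tau <- ln half-life ratio, sigma <- ln CDF-slope ratio."""
    return {
        "gamma": float(np.log(contrast.amplitude_ratio)),
        "tau": float(np.log(contrast.half_life_ratio)),
        "sigma": float(np.log(contrast.slope_ratio)),
    }


def build_model_space() -> ModelSpace:
    """The 22-model space: null + 7 group subsets x 3 population subsets.

    Deterministic order: the null model first, then groups in the order
    (gamma, tau, sigma, gamma+tau, gamma+sigma, tau+sigma, gamma+tau+sigma),
    each crossed with populations (superficial, deep, both).
    """
    group_subsets = (
        ("gamma",), ("tau",), ("sigma",),
        ("gamma", "tau"), ("gamma", "sigma"), ("tau", "sigma"),
        ("gamma", "tau", "sigma"),
    )
    specs = [ModelSpec(informed_groups=(), informed_populations="both", is_null=True)]
    for groups in group_subsets:
        for pops in ("superficial", "deep", "both"):
            specs.append(ModelSpec(informed_groups=groups, informed_populations=pops))
    return ModelSpace(tuple(specs))


def _informed_indices(spec: ModelSpec) -> list[int]:
    """Indices into the 18-parameter lambda vector informed by ``spec``.

    tau and sigma shifts apply to the populations' own parameters; a gamma
    coupling belongs to the population whose synaptic response it scales
    (its target).
    """
    if spec.is_null:
        return []
    pops = set(spec.populations)
    idx = []
    for i, name in enumerate(PARAM_NAMES):
        if name.startswith("tau_") and "tau" in spec.informed_groups:
            if name.split("_")[1] in pops:
                idx.append(i)
        elif name.startswith("gamma") and "gamma" in spec.informed_groups:
            k = int(name[5:]) - 1
            if GAMMA_TARGETS[k] in pops:
                idx.append(i)
        elif name.startswith("sigma_") and "sigma" in spec.informed_groups:
            if name.split("_")[1] in pops:
                idx.append(i)
    return idx


def informed_priors(
    base: ParameterDensity, spec: ModelSpec, shifts: dict[str, float]
) -> ParameterDensity:
    """Shift the prior means of the parameters informed by ``spec``.

    Shifts are added in log-scaling space; covariances are never altered.
    The null spec returns the base density unchanged.
    """
    if base.dim != len(PARAM_NAMES):
        raise ValueError(f"base prior must have {len(PARAM_NAMES)} parameters")
    if spec.is_null:
        return ParameterDensity(base.mean.copy(), base.cov.copy())
    mean = base.mean.copy()
    for i in _informed_indices(spec):
        name = PARAM_NAMES[i]
        group = "tau" if name.startswith("tau") else (
            "gamma" if name.startswith("gamma") else "sigma"
        )
        mean[i] += shifts[group]
    return ParameterDensity(mean, base.cov.copy())
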