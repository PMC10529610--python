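"""Registry of candidate perceptual models.

Each :class:`ModelSpec` bundles a perceptual filter (HGF3, HGF4,
Rescorla-Wagner or Sutton K1) with its free parameters, their transforms
to unconstrained fitting space, and default priors.  The registry is the
single point the simulator, the inverter and the pipeline dispatch on.

Transforms follow standard practice: log for positive parameters
(theta, zeta, the K1 meta-rate), logit for unit-interval parameters
(alpha, v0), identity for the omegas.  Default prior variance is 4 in
transformed space ("relatively uninformative"); the HGF4 top-level walk
variance theta is pinned by a tight prior, reflecting its weak
identifiability from short binary series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
from scipy.special import expit, logit

from sensolearn.learning import (
    BeliefTrajectory,
    HGFParameters,
    ValueTrajectory,
    hgf_filter,
    k1_filter,
    rw_filter,
)

__all__ = ["ParamDef", "ModelSpec", "MODELS", "get_model", "MODEL_NAMES"]

_BELIEF_EPS = 1e-9  # keep beliefs strictly inside (0, 1) for the sigmoid


def _identity(x: float) -> float:
    return x


_TRANSFORMS: dict[str, tuple[Callable, Callable]] = {
    # name -> (to_native, to_transformed)
    "identity": (_identity, _identity),
    "log": (math.exp, math.log),
    "logit": (lambda x: float(expit(x)), lambda p: float(logit(p))),
}


@dataclass(frozen=True)
class ParamDef:
    """One free parameter: its transform and default prior (transformed
    space)."""

    name: str
    transform: str
    prior_mean: float
    prior_var: float

    def to_native(self, x: float) -> float:
        return _TRANSFORMS[self.transform][0](x)

    def to_transformed(self, v: float) -> float:
        return _TRANSFORMS[self.transform][1](v)


@dataclass(frozen=True)
class ModelSpec:
    name: str
    family: str  # "hierarchical" | "associative"
    perceptual: tuple[ParamDef, ...]
    response: ParamDef
    fixed: dict

    @property
    def free_params(self) -> tuple[ParamDef, ...]:
        return self.perceptual + (self.response,)

    @property
    def n_free(self) -> int:
        return len(self.free_params)

    def predict(self, u, params: dict) -> np.ndarray:
        """Per-trial response-driving beliefs p(u=1) (previous-trial
        posterior), clipped strictly inside (0, 1)."""
        traj = self.filter(u, params)
        return np.clip(traj.predictions, _BELIEF_EPS, 1.0 - _BELIEF_EPS)

    def filter(self, u, params: dict) -> BeliefTrajectory | ValueTrajectory:
        raise NotImplementedError

    def default_params(self) -> dict:
        out = {p.name: p.to_native(p.prior_mean) for p in self.perceptual}
        out[self.response.name] = self.response.to_native(
            self.response.prior_mean)
        return out


@dataclass(frozen=True)
class _HGFSpec(ModelSpec):
    levels: int = 3

    def filter(self, u, params: dict) -> BeliefTrajectory:
        kwargs = dict(self.fixed)
        kwargs.update({k: v for k, v in params.items() if k != "zeta"})
        hp = HGFParameters(levels=self.levels, **kwargs)
        return hgf_filter(u, hp)


@dataclass(frozen=True)
class _RWSpec(ModelSpec):
    def filter(self, u, params: dict) -> ValueTrajectory:
        return rw_filter(u, alpha=params["alpha"], v0=params["v0"])


@dataclass(frozen=True)
class _K1Spec(ModelSpec):
    def filter(self, u, params: dict) -> ValueTrajectory:
        return k1_filter(u, alpha0=params["alpha0"],
                         mu_meta=params["mu_meta"], v0=params["v0"])


_ZETA = ParamDef("zeta", "log", 0.0, 4.0)  # prior centred on matching

MODELS: dict[str, ModelSpec] = {
    "HGF3": _HGFSpec(
        name="HGF3", family="hierarchical",
        perceptual=(
            ParamDef("omega2", "identity", -3.0, 4.0),
            ParamDef("theta", "log", math.log(0.0025), 4.0),
        ),
        response=_ZETA,
        fixed={"kappa2": 1.0},
        levels=3,
    ),
    "HGF4": _HGFSpec(
        name="HGF4", family="hierarchical",
        perceptual=(
            ParamDef("omega2", "identity", -3.0, 4.0),
            ParamDef("omega3", "identity", -6.0, 4.0),
            # top-level walk variance pinned by a tight prior: short
            # binary series carry almost no information about it
            ParamDef("theta", "log", math.log(0.0025), 1e-4),
        ),
        response=_ZETA,
        fixed={"kappa2": 1.0, "kappa3": 1.0},
        levels=4,
    ),
    "RW": _RWSpec(
        name="RW", family="associative",
        perceptual=(
            ParamDef("alpha", "logit", 0.0, 4.0),
            ParamDef("v0", "logit", 0.0, 4.0),
        ),
        response=_ZETA,
        fixed={},
    ),
    "SuttonK1": _K1Spec(
        name="SuttonK1", family="associative",
        perceptual=(
            ParamDef("alpha0", "logit", 0.0, 4.0),
            ParamDef("mu_meta", "log", math.log(0.1), 4.0),
            ParamDef("v0", "logit", 0.0, 4.0),
        ),
        response=_ZETA,
        fixed={},
    ),
}

MODEL_NAMES = tuple(MODELS)


def get_model(name: str) -> ModelSpec:
    try:
        return MODELS[name]
    except KeyError:
        raise ValueError(
            f"unknown model {name!r}; registered: {sorted(MODELS)}"
        ) from None


def with_priors(spec: ModelSpec, means: dict[str, float] | None = None,
                variances: dict[str, float] | None = None) -> ModelSpec:
    """A copy of ``spec`` with overridden prior means/variances
    (transformed space)."""
    means = means or {}
    variances = variances or {}

    def upd(p: ParamDef) -> ParamDef:
        return ParamDef(p.name, p.transform,
                        means.get(p.name, p.prior_mean),
                        variances.get(p.name, p.prior_var))

    return replace(spec, perceptual=tuple(upd(p) for p in spec.perceptual),
                   response=upd(spec.response))
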