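"""Forward simulation of learning agents on experiment designs."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sensolearn.designs import InterceptionDesign, SWIDesign
from sensolearn.errors import ModelDivergenceError, SimulationError
from sensolearn.models import get_model
from sensolearn.responses import response_probability

__all__ = ["AgentRecord", "simulate_agent", "derive_inputs"]


@dataclass
class AgentRecord:
    """One simulated subject on one design: the generating model, its
    true parameters, and the sampled input/response series."""

    subject: str
    group: str
    design: SWIDesign | InterceptionDesign
    model_name: str
    params: dict
    zeta: float
    u: np.ndarray
    y: np.ndarray
    seed: int
    predictions: np.ndarray = field(repr=False, default=None)  # type: ignore

    def to_frame(self) -> pd.DataFrame:
        cond = getattr(self.design, "condition", "swi")
        return pd.DataFrame({
            "subject": self.subject, "group": self.group,
            "condition": cond, "trial": np.arange(len(self.u)),
            "u": self.u, "y": self.y,
        })

    def sidecar(self) -> dict:
        return {
            "subject": self.subject, "group": self.group,
            "model": self.model_name, "seed": int(self.seed),
            "params": {k: float(v) for k, v in self.params.items()},
            "zeta": float(self.zeta),
        }


def derive_inputs(design) -> np.ndarray:
    """Binary input series u for a design, by the coding rules of the
    preprocessing module (veridical coding for SWI; expected-ball coding
    for interception).  A pre-coded binary array passes through, so
    harnesses can run agents on arbitrary input sequences."""
    from sensolearn import preprocessing

    if isinstance(design, SWIDesign):
        u, _ = preprocessing.code_swi_inputs(design, mode="veridical")
        return u
    if isinstance(design, InterceptionDesign):
        return preprocessing.code_interception_inputs(design)
    arr = np.asarray(design)
    if arr.ndim == 1 and np.all((arr == 0) | (arr == 1)):
        return arr.astype(int)
    raise TypeError(f"unsupported design type {type(design).__name__}")


def simulate_agent(design, model_name: str, params: dict,
                   response_params: dict, seed: int,
                   subject: str = "sim", group: str = "") -> AgentRecord:
    """Simulate one agent: derive u from the design, run the perceptual
    filter forward, and sample each response y^(k) as a Bernoulli draw
    from the response model applied to the previous-trial belief."""
    model = get_model(model_name)
    zeta = float(response_params["zeta"])
    u = derive_inputs(design)
    try:
        beliefs = model.predict(u, params)
    except ModelDivergenceError as err:
        raise SimulationError(
            f"simulation diverged at trial {err.trial} "
            f"(model {model_name}, params {params})",
            trial=err.trial,
        ) from err
    p = response_probability(beliefs, zeta)
    rng = np.random.default_rng(seed)
    y = rng.binomial(1, p)
    return AgentRecord(
        subject=subject, group=group, design=design, model_name=model_name,
        params=dict(params), zeta=zeta, u=u, y=y, seed=seed,
        predictions=beliefs,
    )
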