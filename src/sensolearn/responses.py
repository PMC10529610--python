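"""Response (decision) model: mapping beliefs to binary actions.

A single free parameter, the inverse decision temperature ``zeta``,
shapes a unit-square sigmoid from the belief b = p(u=1) to the response
probability::

    p(y=1) = b**zeta / (b**zeta + (1-b)**zeta)

zeta = 1 is probability matching (p = b); zeta -> infinity approaches a
deterministic step at b = 0.5.  The belief driving trial k's response is
the *previous* trial's posterior — filters expose exactly this series as
``predictions``.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy.special import expit, logit

__all__ = ["response_probability", "response_loglik", "PROB_FLOOR"]

PROB_FLOOR = 1e-12  # likelihood clamp keeping the objective finite


def response_probability(belief, zeta: float):
    """Unit-square sigmoid response probability p(y=1 | belief, zeta).

    Accepts a scalar or array of beliefs in the open interval (0, 1).
    Computed as ``expit(zeta * logit(b))``, the numerically stable form
    of b**zeta / (b**zeta + (1-b)**zeta).
    """
    if not (zeta > 0 and math.isfinite(zeta)):
        raise ValueError(f"zeta must be positive and finite, got {zeta}")
    b = np.asarray(belief, dtype=float)
    if np.any((b <= 0) | (b >= 1)):
        raise ValueError("beliefs must lie strictly inside (0, 1)")
    p = expit(zeta * logit(b))
    return float(p) if np.isscalar(belief) or b.ndim == 0 else p


def response_loglik(beliefs: Sequence[float], y: Sequence[int], zeta: float,
                    mask: Sequence[bool] | None = None) -> float:
    """Total Bernoulli log-likelihood of binary responses.

    ``beliefs`` must be the per-trial predictions (previous-trial
    posterior) of a filter; masked trials are skipped.  Probabilities are
    clamped to [PROB_FLOOR, 1 - PROB_FLOOR] so a deterministic miss is
    heavily penalised rather than -inf.
    """
    b = np.asarray(beliefs, dtype=float)
    y_arr = np.asarray(y, dtype=float)
    if b.shape != y_arr.shape:
        raise ValueError("beliefs and responses must be aligned")
    if mask is not None:
        keep = np.asarray(mask, dtype=bool)
        b, y_arr = b[keep], y_arr[keep]
    p = np.clip(response_probability(b, zeta), PROB_FLOOR, 1.0 - PROB_FLOOR)
    return float(np.sum(y_arr * np.log(p) + (1.0 - y_arr) * np.log(1.0 - p)))
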