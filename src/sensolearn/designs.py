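"""Experiment designs: size-weight-illusion lifting and ball interception.

Two trial-sequence generators emulate the behavioural tasks the models
are fitted to:

* a size-weight illusion (SWI) lifting session — 5 baseline lifts of a
  medium control object followed by 32 test lifts of four objects
  crossing size (small 5 cm / large 10 cm) with mass (light 355 g /
  heavy 490 g), eight lifts each, in pseudorandom orders constrained so
  that both heavy objects are lifted before any light object;
* an interception session — 45 trials whose ball elasticity is either
  the expected 0.65 (30 trials) or an unexpectedly bouncy 0.85
  (15 trials), presented under a *stable* condition with a fixed
  marginal probability (30/45) or a *volatile* condition whose
  ground-truth probability of a normal ball switches between 83%, 67%
  and 50% in blocks of 6, 9 or 12 trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "SIZES_CM",
    "MASSES_G",
    "SWITrial",
    "SWIDesign",
    "InterceptionDesign",
    "gen_swi_design",
    "gen_interception_design",
]

SIZES_CM = {"small": 5.0, "large": 10.0, "medium": 7.5}
MASSES_G = {"light": 355.0, "heavy": 490.0, "control": 490.0}

ELASTICITY_EXPECTED = 0.65
ELASTICITY_UNEXPECTED = 0.85
N_EXPECTED = 30
N_UNEXPECTED = 15
BLOCK_LENGTHS = (6, 9, 12)
BLOCK_PROBS = (0.83, 0.67, 0.50)

N_BASELINE = 5
N_TEST = 32
LIFTS_PER_OBJECT = 8
TEST_OBJECTS = (
    ("small", 355.0), ("small", 490.0), ("large", 355.0), ("large", 490.0),
)


@dataclass(frozen=True)
class SWITrial:
    size: str            # small | large | medium
    mass: float          # grams
    phase: str = "test"  # baseline | test

    @property
    def diameter_cm(self) -> float:
        return SIZES_CM[self.size]


@dataclass(frozen=True)
class SWIDesign:
    """An SWI session: baseline lifts of the control object, then the
    pseudorandomised test sequence."""

    trials: tuple[SWITrial, ...]
    order_id: int | str
    n_baseline: int = N_BASELINE

    @property
    def baseline_trials(self) -> tuple[SWITrial, ...]:
        return self.trials[: self.n_baseline]

    @property
    def test_trials(self) -> tuple[SWITrial, ...]:
        return self.trials[self.n_baseline:]

    @property
    def n_test(self) -> int:
        return len(self.test_trials)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "trial": np.arange(len(self.trials)),
            "phase": [t.phase for t in self.trials],
            "size": [t.size for t in self.trials],
            "mass_g": [t.mass for t in self.trials],
        })


@dataclass(frozen=True)
class InterceptionDesign:
    """One 45-trial interception condition.

    ``blocks`` records the volatile condition's (length, p_normal)
    schedule; the stable condition has a single implicit block and
    ``blocks`` is None.
    """

    condition: Literal["stable", "volatile"]
    elasticity: tuple[float, ...]
    blocks: tuple[tuple[int, float], ...] | None = None

    @property
    def n_trials(self) -> int:
        return len(self.elasticity)

    @property
    def n_expected(self) -> int:
        return sum(1 for e in self.elasticity if e == ELASTICITY_EXPECTED)

    @property
    def n_unexpected(self) -> int:
        return sum(1 for e in self.elasticity if e == ELASTICITY_UNEXPECTED)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "trial": np.arange(self.n_trials),
            "condition": self.condition,
            "elasticity": list(self.elasticity),
        })


def _swi_constraint_ok(labels: list[tuple[str, float]]) -> bool:
    """Both heavy test objects must occur before any light trial."""
    first_light = next(
        (i for i, (_, m) in enumerate(labels) if m == MASSES_G["light"]),
        len(labels),
    )
    seen = {(s, m) for s, m in labels[:first_light] if m == MASSES_G["heavy"]}
    return len(seen) == 2


def _random_test_order(rng: np.random.Generator) -> list[tuple[str, float]]:
    pool = [obj for obj in TEST_OBJECTS for _ in range(LIFTS_PER_OBJECT)]
    while True:
        order = [pool[i] for i in rng.permutation(len(pool))]
        if _swi_constraint_ok(order):
            return order


# The three fixed pseudorandom test orders shipped with the package,
# derived once from internal seeds under the heavy-before-light
# constraint (synthetic stand-ins for the original predetermined
# sequences, whose content was never published).
_FIXED_ORDER_SEEDS = {1: 20230911, 2: 20230912, 3: 20230913}
_FIXED_ORDERS = {
    oid: _random_test_order(np.random.default_rng(s))
    for oid, s in _FIXED_ORDER_SEEDS.items()
}


def gen_swi_design(order_id: int | str = 1, seed: int = 0) -> SWIDesign:
    """Generate an SWI design.

    ``order_id`` selects one of the three fixed pseudorandom test orders
    (1..3, independent of ``seed``) or, with ``"random"``, draws a fresh
    constrained order from ``seed``.
    """
    if order_id == "random":
        order = _random_test_order(np.random.default_rng(seed))
    elif order_id in _FIXED_ORDERS:
        order = _FIXED_ORDERS[order_id]
    else:
        raise ValueError(
            f"order_id must be 1, 2, 3 or 'random', got {order_id!r}"
        )
    baseline = tuple(
        SWITrial("medium", MASSES_G["control"], phase="baseline")
        for _ in range(N_BASELINE)
    )
    test = tuple(SWITrial(s, m, phase="test") for s, m in order)
    return SWIDesign(trials=baseline + test, order_id=order_id)


def _volatile_block_lengths(rng: np.random.Generator,
                            total: int = 45) -> list[int]:
    """Random composition of ``total`` into parts from {6, 9, 12}."""

    def feasible(r: int) -> bool:
        return r == 0 or (r >= min(BLOCK_LENGTHS) and r % 3 == 0)

    lengths: list[int] = []
    r = total
    while r > 0:
        options = [p for p in BLOCK_LENGTHS if feasible(r - p)]
        p = int(rng.choice(options))
        lengths.append(p)
        r -= p
    return lengths


def _block_expected_counts(rng: np.random.Generator, lengths: list[int],
                           probs: list[float], target: int) -> list[int]:
    """Per-block expected-ball counts near p*length, summing to target."""
    counts = [int(round(p * n)) for p, n in zip(probs, lengths)]
    while sum(counts) != target:
        step = 1 if sum(counts) < target else -1
        movable = [
            i for i, (c, n) in enumerate(zip(counts, lengths))
            if 0 <= c + step <= n
        ]
        counts[int(rng.choice(movable))] += step
    return counts


def gen_interception_design(condition: str,
                            seed: int = 0) -> InterceptionDesign:
    """Generate one interception condition (45 trials, 30 expected /
    15 unexpected), deterministic given ``(condition, seed)``."""
    if condition not in ("stable", "volatile"):
        raise ValueError(
            f"condition must be 'stable' or 'volatile', got {condition!r}"
        )
    rng = np.random.default_rng(seed)
    total = N_EXPECTED + N_UNEXPECTED

    if condition == "stable":
        seq = [ELASTICITY_EXPECTED] * N_EXPECTED + \
              [ELASTICITY_UNEXPECTED] * N_UNEXPECTED
        seq = [seq[i] for i in rng.permutation(total)]
        return InterceptionDesign("stable", tuple(seq), blocks=None)

    lengths = _volatile_block_lengths(rng, total)
    probs: list[float] = []
    for _ in lengths:
        if not probs:
            probs.append(float(rng.choice(BLOCK_PROBS)))
        else:
            others = [p for p in BLOCK_PROBS if p != probs[-1]]
            probs.append(float(rng.choice(others)))
    counts = _block_expected_counts(rng, lengths, probs, N_EXPECTED)

    seq: list[float] = []
    for n, c in zip(lengths, counts):
        block = [ELASTICITY_EXPECTED] * c + \
                [ELASTICITY_UNEXPECTED] * (n - c)
        seq.extend(block[i] for i in rng.permutation(n))
    blocks = tuple(zip(lengths, probs))
    return InterceptionDesign("volatile", tuple(seq), blocks=blocks)
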