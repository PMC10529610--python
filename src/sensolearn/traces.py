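"""Synthetic raw signals: grip-force traces and gaze-pitch traces.

These generators exist to exercise the preprocessing operators (filtering,
peak-rate extraction, fixation detection) on signals whose ground truth is
known in closed form.  They use simple parametric kinematics — a logistic
force rise whose amplitude grows with the agent's heaviness belief, and a
pursuit-then-fixation gaze profile whose fixation pitch encodes the
expected bounce height — and make no claim to biomechanical fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ForceTrace",
    "GazeTrace",
    "synth_force_trace",
    "synth_gaze_trace",
    "force_peak_rate_analytic",
]

FORCE_FS = 500.0  # grip-force transducer sampling rate, samples/s
GAZE_FS = 120.0   # eye-tracker sampling rate, samples/s


@dataclass
class ForceTrace:
    """Grip force over one lifting trial (newtons, >= 1 s)."""

    fs: float
    force: np.ndarray
    size: str = ""
    mass_g: float = float("nan")

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.force) / self.fs < 1.0:
            raise ValueError("force trace must cover at least 1 s")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.force)) / self.fs

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"time_s": self.times, "force_n": self.force})


@dataclass
class GazeTrace:
    """Head-centred gaze pitch angle over one interception trial.

    ``pitch_deg`` is NaN where samples are missing; ``missing_mask`` is
    True at those samples.  ``bounce_index`` marks the ball-bounce sample
    at which the pre-bounce fixation is read out.
    """

    fs: float
    pitch_deg: np.ndarray
    bounce_index: int
    ball_rel_pos: np.ndarray | None = None
    missing_mask: np.ndarray = field(default=None)  # type: ignore

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not 0 <= self.bounce_index < len(self.pitch_deg):
            raise ValueError("bounce index must lie within the trace")
        if self.missing_mask is None:
            self.missing_mask = ~np.isfinite(self.pitch_deg)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.pitch_deg)) / self.fs

    @property
    def missing_fraction(self) -> float:
        return float(np.mean(self.missing_mask))

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"time_s": self.times, "pitch_deg": self.pitch_deg})


# Logistic rise parameters: grip builds from ~0 to an amplitude set by the
# heaviness belief, centred at RISE_T0 with rate RISE_RATE.
FORCE_BASE_N = 6.0    # amplitude for belief 0, N
FORCE_GAIN_N = 6.0    # extra amplitude at belief 1, N
RISE_RATE = 18.0      # logistic growth rate, 1/s
RISE_T0 = 0.5         # time of steepest rise, s


def force_peak_rate_analytic(belief: float) -> float:
    """Closed-form peak dF/dt of the noiseless generator: A*r/4 for the
    logistic rise F(t) = A / (1 + exp(-r (t - t0)))."""
    amplitude = FORCE_BASE_N + FORCE_GAIN_N * belief
    return amplitude * RISE_RATE / 4.0


def synth_force_trace(belief: float, size: str = "medium",
                      mass_g: float = 490.0, noise_n: float = 0.0,
                      seed: int = 0, duration_s: float = 1.2,
                      fs: float = FORCE_FS) -> ForceTrace:
    """Synthesise a grip-force trace whose peak rate grows monotonically
    with the heaviness belief in [0, 1], plus additive Gaussian noise."""
    if not 0.0 <= belief <= 1.0:
        raise ValueError(f"belief must lie in [0, 1], got {belief}")
    if noise_n < 0:
        raise ValueError("noise level must be non-negative")
    t = np.arange(int(round(duration_s * fs))) / fs
    amplitude = FORCE_BASE_N + FORCE_GAIN_N * belief
    force = amplitude / (1.0 + np.exp(-RISE_RATE * (t - RISE_T0)))
    if noise_n > 0:
        force = force + np.random.default_rng(seed).normal(0, noise_n, t.size)
    return ForceTrace(fs=fs, force=force, size=size, mass_g=mass_g)


# Gaze profile: smooth pursuit sweeping downward with the approaching
# ball, then a pre-bounce fixation held at the belief-driven target pitch.
PURSUIT_START_DEG = 18.0   # pitch at ball release, deg
PURSUIT_END_S = 0.45       # pursuit ends, fixation begins, s
FIXATION_MARGIN_S = 0.05   # fixation persists past the bounce, s


def synth_gaze_trace(target_pitch_deg: float, noise_deg: float = 0.0,
                     missing_fraction: float = 0.0, seed: int = 0,
                     duration_s: float = 1.0, bounce_time_s: float = 0.8,
                     fs: float = GAZE_FS) -> GazeTrace:
    """Synthesise a gaze-pitch trace: a fast pursuit sweep followed by a
    pre-bounce fixation at ``target_pitch_deg`` (plus per-sample Gaussian
    noise), with samples masked at the requested rate.

    The fixation spans from PURSUIT_END_S until just after the bounce, so
    it always exceeds the 100 ms detectability minimum.  The construction
    is additive in the target: two traces generated with the same seed
    and targets differing by c have fixation pitches differing by c.
    """
    if not 0.0 <= missing_fraction < 1.0:
        raise ValueError("missing fraction must lie in [0, 1)")
    if noise_deg < 0:
        raise ValueError("noise level must be non-negative")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    bounce_index = int(round(bounce_time_s * fs))

    pitch = np.empty(n)
    pursuit = t < PURSUIT_END_S
    # linear sweep from the release pitch down to the fixation target
    frac = t[pursuit] / PURSUIT_END_S
    pitch[pursuit] = PURSUIT_START_DEG + frac * (target_pitch_deg
                                                 - PURSUIT_START_DEG)
    pitch[~pursuit] = target_pitch_deg
    if noise_deg > 0:
        pitch = pitch + rng.normal(0, noise_deg, n)

    mask = np.zeros(n, dtype=bool)
    n_missing = int(round(missing_fraction * n))
    if n_missing:
        mask[rng.choice(n, size=n_missing, replace=False)] = True
        pitch = pitch.copy()
        pitch[mask] = np.nan

    ball = np.column_stack([np.zeros(n), np.maximum(0.0, t - bounce_time_s)])
    return GazeTrace(fs=fs, pitch_deg=pitch, bounce_index=bounce_index,
                     ball_rel_pos=ball, missing_mask=mask)
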