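"""Preprocessing: raw signals and stimulus metadata -> binary series.

Implements every reduction between raw recordings and the binary input
(u) / response (y) series the learning models consume:

* grip force: 14 Hz low-pass Butterworth (2nd order, zero-phase), 5-point
  central-difference differentiation, peak grip-force rate (pGFR),
  baseline correction against the final baseline lift;
* heaviness ratings: per-subject z-scoring;
* input coding: u = 1 when object size predicted weight (veridical by
  true mass, or "felt" by the subject's own heaviness classification);
* response coding: per-subject median split of baseline-corrected pGFR
  conditioned on object size;
* gaze: 3-frame median filter + 2nd-order 15 Hz Butterworth, spatial
  dispersion fixation detection (3 deg, 100 ms), pre-bounce fixation
  pitch read-out, 3.29-SD outlier screening with a 15% exclusion rule,
  and 1-SD change discretisation of pitch angles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from sensolearn.designs import MASSES_G, SWIDesign
from sensolearn.errors import PreprocessingError
from sensolearn.traces import ForceTrace, GazeTrace

__all__ = [
    "five_point_derivative",
    "extract_pgfr",
    "baseline_correct",
    "zscore_ratings",
    "code_swi_inputs",
    "code_interception_inputs",
    "discretize_grip_responses",
    "Fixation",
    "FixationSet",
    "detect_fixations",
    "screen_outliers",
    "discretize_gaze_responses",
]

FORCE_CUTOFF_HZ = 14.0
GAZE_CUTOFF_HZ = 15.0
DISPERSION_DEG = 3.0
MIN_FIXATION_S = 0.100
OUTLIER_SD = 3.29
EXCLUSION_FRACTION = 0.15
MAX_MISSING_FRACTION = 0.20
MAX_TRACKING_LOSS_S = 0.100


def five_point_derivative(x: np.ndarray, dt: float) -> np.ndarray:
    """5-point central-difference derivative at interior points.

    Returns the derivative at indices 2 .. n-3; exact for polynomials up
    to degree 4.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 5:
        raise PreprocessingError("need at least 5 samples for the 5-point stencil")
    return (x[:-4] - 8.0 * x[1:-3] + 8.0 * x[3:-1] - x[4:]) / (12.0 * dt)


def _lowpass(x: np.ndarray, cutoff_hz: float, fs: float) -> np.ndarray:
    """Zero-phase (forward-backward) 2nd-order Butterworth low-pass."""
    sos = signal.butter(2, cutoff_hz, btype="low", fs=fs, output="sos")
    padlen = 3 * 6  # sosfiltfilt default for one 2nd-order section
    if x.size <= padlen:
        raise PreprocessingError(
            f"trace of {x.size} samples is shorter than the filter warm-up"
        )
    return signal.sosfiltfilt(sos, x)


def extract_pgfr(trace: ForceTrace, contact_index: int | None = None) -> float:
    """Peak grip-force rate (N/s): maximum of the 5-point derivative of
    the 14-Hz low-passed force, over the pre-contact window.

    For synthetic traces the whole trace is the pre-contact window;
    real-data imports may supply ``contact_index`` to truncate it.
    """
    force = np.asarray(trace.force, dtype=float)
    if contact_index is not None:
        force = force[:contact_index]
    smoothed = _lowpass(force, FORCE_CUTOFF_HZ, trace.fs)
    rate = five_point_derivative(smoothed, 1.0 / trace.fs)
    return float(np.max(rate))


def baseline_correct(pgfr: float, baseline_pgfr: float) -> float:
    """Trial pGFR minus the final-baseline-lift pGFR."""
    if not (math.isfinite(pgfr) and math.isfinite(baseline_pgfr)):
        raise ValueError("pGFR values must be finite")
    return pgfr - baseline_pgfr


def zscore_ratings(ratings, subject: str = "") -> np.ndarray:
    """Per-subject standardisation of heaviness ratings (mean 0, SD 1,
    sample SD)."""
    r = np.asarray(ratings, dtype=float)
    if np.unique(r[np.isfinite(r)]).size < 2:
        raise PreprocessingError(
            f"cannot z-score ratings with zero variance (subject {subject!r})"
        )
    mean = np.nanmean(r)
    sd = np.nanstd(r, ddof=1)
    return (r - mean) / sd


def _congruent(size: str, heavy: bool) -> int:
    """u = 1 when size predicted weight: large & heavy or small & light."""
    return int((size == "large" and heavy) or (size == "small" and not heavy))


def code_swi_inputs(design: SWIDesign, mode: str = "veridical",
                    ratings=None) -> tuple[np.ndarray, np.ndarray]:
    """Code the SWI test sequence into the binary input series u.

    veridical: heaviness by true mass.  felt: heaviness classified from
    the subject's z-scored ratings (above their median = heavy); trials
    with a missing rating are masked.  Returns ``(u, valid_mask)`` over
    the test trials.
    """
    test = design.test_trials
    n = len(test)
    valid = np.ones(n, dtype=bool)
    if mode == "veridical":
        u = np.array([
            _congruent(t.size, t.mass == MASSES_G["heavy"]) for t in test
        ])
    elif mode == "felt":
        if ratings is None:
            raise ValueError("felt coding requires heaviness ratings")
        z = zscore_ratings(ratings)
        if len(z) != n:
            raise ValueError("one rating per test trial is required")
        valid = np.isfinite(z)
        med = np.nanmedian(z[valid])
        u = np.zeros(n, dtype=int)
        for i, t in enumerate(test):
            if valid[i]:
                u[i] = _congruent(t.size, bool(z[i] > med))
    else:
        raise ValueError(f"mode must be 'veridical' or 'felt', got {mode!r}")
    return u, valid


def code_interception_inputs(design) -> np.ndarray:
    """u = 1 for an expected ('normal', elasticity 0.65) ball."""
    from sensolearn.designs import ELASTICITY_EXPECTED
    return np.array([int(e == ELASTICITY_EXPECTED) for e in design.elasticity])


def discretize_grip_responses(corrected_pgfr, sizes) -> np.ndarray:
    """Median-split grip coding: y = 1 when pGFR is above the subject's
    median for large objects or at/below it for small objects — an
    expectation that weight follows size.  Ties go to the low class."""
    g = np.asarray(corrected_pgfr, dtype=float)
    if g.size < 2:
        raise PreprocessingError("need at least 2 trials for a median split")
    if len(sizes) != g.size:
        raise ValueError("sizes and pGFR series must be aligned")
    med = float(np.median(g))
    y = np.empty(g.size, dtype=int)
    for i, (v, s) in enumerate(zip(g, sizes)):
        high = v > med
        y[i] = int((s == "large" and high) or (s == "small" and not high))
    return y


@dataclass(frozen=True)
class Fixation:
    onset_s: float
    offset_s: float
    centroid_deg: float

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class FixationSet:
    fixations: list[Fixation]
    bounce_pitch_deg: float          # NaN when no fixation spans the bounce
    missing_fraction: float
    max_gap_s: float
    valid: bool = True
    flags: list[str] = field(default_factory=list)


def _interpolate_gaps(x: np.ndarray) -> np.ndarray:
    """Linear interpolation across missing samples (for filtering only)."""
    x = x.copy()
    ok = np.isfinite(x)
    if ok.all():
        return x
    idx = np.arange(x.size)
    x[~ok] = np.interp(idx[~ok], idx[ok], x[ok])
    return x


def detect_fixations(trace: GazeTrace) -> FixationSet:
    """Dispersion-based fixation detection on a gaze-pitch trace.

    The signal is median-filtered (3 frames) and low-passed (2nd-order
    15 Hz, zero-phase); windows are grown greedily while the pitch
    dispersion stays within 3 deg of visual angle and emitted once they
    last at least 100 ms.  Centroids and the pre-bounce pitch are read
    from the median-filtered signal, so a stationary segment is reported
    exactly.  Trials with > 20% missing data or a tracking loss longer
    than 100 ms are flagged invalid rather than raising.
    """
    pitch = np.asarray(trace.pitch_deg, dtype=float)
    fs = trace.fs
    n = pitch.size
    if n / fs < MIN_FIXATION_S:
        raise PreprocessingError("gaze trace shorter than 100 ms")

    missing = ~np.isfinite(pitch)
    missing_fraction = float(np.mean(missing))
    max_gap = 0
    run = 0
    for m in missing:
        run = run + 1 if m else 0
        max_gap = max(max_gap, run)
    max_gap_s = max_gap / fs

    flags = []
    if missing_fraction > MAX_MISSING_FRACTION:
        flags.append("missing_data")
    if max_gap_s > MAX_TRACKING_LOSS_S:
        flags.append("tracking_loss")

    filled = _interpolate_gaps(pitch)
    med = signal.medfilt(filled, kernel_size=3)
    smooth = _lowpass(med, GAZE_CUTOFF_HZ, fs)

    min_samples = int(math.ceil(MIN_FIXATION_S * fs))
    fixations: list[Fixation] = []
    spans: list[tuple[int, int]] = []
    start = 0
    while start < n:
        end = start
        lo = hi = smooth[start]
        while end + 1 < n:
            v = smooth[end + 1]
            if max(hi, v) - min(lo, v) > DISPERSION_DEG:
                break
            lo, hi = min(lo, v), max(hi, v)
            end += 1
        if end - start + 1 >= min_samples:
            seg = med[start:end + 1]
            fixations.append(Fixation(
                onset_s=start / fs, offset_s=(end + 1) / fs,
                centroid_deg=float(np.mean(seg)),
            ))
            spans.append((start, end))
            start = end + 1
        else:
            start += 1

    bounce_pitch = float("nan")
    for (s0, s1) in spans:
        if s0 <= trace.bounce_index <= s1:
            bounce_pitch = float(med[trace.bounce_index])
            break
    if not np.isfinite(bounce_pitch):
        flags.append("no_bounce_fixation")

    return FixationSet(
        fixations=fixations, bounce_pitch_deg=bounce_pitch,
        missing_fraction=missing_fraction, max_gap_s=max_gap_s,
        valid=not ({"missing_data", "tracking_loss"} & set(flags)),
        flags=flags,
    )


def screen_outliers(table: pd.DataFrame, value_col: str = "pitch_deg",
                    subject_col: str = "subject"
                    ) -> tuple[np.ndarray, set]:
    """Outlier and exclusion screening over a trial table.

    Values more than 3.29 SD from the pooled mean (NaN = missing) are
    flagged; subjects with more than 15% of trials flagged or missing
    are excluded.  Returns ``(outlier_mask, excluded_subjects)``.  The
    rule is single-pass (mean/SD from the full sample), so re-running it
    on the same table reproduces the same flags.
    """
    vals = table[value_col].to_numpy(dtype=float)
    if np.sum(np.isfinite(vals)) < 3:
        raise PreprocessingError("need at least 3 finite values to screen")
    mean = np.nanmean(vals)
    sd = np.nanstd(vals, ddof=1)
    outlier = np.zeros(vals.size, dtype=bool)
    if sd > 0:
        outlier = np.abs(vals - mean) > OUTLIER_SD * sd
    outlier &= np.isfinite(vals)

    excluded = set()
    bad = outlier | ~np.isfinite(vals)
    for subj, idx in table.groupby(subject_col).groups.items():
        frac = float(np.mean(bad[table.index.get_indexer(idx)]))
        if frac > EXCLUSION_FRACTION:
            excluded.add(subj)
    return outlier, excluded


def discretize_gaze_responses(pitch, valid=None,
                              init: int = 1) -> tuple[np.ndarray, float]:
    """1-SD change rule: y = 1 when gaze shifted up by more than one SD
    of the trial-to-trial pitch changes, y = 0 when down by more than
    one SD, otherwise the previous y is carried forward (no belief
    shift).  The first trial takes the modal expectation ``init``.

    Returns ``(y, sd_used)``; invalid trials inherit the running y and
    should be masked downstream via the validity mask.
    """
    p = np.asarray(pitch, dtype=float)
    ok = np.isfinite(p) if valid is None else (np.asarray(valid, bool)
                                               & np.isfinite(p))
    if ok.sum() < 2:
        raise PreprocessingError("need at least 2 valid trials to discretise")
    vi = np.flatnonzero(ok)
    diffs = np.diff(p[vi])
    sd = float(np.std(diffs, ddof=1)) if diffs.size > 1 else float(abs(diffs[0]))
    y = np.empty(p.size, dtype=int)
    cur = init
    prev_pitch = None
    for k in range(p.size):
        if ok[k]:
            if prev_pitch is not None and sd > 0:
                d = p[k] - prev_pitch
                if d > sd:
                    cur = 1
                elif d < -sd:
                    cur = 0
            prev_pitch = p[k]
        y[k] = cur
    return y, sd
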