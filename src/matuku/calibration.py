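"""Calibrating recorder counts against field-observer counts.

For each recorder x processing option the paired per-session counts
(observer, device) are summarised two ways, following common practice for
count indices that are non-normal:

* Spearman's rank correlation rho (ties averaged), its Fisher
  transformation z = atanh(rho), and a p-value from the t approximation
  with n - 2 degrees of freedom;
* a least-squares regression forced through the origin, y = b x with
  x = observer count and y = device count, whose slope b estimates the
  device's per-call detection ratio on the 1:1 scale, with SE and a
  t-based confidence interval on n - 1 degrees of freedom.

The same machinery compares minimum *individual* counts from stereo
recordings with observer individual counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assignment import assign_observer, assign_stereo_audible
from .survey import MONO, OBS, STEREO, CountSession

__all__ = [
    "OPTIONS",
    "PairedCounts",
    "CalibrationResult",
    "InsufficientDataError",
    "ZeroVarianceError",
    "spearman",
    "fisher_z",
    "through_origin_fit",
    "calibration_table",
    "individuals_calibration",
    "results_to_frame",
    "pairs_to_frame",
]

# Recorder x processing options; VISUAL and AUDIBLE differ in the sound
# files' processing, so both draw on the same recorded channel.
OPTIONS = ("MONO-VISUAL", "MONO-AUDIBLE", "STEREO-VISUAL", "STEREO-AUDIBLE")
_OPTION_CHANNEL = {
    "MONO-VISUAL": MONO,
    "MONO-AUDIBLE": MONO,
    "STEREO-VISUAL": STEREO,
    "STEREO-AUDIBLE": STEREO,
}


class InsufficientDataError(ValueError):
    """Too few pairs for the requested statistic."""


class ZeroVarianceError(ValueError):
    """A margin is constant, so the rank correlation is undefined."""


@dataclass(frozen=True)
class PairedCounts:
    """Per-session (observer_count, device_count) pairs for one option."""

    option: str
    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        for x, y in self.pairs:
            if x < 0 or y < 0:
                raise ValueError("counts must be non-negative")

    @property
    def observer(self) -> np.ndarray:
        return np.array([p[0] for p in self.pairs], dtype=float)

    @property
    def device(self) -> np.ndarray:
        return np.array([p[1] for p in self.pairs], dtype=float)


@dataclass(frozen=True)
class CalibrationResult:
    option: str
    rho: float
    z: float
    p: float
    df: int
    n: int
    slope: float
    slope_se: float
    ci_low: float
    ci_high: float


def spearman(pairs: PairedCounts | Sequence[tuple[int, int]]) -> tuple[float, float, int, int]:
    """Spearman's rho with tie-averaged ranks; returns (rho, p, df, n).

    The p-value uses the t approximation on n - 2 degrees of freedom,
    appropriate for the sample sizes of a season-long campaign.
    """
    pc = pairs if isinstance(pairs, PairedCounts) else PairedCounts("", tuple(pairs))
    x, y = pc.observer, pc.device
    n = len(x)
    if n < 3:
        raise InsufficientDataError(f"need at least 3 pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("a margin has zero variance; rho undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p), n - 2, n


def fisher_z(rho: float) -> float:
    """Fisher's variance-stabilising transformation, atanh(rho)."""
    if abs(rho) >= 1.0:
        raise ValueError("|rho| must be < 1 for the Fisher transformation")
    return math.atanh(rho)


def through_origin_fit(
    pairs: PairedCounts | Sequence[tuple[float, float]],
    ci_level: float = 0.95,
    *,
    normal_ci: bool = False,
) -> tuple[float, float, float, float]:
    """Least-squares slope of device on observer counts through the origin.

    Returns (slope, slope_se, ci_low, ci_high) for y = b x with
    b = sum(xy) / sum(x^2) and SE = sqrt(RSS / (n-1) / sum(x^2)).  The CI
    multiplier is the t quantile on n - 1 df (``normal_ci=True`` uses the
    normal quantile instead).
    """
    pc = pairs if isinstance(pairs, PairedCounts) else PairedCounts("", tuple(pairs))
    x, y = pc.observer, pc.device
    n = len(x)
    if n < 2:
        raise InsufficientDataError(f"need at least 2 pairs, got {n}")
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ZeroVarianceError("all observer counts are zero; slope undefined")
    slope = float(np.sum(x * y)) / sxx
    rss = float(np.sum((y - slope * x) ** 2))
    slope_se = math.sqrt(rss / (n - 1) / sxx)
    if normal_ci:
        q = stats.norm.ppf(0.5 + ci_level / 2.0)
    else:
        q = stats.t.ppf(0.5 + ci_level / 2.0, df=n - 1)
    return slope, slope_se, slope - q * slope_se, slope + q * slope_se


def _calibrate(option: str, pairs: list[tuple[int, int]], ci_level: float) -> CalibrationResult:
    pc = PairedCounts(option, tuple(pairs))
    slope, se, lo, hi = through_origin_fit(pc, ci_level)
    try:
        rho, p, df, n = spearman(pc)
        z = fisher_z(rho) if abs(rho) < 1.0 else math.copysign(math.inf, rho)
    except ZeroVarianceError:
        # Flagged undefined correlation (constant margin) — keep the fit.
        rho = z = p = math.nan
        n = len(pairs)
        df = n - 2
    return CalibrationResult(option, rho, z, p, df, n, slope, se, lo, hi)


def calibration_table(
    sessions: Iterable[CountSession],
    options: Sequence[str] = OPTIONS,
    ci_level: float = 0.95,
) -> list[CalibrationResult]:
    """One calibration row per recorder x processing option.

    Each session contributes a pair (observer call count, device call
    count) to every option whose channel it carries alongside OBS.
    Options with no paired sessions are omitted with a warning.
    """
    sessions = list(sessions)
    results = []
    for option in options:
        channel = _OPTION_CHANNEL[option]
        pairs = [
            (s.count(OBS), s.count(channel))
            for s in sessions
            if OBS in s.channels_present and channel in s.channels_present
        ]
        if not pairs:
            warnings.warn(f"no paired sessions for option {option}; omitted")
            continue
        results.append(_calibrate(option, pairs, ci_level))
    return results


def individuals_calibration(
    sessions: Iterable[CountSession],
    *,
    bearing_threshold_deg: float = 10.0,
    use_truth: bool = False,
    ci_level: float = 0.95,
) -> CalibrationResult:
    """Calibrate stereo-audible individual counts against observer counts.

    For every session carrying a STEREO channel, the stereo-audible
    volume x direction count is paired with the observer-rules minimum
    count on the OBS channel (or with the simulation truth when
    ``use_truth=True``).
    """
    pairs = []
    for s in sessions:
        if STEREO not in s.channels_present:
            continue
        device = assign_stereo_audible(s.calls.get(STEREO, [])).n_individuals
        if use_truth:
            if s.truth_n_calling is None:
                raise ValueError("use_truth requires simulated sessions")
            observer = s.truth_n_calling
        else:
            observer = assign_observer(
                s.calls.get(OBS, []), bearing_threshold_deg
            ).n_individuals
        pairs.append((observer, device))
    if not pairs:
        raise InsufficientDataError("no sessions with a STEREO channel")
    return _calibrate("STEREO-AUDIBLE-INDIVIDUALS", pairs, ci_level)


def results_to_frame(results: Iterable[CalibrationResult]) -> pd.DataFrame:
    """Summary table, one row per option (option, z, rho, p, df, n, slope, CI)."""
    return pd.DataFrame(
        [
            {
                "option": r.option,
                "z": r.z,
                "rho": r.rho,
                "p": r.p,
                "df": r.df,
                "n": r.n,
                "slope": r.slope,
                "slope_se": r.slope_se,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
            }
            for r in results
        ]
    )


def pairs_to_frame(sessions: Iterable[CountSession], option: str) -> pd.DataFrame:
    """XY pairs (observer_count, device_count) for scatter plots of one option."""
    channel = _OPTION_CHANNEL[option]
    rows = [
        {
            "session_id": s.session_id,
            "observer_count": s.count(OBS),
            "device_count": s.count(channel),
        }
        for s in sessions
        if OBS in s.channels_present and channel in s.channels_present
    ]
    return pd.DataFrame(rows)
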