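"""Synthetic paired call-count surveys.

Simulates 15-minute call-count sessions in which a field observer (OBS) and
up to two autonomous recorders (MONO, STEREO) simultaneously log the call
sequences of booming male bitterns.  Each calling bird is an agent with a
fixed bearing and distance from the listening point; each of its call
sequences carries a bearing (with observer/recorder jitter), a perceived
volume class (low/med/high, from source loudness and inverse-square
attenuation), a boom count, and — on stereo recordings — a left/right
channel assigned from the recorder's heading.

The simulator exists so that every downstream stage (individual assignment,
device calibration, power analysis) is testable without field data; its
defaults are illustrative, not calibrated to any particular wetland.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "OBS",
    "MONO",
    "STEREO",
    "CHANNELS",
    "VOLUME_CLASSES",
    "SESSION_DURATION_MIN",
    "BitternAgent",
    "CallSequence",
    "CountSession",
    "CampaignSpec",
    "DetectionSpec",
    "simulate_population",
    "simulate_session",
    "simulate_campaign",
    "simulate_session_counts",
    "stereo_channel_of",
]

OBS = "OBS"
MONO = "MONO"
STEREO = "STEREO"
CHANNELS = (OBS, MONO, STEREO)

VOLUME_CLASSES = ("low", "med", "high")

SESSION_DURATION_MIN = 15.0
_SESSION_DURATION_S = SESSION_DURATION_MIN * 60.0


@dataclass(frozen=True)
class BitternAgent:
    """One calling male: position and calling behaviour at a count station.

    ``call_rate`` is the expected number of call sequences per 15-min
    session, ``boom_mean`` the expected booms per sequence, and ``loudness``
    a positive source level on an arbitrary scale (volume classes are cut
    on ``loudness / distance^2``).
    """

    id: int
    bearing_deg: float
    distance_m: float
    call_rate: float
    boom_mean: float
    loudness: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.bearing_deg < 360.0:
            raise ValueError(f"bearing_deg must be in [0, 360), got {self.bearing_deg}")
        if self.distance_m <= 0:
            raise ValueError("distance_m must be > 0")
        if self.call_rate < 0:
            raise ValueError("call_rate must be >= 0")
        if self.boom_mean <= 0:
            raise ValueError("boom_mean must be > 0")
        if self.loudness <= 0:
            raise ValueError("loudness must be > 0")


@dataclass(frozen=True)
class CallSequence:
    """One detected call sequence (a series of booms counted as one event).

    ``channel`` is the stereo left/right assignment and is ``None`` on
    observer and mono records.  ``truth_id`` is the emitting agent's id and
    is ``None`` for real annotation data.
    """

    time_s: float
    bearing_deg: float
    volume_class: str
    boom_count: int
    channel: str | None = None
    truth_id: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.time_s <= _SESSION_DURATION_S:
            raise ValueError(f"time_s outside session duration: {self.time_s}")
        if self.volume_class not in VOLUME_CLASSES:
            raise ValueError(f"volume_class must be one of {VOLUME_CLASSES}")
        if self.boom_count < 1:
            raise ValueError("boom_count must be >= 1")
        if self.channel is not None and self.channel not in ("left", "right"):
            raise ValueError("channel must be 'left', 'right' or None")


@dataclass
class CountSession:
    """One 15-min station x occasion count with per-channel call lists."""

    station_id: str
    occasion: int
    channels_present: tuple[str, ...]
    calls: dict[str, list[CallSequence]]
    truth_n_calling: int | None = None
    duration_min: float = SESSION_DURATION_MIN
    session_id: str = ""

    def __post_init__(self) -> None:
        if self.duration_min <= 0:
            raise ValueError("duration_min must be > 0")
        for ch in self.calls:
            if ch not in self.channels_present:
                raise ValueError(f"calls contain channel {ch!r} not in channels_present")
        for ch, lst in self.calls.items():
            if any(a.time_s > b.time_s for a, b in zip(lst, lst[1:])):
                raise ValueError(f"call list for {ch!r} not sorted by time_s")

    def count(self, channel: str) -> int:
        """Number of call sequences detected on ``channel``."""
        return len(self.calls.get(channel, []))


@dataclass(frozen=True)
class CampaignSpec:
    """Composition of a paired campaign.

    Defaults mirror a season of 137 counts in which 43 sessions carried all
    three channels, 80 paired the observer with a mono recorder only, and
    14 with a stereo recorder only.
    """

    n_three_way: int = 43
    n_obs_mono: int = 80
    n_obs_stereo: int = 14
    station_count: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_three_way", "n_obs_mono", "n_obs_stereo"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.station_count < 1:
            raise ValueError("station_count must be >= 1")

    @property
    def n_sessions(self) -> int:
        return self.n_three_way + self.n_obs_mono + self.n_obs_stereo


# p_detect values may be plain probabilities or callables of distance (m),
# allowing a declining detection function per channel.
DetectProb = float | Callable[[float], float]


@dataclass(frozen=True)
class DetectionSpec:
    """Noise model linking true emissions to per-channel detections.

    ``volume_cuts`` are thresholds on the received intensity
    ``loudness * (200 / distance_m)**2``: at or above the first cut the
    class is high, at or above the second it is med, below it low.
    Misclassification flips to an adjacent class only.
    """

    p_detect: Mapping[str, DetectProb] = field(
        default_factory=lambda: {OBS: 1.0, MONO: 0.9, STEREO: 0.9}
    )
    bearing_noise_sd: float = 5.0
    volume_misclass_p: float = 0.0
    volume_cuts: tuple[float, float] = (1.0, 0.25)
    recorder_heading_deg: float = 0.0

    def __post_init__(self) -> None:
        for ch, p in self.p_detect.items():
            if not callable(p) and not 0.0 <= p <= 1.0:
                raise ValueError(f"p_detect[{ch!r}] outside [0, 1]")
        if self.bearing_noise_sd < 0:
            raise ValueError("bearing_noise_sd must be >= 0")
        if not 0.0 <= self.volume_misclass_p <= 1.0:
            raise ValueError("volume_misclass_p outside [0, 1]")
        if self.volume_cuts[0] <= self.volume_cuts[1]:
            raise ValueError("volume_cuts must be (high_cut, med_cut) with high_cut > med_cut")

    def prob(self, channel: str, distance_m: float) -> float:
        p = self.p_detect.get(channel, 0.0)
        return float(p(distance_m)) if callable(p) else float(p)


def stereo_channel_of(bearing_deg: float, recorder_heading_deg: float = 0.0) -> str:
    """Left/right channel for a call at ``bearing_deg`` given the recorder heading.

    Bearings strictly in the half-plane left of the heading axis map to
    ``"left"``; everything else, including bearings exactly on the axis
    (the documented tie-break), maps to ``"right"``.
    """
    if not (math.isfinite(bearing_deg) and math.isfinite(recorder_heading_deg)):
        raise ValueError("bearing and heading must be finite")
    rel = (bearing_deg - recorder_heading_deg) % 360.0
    return "left" if 180.0 < rel < 360.0 else "right"


def simulate_population(
    n_birds: int,
    spatial_extent: float = 360.0,
    seed: int | np.random.Generator = 0,
    *,
    distance_range_m: tuple[float, float] = (100.0, 800.0),
    call_rate_mean: float = 3.0,
    boom_mean_range: tuple[float, float] = (2.0, 4.0),
) -> list[BitternAgent]:
    """Draw ``n_birds`` calling males around a station.

    Bearings are uniform on ``[0, spatial_extent)`` — the arc visible from
    the station, 360 for a mid-wetland deployment, 180 for an edge one.
    Distances are uniform on ``distance_range_m``; per-session call rates
    are Gamma with mean ``call_rate_mean`` (shape 2); per-sequence boom
    means are uniform on ``boom_mean_range``; loudness is log-normal.
    """
    if n_birds < 0:
        raise ValueError("n_birds must be >= 0")
    if not 0.0 < spatial_extent <= 360.0:
        raise ValueError("spatial_extent must be in (0, 360]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    agents = []
    for i in range(n_birds):
        agents.append(
            BitternAgent(
                id=i,
                bearing_deg=float(rng.uniform(0.0, spatial_extent)) % 360.0,
                distance_m=float(rng.uniform(*distance_range_m)),
                call_rate=float(rng.gamma(2.0, call_rate_mean / 2.0)),
                boom_mean=float(rng.uniform(*boom_mean_range)),
                loudness=float(rng.lognormal(0.0, 0.3)),
            )
        )
    return agents


def _true_volume_class(agent: BitternAgent, cuts: tuple[float, float]) -> str:
    intensity = agent.loudness * (200.0 / agent.distance_m) ** 2
    if intensity >= cuts[0]:
        return "high"
    if intensity >= cuts[1]:
        return "med"
    return "low"


def _maybe_misclassify(volume: str, p: float, rng: np.random.Generator) -> str:
    if p <= 0.0 or rng.random() >= p:
        return volume
    i = VOLUME_CLASSES.index(volume)
    if i == 0:
        return VOLUME_CLASSES[1]
    if i == len(VOLUME_CLASSES) - 1:
        return VOLUME_CLASSES[-2]
    return VOLUME_CLASSES[i + rng.choice((-1, 1))]


def simulate_session(
    agents: Sequence[BitternAgent],
    detection: DetectionSpec,
    channels: Sequence[str] = CHANNELS,
    seed: int | np.random.Generator = 0,
    *,
    station_id: str = "S01",
    occasion: int = 1,
) -> CountSession:
    """Simulate one 15-min count.

    Each agent emits Poisson(call_rate) sequences at uniform times; every
    emission is then thinned independently per channel with that channel's
    detection probability, and the surviving copies pick up bearing jitter,
    possible volume misclassification, and (STEREO) a left/right channel.
    ``truth_n_calling`` counts agents that emitted at least once.
    """
    channels = tuple(channels)
    if not channels:
        raise ValueError("channel set must be non-empty")
    for ch in channels:
        if ch not in CHANNELS:
            raise ValueError(f"unknown channel {ch!r}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    # Emission stage, shared by all channels.  Boom count is a per-bird
    # signature: drawn once per session (1 + Poisson(boom_mean - 1), so
    # support >= 1 with mean boom_mean) and repeated on every sequence —
    # the within-individual consistency the boom criterion relies on.
    emissions: list[tuple[float, BitternAgent, str, int]] = []
    truth_n_calling = 0
    for agent in agents:
        n_seq = int(rng.poisson(agent.call_rate))
        if n_seq > 0:
            truth_n_calling += 1
        times = np.sort(rng.uniform(0.0, _SESSION_DURATION_S, size=n_seq))
        true_vol = _true_volume_class(agent, detection.volume_cuts)
        boom = 1 + int(rng.poisson(max(agent.boom_mean - 1.0, 0.0)))
        for t in times:
            emissions.append((float(t), agent, true_vol, boom))
    emissions.sort(key=lambda e: e[0])

    # Per-channel detection stage.
    calls: dict[str, list[CallSequence]] = {ch: [] for ch in channels}
    for t, agent, true_vol, boom in emissions:
        for ch in channels:
            if rng.random() >= detection.prob(ch, agent.distance_m):
                continue
            bearing = agent.bearing_deg
            if detection.bearing_noise_sd > 0:
                bearing = (bearing + rng.normal(0.0, detection.bearing_noise_sd)) % 360.0
            vol = _maybe_misclassify(true_vol, detection.volume_misclass_p, rng)
            stereo_ch = (
                stereo_channel_of(bearing, detection.recorder_heading_deg)
                if ch == STEREO
                else None
            )
            calls[ch].append(
                CallSequence(
                    time_s=t,
                    bearing_deg=bearing,
                    volume_class=vol,
                    boom_count=boom,
                    channel=stereo_ch,
                    truth_id=agent.id,
                )
            )

    return CountSession(
        station_id=station_id,
        occasion=occasion,
        channels_present=channels,
        calls=calls,
        truth_n_calling=truth_n_calling,
    )


def simulate_campaign(
    spec: CampaignSpec,
    detection: DetectionSpec | None = None,
    *,
    mean_birds: float = 3.0,
    spatial_extent: float = 360.0,
) -> list[CountSession]:
    """Simulate a full paired campaign.

    Sessions are generated in three blocks with channel subsets
    (OBS, MONO, STEREO), (OBS, MONO) and (OBS, STEREO), sized by ``spec``.
    Stations cycle over ``spec.station_count``, the occasion number
    incrementing each time the cycle wraps.  Each session sees a fresh
    population of Poisson(``mean_birds``) agents.  Fully deterministic
    under ``spec.seed``.
    """
    detection = detection or DetectionSpec()
    rng = np.random.default_rng(spec.seed)
    blocks = [
        ((OBS, MONO, STEREO), spec.n_three_way),
        ((OBS, MONO), spec.n_obs_mono),
        ((OBS, STEREO), spec.n_obs_stereo),
    ]
    sessions: list[CountSession] = []
    i = 0
    for channels, count in blocks:
        for _ in range(count):
            station = i % spec.station_count
            occasion = i // spec.station_count + 1
            n_birds = int(rng.poisson(mean_birds))
            agents = simulate_population(n_birds, spatial_extent, rng)
            sess = simulate_session(
                agents,
                detection,
                channels,
                rng,
                station_id=f"S{station + 1:02d}",
                occasion=occasion,
            )
            sess.session_id = f"C{i + 1:03d}"
            sessions.append(sess)
            i += 1
    return sessions


def simulate_session_counts(
    rate: float, n_sessions: int, rng: np.random.Generator
) -> np.ndarray:
    """Session-level call-sequence counts at expected ``rate`` per session.

    Per-agent emissions are Poisson, so the session total over any
    population with summed rate ``rate`` is Poisson(``rate``); this is the
    aggregate shortcut the power module uses to avoid building call objects.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    return rng.poisson(rate, size=n_sessions)
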