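"""Rule-based minimum numbers of calling individuals.

Two conservative estimators of how many distinct birds called during a
count, both designed so that ambiguity always merges candidates (a
*minimum* count):

* the field-observer rules — a call belongs to an already-heard bird
  unless its bearing is more than a threshold (default 10 degrees) from
  every candidate, or its volume class clashes, or its boom count is
  consistently different;
* the stereo-audible rules — birds on a stereo recording are told apart
  only by the combination of volume class (low/med/high) and ear
  (left/right), which caps the count at 3 x 2 = 6.

The observer rules are stated per call pair in the field protocol; here
they are operationalised as incremental clustering: each call, in temporal
order, either joins the nearest accepting cluster or founds a new one.
The exact acceptance rule and its tie-breaks are documented on
:func:`assign_observer`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .survey import VOLUME_CLASSES, CallSequence

__all__ = [
    "BirdCluster",
    "AssignmentResult",
    "assign_observer",
    "assign_stereo_audible",
    "distinguishable_capacity",
    "circular_difference",
    "circular_mean",
]


def circular_difference(a_deg: float, b_deg: float) -> float:
    """Absolute angular difference in degrees, folded into [0, 180]."""
    return abs((a_deg - b_deg + 180.0) % 360.0 - 180.0)


def circular_mean(bearings_deg: Sequence[float]) -> float:
    """Circular mean bearing in [0, 360)."""
    if not bearings_deg:
        raise ValueError("need at least one bearing")
    s = sum(math.sin(math.radians(b)) for b in bearings_deg)
    c = sum(math.cos(math.radians(b)) for b in bearings_deg)
    if s == 0.0 and c == 0.0:
        # Perfectly antipodal set: mean direction undefined; fall back to
        # the first bearing for determinism.
        return bearings_deg[0] % 360.0
    mean = math.degrees(math.atan2(s, c)) % 360.0
    # A tiny negative angle can fold to exactly 360.0 in floating point.
    return 0.0 if mean >= 360.0 else mean


@dataclass
class BirdCluster:
    """Bookkeeping for one putative bird during incremental assignment."""

    cluster_id: int
    member_calls: list[CallSequence] = field(default_factory=list)
    reference_bearing_deg: float = 0.0
    volume_classes_seen: set[str] = field(default_factory=set)
    boom_counts_seen: set[int] = field(default_factory=set)

    def add(self, call: CallSequence) -> None:
        self.member_calls.append(call)
        self.volume_classes_seen.add(call.volume_class)
        self.boom_counts_seen.add(call.boom_count)
        self.reference_bearing_deg = circular_mean(
            [c.bearing_deg for c in self.member_calls]
        )


@dataclass
class AssignmentResult:
    n_individuals: int
    clusters: list[BirdCluster]
    method: str

    def __post_init__(self) -> None:
        if self.n_individuals != len(self.clusters):
            raise ValueError("n_individuals must equal number of clusters")


def _volume_adjacent(a: str, b: str) -> bool:
    return abs(VOLUME_CLASSES.index(a) - VOLUME_CLASSES.index(b)) == 1


def _cluster_accepts(
    cluster: BirdCluster,
    call: CallSequence,
    bearing_threshold_deg: float,
    adjacent_volume_start: bool,
) -> bool:
    diff = circular_difference(call.bearing_deg, cluster.reference_bearing_deg)
    if diff > bearing_threshold_deg:
        return False
    if call.volume_class not in cluster.volume_classes_seen:
        # A different volume category normally marks a new bird.  A
        # single-observation cluster may still absorb an *adjacent* class
        # when the bearings nearly coincide (within half the threshold):
        # one observation fixes the category only loosely.  Disable via
        # adjacent_volume_start=False for the strict reading.
        soft = (
            adjacent_volume_start
            and len(cluster.member_calls) == 1
            and _volume_adjacent(call.volume_class, next(iter(cluster.volume_classes_seen)))
            and diff <= bearing_threshold_deg / 2.0
        )
        if not soft:
            return False
    # "Consistently" different booms needs repetition: a cluster observed
    # only once cannot yet be consistently different from anything.
    if len(cluster.member_calls) >= 2 and call.boom_count not in cluster.boom_counts_seen:
        return False
    return True


def assign_observer(
    calls: Sequence[CallSequence],
    bearing_threshold_deg: float = 10.0,
    *,
    adjacent_volume_start: bool = True,
) -> AssignmentResult:
    """Minimum number of calling birds under the field-observer rules.

    Calls are processed in temporal order against the running cluster set.
    A cluster accepts a call iff all of:

    * the circular difference between the call bearing and the cluster's
      reference bearing (circular mean of members) is within
      ``bearing_threshold_deg``;
    * the call's volume class has been seen in the cluster — or the
      cluster has a single member, the classes are adjacent, and the
      bearing difference is within half the threshold (set
      ``adjacent_volume_start=False`` to disable this softening);
    * the call's boom count is not *consistently* different, i.e. the
      cluster has at least two members and none shares the boom count.

    A call accepted by no cluster founds a new bird.  If several clusters
    accept, the smallest bearing difference wins, ties going to the lowest
    cluster id — ambiguity always resolves to fewer birds.
    """
    if bearing_threshold_deg < 0:
        raise ValueError("bearing_threshold_deg must be >= 0")
    calls = list(calls)
    if any(a.time_s > b.time_s for a, b in zip(calls, calls[1:])):
        raise ValueError("calls must be sorted by time_s")
    for call in calls:
        if not 0.0 <= call.bearing_deg < 360.0:
            raise ValueError(f"bearing outside [0, 360): {call.bearing_deg}")

    clusters: list[BirdCluster] = []
    for call in calls:
        accepting = [
            c
            for c in clusters
            if _cluster_accepts(c, call, bearing_threshold_deg, adjacent_volume_start)
        ]
        if accepting:
            best = min(
                accepting,
                key=lambda c: (
                    circular_difference(call.bearing_deg, c.reference_bearing_deg),
                    c.cluster_id,
                ),
            )
            best.add(call)
        else:
            new = BirdCluster(cluster_id=len(clusters))
            new.add(call)
            clusters.append(new)

    return AssignmentResult(
        n_individuals=len(clusters), clusters=clusters, method="observer_criteria"
    )


def assign_stereo_audible(calls: Sequence[CallSequence]) -> AssignmentResult:
    """Minimum number of birds audible on a stereo recording.

    Two calls are attributed to different birds only when their
    (volume class, left/right channel) combinations differ, so the result
    never exceeds the six available combinations.
    """
    for call in calls:
        if call.channel is None:
            raise ValueError("every call needs a stereo channel for the audible rules")

    clusters: dict[tuple[str, str], BirdCluster] = {}
    for call in calls:
        key = (call.volume_class, call.channel)
        if key not in clusters:
            clusters[key] = BirdCluster(cluster_id=len(clusters))
        clusters[key].add(call)

    cluster_list = list(clusters.values())
    return AssignmentResult(
        n_individuals=len(cluster_list), clusters=cluster_list, method="stereo_audible"
    )


def distinguishable_capacity(n_volume_classes: int = 3, n_direction_classes: int = 2) -> int:
    """Maximum number of birds separable by volume x direction combinations."""
    if n_volume_classes < 1 or n_direction_classes < 1:
        raise ValueError("class counts must be >= 1")
    return n_volume_classes * n_direction_classes
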