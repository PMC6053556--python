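"""Reading and writing call-count data.

Two plain-text interchange formats are supported:

* a campaign as a pair of CSVs — one row per detected call sequence plus a
  sessions table — which round-trips the simulator's output and is also
  the entry point for real annotation tables;
* Raven-style tab-separated selection tables (one selection per row, with
  "Begin Time (s)" and "Channel" columns), extended with volume-class and
  boom-count columns, as produced when sound files are annotated by hand.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd

from .survey import CallSequence, CountSession

__all__ = [
    "calls_to_frame",
    "sessions_to_frame",
    "export_campaign",
    "import_campaign",
    "read_raven_selection_table",
]

CALL_COLUMNS = [
    "session_id",
    "station_id",
    "occasion",
    "channel",
    "time_s",
    "bearing_deg",
    "volume_class",
    "boom_count",
    "stereo_channel",
    "truth_id",
]

SESSION_COLUMNS = [
    "session_id",
    "station_id",
    "occasion",
    "channels_present",
    "truth_n_calling",
]


def calls_to_frame(sessions: Iterable[CountSession]) -> pd.DataFrame:
    """One row per detected call sequence across all sessions and channels."""
    rows = []
    for sess in sessions:
        for channel in sess.channels_present:
            for call in sess.calls.get(channel, []):
                rows.append(
                    {
                        "session_id": sess.session_id,
                        "station_id": sess.station_id,
                        "occasion": sess.occasion,
                        "channel": channel,
                        "time_s": call.time_s,
                        "bearing_deg": call.bearing_deg,
                        "volume_class": call.volume_class,
                        "boom_count": call.boom_count,
                        "stereo_channel": call.channel if call.channel else "",
                        "truth_id": call.truth_id if call.truth_id is not None else "",
                    }
                )
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def sessions_to_frame(sessions: Iterable[CountSession]) -> pd.DataFrame:
    rows = [
        {
            "session_id": s.session_id,
            "station_id": s.station_id,
            "occasion": s.occasion,
            "channels_present": "+".join(s.channels_present),
            "truth_n_calling": s.truth_n_calling if s.truth_n_calling is not None else "",
        }
        for s in sessions
    ]
    return pd.DataFrame(rows, columns=SESSION_COLUMNS)


def export_campaign(sessions: Iterable[CountSession], out_dir: str) -> tuple[str, str]:
    """Write ``calls.csv`` and ``sessions.csv`` under ``out_dir``; return the paths."""
    sessions = list(sessions)
    os.makedirs(out_dir, exist_ok=True)
    calls_path = os.path.join(out_dir, "calls.csv")
    sessions_path = os.path.join(out_dir, "sessions.csv")
    calls_to_frame(sessions).to_csv(calls_path, index=False, float_format="%.6f")
    sessions_to_frame(sessions).to_csv(sessions_path, index=False)
    return calls_path, sessions_path


def _call_from_row(row: pd.Series) -> CallSequence:
    stereo = row.get("stereo_channel", "")
    truth = row.get("truth_id", "")
    return CallSequence(
        time_s=float(row["time_s"]),
        bearing_deg=float(row["bearing_deg"]),
        volume_class=str(row["volume_class"]),
        boom_count=int(row["boom_count"]),
        channel=str(stereo) if isinstance(stereo, str) and stereo else None,
        truth_id=int(truth) if truth not in ("", None) and not pd.isna(truth) else None,
    )


def import_campaign(in_dir: str) -> list[CountSession]:
    """Rebuild :class:`CountSession` objects from a campaign directory."""
    calls = pd.read_csv(os.path.join(in_dir, "calls.csv"), keep_default_na=False)
    meta = pd.read_csv(os.path.join(in_dir, "sessions.csv"), keep_default_na=False)
    grouped = dict(tuple(calls.groupby("session_id"))) if len(calls) else {}
    sessions = []
    for _, m in meta.iterrows():
        channels = tuple(str(m["channels_present"]).split("+"))
        per_channel: dict[str, list[CallSequence]] = {ch: [] for ch in channels}
        g = grouped.get(m["session_id"])
        if g is not None:
            for ch, sub in g.groupby("channel"):
                sub = sub.sort_values("time_s")
                per_channel[str(ch)] = [_call_from_row(r) for _, r in sub.iterrows()]
        truth = m["truth_n_calling"]
        sessions.append(
            CountSession(
                station_id=str(m["station_id"]),
                occasion=int(m["occasion"]),
                channels_present=channels,
                calls=per_channel,
                truth_n_calling=int(truth) if str(truth) != "" else None,
                session_id=str(m["session_id"]),
            )
        )
    return sessions


def read_raven_selection_table(
    path: str,
    *,
    volume_column: str = "Volume",
    boom_column: str = "Booms",
    bearing_column: str = "Bearing (deg)",
) -> list[CallSequence]:
    """Read an annotated Raven-style selection table into call sequences.

    Requires "Begin Time (s)" plus the volume-class and boom-count
    extension columns; "Channel" (1 = left, 2 = right, Raven convention)
    and a bearing column are used when present.  Rows are returned sorted
    by begin time.
    """
    df = pd.read_csv(path, sep="\t")
    required = ["Begin Time (s)", volume_column, boom_column]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"selection table missing columns: {missing}")
    df = df.sort_values("Begin Time (s)")
    calls = []
    for _, row in df.iterrows():
        channel = None
        if "Channel" in df.columns and not pd.isna(row["Channel"]):
            channel = "left" if int(row["Channel"]) == 1 else "right"
        bearing = 0.0
        if bearing_column in df.columns and not pd.isna(row[bearing_column]):
            bearing = float(row[bearing_column]) % 360.0
        calls.append(
            CallSequence(
                time_s=float(row["Begin Time (s)"]),
                bearing_deg=bearing,
                volume_class=str(row[volume_column]).strip().lower(),
                boom_count=int(row[boom_column]),
                channel=channel,
            )
        )
    return calls
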