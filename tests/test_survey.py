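"""Synthetic survey generator: structure, noise model, reproducibility."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from matuku import (
    BitternAgent,
    CallSequence,
    CampaignSpec,
    DetectionSpec,
    simulate_campaign,
    simulate_population,
    simulate_session,
    stereo_channel_of,
)
from matuku.io import calls_to_frame, export_campaign, import_campaign, read_raven_selection_table
from matuku.survey import simulate_session_counts


class TestPopulation:
    def test_empty_population(self):
        assert simulate_population(0) == []

    def test_bearings_respect_arc(self):
        agents = simulate_population(6, spatial_extent=180.0, seed=7)
        assert len(agents) == 6
        assert all(0.0 <= a.bearing_deg < 180.0 for a in agents)

    def test_deterministic_under_seed(self):
        assert simulate_population(12, seed=1) == simulate_population(12, seed=1)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            simulate_population(-1)

    def test_agent_field_validation(self):
        with pytest.raises(ValueError):
            BitternAgent(id=0, bearing_deg=360.0, distance_m=100, call_rate=1, boom_mean=2)
        with pytest.raises(ValueError):
            BitternAgent(id=0, bearing_deg=0, distance_m=-5, call_rate=1, boom_mean=2)


class TestSession:
    def test_empty_population_gives_empty_session(self, noiseless_detection):
        sess = simulate_session([], noiseless_detection, seed=0)
        assert sess.truth_n_calling == 0
        assert all(sess.count(ch) == 0 for ch in sess.channels_present)

    def test_perfect_detection_equal_channels(self, noiseless_detection):
        agents = simulate_population(5, seed=3)
        sess = simulate_session(agents, noiseless_detection, seed=4)
        obs, mono, stereo = sess.calls["OBS"], sess.calls["MONO"], sess.calls["STEREO"]
        assert len(obs) == len(mono) == len(stereo) > 0
        for a, b, c in zip(obs, mono, stereo):
            assert a.time_s == b.time_s == c.time_s
            assert a.bearing_deg == b.bearing_deg == c.bearing_deg
            assert a.volume_class == b.volume_class == c.volume_class
            assert a.boom_count == b.boom_count == c.boom_count
            assert c.channel in ("left", "right") and a.channel is None

    def test_forced_miss_on_one_channel(self):
        det = DetectionSpec(p_detect={"OBS": 1.0, "MONO": 0.0, "STEREO": 1.0})
        agents = [BitternAgent(0, 10.0, 300.0, call_rate=8.0, boom_mean=3.0)]
        sess = simulate_session(agents, det, seed=5)
        assert sess.count("MONO") == 0
        assert sess.count("OBS") > 0

    def test_empty_channel_set_rejected(self, noiseless_detection):
        with pytest.raises(ValueError):
            simulate_session([], noiseless_detection, channels=())

    def test_truth_counts_only_calling_agents(self, noiseless_detection):
        silent = BitternAgent(0, 0.0, 300.0, call_rate=0.0, boom_mean=2.0)
        loud = BitternAgent(1, 90.0, 300.0, call_rate=20.0, boom_mean=2.0)
        sess = simulate_session([silent, loud], noiseless_detection, seed=6)
        assert sess.truth_n_calling == 1

    def test_detection_monotone_in_probability(self):
        """Raising a channel's detection probability raises its mean count."""
        agents = simulate_population(4, seed=11)
        totals = {}
        for p in (0.3, 0.9):
            det = DetectionSpec(p_detect={"OBS": p})
            totals[p] = sum(
                simulate_session(agents, det, channels=("OBS",), seed=s).count("OBS")
                for s in range(250)
            )
        assert totals[0.9] > totals[0.3]

    def test_distance_dependent_detection(self):
        near = BitternAgent(0, 0.0, 100.0, call_rate=10.0, boom_mean=2.0)
        far = BitternAgent(1, 90.0, 790.0, call_rate=10.0, boom_mean=2.0)
        det = DetectionSpec(p_detect={"OBS": lambda d: 1.0 if d < 400 else 0.0})
        sess = simulate_session([near, far], det, channels=("OBS",), seed=8)
        assert sess.count("OBS") > 0
        assert all(c.truth_id == 0 for c in sess.calls["OBS"])


class TestStereoChannel:
    @pytest.mark.parametrize(
        "bearing,heading,expected",
        [
            (90.0, 0.0, "right"),
            (270.0, 0.0, "left"),
            (0.0, 0.0, "right"),  # on-axis tie-break
            (180.0, 0.0, "right"),  # rear on-axis tie-break
            (10.0, 100.0, "left"),
            (350.0, 270.0, "right"),
        ],
    )
    def test_half_plane_convention(self, bearing, heading, expected):
        assert stereo_channel_of(bearing, heading) == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            stereo_channel_of(float("nan"), 0.0)


class TestCampaign:
    def test_default_composition(self, default_campaign):
        assert len(default_campaign) == 137
        subsets = [tuple(s.channels_present) for s in default_campaign]
        assert subsets.count(("OBS", "MONO", "STEREO")) == 43
        assert subsets.count(("OBS", "MONO")) == 80
        assert subsets.count(("OBS", "STEREO")) == 14

    def test_empty_spec(self):
        spec = CampaignSpec(n_three_way=0, n_obs_mono=0, n_obs_stereo=0)
        assert simulate_campaign(spec) == []

    def test_stations_cycle(self):
        camp = simulate_campaign(CampaignSpec(station_count=10, seed=0))
        assert camp[0].station_id == "S01" and camp[10].station_id == "S01"
        assert camp[10].occasion == 2

    def test_campaign_csv_roundtrip_bit_identical(self, tmp_path):
        spec = CampaignSpec(n_three_way=5, n_obs_mono=3, n_obs_stereo=2, seed=9)
        for d in ("a", "b"):
            export_campaign(simulate_campaign(spec), tmp_path / d)
        assert (tmp_path / "a" / "calls.csv").read_bytes() == (
            tmp_path / "b" / "calls.csv"
        ).read_bytes()

    def test_import_rebuilds_sessions(self, tmp_path):
        camp = simulate_campaign(CampaignSpec(n_three_way=4, n_obs_mono=2, n_obs_stereo=1, seed=5))
        export_campaign(camp, tmp_path)
        back = import_campaign(str(tmp_path))
        assert len(back) == len(camp)
        for orig, re in zip(camp, back):
            assert re.session_id == orig.session_id
            assert re.channels_present == orig.channels_present
            assert re.truth_n_calling == orig.truth_n_calling
            for ch in orig.channels_present:
                assert re.count(ch) == orig.count(ch)
                for c1, c2 in zip(orig.calls[ch], re.calls[ch]):
                    assert c2.volume_class == c1.volume_class
                    assert c2.boom_count == c1.boom_count
                    assert c2.channel == c1.channel
                    assert abs(c2.bearing_deg - c1.bearing_deg) < 1e-5


class TestRavenReader:
    def test_selection_table(self, tmp_path):
        table = (
            "Selection\tView\tChannel\tBegin Time (s)\tEnd Time (s)\tVolume\tBooms\n"
            "1\tSpectrogram 1\t1\t12.5\t16.0\tHigh\t3\n"
            "2\tSpectrogram 1\t2\t80.0\t84.0\tlow\t2\n"
            "3\tSpectrogram 1\t1\t40.0\t43.0\tmed\t4\n"
        )
        path = tmp_path / "sel.txt"
        path.write_text(table)
        calls = read_raven_selection_table(str(path))
        assert [c.time_s for c in calls] == [12.5, 40.0, 80.0]
        assert [c.channel for c in calls] == ["left", "left", "right"]
        assert [c.volume_class for c in calls] == ["high", "med", "low"]
        assert [c.boom_count for c in calls] == [3, 4, 2]

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("Selection\tBegin Time (s)\n1\t3.0\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_raven_selection_table(str(path))


class TestSessionCounts:
    def test_poisson_mean(self, rng):
        counts = simulate_session_counts(9.0, 20000, rng)
        assert abs(counts.mean() - 9.0) < 0.1

    def test_negative_rate_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_session_counts(-1.0, 10, rng)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    bearing=st.floats(0.0, 359.999),
    heading=st.floats(-720.0, 720.0),
)
def test_stereo_channels_partition_the_circle(bearing, heading):
    """Every bearing maps to exactly one channel; mirrored bearings differ."""
    ch = stereo_channel_of(bearing, heading)
    assert ch in ("left", "right")
    rel = (bearing - heading) % 360.0
    off_axis = min(rel, abs(rel - 180.0), 360.0 - rel) > 1e-6
    if off_axis:
        mirrored = (heading - rel) % 360.0
        assert stereo_channel_of(mirrored, heading) != ch


def test_calls_frame_has_expected_schema(default_campaign):
    df = calls_to_frame(default_campaign[:5])
    assert list(df.columns) == [
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
    assert set(df["volume_class"]) <= {"low", "med", "high"}
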