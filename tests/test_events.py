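"""Detection-record I/O, independent-event filtering and count tables."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from camtraptime.events import (
    RowParseError,
    SchemaError,
    deduplicate,
    read_detections,
    read_deployments,
    summarize_counts,
    to_time_of_day,
)

CSV_HEADER = "station_id,site_id,species,datetime,individual_id,sex\n"


def _csv(rows: list[str]) -> io.StringIO:
    return io.StringIO(CSV_HEADER + "\n".join(rows) + "\n")


def _records(times, station="S1", species="leopard", individual=None):
    return pd.DataFrame(
        {
            "station_id": station,
            "site_id": "site1",
            "species": species,
            "timestamp": pd.to_datetime(times),
            "individual_id": individual if individual is not None else pd.NA,
            "sex": pd.NA,
        }
    )


class TestReadDetections:
    def test_well_formed_csv_loads_every_row(self):
        df = read_detections(
            _csv(
                [
                    "S1,site1,leopard,2018-07-01 21:15:00,,",
                    "S1,site1,lion,2018-07-01 23:40:00,,M",
                    "S2,site1,leopard,2018-07-02 04:10:00,L01,F",
                ]
            )
        )
        assert len(df) == 3
        assert list(df["species"]) == ["leopard", "lion", "leopard"]
        assert df["timestamp"].dtype.kind == "M"

    def test_missing_species_column_raises_schema_error(self):
        bad = io.StringIO("station_id,site_id,datetime\nS1,site1,2018-07-01 10:00:00\n")
        with pytest.raises(SchemaError, match="species"):
            read_detections(bad)

    def test_unparseable_timestamp_reports_line_number(self):
        rows = [
            "S1,site1,leopard,2018-07-01 21:15:00,,",
            "S1,site1,leopard,2018-07-01 25:00:00,,",
            "S1,site1,leopard,2018-07-01 22:15:00,,",
        ]
        with pytest.raises(RowParseError) as exc:
            read_detections(_csv(rows))
        assert exc.value.lines == [3]
        with pytest.warns(UserWarning):
            df = read_detections(_csv(rows), on_error="skip")
        assert len(df) == 2
        assert df.attrs["row_errors"] == [3]

    def test_schema_mapping_renames_columns(self):
        src = io.StringIO(
            "cam,area,sp,when\nC1,north,lion,2018-07-01 02:00:00\n"
        )
        df = read_detections(
            src,
            schema={
                "station_id": "cam",
                "site_id": "area",
                "species": "sp",
                "timestamp": "when",
            },
        )
        assert df.loc[0, "station_id"] == "C1"


def test_read_deployments_rejects_inverted_window(tmp_path):
    p = tmp_path / "dep.csv"
    p.write_text(
        "station_id,site_id,start,end\nS1,site1,2018-09-01,2018-07-01\n"
    )
    with pytest.raises(ValueError, match="S1"):
        read_deployments(p)


class TestDeduplicate:
    def test_rolling_rule_keeps_first_of_each_cluster(self):
        # 00:00, 00:10, 00:25, 00:45 -> the 30-min rolling rule keeps
        # 00:00 (first) and 00:45 (45 min after the last retained event)
        recs = _records(
            ["2018-07-01 00:00", "2018-07-01 00:10", "2018-07-01 00:25", "2018-07-01 00:45"]
        )
        ev = deduplicate(recs)
        assert list(ev["timestamp"].dt.strftime("%H:%M")) == ["00:00", "00:45"]

    def test_distinct_individuals_never_suppress_each_other(self):
        recs = _records(
            ["2018-07-01 21:00", "2018-07-01 21:05"], individual=["L01", "L02"]
        )
        assert len(deduplicate(recs)) == 2
        # ignoring ids collapses them again
        assert len(deduplicate(recs, use_individual_ids=False)) == 1

    def test_single_record_is_retained_unchanged(self):
        recs = _records(["2018-07-01 12:00"])
        ev = deduplicate(recs)
        assert len(ev) == 1
        assert ev.loc[0, "time_of_day_rad"] == pytest.approx(np.pi)

    def test_exactly_window_apart_is_retained(self):
        # events "at least 30 minutes" apart are independent
        recs = _records(["2018-07-01 10:00", "2018-07-01 10:30"])
        assert len(deduplicate(recs)) == 2

    def test_different_stations_do_not_interact(self):
        recs = pd.concat(
            [
                _records(["2018-07-01 10:00"], station="S1"),
                _records(["2018-07-01 10:05"], station="S2"),
            ],
            ignore_index=True,
        )
        assert len(deduplicate(recs)) == 2

    def test_empty_input_gives_empty_output(self):
        ev = deduplicate(_records([]).iloc[0:0])
        assert len(ev) == 0

    @given(
        minutes=st.lists(
            st.integers(min_value=0, max_value=6 * 60), min_size=1, max_size=25, unique=True
        ),
        order=st.randoms(use_true_random=False),
    )
    def test_idempotent_and_order_insensitive(self, minutes, order):
        times = [pd.Timestamp("2018-07-01") + pd.Timedelta(minutes=m) for m in minutes]
        recs = _records(times)
        shuffled = recs.sample(frac=1, random_state=order.randint(0, 2**16)).reset_index(
            drop=True
        )
        once = deduplicate(recs)
        assert list(deduplicate(shuffled)["timestamp"]) == list(once["timestamp"])
        assert list(deduplicate(once)["timestamp"]) == list(once["timestamp"])
        # retained events honour the spacing invariant
        gaps = once["timestamp"].diff().dropna()
        assert (gaps >= pd.Timedelta(minutes=30)).all()

    @given(
        minutes=st.lists(
            st.integers(min_value=0, max_value=12 * 60), min_size=1, max_size=30, unique=True
        ),
        w1=st.integers(min_value=1, max_value=60),
        w2=st.integers(min_value=1, max_value=60),
    )
    def test_wider_window_never_retains_more(self, minutes, w1, w2):
        times = [pd.Timestamp("2018-07-01") + pd.Timedelta(minutes=m) for m in minutes]
        recs = _records(times)
        lo, hi = sorted((w1, w2))
        assert len(deduplicate(recs, window_minutes=hi)) <= len(
            deduplicate(recs, window_minutes=lo)
        )


class TestTimeOfDay:
    @pytest.mark.parametrize(
        "clock,expected",
        [("00:00:00", 0.0), ("12:00:00", np.pi), ("06:00:00", np.pi / 2)],
    )
    def test_clock_to_radians(self, clock, expected):
        df = to_time_of_day(_records([f"2018-07-01 {clock}"]))
        assert df.loc[0, "time_of_day_rad"] == pytest.approx(expected)

    def test_range_is_half_open(self):
        df = to_time_of_day(_records(["2018-07-01 23:59:59"]))
        assert 0.0 <= df.loc[0, "time_of_day_rad"] < 2 * np.pi


class TestSummarizeCounts:
    def test_empty_events_give_empty_table(self):
        out = summarize_counts(_records([]).iloc[0:0])
        assert out.empty

    def test_single_group_count(self):
        ev = deduplicate(
            _records([f"2018-07-0{d} 1{h}:00" for d, h in zip(range(1, 6), range(5))] * 2)
        )
        out = summarize_counts(ev)
        assert out.loc[0, "n_events"] == len(ev)

    def test_sex_classes_partition_all(self, guild):
        ev = guild["events"].copy()
        rng = np.random.default_rng(1)
        ev["sex"] = rng.choice(["M", "F", "Unk", None], size=len(ev))
        out = summarize_counts(ev, sex_split=True)
        assert (out["All"] == out["M"] + out["F"] + out["Unk"]).all()
        assert out["All"].sum() == len(ev)

    def test_totals_conserve_events(self, guild):
        out = summarize_counts(guild["events"])
        assert out["n_events"].sum() == len(guild["events"])
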