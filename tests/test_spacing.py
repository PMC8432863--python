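"""Temporal-spacing offsets, binning, randomization null and permutation test."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

import camtraptime as ct
from camtraptime.circular import TWO_PI, estimate_activity
from camtraptime.spacing import (
    bin_offsets,
    co_occurrence_stations,
    min_time_offsets,
    randomize_B,
    spacing_test,
)


def _ev(rows):
    """rows: (station, species, timestamp-string)"""
    return pd.DataFrame(
        {
            "station_id": [r[0] for r in rows],
            "site_id": "site1",
            "species": [r[1] for r in rows],
            "timestamp": pd.to_datetime([r[2] for r in rows]),
        }
    )


class TestCoOccurrence:
    def test_set_intersection(self):
        ev = _ev(
            [
                ("1", "A", "2018-07-01 10:00"),
                ("2", "A", "2018-07-01 10:00"),
                ("2", "B", "2018-07-01 11:00"),
                ("3", "B", "2018-07-01 11:00"),
            ]
        )
        assert co_occurrence_stations(ev, "A", "B") == ["2"]

    def test_disjoint_stations_empty(self):
        ev = _ev([("1", "A", "2018-07-01 10:00"), ("2", "B", "2018-07-01 11:00")])
        assert co_occurrence_stations(ev, "A", "B") == []

    def test_synthetic_construction(self, rng):
        rows = []
        for i in range(10):
            rows.append((f"S{i}", "A", "2018-07-01 10:00"))
            if i < 5:
                rows.append((f"S{i}", "B", "2018-07-01 12:00"))
        assert co_occurrence_stations(_ev(rows), "A", "B") == [f"S{i}" for i in range(5)]


class TestMinTimeOffsets:
    def test_simple_after_offset(self):
        ev = _ev([("1", "A", "2018-07-01 10:00"), ("1", "B", "2018-07-01 10:30")])
        off = min_time_offsets(ev, "A", "B")
        assert len(off) == 1
        assert off.iloc[0]["direction"] == "after"
        assert off.iloc[0]["offset_hours"] == pytest.approx(0.5)

    def test_intervening_A_excludes_reference(self):
        ev = _ev(
            [
                ("1", "A", "2018-07-01 10:00"),
                ("1", "A", "2018-07-01 10:20"),
                ("1", "B", "2018-07-01 10:30"),
            ]
        )
        off = min_time_offsets(ev, "A", "B")
        after = off[off["direction"] == "after"]
        assert len(after) == 1
        assert after.iloc[0]["offset_hours"] == pytest.approx(1 / 6, abs=1e-9)
        # the excluded reference also leaves the after-direction denominator
        assert off.attrs["n_ref"]["after"] == 1

    def test_beyond_window_emits_nothing(self):
        ev = _ev([("1", "A", "2018-07-01 10:00"), ("1", "B", "2018-07-01 23:30")])
        off = min_time_offsets(ev, "A", "B", window_hours=12.0)
        assert len(off) == 0
        # the reference is retained (nothing intervenes), just out of window
        assert off.attrs["n_ref"]["after"] == 1

    def test_simultaneous_capture_counts_as_after(self):
        ev = _ev([("1", "A", "2018-07-01 10:00"), ("1", "B", "2018-07-01 10:00")])
        off = min_time_offsets(ev, "A", "B")
        after = off[off["direction"] == "after"]
        assert len(after) == 1 and after.iloc[0]["offset_hours"] == 0.0


class TestBinOffsets:
    @pytest.mark.parametrize(
        "direction,offset,expected_bin",
        [
            ("after", 0.5, 1),
            ("after", 1.0, 1),  # upper-closed bins
            ("after", 1.0001, 2),
            ("after", 0.0, 1),
            ("before", 11.2, -12),
            ("before", 0.3, -1),
        ],
    )
    def test_binning_rule(self, direction, offset, expected_bin):
        off = pd.DataFrame({"direction": [direction], "offset_hours": [offset]})
        prof = bin_offsets(off, n_ref=10)
        assert prof.counts[prof.bins == expected_bin][0] == 1
        assert prof.counts.sum() == 1

    def test_probabilities_use_direction_denominators(self):
        off = pd.DataFrame(
            {"direction": ["after", "after", "before"], "offset_hours": [0.5, 2.5, 1.5]}
        )
        prof = bin_offsets(off, n_ref={"before": 4, "after": 8})
        assert prof.probabilities[prof.bins == 1][0] == pytest.approx(1 / 8)
        assert prof.probabilities[prof.bins == -2][0] == pytest.approx(1 / 4)
        assert prof.probabilities.sum() <= 2.0

    def test_half_hour_bins_conserve_mass(self, rng):
        offs = pd.DataFrame(
            {
                "direction": rng.choice(["before", "after"], 200),
                "offset_hours": rng.uniform(0, 12, 200),
            }
        )
        one = bin_offsets(offs, n_ref=300, bin_width_hours=1.0)
        half = bin_offsets(offs, n_ref=300, bin_width_hours=0.5)
        assert half.bins.size == 48 and one.bins.size == 24
        assert half.counts.sum() == one.counts.sum()
        assert half.probabilities.sum() == pytest.approx(one.probabilities.sum())


class TestRandomizeB:
    def test_counts_preserved_per_station(self, guild, rng):
        ev, dep = guild["events"], guild["deployments"]
        pat = estimate_activity(
            ev.loc[ev["species"] == "leopard", "time_of_day_rad"].to_numpy(float)
        )
        out = randomize_B(ev, "leopard", dep, pat, rng)
        before = ev[ev["species"] == "leopard"].groupby("station_id").size()
        after = out[out["species"] == "leopard"].groupby("station_id").size()
        pd.testing.assert_series_equal(before, after)
        # other species untouched
        pd.testing.assert_frame_equal(
            ev[ev["species"] != "leopard"], out[out["species"] != "leopard"]
        )

    def test_fixed_seed_reproduces(self, guild):
        ev, dep = guild["events"], guild["deployments"]
        pat = estimate_activity(
            ev.loc[ev["species"] == "leopard", "time_of_day_rad"].to_numpy(float)
        )
        a = randomize_B(ev, "leopard", dep, pat, 5)
        b = randomize_B(ev, "leopard", dep, pat, 5)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_deployment_names_station(self, guild):
        ev, dep = guild["events"], guild["deployments"]
        pat = estimate_activity(
            ev.loc[ev["species"] == "leopard", "time_of_day_rad"].to_numpy(float)
        )
        with pytest.raises(ValueError, match="ST001"):
            randomize_B(ev, "leopard", dep[dep["station_id"] != "ST001"], pat, 1)

    def test_randomized_times_match_activity_pattern(self, guild):
        ev, dep = guild["events"], guild["deployments"]
        tod = ev.loc[ev["species"] == "leopard", "time_of_day_rad"].to_numpy(float)
        pat = estimate_activity(tod)
        # pool many randomizations to compare diel distributions
        draws = []
        for seed in range(40):
            out = randomize_B(ev, "leopard", dep, pat, seed)
            ts = pd.to_datetime(out.loc[out["species"] == "leopard", "timestamp"])
            draws.append(
                (ts.dt.hour + ts.dt.minute / 60 + ts.dt.second / 3600).to_numpy()
                / 24.0 * TWO_PI
            )
        pooled = np.concatenate(draws)
        # plug-in bandwidth at the pooled size: a consistent estimate of the
        # draw distribution, avoiding double-smoothing against the source
        refit = estimate_activity(pooled)
        assert ct.overlap_delta1(refit, pat) >= 0.95


class TestSpacingTest:
    def test_zero_co_occurrence_gives_empty_result(self):
        ev = _ev([("1", "A", "2018-07-01 10:00"), ("2", "B", "2018-07-01 11:00")])
        dep = pd.DataFrame(
            {
                "station_id": ["1", "2"],
                "site_id": "site1",
                "start": pd.Timestamp("2018-07-01"),
                "end": pd.Timestamp("2018-09-01"),
            }
        )
        res = spacing_test(ev, "A", "B", dep, R=100, seed=1)
        assert res.n_stations == 0
        assert res.observed is None
        assert res.n_ref == {"before": 0, "after": 0}
        assert res.to_frame().empty

    def test_deterministic_and_station_order_invariant(self, guild):
        ev, dep = guild["events"], guild["deployments"]
        r1 = spacing_test(ev, "lion", "leopard", dep, R=50, seed=9)
        shuffled = ev.sample(frac=1, random_state=0).reset_index(drop=True)
        r2 = spacing_test(shuffled, "lion", "leopard", dep, R=50, seed=9)
        np.testing.assert_array_equal(r1.null_probs, r2.null_probs)
        np.testing.assert_array_equal(
            r1.observed.counts, r2.observed.counts
        )

    def test_profile_conservation_per_direction(self, guild):
        ev, dep = guild["events"], guild["deployments"]
        res = spacing_test(ev, "lion", "leopard", dep, R=20, seed=2)
        k = res.observed.bins.size // 2
        assert res.observed.counts[:k].sum() <= res.observed.n_ref_before
        assert res.observed.counts[k:].sum() <= res.observed.n_ref_after
        assert (res.null_probs >= 0).all() and (res.null_probs <= 1).all()

    def test_bonferroni_and_adjusted_p(self, guild):
        ev, dep = guild["events"], guild["deployments"]
        res = spacing_test(ev, "lion", "leopard", dep, R=50, seed=4)
        m = res.observed.bins.size
        np.testing.assert_allclose(res.adj_p, np.minimum(1.0, m * res.raw_p))
        assert (res.raw_p > 0).all()

    def test_double_randomization_p_values_are_uniform(self, rng):
        """With B re-randomized before testing, raw p-values are ~U(0,1).

        Uses a dense guild (~1000 events/species) so per-bin counts are
        large enough for the discrete permutation p to be near-continuous.
        """
        cfg0 = ct.default_guild_config(seed=1, n_stations=40)
        cfg = ct.SimulationConfig(
            n_stations=cfg0.n_stations,
            start=cfg0.start,
            n_days=cfg0.n_days,
            species={
                k: ct.SpeciesActivitySpec(v.components, 0.3)
                for k, v in cfg0.species.items()
            },
            seed=cfg0.seed,
        )
        ps = []
        while len(ps) < 200:
            cfg = ct.SimulationConfig(**{**cfg.__dict__, "seed": int(rng.integers(2**31))})
            rec, dep, _ = ct.simulate_guild(cfg)
            ev = ct.deduplicate(rec)
            tod = ev.loc[ev["species"] == "leopard", "time_of_day_rad"].to_numpy(float)
            pat = estimate_activity(tod, adjust=1.0)
            ev2 = randomize_B(ev, "leopard", dep, pat, rng)
            res = spacing_test(
                ev2, "lion", "leopard", dep, R=500, seed=int(rng.integers(2**31))
            )
            ps.extend(res.raw_p.tolist())
        assert kstest(np.asarray(ps[:200]), "uniform").statistic < 0.1
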