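"""Spatiotemporal avoidance/attraction (temporal spacing) analysis.

For a species pair (A, B), measures how often B is detected in hourly bins
before and after each A capture at stations where both occur, against a
randomization null that keeps each station's B capture *count* and B's diel
activity pattern but redraws every B detection a uniform-random day within
the station's deployment and a time of day sampled from B's fitted activity
density.  The null therefore preserves where and how much B is detected and
when in the diel cycle it is active, while destroying any day-level or
fine-scale association with A.

Offsets are the minimum time from each A capture to the nearest B capture
in each direction, with an A capture excluded (per direction) when another
A capture lies strictly between it and that B capture.  Per-bin two-sided
permutation p-values carry a Bonferroni correction over the bins of one
pair analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circular import TWO_PI, ActivityPattern, estimate_activity, sample_times

__all__ = [
    "SpacingProfile",
    "SpacingResult",
    "co_occurrence_stations",
    "min_time_offsets",
    "bin_offsets",
    "randomize_B",
    "spacing_test",
]

_EPOCH = pd.Timestamp("1970-01-01")


def _hours(ts: pd.Series) -> np.ndarray:
    return ((pd.to_datetime(ts) - _EPOCH) / pd.Timedelta(hours=1)).to_numpy(dtype=float)


def co_occurrence_stations(
    events: pd.DataFrame, speciesA: str, speciesB: str
) -> list[str]:
    """Stations with at least one capture of each species, sorted."""
    stA = set(events.loc[events["species"] == speciesA, "station_id"])
    stB = set(events.loc[events["species"] == speciesB, "station_id"])
    return sorted(stA & stB)


def _direction_offsets(
    a: np.ndarray, b: np.ndarray, window: float
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Per-direction minimum offsets from sorted A times to sorted B times.

    Returns (after_offsets, before_offsets, n_ref_after, n_ref_before) where
    the n_ref counts are the A captures *retained* in that direction (not
    excluded by an intervening A capture).  Emitted offsets are additionally
    limited to the window; retained-but-out-of-window references count
    toward the denominator with no detection.
    """
    inf = np.inf
    # after: nearest B at or after the reference (offset 0 counts as after)
    ib = np.searchsorted(b, a, side="left")
    tB_after = np.where(ib < b.size, b[np.minimum(ib, b.size - 1)], inf)
    ia = np.searchsorted(a, a, side="right")
    tA_after = np.where(ia < a.size, a[np.minimum(ia, a.size - 1)], inf)
    retained_after = ~(tA_after < tB_after)
    off_after = tB_after - a
    emit_after = retained_after & (off_after <= window)
    # before: nearest B strictly before the reference
    ib = np.searchsorted(b, a, side="left") - 1
    tB_before = np.where(ib >= 0, b[np.maximum(ib, 0)], -inf)
    ia = np.searchsorted(a, a, side="left") - 1
    tA_before = np.where(ia >= 0, a[np.maximum(ia, 0)], -inf)
    retained_before = ~(tA_before > tB_before)
    off_before = a - tB_before
    emit_before = retained_before & (off_before <= window)
    return (
        off_after[emit_after],
        off_before[emit_before],
        int(retained_after.sum()),
        int(retained_before.sum()),
    )


def min_time_offsets(
    events_at_station: pd.DataFrame,
    speciesA: str,
    speciesB: str,
    window_hours: float = 12.0,
) -> pd.DataFrame:
    """Offsets from each A capture to the nearest B capture, per direction.

    One row per (reference capture, direction) that survives both the
    intervening-A exclusion rule and the window limit.  The frame's
    ``attrs["n_ref"]`` records the per-direction retained reference counts.
    """
    df = events_at_station
    a = np.sort(_hours(df.loc[df["species"] == speciesA, "timestamp"]))
    b = np.sort(_hours(df.loc[df["species"] == speciesB, "timestamp"]))
    if a.size == 0 or b.size == 0:
        out = pd.DataFrame(columns=["direction", "offset_hours"])
        out.attrs["n_ref"] = {"after": 0, "before": 0}
        return out
    off_after, off_before, n_after, n_before = _direction_offsets(a, b, window_hours)
    out = pd.DataFrame(
        {
            "direction": ["after"] * off_after.size + ["before"] * off_before.size,
            "offset_hours": np.concatenate([off_after, off_before]),
        }
    )
    out.attrs["n_ref"] = {"after": n_after, "before": n_before}
    return out


@dataclass(frozen=True)
class SpacingProfile:
    """Binned detection probabilities of B around A captures.

    ``bins`` are labelled -K..-1 (before) and +1..+K (after) with
    K = window / bin_width; bin +k covers offsets in ((k-1)w, kw] and an
    offset of exactly 0 falls in bin +1.  Probabilities divide each bin
    count by the number of retained A references in that direction.
    """

    bin_width_hours: float
    window_hours: float
    bins: np.ndarray
    counts: np.ndarray
    n_ref_before: int
    n_ref_after: int

    @property
    def n_ref(self) -> dict:
        return {"before": self.n_ref_before, "after": self.n_ref_after}

    @property
    def probabilities(self) -> np.ndarray:
        k = self.bins.size // 2
        denom = np.concatenate(
            [
                np.full(k, max(self.n_ref_before, 1)),
                np.full(k, max(self.n_ref_after, 1)),
            ]
        )
        out = self.counts / denom
        if self.n_ref_before == 0:
            out[:k] = 0.0
        if self.n_ref_after == 0:
            out[k:] = 0.0
        return out


def _bin_counts(
    off_after: np.ndarray, off_before: np.ndarray, w: float, window: float
) -> tuple[np.ndarray, np.ndarray]:
    k = int(round(window / w))
    # half-open upper-closed: offset o -> bin ceil(o/w); exactly 0 -> bin 1
    def idx(o):
        i = np.ceil(o / w).astype(int)
        i[o == 0.0] = 1
        return i

    ca = np.bincount(idx(off_after), minlength=k + 1)[1 : k + 1] if off_after.size else np.zeros(k, int)
    cb = np.bincount(idx(off_before), minlength=k + 1)[1 : k + 1] if off_before.size else np.zeros(k, int)
    return cb, ca


def bin_offsets(
    offsets: pd.DataFrame,
    n_ref: dict | int,
    bin_width_hours: float = 1.0,
    window_hours: float = 12.0,
) -> SpacingProfile:
    """Aggregate offset records into a before/after bin profile."""
    if isinstance(n_ref, int):
        n_ref = {"before": n_ref, "after": n_ref}
    off_a = offsets.loc[offsets["direction"] == "after", "offset_hours"].to_numpy(float)
    off_b = offsets.loc[offsets["direction"] == "before", "offset_hours"].to_numpy(float)
    cb, ca = _bin_counts(off_a, off_b, bin_width_hours, window_hours)
    k = cb.size
    bins = np.concatenate([-np.arange(k, 0, -1), np.arange(1, k + 1)])
    counts = np.concatenate([cb[::-1], ca])
    return SpacingProfile(
        bin_width_hours=bin_width_hours,
        window_hours=window_hours,
        bins=bins,
        counts=counts,
        n_ref_before=int(n_ref["before"]),
        n_ref_after=int(n_ref["after"]),
    )


def randomize_B(
    events: pd.DataFrame,
    speciesB: str,
    deployments: pd.DataFrame,
    pattern_B: ActivityPattern,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Redraw every B detection time under the spacing null.

    Per station the B capture count is preserved; each randomized detection
    gets a date drawn uniformly from the whole days of that station's
    deployment window and a time of day drawn from the fitted activity
    density of B.  All other species' events are returned untouched.
    """
    rng = np.random.default_rng(rng)
    out = events.copy()
    is_b = out["species"] == speciesB
    dep = deployments.set_index("station_id")
    new_ts = out["timestamp"].copy()
    for station, grp in out.loc[is_b].groupby("station_id", sort=True):
        if station not in dep.index:
            raise ValueError(f"no deployment window for station {station!r}")
        row = dep.loc[station]
        d0 = pd.Timestamp(row["start"]).normalize()
        d1 = pd.Timestamp(row["end"]).normalize()
        n_days = (d1 - d0).days + 1
        days = rng.integers(0, n_days, size=len(grp))
        tod = sample_times(pattern_B, len(grp), rng)
        ts = d0 + pd.to_timedelta(days, unit="D") + pd.to_timedelta(
            tod / TWO_PI * 24.0, unit="h"
        )
        new_ts.loc[grp.index] = ts
    out["timestamp"] = new_ts
    return out


@dataclass(frozen=True)
class SpacingResult:
    pair: tuple[str, str]
    observed: SpacingProfile | None
    null_probs: np.ndarray = field(repr=False)  # (R, 2K)
    raw_p: np.ndarray
    adj_p: np.ndarray
    direction: np.ndarray
    R: int
    seed: int | None
    n_stations: int

    @property
    def n_ref(self) -> dict:
        return self.observed.n_ref if self.observed is not None else {"before": 0, "after": 0}

    def to_frame(self) -> pd.DataFrame:
        """Tabular summary: one row per bin (the Fig-3-style table)."""
        if self.observed is None:
            return pd.DataFrame(
                columns=[
                    "bin", "observed_prob", "null_mean", "null_q025",
                    "null_q975", "raw_p", "adj_p", "direction",
                ]
            )
        obs = self.observed.probabilities
        return pd.DataFrame(
            {
                "bin": self.observed.bins,
                "observed_prob": obs,
                "null_mean": self.null_probs.mean(axis=0),
                "null_q025": np.quantile(self.null_probs, 0.025, axis=0),
                "null_q975": np.quantile(self.null_probs, 0.975, axis=0),
                "raw_p": self.raw_p,
                "adj_p": self.adj_p,
                "direction": self.direction,
            }
        )


def _profile_probs(
    station_arrays: list[tuple[np.ndarray, np.ndarray]],
    w: float,
    window: float,
) -> SpacingProfile:
    offs_a, offs_b = [], []
    n_after = n_before = 0
    for a, b in station_arrays:
        oa, ob, na, nb = _direction_offsets(a, b, window)
        offs_a.append(oa)
        offs_b.append(ob)
        n_after += na
        n_before += nb
    oa = np.concatenate(offs_a) if offs_a else np.empty(0)
    ob = np.concatenate(offs_b) if offs_b else np.empty(0)
    cb, ca = _bin_counts(oa, ob, w, window)
    k = cb.size
    return SpacingProfile(
        bin_width_hours=w,
        window_hours=window,
        bins=np.concatenate([-np.arange(k, 0, -1), np.arange(1, k + 1)]),
        counts=np.concatenate([cb[::-1], ca]),
        n_ref_before=n_before,
        n_ref_after=n_after,
    )


def spacing_test(
    events: pd.DataFrame,
    speciesA: str,
    speciesB: str,
    deployments: pd.DataFrame,
    R: int = 1000,
    bin_width_hours: float = 1.0,
    window_hours: float = 12.0,
    seed: int | np.random.Generator | None = None,
    pattern_B: ActivityPattern | None = None,
) -> SpacingResult:
    """Permutation test for spatiotemporal avoidance/attraction of a pair.

    Computes the observed spacing profile of B around A at co-occurrence
    stations, re-runs the whole offset/binning procedure on ``R``
    randomizations of B's detection times, and reports per-bin two-sided
    add-one permutation p-values (doubled tail counts, capped at 1) with a
    Bonferroni correction over the 2K bins.  ``direction`` flags whether the
    observed probability lies above or below the null median.

    ``pattern_B`` defaults to a kernel fit to the time of day of *all* B
    events in ``events`` (pooled across stations and sites).
    """
    rng = np.random.default_rng(seed)
    stations = co_occurrence_stations(events, speciesA, speciesB)
    k = int(round(window_hours / bin_width_hours))
    if not stations:
        return SpacingResult(
            pair=(speciesA, speciesB),
            observed=None,
            null_probs=np.empty((0, 2 * k)),
            raw_p=np.empty(0),
            adj_p=np.empty(0),
            direction=np.empty(0, dtype=object),
            R=R,
            seed=seed if isinstance(seed, int) else None,
            n_stations=0,
        )
    if pattern_B is None:
        b_all = events.loc[events["species"] == speciesB, "timestamp"]
        tod = _hours(b_all) % 24.0 / 24.0 * TWO_PI
        pattern_B = estimate_activity(tod, adjust=1.0)

    dep = deployments.drop_duplicates("station_id").set_index("station_id")
    a_times: dict[str, np.ndarray] = {}
    b_counts: dict[str, int] = {}
    day0: dict[str, int] = {}
    n_days: dict[str, int] = {}
    for st in stations:
        sub = events.loc[events["station_id"] == st]
        a_times[st] = np.sort(_hours(sub.loc[sub["species"] == speciesA, "timestamp"]))
        b_counts[st] = int((sub["species"] == speciesB).sum())
        if st not in dep.index:
            raise ValueError(f"no deployment window for station {st!r}")
        d0 = pd.Timestamp(dep.loc[st, "start"]).normalize()
        d1 = pd.Timestamp(dep.loc[st, "end"]).normalize()
        day0[st] = int((d0 - _EPOCH).days)
        n_days[st] = (d1 - d0).days + 1

    def observed_arrays():
        arrays = []
        for st in stations:
            sub = events.loc[events["station_id"] == st]
            b = np.sort(_hours(sub.loc[sub["species"] == speciesB, "timestamp"]))
            arrays.append((a_times[st], b))
        return arrays

    observed = _profile_probs(observed_arrays(), bin_width_hours, window_hours)
    obs_p = observed.probabilities

    # vectorized null draws: one uniform-day and one activity draw per B
    # event per replicate, split back into per-station arrays
    counts_arr = np.array([b_counts[st] for st in stations])
    day0_arr = np.repeat(np.array([day0[st] for st in stations], dtype=float), counts_arr)
    ndays_arr = np.repeat(np.array([n_days[st] for st in stations], dtype=float), counts_arr)
    splits = np.cumsum(counts_arr)[:-1]
    nb_total = int(counts_arr.sum())
    null_probs = np.empty((R, 2 * k))
    for r in range(R):
        days = day0_arr + np.floor(rng.random(nb_total) * ndays_arr)
        tod = sample_times(pattern_B, nb_total, rng)
        b_all = days * 24.0 + tod / TWO_PI * 24.0
        arrays = [
            (a_times[st], np.sort(b))
            for st, b in zip(stations, np.split(b_all, splits))
        ]
        null_probs[r] = _profile_probs(arrays, bin_width_hours, window_hours).probabilities

    ge = (null_probs >= obs_p[None, :]).sum(axis=0)
    le = (null_probs <= obs_p[None, :]).sum(axis=0)
    raw_p = np.minimum(1.0, 2.0 * (np.minimum(ge, le) + 1) / (R + 1))
    adj_p = np.minimum(1.0, 2 * k * raw_p)
    med = np.median(null_probs, axis=0)
    direction = np.where(obs_p > med, "above", "below").astype(object)
    return SpacingResult(
        pair=(speciesA, speciesB),
        observed=observed,
        null_probs=null_probs,
        raw_p=raw_p,
        adj_p=adj_p,
        direction=direction,
        R=R,
        seed=seed if isinstance(seed, int) else None,
        n_stations=len(stations),
    )
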