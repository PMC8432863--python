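"""Camera-trap detection records: CSV I/O, independent-event filtering, counts.

A *detection record* is one photographic capture (station, site, species,
timestamp, optional individual id and sex).  The analysis unit is the
*capture event*: detections of the same species at the same station are
collapsed so that retained events are at least ``window_minutes`` apart,
with the earliest capture of each cluster retained — unless the animals can
be told apart by individual id, in which case they never suppress one
another.  Event times of day are expressed in radians on [0, 2pi) with
midnight at 0 and noon at pi; clock times are used as-is (no sunrise/sunset
standardization).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .circular import TWO_PI

DEFAULT_SCHEMA = {
    "station_id": "station_id",
    "site_id": "site_id",
    "species": "species",
    "timestamp": "datetime",
    "individual_id": "individual_id",
    "sex": "sex",
}

DEPLOYMENT_SCHEMA = {
    "station_id": "station_id",
    "site_id": "site_id",
    "start": "start",
    "end": "end",
}

REQUIRED_COLUMNS = ("station_id", "site_id", "species", "timestamp")


class SchemaError(ValueError):
    """A required column is missing from an input CSV."""


class RowParseError(ValueError):
    """One or more rows could not be parsed (carries 1-based line numbers)."""

    def __init__(self, lines: list[int], message: str):
        super().__init__(message)
        self.lines = lines


def _resolve_schema(columns, schema: dict | None, required) -> dict:
    mapping = dict(DEFAULT_SCHEMA)
    if schema:
        mapping.update(schema)
    for canonical in required:
        if mapping[canonical] not in columns:
            raise SchemaError(
                f"required column '{mapping[canonical]}' (for field '{canonical}') "
                f"not found; available columns: {list(columns)}"
            )
    return mapping


def read_detections(
    path,
    schema: dict | None = None,
    on_error: str = "raise",
) -> pd.DataFrame:
    """Read a detections CSV into a canonical DataFrame.

    Parameters
    ----------
    path : str or file-like
        CSV with at least station, site, species and timestamp columns.
    schema : dict, optional
        Mapping from canonical field names (``station_id``, ``site_id``,
        ``species``, ``timestamp``, ``individual_id``, ``sex``) to the
        column names actually present in the file.
    on_error : {"raise", "skip"}
        With ``"raise"``, any unparseable timestamp aborts with a
        :class:`RowParseError` naming the offending line numbers.  With
        ``"skip"``, bad rows are dropped with a warning and recorded in
        ``df.attrs["row_errors"]``; all other rows load normally.

    Returns a DataFrame with canonical column names, row order preserved.
    """
    raw = pd.read_csv(path, dtype=str)
    mapping = _resolve_schema(raw.columns, schema, REQUIRED_COLUMNS)
    df = pd.DataFrame(index=raw.index)
    for canonical, col in mapping.items():
        if col in raw.columns:
            df[canonical] = raw[col]
    for canonical in ("individual_id", "sex"):
        if canonical not in df.columns:
            df[canonical] = pd.NA

    parsed = pd.to_datetime(df["timestamp"], errors="coerce", format="mixed")
    bad = parsed.isna() | df["station_id"].isna() | df["species"].isna()
    if bad.any():
        # +2: 1-based and one header line
        lines = [int(i) + 2 for i in df.index[bad]]
        msg = f"{bad.sum()} row(s) failed to parse (line numbers: {lines})"
        if on_error == "raise":
            raise RowParseError(lines, msg)
        warnings.warn(msg)
    df = df.loc[~bad].copy()
    df["timestamp"] = parsed.loc[~bad]
    df.attrs["row_errors"] = [int(i) + 2 for i in bad.index[bad]] if bad.any() else []
    return df.reset_index(drop=True)


def read_deployments(path, schema: dict | None = None) -> pd.DataFrame:
    """Read station deployment windows (station_id, site_id, start, end)."""
    raw = pd.read_csv(path, dtype=str)
    mapping = dict(DEPLOYMENT_SCHEMA)
    if schema:
        mapping.update(schema)
    for canonical, col in mapping.items():
        if col not in raw.columns:
            raise SchemaError(f"required column '{col}' (for field '{canonical}') not found")
    df = pd.DataFrame(
        {
            "station_id": raw[mapping["station_id"]],
            "site_id": raw[mapping["site_id"]],
            "start": pd.to_datetime(raw[mapping["start"]], format="mixed"),
            "end": pd.to_datetime(raw[mapping["end"]], format="mixed"),
        }
    )
    if (df["start"] >= df["end"]).any():
        bad = df.loc[df["start"] >= df["end"], "station_id"].tolist()
        raise ValueError(f"deployment start >= end for station(s): {bad}")
    return df


def deduplicate(
    records: pd.DataFrame,
    window_minutes: float = 30.0,
    use_individual_ids: bool = True,
) -> pd.DataFrame:
    """Collapse detections into independent capture events.

    Within each (station, species, individual) chain, a record is suppressed
    if it falls strictly less than ``window_minutes`` after the last
    *retained* event of that chain (rolling rule, earliest capture kept), so
    retained events are always >= the window apart.  Records carrying
    distinct individual ids form separate chains and never suppress one
    another; records without an id are treated as indistinguishable.  With
    ``use_individual_ids=False`` ids are ignored entirely.
    """
    if records.empty:
        out = records.copy()
        out["time_of_day_rad"] = pd.Series(dtype=float)
        return out
    df = records.copy()
    if use_individual_ids and "individual_id" in df.columns:
        chain_id = df["individual_id"].fillna("").astype(str)
    else:
        chain_id = pd.Series("", index=df.index)
    df["_chain"] = chain_id
    # stable sort: equal timestamps keep file order, so the first by file
    # order is the one retained
    df = df.sort_values(
        ["station_id", "species", "_chain", "timestamp"], kind="stable"
    )
    window = pd.Timedelta(minutes=window_minutes)

    keep_idx = []
    for _, grp in df.groupby(["station_id", "species", "_chain"], sort=False):
        last_kept = None
        for idx, ts in zip(grp.index, grp["timestamp"]):
            if last_kept is None or ts - last_kept >= window:
                keep_idx.append(idx)
                last_kept = ts
    out = records.loc[sorted(keep_idx)].copy()
    out = out.sort_values(["station_id", "species", "timestamp"], kind="stable")
    return to_time_of_day(out).reset_index(drop=True)


def to_time_of_day(events: pd.DataFrame) -> pd.DataFrame:
    """Attach ``time_of_day_rad``: 2pi * (seconds since midnight) / 86400."""
    out = events.copy()
    ts = pd.to_datetime(out["timestamp"])
    seconds = (
        ts.dt.hour * 3600 + ts.dt.minute * 60 + ts.dt.second + ts.dt.microsecond / 1e6
    )
    out["time_of_day_rad"] = seconds.to_numpy(dtype=float) / 86400.0 * TWO_PI
    return out


def summarize_counts(
    events: pd.DataFrame,
    by: tuple[str, ...] = ("site_id", "species"),
    sex_split: bool = False,
) -> pd.DataFrame:
    """Count capture events per grouping, optionally split by sex class.

    With ``sex_split=True`` the result has columns M, F, Unk and All per
    (site, species), with All = M + F + Unk; unknown/missing sex falls into
    Unk.  Totals always partition the events exactly.
    """
    if events.empty:
        cols = list(by) + (["M", "F", "Unk", "All"] if sex_split else ["n_events"])
        return pd.DataFrame(columns=cols)
    if not sex_split:
        out = events.groupby(list(by), sort=True).size().reset_index(name="n_events")
        return out
    df = events.copy()
    sex = df.get("sex")
    sex = sex.where(sex.isin(["M", "F"]), "Unk") if sex is not None else "Unk"
    df["_sex_class"] = sex
    wide = (
        df.groupby(list(by) + ["_sex_class"], sort=True)
        .size()
        .unstack("_sex_class", fill_value=0)
        .reindex(columns=["M", "F", "Unk"], fill_value=0)
        .reset_index()
    )
    wide.columns.name = None
    wide["All"] = wide[["M", "F", "Unk"]].sum(axis=1)
    return wide
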