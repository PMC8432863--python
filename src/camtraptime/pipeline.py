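"""End-to-end pipeline: detections CSV in, analysis tables out.

Orchestrates the stages — independent-event filtering, per-site/species
event counts, activity-overlap matrices (within species across sites and
across species within sites) with randomization equality tests, and
temporal-spacing analyses for configured species pairs — writing one CSV
per surface plus a machine-readable run manifest.  All randomness derives
from the run seed through fixed spawn keys, so a rerun with the same config
produces byte-identical outputs.
"""

from __future__ import annotations

import itertools
import json
import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .comparison import compare_activity
from .events import deduplicate, read_detections, read_deployments, summarize_counts
from .overlap import OverlapResult, OverlapSkipped, overlap_analysis
from .spacing import spacing_test

logger = logging.getLogger(__name__)

SKIP_MARKER = "-"


@dataclass
class RunConfig:
    """Full parameterization of one pipeline run (YAML-serializable)."""

    detections: str
    deployments: str | None = None
    output_dir: str = "results"
    seed: int = 20180901
    schema: dict | None = None
    skip_dedup: bool = False  # input already holds independent events
    window_minutes: float = 30.0
    include_sites: list | None = None
    include_species: list | None = None
    site_groups: dict = field(default_factory=dict)  # raw site -> grouped site
    min_n: int = 30
    n_boot: int = 10_000
    compare_R: int = 999
    spacing_R: int = 1000
    spacing_pairs: list | None = None  # ordered [A, B] pairs; None = all
    bin_width_hours: float = 1.0
    window_hours: float = 12.0
    run_counts: bool = True
    run_overlap_sites: bool = True
    run_overlap_species: bool = True
    run_comparisons: bool = True
    run_spacing: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _overlap_row(pair_kind, label, pair, res, comp) -> dict:
    row = {
        "analysis": pair_kind,
        "group": label,
        "a": pair[0],
        "b": pair[1],
        "n1": res.n1,
        "n2": res.n2,
    }
    if isinstance(res, OverlapSkipped):
        row.update(
            {
                "estimator": SKIP_MARKER,
                "delta": SKIP_MARKER,
                "ci_low": SKIP_MARKER,
                "ci_high": SKIP_MARKER,
                "skipped": True,
            }
        )
    else:
        row.update(
            {
                "estimator": res.estimator,
                "delta": round(res.delta_hat, 4),
                "ci_low": round(res.ci_low, 4),
                "ci_high": round(res.ci_high, 4),
                "skipped": False,
            }
        )
    if comp is not None:
        row.update(
            {"p_value": round(comp.p_value, 5), "tier": comp.significance_tier}
        )
    else:
        row.update({"p_value": SKIP_MARKER, "tier": SKIP_MARKER})
    return row


def run_pipeline(config: RunConfig) -> dict:
    """Run every enabled stage; returns {output name: path}.

    Any stage error aborts with the stage name attached to the exception.
    """
    from pathlib import Path

    t0 = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    timings: dict[str, float] = {}
    root = config.seed

    def stage(name):
        logger.info("stage %s", name)
        timings[name] = time.time()
        return name

    def done(name):
        timings[name] = round(time.time() - timings[name], 3)

    try:
        name = stage("load")
        records = read_detections(config.detections, schema=config.schema)
        deployments = (
            read_deployments(config.deployments) if config.deployments else None
        )
        if config.site_groups:
            records["site_id"] = records["site_id"].replace(config.site_groups)
            if deployments is not None:
                deployments["site_id"] = deployments["site_id"].replace(
                    config.site_groups
                )
        if config.include_sites:
            records = records[records["site_id"].isin(config.include_sites)]
        if config.include_species:
            records = records[records["species"].isin(config.include_species)]
        done(name)

        name = stage("dedup")
        if config.skip_dedup:
            from .events import to_time_of_day

            events = to_time_of_day(records).reset_index(drop=True)
        else:
            events = deduplicate(records, window_minutes=config.window_minutes)
        path = outdir / "events.csv"
        events.to_csv(path, index=False)
        outputs["events"] = str(path)
        done(name)

        if config.run_counts:
            name = stage("counts")
            counts = summarize_counts(events, sex_split=True)
            path = outdir / "counts.csv"
            counts.to_csv(path, index=False)
            outputs["counts"] = str(path)
            done(name)

        sites = sorted(events["site_id"].dropna().unique())
        species = sorted(events["species"].dropna().unique())

        def times(site=None, sp=None):
            sub = events
            if site is not None:
                sub = sub[sub["site_id"] == site]
            if sp is not None:
                sub = sub[sub["species"] == sp]
            return sub["time_of_day_rad"].to_numpy(dtype=float)

        def seed_for(*key) -> int:
            # stable across processes (unlike hash() on strings)
            import hashlib

            digest = hashlib.sha256(repr((root,) + key).encode()).digest()
            return int.from_bytes(digest[:4], "little") % (2**31)

        def analyse_pair(kind, label, pair, tA, tB, k):
            res = overlap_analysis(
                tA, tB, pair=pair, min_n=config.min_n,
                n_boot=config.n_boot, seed=seed_for(k, "boot"),
            )
            comp = None
            if config.run_comparisons and not isinstance(res, OverlapSkipped):
                comp = compare_activity(
                    tA, tB, R=config.compare_R, seed=seed_for(k, "cmp"), pair=pair
                )
            return _overlap_row(kind, label, pair, res, comp)

        if config.run_overlap_sites:
            name = stage("overlap_sites")
            rows = []
            for sp in species:
                for sA, sB in itertools.combinations(sites, 2):
                    tA, tB = times(sA, sp), times(sB, sp)
                    if tA.size == 0 or tB.size == 0:
                        continue
                    rows.append(
                        analyse_pair(
                            "within-species-across-sites", sp, (sA, sB),
                            tA, tB, (sp, sA, sB),
                        )
                    )
            path = outdir / "overlap_sites.csv"
            pd.DataFrame(rows).to_csv(path, index=False)
            outputs["overlap_sites"] = str(path)
            done(name)

        if config.run_overlap_species:
            name = stage("overlap_species")
            rows = []
            for site in sites:
                for spA, spB in itertools.combinations(species, 2):
                    tA, tB = times(site, spA), times(site, spB)
                    if tA.size == 0 or tB.size == 0:
                        continue
                    rows.append(
                        analyse_pair(
                            "across-species-within-site", site, (spA, spB),
                            tA, tB, (site, spA, spB),
                        )
                    )
            path = outdir / "overlap_species.csv"
            pd.DataFrame(rows).to_csv(path, index=False)
            outputs["overlap_species"] = str(path)
            done(name)

        if config.run_spacing:
            name = stage("spacing")
            if deployments is None:
                raise ValueError("spacing analysis requires a deployments CSV")
            pairs = config.spacing_pairs or [
                list(p) for p in itertools.permutations(species, 2)
            ]
            for spA, spB in pairs:
                res = spacing_test(
                    events, spA, spB, deployments,
                    R=config.spacing_R,
                    bin_width_hours=config.bin_width_hours,
                    window_hours=config.window_hours,
                    seed=seed_for("spacing", spA, spB),
                )
                path = outdir / f"spacing_{spA}_vs_{spB}.csv"
                res.to_frame().to_csv(path, index=False)
                outputs[f"spacing_{spA}_vs_{spB}"] = str(path)
            done(name)

        name = stage("manifest")
        manifest = {
            "package": "camtraptime",
            "version": __version__,
            "config": asdict(config),
            "outputs": outputs,
            "timings_s": {k: v for k, v in timings.items() if isinstance(v, float)},
            "elapsed_s": round(time.time() - t0, 3),
        }
        path = outdir / "manifest.json"
        with open(path, "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        outputs["manifest"] = str(path)
        done(name)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
    return outputs
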