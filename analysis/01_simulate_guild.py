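#!/usr/bin/env python
"""Simulate the synthetic carnivore guild used by the downstream analyses.

Writes two datasets in the on-disk CSV schema the loaders read:
  * an independent guild (no interactions) — the null study system;
  * a guild in which the lion-like species follows the leopard-like species
    at a ~30-minute lag with probability 0.5 — the injected-attraction
    system the spacing analysis should detect.

Detections and deployment windows go to scratch/analysis_data/ (regenerable
at any time from the seed); the ground-truth ledgers stay alongside them.
"""

import argparse
from pathlib import Path

import camtraptime as ct

FOLLOWING = ct.InteractionSpec(
    "leopard", "lion", mode="following", p_effect=0.5,
    lag_mean_hours=0.5, lag_sd_hours=0.2,
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=20180901)
    ap.add_argument("--out", type=Path, default=Path("scratch/analysis_data"))
    args = ap.parse_args()

    for name, interactions in [("independent", ()), ("following", (FOLLOWING,))]:
        cfg = ct.default_guild_config(seed=args.seed, interactions=interactions)
        records, deployments, ledger = ct.simulate_guild(cfg)
        outdir = args.out / name
        outdir.mkdir(parents=True, exist_ok=True)
        records.rename(columns={"timestamp": "datetime"}).to_csv(
            outdir / "detections.csv", index=False
        )
        deployments.to_csv(outdir / "deployments.csv", index=False)
        ledger.to_csv(outdir / "ledger.csv", index=False)
        cfg.to_yaml(outdir / "config.yaml")
        injected = ledger["origin"].str.startswith("injected").sum() if len(ledger) else 0
        print(
            f"[{name}] {len(records)} detections at {cfg.n_stations} stations "
            f"over {cfg.n_days} days ({injected} injected follower events) "
            f"-> {outdir}/"
        )


if __name__ == "__main__":
    main()
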