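#!/usr/bin/env python
"""Build D and the twelve connectivity matrices for every individual.

For each individual's nest network this computes the log-distance matrix
D = log(d + 1 m) and the binary connectivity matrix under all twelve
definitions (C1-C6 straight/free routes in suitable or suitable+movement
forest, within or beyond the home range; C1g-C6g the same with <= 50 m
glidable gaps), and writes one labeled CSV per matrix.

Run:  python analysis/03_connectivity_matrices.py
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from nestnet.connectivity import (
    NestSite,
    build_all_connectivity,
    log_distance_matrix,
)
from nestnet.landscape import compute_mcp, read_ascii_grid


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results/matrices"))
    args = ap.parse_args()

    raster = read_ascii_grid(args.data / "habitat.asc")
    nests = pd.read_csv(args.data / "nests.csv")
    hr_pts = pd.read_csv(args.data / "home_ranges.csv")
    args.out.mkdir(parents=True, exist_ok=True)

    frac_connected = {}
    for pid, g in nests.groupby("individual_id"):
        sites = [
            NestSite(r.nest_id, float(r.x), float(r.y), r.nest_type)
            for r in g.itertuples()
        ]
        ids = [s.nest_id for s in sites]
        hr = compute_mcp(
            hr_pts[hr_pts.id == pid][["x", "y"]].to_numpy(), pid
        )
        D = log_distance_matrix(sites)
        pd.DataFrame(D, index=ids, columns=ids).to_csv(args.out / f"{pid}_D.csv")
        mats = build_all_connectivity(sites, raster, hr)
        n_pairs = len(sites) * (len(sites) - 1) / 2
        for name, C in mats.items():
            pd.DataFrame(C, index=ids, columns=ids).to_csv(
                args.out / f"{pid}_{name}.csv"
            )
            frac_connected.setdefault(name, []).append(
                np.triu(C, 1).sum() / n_pairs
            )

    print("fraction of nest pairs connected, by definition "
          "(mean over individuals):")
    for name, vals in frac_connected.items():
        print(f"  {name:>4}: {np.mean(vals):.2f}")
    print(f"matrices -> {args.out}/")


if __name__ == "__main__":
    main()
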