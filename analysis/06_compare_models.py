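#!/usr/bin/env python
"""Rank nest-switching models by DIC.

Compares a reduced family on the simulated study: distance only,
connectivity only, and distance + connectivity, for a subset of
connectivity definitions (the full family is 1 + 12 + 12 = 25 models;
pass --definitions to widen).  Data were generated under distance + C5g,
so that model should rank at or near the top.

Run:  python analysis/06_compare_models.py [--definitions C5g C2g]
"""

import argparse
import importlib.util
from pathlib import Path

from nestnet.bayes_fit import McmcConfig, ModelSpec, compare_models

_spec = importlib.util.spec_from_file_location(
    "fit_driver", Path(__file__).parent / "05_fit_switching_model.py"
)
_mod = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_mod)
load_dataset = _mod.load_dataset


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--definitions", nargs="+", default=["C5g"])
    ap.add_argument("--iters", type=int, default=5000)
    ap.add_argument("--burnin", type=int, default=1500)
    ap.add_argument("--seed", type=int, default=7)
    args = ap.parse_args()

    dataset = load_dataset(args.data, definitions=tuple(args.definitions))
    specs = [ModelSpec(use_distance=True)]
    for d in args.definitions:
        specs.append(ModelSpec(use_distance=False, use_connectivity=True,
                               connectivity_definition=d))
        specs.append(ModelSpec(use_distance=True, use_connectivity=True,
                               connectivity_definition=d))

    cfg = McmcConfig(iterations=args.iters, burn_in=args.burnin, seed=args.seed)
    table = compare_models(dataset, specs, cfg)
    args.out.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out / "dic_table.csv", index=False)
    print(table.to_string(index=False, float_format=lambda v: f"{v:.1f}"))
    print(f"-> {args.out / 'dic_table.csv'}")


if __name__ == "__main__":
    main()
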