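#!/usr/bin/env python
"""Simulate the synthetic EHR cohort.

Draws n persons from the six-factor liability-threshold preset (39
diagnoses; Fear, Distress, Externalizing, Substance Use, Thought Problems,
Neurodevelopmental Disorders) and writes the raw event table, code cluster
map, external correlates, and the generating truth to results/data/.
"""

import argparse
from pathlib import Path

from spectra.synth import simulate_dataset, six_factor_preset


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n", type=int, default=20_000)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = six_factor_preset(n_persons=args.n, seed=args.seed)
    matrix, events, cmap, correlates, truth = simulate_dataset(cfg)
    matrix.write_tsv(args.out / "matrix_raw.tsv")
    events.to_csv(args.out / "events.tsv", sep="\t", index=False)
    cmap.write_tsv(args.out / "cluster_map.tsv")
    correlates.to_csv(args.out / "correlates.tsv", sep="\t", index=False)
    cfg.write_yaml(args.out / "generator_truth.yaml")

    n_zero = int((matrix.values.sum(axis=1) == 0).sum())
    print(f"simulated {matrix.n_persons:,} persons x {len(matrix.labels)} "
          f"diagnoses ({len(events):,} coded events, "
          f"{len(cmap.raw_to_label)} raw codes)")
    print(f"{n_zero:,} persons carry no psychiatric diagnosis and will be "
          "removed by the cohort filter")
    print(f"wrote data and generating truth to {args.out}/")


if __name__ == "__main__":
    main()
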