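#!/usr/bin/env python
"""Collapse raw codes into primary diagnoses and apply the cohort filter.

Rebuilds the person x diagnosis lifetime indicator matrix from the coded
event table through the cluster map (so the code-clustering path is
exercised, not bypassed), then keeps persons with at least one psychiatric
diagnosis.  Writes results/data/matrix.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from spectra.ehr_prep import ClusterMap, collapse_codes, filter_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    args = ap.parse_args()

    events = pd.read_csv(args.data / "events.tsv", sep="\t", dtype=str)
    cmap = ClusterMap.read_tsv(args.data / "cluster_map.tsv")
    raw = collapse_codes(events, cmap)
    m = filter_cohort(raw)
    m.write_tsv(args.data / "matrix.tsv")

    prev = m.prevalence.sort_values(ascending=False)
    print(f"collapsed {len(events):,} events over "
          f"{len(cmap.raw_to_label)} raw codes into {len(m.labels)} "
          f"primary diagnoses ({len(raw.meta['unmapped'])} unmapped codes)")
    print(f"analytic cohort: {m.n_persons:,} persons with >= 1 diagnosis "
          f"({m.meta['removed_no_diagnosis']:,} removed)")
    print("most/least prevalent in the analytic cohort:")
    print(pd.concat([prev.head(3), prev.tail(3)]).round(3).to_string())


if __name__ == "__main__":
    main()
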