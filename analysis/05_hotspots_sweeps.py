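#!/usr/bin/env python
"""Hotspot clustering, the dual-allele sweep rule, and truth recovery.

Reads results/gwas/mta_table.tsv, the LD window, the filtered panel and the
planted truth; writes results/sweeps/.
"""

import json
import os

import pandas as pd

from eigensweep import hotspots as hs, io, sweeps
from eigensweep.hotspots import QTLHotspot

ROOT = os.path.join(os.path.dirname(__file__), "..", "results")
TOP = 5.0
ALLELE_THRESHOLD = 0.80


def main() -> None:
    mtas = pd.read_csv(os.path.join(ROOT, "gwas", "mta_table.tsv"), sep="\t",
                       dtype={"marker_id": str, "chromosome": str})
    thr = pd.read_csv(os.path.join(ROOT, "gwas", "thresholds.tsv"), sep="\t")
    with open(os.path.join(ROOT, "ld", "window.json")) as fh:
        window = json.load(fh)["decay_window_cM"]
    filtered, gmap, meta = io.read_genotypes(
        os.path.join(ROOT, "qc", "filtered_genotypes.tsv"),
        os.path.join(ROOT, "panel", "map.tsv"),
        os.path.join(ROOT, "panel", "metadata.tsv"))

    hot, singles = hs.cluster_mtas(mtas, decay_cM=window,
                                   fdr_neg_log10=float(thr["fdr_neg_log10"][0]))
    summary = hs.hotspot_summary(hot, singles)
    out = os.path.join(ROOT, "sweeps")
    io.write_table(hs.hotspot_table(hot), os.path.join(out, "hotspot_table.tsv"),
                   allow_empty=True)
    print(f"{summary['n_hotspots']} hotspots | "
          f"{summary['n_mtas_in_hotspots']} clustered MTAs | "
          f"{summary['n_singletons']} singletons | "
          f"mean {summary['mean_mtas_per_hotspot_rounded']} MTAs/hotspot")

    top = sweeps.select_top_markers(mtas, TOP, hot)
    split = sweeps.split_groups(filtered.subset_markers(top["marker_id"].to_numpy()),
                                meta)
    table = sweeps.allele_rule(
        filtered, split, top["marker_id"].to_numpy(),
        threshold=ALLELE_THRESHOLD,
        positions=gmap.table.set_index("marker_id")["position_cM"],
        hotspot_of=dict(zip(top["marker_id"], top["hotspot_id"])))
    io.write_table(table, os.path.join(out, "sweep_table.tsv"), allow_empty=True)
    io.write_table(split.composition, os.path.join(out, "group_composition.tsv"))
    print(f"{len(top)} top markers; {int(table['passes_rule'].sum())} pass "
          f"the dual-allele ≥{ALLELE_THRESHOLD:.0%} rule")

    # recovery against the planted truth
    truth_pos = pd.read_csv(os.path.join(ROOT, "panel", "sweep_truth.tsv"), sep="\t",
                            dtype={"marker_id": str, "chromosome": str})
    inside = 0
    for _, row in truth_pos.iterrows():
        inside += any(h.chromosome == row["chromosome"]
                      and h.ci_left_cM <= row["position_cM"] <= h.ci_right_cM
                      for h in hot)
    sensitivity = inside / len(truth_pos)
    with open(os.path.join(out, "recovery.json"), "w") as fh:
        json.dump({"n_planted_sweeps": len(truth_pos),
                   "n_recovered": inside,
                   "sensitivity": sensitivity,
                   "decay_window_cM": window}, fh, indent=2)
    print(f"sensitivity vs planted sweeps: {sensitivity:.2f}")


if __name__ == "__main__":
    main()
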