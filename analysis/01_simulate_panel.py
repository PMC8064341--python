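#!/usr/bin/env python
"""Generate the synthetic durum-style panel used by the downstream scripts.

Writes genotypes/map/metadata TSVs plus the generating truth to
results/panel/. All computation lives in eigensweep.simulate.
"""

import argparse
import json
import os

from eigensweep import io
from eigensweep.simulate import SimulationConfig, simulate_panel

OUT = os.path.join(os.path.dirname(__file__), "..", "results", "panel")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    cfg = SimulationConfig(seed=args.seed)
    geno, gmap, meta, truth = simulate_panel(cfg)

    os.makedirs(OUT, exist_ok=True)
    io.write_genotypes(geno, os.path.join(OUT, "genotypes.tsv"))
    io.write_map(gmap, os.path.join(OUT, "map.tsv"))
    io.write_metadata(meta, os.path.join(OUT, "metadata.tsv"))
    io.write_table(truth.sweep_positions, os.path.join(OUT, "sweep_truth.tsv"))
    with open(os.path.join(OUT, "truth.json"), "w") as fh:
        json.dump({
            "seed": args.seed,
            "sweep_marker_ids": truth.sweep_marker_ids,
            "duplicate_pairs": truth.duplicate_pairs,
            "covariate_marker": truth.covariate_marker,
        }, fh, indent=2)
    print(f"panel: {geno.n_markers} markers × {geno.n_samples} samples → {OUT}")


if __name__ == "__main__":
    main()
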