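#!/usr/bin/env python
"""LD-decay estimation per genome and the hotspot clustering window.

Reads results/qc/filtered_genotypes.tsv + the map, writes results/ld/.
"""

import json
import os

from eigensweep import io, ld

ROOT = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    filtered, gmap, _ = io.read_genotypes(
        os.path.join(ROOT, "qc", "filtered_genotypes.tsv"),
        os.path.join(ROOT, "panel", "map.tsv"))

    pairs, n_skipped = ld.pairwise_r2(filtered, gmap)
    models, table = ld.decay_by_genome(pairs)
    window = ld.hotspot_window(models)

    out = os.path.join(ROOT, "ld")
    io.write_table(table, os.path.join(out, "ld_decay.tsv"))
    with open(os.path.join(out, "window.json"), "w") as fh:
        json.dump({"decay_window_cM": window, "n_pairs": len(pairs),
                   "n_pairs_skipped": n_skipped}, fh, indent=2)
    print(table.to_string(index=False))
    print(f"hotspot clustering window: {window} cM")


if __name__ == "__main__":
    main()
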