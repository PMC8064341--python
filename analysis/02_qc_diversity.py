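#!/usr/bin/env python
"""Marker QC (filter chain) and Nei diversity/gene-flow tables.

Reads results/panel/, writes results/qc/ (report + filtered panel) and
results/diversity/.
"""

import os

from eigensweep import diversity as div, io, qc

ROOT = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    geno, gmap, meta = io.read_genotypes(
        os.path.join(ROOT, "panel", "genotypes.tsv"),
        os.path.join(ROOT, "panel", "map.tsv"),
        os.path.join(ROOT, "panel", "metadata.tsv"))

    filtered, report = qc.filter_chain(geno, gmap)
    qc_dir = os.path.join(ROOT, "qc")
    io.write_table(report.stages, os.path.join(qc_dir, "qc_report.tsv"))
    io.write_table(report.per_marker, os.path.join(qc_dir, "qc_per_marker.tsv"))
    io.write_genotypes(filtered, os.path.join(qc_dir, "filtered_genotypes.tsv"))
    print(report.stages.to_string(index=False))
    print(f"{filtered.n_markers}/{geno.n_markers} markers retained")

    table = div.diversity_table(filtered, meta)
    io.write_table(table, os.path.join(ROOT, "diversity", "diversity_table.tsv"))
    total = table.iloc[0]
    print(f"Total: HT={total['HT']:.3f} HS={total['HS']:.3f} "
          f"DST={total['DST']:.3f} GST={total['GST']:.3f} Nm={total['Nm']:.2f}")


if __name__ == "__main__":
    main()
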