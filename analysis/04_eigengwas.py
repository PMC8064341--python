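#!/usr/bin/env python
"""eigenGWAS: PCoA eigenvector phenotypes scanned with the MLM.

Reads the filtered panel, writes results/gwas/ (phenotypes, full scan,
thresholds, MTA table).
"""

import dataclasses
import os

import pandas as pd

from eigensweep import gwas, io, ordination as ordn

ROOT = os.path.join(os.path.dirname(__file__), "..", "results")
N_EIGEN = 10
N_PCS = 6
MODERATE = 3.0


def main() -> None:
    filtered, gmap, meta = io.read_genotypes(
        os.path.join(ROOT, "qc", "filtered_genotypes.tsv"),
        os.path.join(ROOT, "panel", "map.tsv"),
        os.path.join(ROOT, "panel", "metadata.tsv"))

    dist = ordn.simple_matching_distance(filtered)
    pc = ordn.orient_axes(ordn.pcoa(dist, k_axes=N_EIGEN), meta)
    phen = ordn.eigen_phenotypes(pc, top_k=N_EIGEN)

    kin = gwas.kinship(filtered)
    cov = meta.covariate("heading_date") if "heading_date" in meta.table else None
    scan = gwas.mlm_scan(filtered, phen, kin, gmap=gmap, n_pcs=N_PCS,
                         covariates=cov)
    thr = gwas.derive_thresholds(scan, moderate_neg_log10=MODERATE)
    mtas = gwas.significant_mtas(scan, MODERATE)

    out = os.path.join(ROOT, "gwas")
    io.write_table(phen.reset_index(names="sample_id"),
                   os.path.join(out, "eigen_phenotypes.tsv"))
    io.write_table(scan, os.path.join(out, "scan.tsv"))
    io.write_table(pd.DataFrame([dataclasses.asdict(thr)]),
                   os.path.join(out, "thresholds.tsv"))
    io.write_table(mtas, os.path.join(out, "mta_table.tsv"), allow_empty=True)
    print(f"{len(mtas)} MTAs above -log10 p = {MODERATE}; "
          f"FDR line at {thr.fdr_neg_log10:.2f} ({thr.n_fdr} tests)")


if __name__ == "__main__":
    main()
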