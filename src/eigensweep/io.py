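"""Reading and writing panel files.

Native format is three TSVs:

* genotypes: markers as rows; columns ``marker_id``, ``marker_type``,
  ``allele0``, ``allele1``, then one column per sample with calls in
  {0, 1, NA};
* map: ``marker_id``, ``chromosome``, ``position_cM``;
* metadata: ``sample_id``, ``era``, ``origin``, ``subpopulation`` plus any
  numeric covariate columns.

VCF 4.x import is supported for biallelic sites (homozygous ref → 0,
homozygous alt → 1, heterozygous or missing → NA; multiallelic sites are
skipped with a logged count — the panel model is inbred).
"""

from __future__ import annotations

import logging
import os
from typing import Optional

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, GeneticMap, SampleMetadata

logger = logging.getLogger(__name__)

MISSING_TOKEN = "NA"
FLOAT_FORMAT = "%.6g"

_GENO_META_COLS = ["marker_id", "marker_type", "allele0", "allele1"]


def write_genotypes(geno: GenotypeMatrix, path: str) -> None:
    calls = geno.calls.astype(object)
    calls[geno.calls == MISSING] = MISSING_TOKEN
    df = pd.DataFrame(calls, columns=geno.sample_ids)
    df.insert(0, "allele1", [b for _, b in geno.allele_labels])
    df.insert(0, "allele0", [a for a, _ in geno.allele_labels])
    df.insert(0, "marker_type", geno.marker_type)
    df.insert(0, "marker_id", geno.marker_ids)
    df.to_csv(path, sep="\t", index=False)


def read_genotypes(
    geno_path: str,
    map_path: Optional[str] = None,
    meta_path: Optional[str] = None,
) -> tuple[GenotypeMatrix, Optional[GeneticMap], Optional[SampleMetadata]]:
    """Read the native genotype/map/metadata triple.

    Samples are reordered to follow the metadata table when one is given;
    unmapped markers are retained (downstream QC flags them). Invalid calls
    or duplicated identifiers raise with the offending cell/id named.
    """
    df = pd.read_csv(geno_path, sep="\t", dtype=str, keep_default_na=False)
    for col in _GENO_META_COLS:
        if col not in df.columns:
            raise ValueError(f"genotype file missing column {col!r}")
    sample_cols = [c for c in df.columns if c not in _GENO_META_COLS]
    raw = df[sample_cols].to_numpy(dtype=object)
    calls = np.full(raw.shape, MISSING, dtype=np.int8)
    for tok, val in (("0", 0), ("1", 1)):
        calls[raw == tok] = val
    bad = ~np.isin(raw, ("0", "1", MISSING_TOKEN))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"invalid call {raw[i, j]!r} at marker {df['marker_id'].iloc[i]!r}, "
            f"sample {sample_cols[j]!r}"
        )
    geno = GenotypeMatrix(
        df["marker_id"].to_numpy(dtype=object),
        np.array(sample_cols, dtype=object),
        calls,
        df["marker_type"].to_numpy(dtype=object),
        list(zip(df["allele0"], df["allele1"])),
    )

    gmap = None
    if map_path is not None:
        mt = pd.read_csv(map_path, sep="\t", dtype={"marker_id": str, "chromosome": str})
        gmap = GeneticMap(mt)
        n_unmapped = int((~gmap.mapped_mask(geno.marker_ids)).sum())
        if n_unmapped:
            logger.info("%d markers have no map position (retained, flagged)", n_unmapped)

    meta = None
    if meta_path is not None:
        meta = SampleMetadata(pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str}))
        meta.aligned_to(geno.sample_ids)  # validates every genotyped sample is annotated
        in_panel = meta.table["sample_id"].isin(set(geno.sample_ids))
        meta = SampleMetadata(meta.table[in_panel].reset_index(drop=True))
        geno = geno.subset_samples(meta.sample_ids)
    return geno, gmap, meta


def write_map(gmap: GeneticMap, path: str) -> None:
    gmap.table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_metadata(meta: SampleMetadata, path: str) -> None:
    meta.table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_table(table: pd.DataFrame, path: str, allow_empty: bool = False,
                float_format: str = FLOAT_FORMAT) -> str:
    """Write any tabular result as TSV with header; floats at declared precision."""
    if len(table) == 0 and not allow_empty:
        raise ValueError(f"refusing to write empty table to {path} (allow_empty=False)")
    d = os.path.dirname(path)
    if d:
        os.makedirs(d, exist_ok=True)
    table.to_csv(path, sep="\t", index=False, float_format=float_format, na_rep=MISSING_TOKEN)
    return path


def import_vcf(vcf_path: str) -> GenotypeMatrix:
    """Import biallelic sites from a VCF.

    GT collapse rule: 0/0 → 0, 1/1 → 1, anything heterozygous or missing →
    NA. Sites with more than one ALT allele are skipped (count logged).
    """
    from cyvcf2 import VCF

    vcf = VCF(vcf_path)
    samples = np.array(vcf.samples, dtype=object)
    marker_ids, rows, types, labels = [], [], [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt (gts012=False default: 3=hom-alt)
        g = var.gt_types
        row = np.full(len(samples), MISSING, dtype=np.int8)
        row[g == 0] = 0
        row[g == 3] = 1
        rows.append(row)
        marker_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        ref, alt = var.REF, var.ALT[0]
        is_snp = len(ref) == 1 and len(alt) == 1 and {ref, alt} <= set("ACGT")
        types.append("SNP" if is_snp else "PAV")
        labels.append((ref, alt))
    if n_multi:
        logger.info("skipped %d multiallelic site(s)", n_multi)
    if not rows:
        raise ValueError(f"no biallelic sites imported from {vcf_path}")
    return GenotypeMatrix(
        np.array(marker_ids, dtype=object), samples,
        np.vstack(rows), np.array(types, dtype=object), labels,
    )


def export_vcf(geno: GenotypeMatrix, path: str, gmap: Optional[GeneticMap] = None) -> None:
    """Write the panel as a minimal haploid-coded VCF (calls as 0/0, 1/1, ./.)."""
    if gmap is not None:
        pos = gmap.table.set_index("marker_id")
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    chroms = []
    for i, m in enumerate(geno.marker_ids):
        if gmap is not None and m in pos.index:
            chrom = str(pos.loc[m, "chromosome"])
            # cM scaled to an integer coordinate; offset by marker index for uniqueness
            p = int(round(float(pos.loc[m, "position_cM"]) * 10000)) + i + 1
        else:
            chrom, p = "un", i + 1
        chroms.append((chrom, p, m))
    for c in dict.fromkeys(ch for ch, _, _ in chroms):
        lines.append(f"##contig=<ID={c}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, geno.sample_ids)))
    gt_tok = {0: "0/0", 1: "1/1", MISSING: "./."}
    for i, (chrom, p, m) in enumerate(chroms):
        a0, a1 = geno.allele_labels[i]
        ref = a0 if set(a0) <= set("ACGT") and len(a0) >= 1 else "A"
        alt = a1 if set(a1) <= set("ACGT") and len(a1) >= 1 and a1 != ref else ("C" if ref != "C" else "G")
        gts = "\t".join(gt_tok[int(v)] for v in geno.calls[i])
        lines.append(f"{chrom}\t{p}\t{m}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
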