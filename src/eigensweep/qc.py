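"""Marker quality control: allele frequencies, PIC, duplicate-pattern
detection and the four-stage filter chain.

Filter order (fixed): (1) drop unmapped markers; (2) drop SNPs with missing
rate above the cap (PAVs are exempt from the missingness filter); (3) drop
markers with MAF below the floor; (4) resolve duplicate call patterns.
Each dropped marker carries exactly one reason — the first failing stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, GeneticMap

DEFAULT_MAF_MIN = 0.05
DEFAULT_MISSING_MAX = 0.30
DEFAULT_DUP_OVERLAP = 0.90


def allele_frequencies(geno: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker frequency of the allele coded 1 (p), of allele 0 (q), MAF
    and missing rate, over non-missing calls only.

    All-missing markers get NaN frequencies and are flagged ``all_missing``.
    """
    obs = geno.calls != MISSING
    n_obs = obs.sum(axis=1)
    ones = (geno.calls == 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_obs > 0, ones / np.maximum(n_obs, 1), np.nan)
    q = 1.0 - p
    return pd.DataFrame({
        "marker_id": geno.marker_ids,
        "p": p,
        "q": q,
        "maf": np.minimum(p, q),
        "missing_rate": 1.0 - n_obs / geno.n_samples,
        "all_missing": n_obs == 0,
    })


def pic_biallelic(p) -> tuple[np.ndarray, np.ndarray]:
    """Botstein PIC and gene diversity (expected heterozygosity) for a
    biallelic locus with allele frequency ``p``.

    he = 1 − p² − q² (max 0.5); pic = he − 2p²q² (max 0.375). PIC-labelled
    output uses the Botstein formula; both are returned because biallelic
    panels are often summarised with either statistic.
    """
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    he = 1.0 - p**2 - q**2
    pic = he - 2.0 * p**2 * q**2
    return pic, he


def find_duplicates(geno: GenotypeMatrix, min_overlap: float = DEFAULT_DUP_OVERLAP,
                    block: int = 512) -> pd.DataFrame:
    """Pairs of markers with identical call patterns.

    Two markers are duplicates when their calls agree at every sample where
    both are non-missing and the jointly non-missing fraction is at least
    ``min_overlap`` of the panel. The returned table proposes which member
    to drop: in a PAV/SNP pair the PAV; same-type pairs drop the member
    with more missing data (tie → lexicographically larger id).
    """
    x1 = (geno.calls == 1).astype(np.float32)
    x0 = (geno.calls == 0).astype(np.float32)
    obs = x1 + x0
    n = geno.n_samples
    miss = n - obs.sum(axis=1)
    rows = []
    m = geno.n_markers
    for s in range(0, m, block):
        e = min(s + block, m)
        agree = x1[s:e] @ x1.T + x0[s:e] @ x0.T
        overlap = obs[s:e] @ obs.T
        ok = (agree == overlap) & (overlap >= min_overlap * n)
        ii, jj = np.nonzero(ok)
        for a, b in zip(ii + s, jj):
            if b <= a:
                continue
            rows.append((a, b))
    out = []
    for a, b in rows:
        ta, tb = geno.marker_type[a], geno.marker_type[b]
        ida, idb = geno.marker_ids[a], geno.marker_ids[b]
        if ta != tb:
            drop = ida if ta == "PAV" else idb
        elif miss[a] != miss[b]:
            drop = ida if miss[a] > miss[b] else idb
        else:
            drop = max(ida, idb)
        out.append((ida, idb, ta, tb, drop))
    return pd.DataFrame(out, columns=["marker_a", "marker_b", "type_a", "type_b", "drop"])


@dataclass
class QCReport:
    stages: pd.DataFrame       # stage, markers_in, markers_dropped, markers_out
    per_marker: pd.DataFrame   # marker_id, maf, missing_rate, pic, he, mapped, dropped_reason

    def validate(self) -> None:
        s = self.stages
        if not (s["markers_in"] - s["markers_dropped"] == s["markers_out"]).all():
            raise AssertionError("stage bookkeeping broken: in − dropped ≠ out")
        if not (s["markers_in"].iloc[1:].to_numpy() == s["markers_out"].iloc[:-1].to_numpy()).all():
            raise AssertionError("stage chaining broken")


def filter_chain(
    geno: GenotypeMatrix,
    gmap: GeneticMap,
    maf_min: float = DEFAULT_MAF_MIN,
    missing_max: float = DEFAULT_MISSING_MAX,
    dup_overlap: float = DEFAULT_DUP_OVERLAP,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the four-stage filter chain; returns survivors and a QC report
    with per-stage counts and one drop reason per discarded marker."""
    freq = allele_frequencies(geno)
    pic, he = pic_biallelic(freq["p"].to_numpy())
    mapped = gmap.mapped_mask(geno.marker_ids)
    reason = np.full(geno.n_markers, None, dtype=object)

    alive = np.ones(geno.n_markers, dtype=bool)
    counts = []

    def stage(name: str, drop_mask: np.ndarray) -> None:
        drop = drop_mask & alive
        reason[drop] = name
        counts.append((name, int(alive.sum()), int(drop.sum()), int(alive.sum() - drop.sum())))
        alive[drop] = False

    stage("unmapped", ~mapped)
    is_snp = geno.marker_type == "SNP"
    miss = freq["missing_rate"].to_numpy()
    stage("high_missing", is_snp & (miss > missing_max))
    maf = freq["maf"].to_numpy()
    stage("low_maf", np.isnan(maf) | (maf < maf_min))

    dup = find_duplicates(geno.subset_markers(alive), min_overlap=dup_overlap)
    drop_ids = set(dup["drop"]) if len(dup) else set()
    stage("duplicate", np.array([m in drop_ids for m in geno.marker_ids]))

    if not alive.any():
        raise ValueError("no markers survive the filter chain")

    report = QCReport(
        stages=pd.DataFrame(counts, columns=["stage", "markers_in", "markers_dropped", "markers_out"]),
        per_marker=pd.DataFrame({
            "marker_id": geno.marker_ids,
            "marker_type": geno.marker_type,
            "maf": maf,
            "missing_rate": miss,
            "pic": pic,
            "he": he,
            "mapped": mapped,
            "dropped_reason": reason,
        }),
    )
    report.validate()
    return geno.subset_markers(alive), report


def filter_bookkeeping(n_in: int, drops: list[int]) -> list[int]:
    """Running survivor counts after each successive drop count.

    Pure ledger arithmetic for published filtering chains; raises when a
    drop exceeds what is left.
    """
    out, n = [], int(n_in)
    for d in drops:
        n -= int(d)
        if n < 0:
            raise ValueError("drop count exceeds remaining markers")
        out.append(n)
    return out
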