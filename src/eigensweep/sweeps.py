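"""Sweep-marker labelling from the strongest associations.

Markers whose best −log₁₀p across eigenvectors exceeds a cutoff (default 5)
are re-ordinated with PCoA; samples are split into two groups by the sign of
the first coordinate (axis oriented so the landrace-majority side is group
2). A marker is labelled a sweep marker when each group's major allele
reaches an 80% within-group frequency (inclusive) AND the two group-major
alleles differ — so the locus is near-fixed for opposite alleles on the two
sides of the split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, SampleMetadata
from .hotspots import QTLHotspot
from .ordination import pcoa, simple_matching_distance

TOP_NEG_LOG10 = 5.0
ALLELE_THRESHOLD = 0.80

SWEEP_COLUMNS = ["hotspot_id", "marker_id", "position_cM",
                 "allele_group1", "freq_group1", "allele_group2", "freq_group2",
                 "passes_rule", "no_calls_flag"]


def select_top_markers(mtas: pd.DataFrame,
                       cutoff_neg_log10: float = TOP_NEG_LOG10,
                       hotspots: list[QTLHotspot] | None = None) -> pd.DataFrame:
    """Unique markers whose best −log₁₀p across eigenvectors exceeds the
    cutoff (strict), with hotspot membership attached when available."""
    best = (mtas.sort_values("neg_log10_p", ascending=False)
                .drop_duplicates("marker_id"))
    sel = best[best["neg_log10_p"] > cutoff_neg_log10].reset_index(drop=True)
    if len(sel) == 0:
        raise ValueError(f"no markers exceed −log10 p = {cutoff_neg_log10}; pipeline stops")
    membership = {}
    if hotspots:
        for h in hotspots:
            for m in h.members["marker_id"].unique():
                membership.setdefault(m, h.hotspot_id)
    sel = sel.copy()
    sel["hotspot_id"] = sel["marker_id"].map(membership) if membership else None
    return sel[["marker_id", "chromosome", "position_cM", "neg_log10_p", "hotspot_id"]]


@dataclass
class GroupSplit:
    group1: np.ndarray             # sample ids (modern-majority side)
    group2: np.ndarray             # sample ids (landrace-majority side)
    composition: pd.DataFrame      # era percentages per group


def split_groups(geno_sel: GenotypeMatrix, meta: SampleMetadata) -> GroupSplit:
    """Two-group split by the sign of PCoA axis 1 on the selected markers.

    The axis is oriented so the landrace-majority side is positive;
    group 2 is the positive side.
    """
    dist = simple_matching_distance(geno_sel)
    res = pcoa(dist, k_axes=1)
    axis = res.coordinates[:, 0]
    meta = meta.aligned_to(geno_sel.sample_ids)
    is_landrace = (meta.table["era"] == "landrace").to_numpy()
    if is_landrace.any() and axis[is_landrace].mean() < 0:
        axis = -axis
    pos = axis > 0
    if pos.all() or (~pos).all():
        raise ValueError("PCoA axis 1 does not split the panel into two groups")
    comp = []
    for name, mask in (("group1", ~pos), ("group2", pos)):
        eras = meta.table.loc[mask, "era"].value_counts(normalize=True) * 100
        comp.append({"group": name, "n": int(mask.sum()),
                     "pct_landrace": float(eras.get("landrace", 0.0)),
                     "pct_modern": float(eras.get("modern", 0.0))})
    return GroupSplit(
        group1=geno_sel.sample_ids[~pos],
        group2=geno_sel.sample_ids[pos],
        composition=pd.DataFrame(comp),
    )


def _group_major(geno: GenotypeMatrix, sample_ids: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-marker major-allele code, its within-group frequency, and a
    no-calls flag, over one sample group."""
    sub = geno.subset_samples(sample_ids)
    obs = sub.calls != MISSING
    n = obs.sum(axis=1)
    ones = (sub.calls == 1).sum(axis=1)
    with np.errstate(invalid="ignore"):
        p1 = np.where(n > 0, ones / np.maximum(n, 1), np.nan)
    major = np.where(p1 >= 0.5, 1, 0)
    freq = np.where(major == 1, p1, 1.0 - p1)
    return major, freq, n == 0


def allele_rule(
    geno: GenotypeMatrix,
    split: GroupSplit,
    marker_ids: np.ndarray,
    threshold: float = ALLELE_THRESHOLD,
    positions: pd.Series | None = None,
    hotspot_of: dict | None = None,
) -> pd.DataFrame:
    """Apply the dual-allele frequency rule to the selected markers.

    Passing requires both group-major frequencies ≥ threshold (inclusive)
    and differing group-major alleles. Markers with no calls in a group are
    flagged and fail.
    """
    sel = geno.subset_markers(np.asarray(marker_ids, dtype=object))
    maj1, f1, miss1 = _group_major(sel, split.group1)
    maj2, f2, miss2 = _group_major(sel, split.group2)
    no_calls = miss1 | miss2
    passes = (~no_calls) & (maj1 != maj2) & (f1 >= threshold) & (f2 >= threshold)
    labels = np.array([sel.allele_labels[i] for i in range(sel.n_markers)], dtype=object)
    out = pd.DataFrame({
        "hotspot_id": [hotspot_of.get(m) if hotspot_of else None for m in sel.marker_ids],
        "marker_id": sel.marker_ids,
        "position_cM": (positions.reindex(sel.marker_ids).to_numpy()
                        if positions is not None else np.nan),
        "allele_group1": [labels[i][maj1[i]] for i in range(sel.n_markers)],
        "freq_group1": f1,
        "allele_group2": [labels[i][maj2[i]] for i in range(sel.n_markers)],
        "freq_group2": f2,
        "passes_rule": passes,
        "no_calls_flag": no_calls,
    })
    return out.sort_values(["hotspot_id", "marker_id"], na_position="last",
                           kind="stable").reset_index(drop=True)


def allele_rule_from_frequencies(table: pd.DataFrame,
                                 threshold: float = ALLELE_THRESHOLD) -> pd.DataFrame:
    """Apply the dual-allele rule to a table of already-computed group-major
    alleles and frequencies (columns allele_group1/freq_group1/
    allele_group2/freq_group2), e.g. a published per-group frequency table."""
    t = table.copy()
    t["passes_rule"] = (
        (t["allele_group1"].astype(str) != t["allele_group2"].astype(str))
        & (t["freq_group1"] >= threshold)
        & (t["freq_group2"] >= threshold)
    )
    return t
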