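"""Nei diversity decomposition and gene flow.

Per locus, gene diversity is H = 1 − Σ allele-freq². For a partition of
samples into groups, the total diversity H_T is computed from the unweighted
mean of group allele frequencies, H_S is the unweighted mean of within-group
H, D_ST = H_T − H_S, G_ST = D_ST / H_T, and gene flow is
Nm = 0.5·(1 − G_ST)/G_ST (infinite when G_ST = 0). Loci fixed in every
group contribute 0 to all components and are kept so marker panels stay
comparable.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, SampleMetadata

DIVERSITY_COLUMNS = ["grouping", "n_samples", "HT", "HS", "DST", "GST", "Nm", "nm_infinite"]


def _group_freqs(geno: GenotypeMatrix, groups: list[np.ndarray]) -> np.ndarray:
    """Per-locus allele-1 frequency in each group (n_markers × n_groups);
    NaN where a group has no calls at a locus."""
    out = np.empty((geno.n_markers, len(groups)))
    for k, idx in enumerate(groups):
        sub = geno.calls[:, idx]
        obs = sub != MISSING
        n = obs.sum(axis=1)
        with np.errstate(invalid="ignore"):
            out[:, k] = np.where(n > 0, (sub == 1).sum(axis=1) / np.maximum(n, 1), np.nan)
    return out


def gene_diversity(geno: GenotypeMatrix, sample_idx: np.ndarray | None = None
                   ) -> tuple[np.ndarray, float]:
    """Per-locus H = 1 − p² − q² over the given samples and the mean across
    loci (all-missing loci excluded from the mean)."""
    if sample_idx is None:
        sample_idx = np.arange(geno.n_samples)
    sample_idx = np.asarray(sample_idx)
    if sample_idx.size == 0:
        raise ValueError("empty sample subset")
    p = _group_freqs(geno, [sample_idx])[:, 0]
    h = 1.0 - p**2 - (1.0 - p) ** 2
    return h, float(np.nanmean(h))


def nm_from_gst(gst: float) -> float:
    """Gene flow from differentiation: Nm = 0.5·(1 − G_ST)/G_ST."""
    if gst <= 0:
        return float("inf")
    return 0.5 * (1.0 - gst) / gst


def diversity_decomposition(
    geno: GenotypeMatrix,
    groups: dict[str, np.ndarray],
    grouping_label: str = "Total",
) -> pd.Series:
    """One diversity-table row for a partition of samples into ≥2 groups."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    idx_list = [np.asarray(v) for v in groups.values()]
    freqs = _group_freqs(geno, idx_list)
    if np.isnan(freqs).all(axis=0).any():
        k = int(np.flatnonzero(np.isnan(freqs).all(axis=0))[0])
        raise ValueError(f"group {list(groups)[k]!r} has no genotyped calls at any locus")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN locus rows
        pbar = np.nanmean(freqs, axis=1)
        h_within = 1.0 - freqs**2 - (1.0 - freqs) ** 2
        ht_locus = 1.0 - pbar**2 - (1.0 - pbar) ** 2
        hs_locus = np.nanmean(h_within, axis=1)
        ht = float(np.nanmean(ht_locus))
        hs = float(np.nanmean(hs_locus))
    dst = ht - hs
    gst = dst / ht if ht > 0 else 0.0
    nm = nm_from_gst(gst)
    return pd.Series({
        "grouping": grouping_label,
        "n_samples": int(sum(len(i) for i in idx_list)),
        "HT": ht, "HS": hs, "DST": dst, "GST": gst,
        "Nm": nm, "nm_infinite": not np.isfinite(nm),
    })


def _subpop_indices(geno: GenotypeMatrix, meta: SampleMetadata) -> dict[str, np.ndarray]:
    meta = meta.aligned_to(geno.sample_ids)
    sp = meta.table["subpopulation"].to_numpy(dtype=object)
    return {
        lab: np.flatnonzero(sp == lab)
        for lab in pd.unique(sp) if isinstance(lab, str)
    }


def diversity_table(geno: GenotypeMatrix, meta: SampleMetadata) -> pd.DataFrame:
    """Full diversity table: a Total row over all labelled groups (including
    admixed), per-group H rows, and one decomposition per subpopulation pair."""
    groups = _subpop_indices(geno, meta)
    rows = [diversity_decomposition(geno, groups, "Total")]
    for lab, idx in groups.items():
        _, h = gene_diversity(geno, idx)
        rows.append(pd.Series({
            "grouping": lab, "n_samples": len(idx), "HT": h,
            "HS": np.nan, "DST": np.nan, "GST": np.nan, "Nm": np.nan,
            "nm_infinite": False,
        }))
    for _, r in pairwise_flow(geno, meta).iterrows():
        rows.append(r)
    return pd.DataFrame(rows, columns=DIVERSITY_COLUMNS).reset_index(drop=True)


def pairwise_flow(geno: GenotypeMatrix, meta: SampleMetadata) -> pd.DataFrame:
    """Diversity decomposition for every unordered subpopulation pair
    (admixed samples excluded); pairs with a group of <2 members are skipped
    with a warning."""
    groups = {k: v for k, v in _subpop_indices(geno, meta).items() if k != "admixed"}
    if len(groups) < 2:
        raise ValueError("need at least two labelled subpopulations")
    rows = []
    for a, b in itertools.combinations(sorted(groups), 2):
        if len(groups[a]) < 2 or len(groups[b]) < 2:
            warnings.warn(f"pair {a}-{b} skipped: a group has <2 members")
            continue
        label = f"{a}–{b.removeprefix('SP')}" if a.startswith("SP") else f"{a}–{b}"
        rows.append(diversity_decomposition(geno, {a: groups[a], b: groups[b]}, label))
    return pd.DataFrame(rows, columns=DIVERSITY_COLUMNS).reset_index(drop=True)
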