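"""QTL hotspot clustering of marker–trait associations along the map.

Each MTA spans ±decay cM around its position; spans that overlap or abut are
merged transitively (single linkage), i.e. two MTAs join when their
positions differ by at most 2×decay. Clusters with at least ``min_members``
MTA records (marker × eigenvector, so one marker significant for several
eigenvectors contributes several members) become hotspots with confidence
interval [min pos − decay, max pos + decay], clipped at 0; smaller clusters
are returned as singletons. Hotspot ids run left-to-right per chromosome as
``eigenQTL<chrom>.<index>``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_MIN_MEMBERS = 2

HOTSPOT_COLUMNS = ["hotspot_id", "chromosome", "ci_left_cM", "ci_right_cM",
                   "n_mtas", "n_fdr", "n_markers"]


@dataclass
class QTLHotspot:
    hotspot_id: str
    chromosome: str
    ci_left_cM: float
    ci_right_cM: float
    members: pd.DataFrame          # MTA rows
    n_fdr: int = 0

    @property
    def n_mtas(self) -> int:
        return len(self.members)


def cluster_mtas(
    mtas: pd.DataFrame,
    decay_cM: float,
    min_members: int = DEFAULT_MIN_MEMBERS,
    fdr_neg_log10: float = float("inf"),
) -> tuple[list[QTLHotspot], pd.DataFrame]:
    """Cluster significant MTAs into hotspots; returns (hotspots, singletons).

    ``mtas`` must already be restricted to the moderate threshold and carry
    ``chromosome`` and ``position_cM``; an unmapped MTA is a hard error.
    """
    if mtas["position_cM"].isna().any() or mtas["chromosome"].isna().any():
        bad = mtas.loc[mtas["position_cM"].isna() | mtas["chromosome"].isna(), "marker_id"]
        raise ValueError(f"unmapped MTA(s): {list(bad[:5])}")
    hotspots: list[QTLHotspot] = []
    singleton_frames = []
    for chrom in sorted(mtas["chromosome"].unique()):
        sub = mtas[mtas["chromosome"] == chrom].sort_values(
            ["position_cM", "marker_id", "eigenvector"], kind="stable")
        pos = sub["position_cM"].to_numpy(dtype=float)
        # new cluster starts where the gap to the previous MTA exceeds 2×decay
        breaks = np.flatnonzero(np.diff(pos) > 2.0 * decay_cM) + 1
        idx = 0
        for chunk in np.split(np.arange(len(sub)), breaks):
            members = sub.iloc[chunk]
            if len(members) >= min_members:
                idx += 1
                p = members["position_cM"].to_numpy()
                hotspots.append(QTLHotspot(
                    hotspot_id=f"eigenQTL{chrom}.{idx}",
                    chromosome=chrom,
                    ci_left_cM=max(float(p.min()) - decay_cM, 0.0),
                    ci_right_cM=float(p.max()) + decay_cM,
                    members=members.reset_index(drop=True),
                    n_fdr=int((members["neg_log10_p"] >= fdr_neg_log10).sum()),
                ))
            else:
                singleton_frames.append(members)
    singletons = (pd.concat(singleton_frames, ignore_index=True)
                  if singleton_frames else mtas.iloc[0:0].copy())
    return hotspots, singletons


def hotspot_table(hotspots: list[QTLHotspot]) -> pd.DataFrame:
    return pd.DataFrame(
        [{
            "hotspot_id": h.hotspot_id, "chromosome": h.chromosome,
            "ci_left_cM": h.ci_left_cM, "ci_right_cM": h.ci_right_cM,
            "n_mtas": h.n_mtas, "n_fdr": h.n_fdr,
            "n_markers": h.members["marker_id"].nunique(),
        } for h in hotspots],
        columns=HOTSPOT_COLUMNS,
    )


def hotspot_summary(hotspots: list[QTLHotspot], singletons: pd.DataFrame) -> dict:
    """Accounting totals over a clustering result."""
    n_in = sum(h.n_mtas for h in hotspots)
    n_hot = len(hotspots)
    per_chrom = pd.Series([h.chromosome for h in hotspots]).value_counts().to_dict() \
        if hotspots else {}
    return {
        "n_hotspots": n_hot,
        "n_mtas_in_hotspots": n_in,
        "n_singletons": int(len(singletons)),
        "n_mtas_total": n_in + int(len(singletons)),
        "mean_mtas_per_hotspot": n_in / n_hot if n_hot else float("nan"),
        "mean_mtas_per_hotspot_rounded": int(round(n_in / n_hot)) if n_hot else 0,
        "n_fdr_in_hotspots": sum(h.n_fdr for h in hotspots),
        "hotspots_per_chromosome": per_chrom,
    }


def hotspot_accounting(n_mtas_total: int, n_mtas_clustered: int, n_hotspots: int) -> dict:
    """Pure arithmetic on published hotspot totals: singleton count and mean
    cluster occupancy (rounded and unrounded)."""
    if n_mtas_clustered > n_mtas_total:
        raise ValueError("clustered MTAs exceed total MTAs")
    mean = n_mtas_clustered / n_hotspots
    return {
        "n_singletons": n_mtas_total - n_mtas_clustered,
        "mean_mtas_per_hotspot": mean,
        "mean_mtas_per_hotspot_rounded": int(round(mean)),
    }
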