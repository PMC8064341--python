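"""Linkage-disequilibrium decay along the genetic map.

r² is the squared Pearson correlation of the 0/1 call vectors of two mapped
markers over their jointly non-missing samples, computed for every
within-chromosome pair closer than a sliding-window span (default 50 cM)
and pooled per genome (chromosomes 1A–7A vs 1B–7B). Significance uses the
haploid χ² approximation χ² = n·r² with 1 df. The decay distance is where a
LOESS fit of r² against distance first drops to the genome-wide mean r².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import MISSING, GenotypeMatrix, GeneticMap

DEFAULT_WINDOW_CM = 50.0
DEFAULT_P_CUT = 1e-3
DEFAULT_SPAN = 0.1  # calibrated by decay-recovery simulation; see docs/methods.md
MIN_JOINT = 10
BIN_THRESHOLD = 1_000_000  # pairs; above this r² is binned to 0.1 cM before LOESS


def genome_of(chrom: str) -> str:
    return chrom[-1]


def pairwise_r2(
    geno: GenotypeMatrix,
    gmap: GeneticMap,
    window_cM: float = DEFAULT_WINDOW_CM,
    min_joint: int = MIN_JOINT,
) -> tuple[pd.DataFrame, int]:
    """All within-chromosome marker pairs at map distance ≤ window.

    Returns (pair table with genome, distance_cM, r2, p_value; count of
    pairs skipped for joint sample count < ``min_joint``).
    """
    mapped = gmap.mapped_mask(geno.marker_ids)
    sub = geno.subset_markers(mapped)
    pos = gmap.positions(sub.marker_ids)
    frames, n_skipped = [], 0
    for chrom in pos["chromosome"].unique():
        rows = np.flatnonzero((pos["chromosome"] == chrom).to_numpy())
        order = rows[np.argsort(pos["position_cM"].to_numpy()[rows], kind="stable")]
        calls = sub.calls[order].astype(np.float64)
        cm = pos["position_cM"].to_numpy()[order]
        obs = (calls != MISSING).astype(np.float64)
        x = np.where(calls == MISSING, 0.0, calls)
        # sums over jointly observed samples (x² = x for 0/1 calls)
        n = obs @ obs.T
        sx = x @ obs.T
        sxy = x @ x.T
        var_x = n * sx - sx**2          # n·Σx − (Σx)², up to scaling
        cov = n * sxy - sx * sx.T
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = cov**2 / (var_x * var_x.T)
        ii, jj = np.triu_indices(len(order), k=1)
        dist = cm[jj] - cm[ii]
        keep = dist <= window_cM
        ii, jj, dist = ii[keep], jj[keep], dist[keep]
        nij = n[ii, jj]
        enough = nij >= min_joint
        n_skipped += int((~enough).sum())
        ii, jj, dist, nij = ii[enough], jj[enough], dist[enough], nij[enough]
        r2v = r2[ii, jj]
        valid = np.isfinite(r2v)  # monomorphic-on-overlap pairs have no r²
        ii, jj, dist, nij, r2v = ii[valid], jj[valid], dist[valid], nij[valid], r2v[valid]
        pv = stats.chi2.sf(nij * r2v, df=1)
        frames.append(pd.DataFrame({
            "marker_a": sub.marker_ids[order][ii],
            "marker_b": sub.marker_ids[order][jj],
            "chromosome": chrom,
            "genome": genome_of(chrom),
            "distance_cM": dist,
            "r2": np.clip(r2v, 0.0, 1.0),
            "p_value": np.maximum(pv, np.finfo(float).tiny),
            "n_joint": nij.astype(int),
        }))
    if not frames:
        raise ValueError("no mapped marker pairs within the window")
    return pd.concat(frames, ignore_index=True), n_skipped


@dataclass
class LDDecayModel:
    genome: str
    n_pairs: int
    pct_significant: float   # % of pairs with p < the significance cut
    mean_r2: float
    grid_cM: np.ndarray
    fitted_r2: np.ndarray
    decay_cM: float
    starts_below_mean: bool  # curve already below mean at distance 0


def fit_decay(
    pairs: pd.DataFrame,
    grid_step: float = 0.01,
    span: float = DEFAULT_SPAN,
    p_cut: float = DEFAULT_P_CUT,
    genome: str = "all",
) -> LDDecayModel:
    """LOESS of r² on distance; decay = first grid distance where the fitted
    curve is at or below the mean r² of all pairs."""
    if len(pairs) < 100:
        raise ValueError(f"need ≥100 pairs to fit a decay curve, got {len(pairs)}")
    d = pairs["distance_cM"].to_numpy(dtype=float)
    r2 = pairs["r2"].to_numpy(dtype=float)
    if np.ptp(d) == 0:
        raise ValueError("all pair distances identical; decay curve undefined")
    mean_r2 = float(r2.mean())
    pct_sig = 100.0 * float((pairs["p_value"] < p_cut).mean())

    if len(pairs) > BIN_THRESHOLD:  # performance guard on very large pair sets
        bins = np.round(d / 0.1) * 0.1
        agg = pd.DataFrame({"d": bins, "r2": r2}).groupby("d")["r2"].mean()
        d_fit, r2_fit = agg.index.to_numpy(), agg.to_numpy()
    else:
        d_fit, r2_fit = d, r2

    sm = lowess(r2_fit, d_fit, frac=span, it=0, delta=0.002 * np.ptp(d_fit))
    grid = np.arange(d.min(), d.max() + grid_step, grid_step)
    fitted = np.interp(grid, sm[:, 0], sm[:, 1])

    below = fitted <= mean_r2
    if below[0]:
        decay, starts_below = 0.0, True
    elif below.any():
        decay, starts_below = float(grid[np.argmax(below)]), False
    else:
        decay, starts_below = float(grid[-1]), False
    return LDDecayModel(genome, len(pairs), pct_sig, mean_r2, grid, fitted, decay, starts_below)


def decay_by_genome(pairs: pd.DataFrame, **kw) -> tuple[dict[str, LDDecayModel], pd.DataFrame]:
    """Fit one decay model per genome; summary table rounds nothing."""
    models, rows = {}, []
    for g in sorted(pairs["genome"].unique()):
        m = fit_decay(pairs[pairs["genome"] == g], genome=g, **kw)
        models[g] = m
        rows.append({"genome": g, "n_pairs": m.n_pairs, "pct_significant": m.pct_significant,
                     "mean_r2": m.mean_r2, "decay_cM": m.decay_cM})
    return models, pd.DataFrame(rows)


def hotspot_window(models: dict[str, LDDecayModel], granularity: float = 0.5) -> float:
    """Clustering window for hotspot calling: the largest per-genome decay,
    rounded up to the given granularity (never below one granule)."""
    worst = max(m.decay_cM for m in models.values())
    return max(granularity, float(np.ceil(worst / granularity) * granularity))
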