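"""Simple-matching distance, principal coordinates analysis, and
eigen-phenotype extraction.

The sample distance is 1 − simple-matching coefficient over jointly
non-missing markers. PCoA applies Gower double-centering to −½·d² and an
eigendecomposition; negative eigenvalues (the distance need not be
Euclidean) are reported but excluded from variance percentages. Each axis
is oriented so that the landrace-era group mean is positive when era labels
are supplied, making downstream group splits reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, SampleMetadata


def simple_matching_distance(geno: GenotypeMatrix) -> pd.DataFrame:
    """d(i,j) = 1 − matches/joint over jointly non-missing markers.

    Returns a symmetric DataFrame indexed by sample id. A pair with zero
    joint coverage is an error (its distance is undefined).
    """
    if geno.n_samples < 2:
        raise ValueError("need at least two samples")
    x1 = (geno.calls == 1).astype(np.float64)
    x0 = (geno.calls == 0).astype(np.float64)
    obs = x1 + x0
    matches = x1.T @ x1 + x0.T @ x0
    joint = obs.T @ obs
    if (joint == 0).any():
        i, j = np.argwhere(joint == 0)[0]
        raise ValueError(
            f"no jointly genotyped markers for samples "
            f"{geno.sample_ids[i]!r} and {geno.sample_ids[j]!r}"
        )
    d = 1.0 - matches / joint
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=geno.sample_ids, columns=geno.sample_ids)


@dataclass
class PCoAResult:
    sample_ids: np.ndarray
    eigenvalues: np.ndarray        # all eigenvalues, descending (may include negatives)
    coordinates: np.ndarray        # samples × k, scaled so ‖col k‖² = λ_k
    pct_variance: np.ndarray       # per returned axis, over the positive-eigenvalue sum
    n_negative: int = 0
    neg_variance_fraction: float = 0.0

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


def pcoa(dist: pd.DataFrame, k_axes: int) -> PCoAResult:
    """Classical PCoA (Gower) of a distance matrix; top ``k_axes`` axes.

    If fewer positive eigenvalues exist than requested, the result is
    truncated with a warning.
    """
    if k_axes < 1:
        raise ValueError("k_axes must be ≥ 1")
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    b = -0.5 * d**2
    b = b - b.mean(axis=0) - b.mean(axis=1)[:, None] + b.mean()
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(abs(vals[0]), 1.0) * 1e-10
    pos = vals > tol
    n_pos = int(pos.sum())
    if n_pos == 0:
        raise ValueError("distance matrix has no positive PCoA axes")
    if k_axes > n_pos:
        warnings.warn(f"only {n_pos} positive axes available; truncating from {k_axes}")
        k_axes = n_pos
    coords = vecs[:, :k_axes] * np.sqrt(vals[:k_axes])
    pos_sum = vals[pos].sum()
    neg_sum = -vals[vals < -tol].sum()
    return PCoAResult(
        sample_ids=np.asarray(dist.index, dtype=object),
        eigenvalues=vals,
        coordinates=coords,
        pct_variance=100.0 * vals[:k_axes] / pos_sum,
        n_negative=int((vals < -tol).sum()),
        neg_variance_fraction=float(neg_sum / (pos_sum + neg_sum)) if neg_sum else 0.0,
    )


def orient_axes(result: PCoAResult, meta: SampleMetadata) -> PCoAResult:
    """Flip each axis so the landrace-era group mean is positive (ties and
    zero means keep the current sign)."""
    meta = meta.aligned_to(result.sample_ids)
    is_landrace = (meta.table["era"] == "landrace").to_numpy()
    if not is_landrace.any():
        return result
    signs = np.sign(result.coordinates[is_landrace].mean(axis=0))
    signs[signs == 0] = 1.0
    result.coordinates = result.coordinates * signs
    return result


def eigen_phenotypes(result: PCoAResult, top_k: int = 10) -> pd.DataFrame:
    """Top-k PCoA axes standardised to zero mean / unit variance, for use as
    GWAS phenotypes. Per-axis variance percentages ride along in ``attrs``."""
    n_pos = int((result.eigenvalues > 0).sum())
    if result.n_axes < top_k or n_pos < top_k:
        raise ValueError(f"need {top_k} positive axes, have {min(result.n_axes, n_pos)}")
    cols = {}
    for k in range(top_k):
        v = result.coordinates[:, k]
        cols[f"EV{k + 1}"] = (v - v.mean()) / v.std()
    out = pd.DataFrame(cols, index=result.sample_ids)
    out.attrs["pct_variance"] = result.pct_variance[:top_k].tolist()
    return out
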