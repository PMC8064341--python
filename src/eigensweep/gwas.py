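"""Mixed-linear-model association scan with eigenvector phenotypes.

The model per marker is y = Xβ + Zu + e with u ~ N(0, σ²g·K) and
e ~ N(0, σ²e·I). Variance components are estimated by REML after a spectral
decomposition of K, reducing the likelihood to a one-dimensional search in
δ = σ²e/σ²g (the EMMA device). With P3D (default) δ is estimated once per
phenotype on the null model and reused for every marker; the per-marker test
is then a generalized-least-squares Wald/F test of the marker coefficient
given the fixed effects (intercept, genotype principal components, optional
covariates).

Kinship is the VanRaden centered cross-product K = M·Mᵀ / Σ2p(1−p) on
marker-mean-imputed calls, clipped to positive semi-definite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .containers import MISSING, GenotypeMatrix, GeneticMap

MODERATE_NEG_LOG10 = 3.0
DEFAULT_FDR_ALPHA = 0.05
DEFAULT_N_PCS = 6

MTA_COLUMNS = ["marker_id", "chromosome", "position_cM", "eigenvector", "beta",
               "p_value", "neg_log10_p", "r2_explained", "collinear"]


def imputed_dosage(geno: GenotypeMatrix) -> np.ndarray:
    """Samples × markers call matrix with missing entries replaced by the
    marker mean (used for kinship, PCA and the scan design only)."""
    x = geno.calls.T.astype(np.float64)  # samples × markers
    obs = x != MISSING
    x = np.where(obs, x, 0.0)
    n_obs = obs.sum(axis=0)
    mean = np.divide(x.sum(axis=0), n_obs, out=np.full(x.shape[1], 0.0), where=n_obs > 0)
    return np.where(obs, x, mean[None, :])


@dataclass
class KinshipMatrix:
    sample_ids: np.ndarray
    K: np.ndarray

    def __post_init__(self) -> None:
        if not np.allclose(self.K, self.K.T, atol=1e-8):
            raise ValueError("kinship matrix is not symmetric")


def kinship(geno: GenotypeMatrix, method: str = "vanraden") -> KinshipMatrix:
    """Genomic relationship matrix from the filtered panel.

    ``vanraden``: centered cross-product scaled by Σ2p(1−p).
    ``ibs``: mean-centered identity-by-state share.
    Eigenvalues are clipped at 0 so K is PSD for the spectral REML.
    """
    x = imputed_dosage(geno)
    p = x.mean(axis=0)
    if method == "vanraden":
        m = x - p[None, :]
        c = float((2.0 * p * (1.0 - p)).sum())
        if c <= 0:
            raise ValueError("zero-variance genotype matrix")
        k = m @ m.T / c
    elif method == "ibs":
        ibs = 1.0 - np.abs(x[:, None, :] - x[None, :, :]).mean(axis=2) if x.shape[0] <= 300 \
            else _ibs_blocked(x)
        k = ibs - ibs.mean()
    else:
        raise ValueError(f"unknown kinship method {method!r}")
    k = (k + k.T) / 2.0
    vals, vecs = np.linalg.eigh(k)
    if vals[0] < -1e-10 * max(vals[-1], 1.0):
        k = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
    return KinshipMatrix(geno.sample_ids.copy(), k)


def _ibs_blocked(x: np.ndarray, block: int = 128) -> np.ndarray:
    n = x.shape[0]
    out = np.empty((n, n))
    for s in range(0, n, block):
        e = min(s + block, n)
        out[s:e] = 1.0 - np.abs(x[s:e, None, :] - x[None, :, :]).mean(axis=2)
    return out


def genotype_pcs(geno: GenotypeMatrix, n_pcs: int = DEFAULT_N_PCS) -> np.ndarray:
    """Principal-component scores (samples × n_pcs) of the column-centered
    genotype matrix — the fixed-effect structure covariates."""
    x = imputed_dosage(geno)
    x = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    if n_pcs > len(s):
        raise ValueError(f"requested {n_pcs} PCs from rank-{len(s)} matrix")
    return u[:, :n_pcs] * s[:n_pcs]


def _reml_neg_loglik(log_delta: float, s: np.ndarray, x_rot: np.ndarray,
                     y_rot: np.ndarray, logdet_xtx: float) -> float:
    delta = np.exp(log_delta)
    w = 1.0 / (s + delta)
    xw = x_rot * w[:, None]
    xtwx = x_rot.T @ xw
    beta = np.linalg.solve(xtwx, xw.T @ y_rot)
    r = y_rot - x_rot @ beta
    n, p = x_rot.shape
    rss = float(r @ (w * r))
    sigma2 = rss / (n - p)
    sign, logdet_xtwx = np.linalg.slogdet(xtwx)
    ll = -0.5 * ((n - p) * (np.log(2 * np.pi * sigma2) + 1.0)
                 + np.log(s + delta).sum() + logdet_xtwx - logdet_xtx)
    return -ll


def reml_delta(s: np.ndarray, x_rot: np.ndarray, y_rot: np.ndarray) -> float:
    """REML estimate of δ = σ²e/σ²g by coarse grid + bounded refinement."""
    _, logdet_xtx = np.linalg.slogdet(x_rot.T @ x_rot)
    grid = np.linspace(-8.0, 8.0, 33)
    vals = [_reml_neg_loglik(g, s, x_rot, y_rot, logdet_xtx) for g in grid]
    i = int(np.argmin(vals))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        _reml_neg_loglik, bounds=(lo, hi), method="bounded",
        args=(s, x_rot, y_rot, logdet_xtx))
    return float(np.exp(res.x))


def _weighted_scan(mw: np.ndarray, a: np.ndarray, yw: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """GLS marker tests on the whitened scale via Frisch–Waugh.

    mw: markers × n whitened dosages; a: n × p whitened base design;
    yw: whitened phenotype. Returns (beta, p, r2_explained, collinear).
    """
    n, p = a.shape
    q, _ = np.linalg.qr(a)
    y_res = yw - q @ (q.T @ yw)
    rss0 = float(y_res @ y_res)
    m_res = mw - (mw @ q) @ q.T
    mtm = np.einsum("ij,ij->i", m_res, m_res)
    mty = m_res @ y_res
    tol = 1e-10 * max(float(mtm.max(initial=0.0)), 1.0)
    collinear = mtm <= tol
    mtm_safe = np.where(collinear, 1.0, mtm)
    beta = mty / mtm_safe
    rss1 = np.maximum(rss0 - mty**2 / mtm_safe, 0.0)
    df = n - p - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (rss0 - rss1) / (rss1 / df)
    pval = stats.f.sf(f, 1, df)
    pval = np.where(collinear, 1.0, pval)
    beta = np.where(collinear, 0.0, beta)
    # variance explained: marker SS increment over total SS about the
    # weighted mean (intercept-only residual)
    a1 = a[:, 0]
    y0 = yw - a1 * (a1 @ yw) / (a1 @ a1)
    tss = float(y0 @ y0)
    r2 = (rss0 - rss1) / tss if tss > 0 else np.zeros_like(beta)
    return beta, pval, np.clip(r2, 0.0, 1.0), collinear


def mlm_scan(
    geno: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    kin: KinshipMatrix,
    gmap: GeneticMap | None = None,
    n_pcs: int = DEFAULT_N_PCS,
    covariates: np.ndarray | None = None,
    p3d: bool = True,
    collinearity_guard: float | None = 0.95,
) -> pd.DataFrame:
    """Association scan of every marker against every phenotype column.

    Returns one row per marker × phenotype with beta, p-value, −log₁₀p and
    the variance explained by the marker term. Map positions are attached
    when a map is given (unmapped markers get NaN positions).

    Because the phenotypes here are themselves eigenvectors of the panel,
    a fixed-effect PC can coincide with the trait being scanned; regressing
    the response on itself is degenerate and silently removes every signal.
    The ``collinearity_guard`` therefore excludes, per trait, any PC whose
    absolute correlation with that trait reaches the guard (the exclusion is
    recorded in ``DataFrame.attrs['pcs_used']``). Set to ``None`` to keep
    all PCs for every trait.
    """
    if not np.array_equal(kin.sample_ids, geno.sample_ids):
        raise ValueError("kinship sample ids do not match the genotype matrix")
    if not np.array_equal(np.asarray(phenotypes.index, dtype=object), geno.sample_ids):
        raise ValueError("phenotype rows must align with genotype samples")

    x = imputed_dosage(geno)                      # samples × markers
    n = geno.n_samples
    pcs = genotype_pcs(geno, n_pcs) if n_pcs > 0 else np.empty((n, 0))
    extras = [np.ones((n, 1))]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        extras.append(cov)
    base = np.hstack(extras)

    s, u = np.linalg.eigh(kin.K)
    s = np.clip(s, 0.0, None)
    m_rot = (x.T @ u)                             # markers × n

    frames = []
    pcs_used: dict[str, list[int]] = {}
    for col in phenotypes.columns:
        y = phenotypes[col].to_numpy(dtype=float)
        keep = list(range(pcs.shape[1]))
        if collinearity_guard is not None and pcs.shape[1]:
            yc = (y - y.mean()) / y.std()
            pc_std = (pcs - pcs.mean(0)) / pcs.std(0)
            r = np.abs(pc_std.T @ yc) / n
            keep = [j for j in keep if r[j] < collinearity_guard]
        pcs_used[col] = keep
        x0 = np.hstack([base, pcs[:, keep]])
        x0_rot = u.T @ x0
        y_rot = u.T @ y
        if p3d:
            delta = reml_delta(s, x0_rot, y_rot)
            w = np.sqrt(1.0 / (s + delta))
            beta, pval, r2, coll = _weighted_scan(
                m_rot * w[None, :], x0_rot * w[:, None], y_rot * w)
        else:
            beta = np.empty(geno.n_markers)
            pval = np.empty(geno.n_markers)
            r2 = np.empty(geno.n_markers)
            coll = np.zeros(geno.n_markers, dtype=bool)
            for j in range(geno.n_markers):
                xj = np.column_stack([x0_rot, m_rot[j]])
                delta = reml_delta(s, xj, y_rot)
                w = np.sqrt(1.0 / (s + delta))
                b, p_, r_, c_ = _weighted_scan(
                    (m_rot[j] * w)[None, :], x0_rot * w[:, None], y_rot * w)
                beta[j], pval[j], r2[j], coll[j] = b[0], p_[0], r_[0], c_[0]
        frames.append(pd.DataFrame({
            "marker_id": geno.marker_ids,
            "eigenvector": col,
            "beta": beta,
            "p_value": np.maximum(pval, np.finfo(float).tiny),
            "r2_explained": r2,
            "collinear": coll,
        }))
    out = pd.concat(frames, ignore_index=True)
    out["neg_log10_p"] = -np.log10(out["p_value"])
    out.attrs["pcs_used"] = pcs_used
    if gmap is not None:
        pos = gmap.table.set_index("marker_id")
        out["chromosome"] = out["marker_id"].map(pos["chromosome"])
        out["position_cM"] = out["marker_id"].map(pos["position_cM"])
    else:
        out["chromosome"] = np.nan
        out["position_cM"] = np.nan
    return out[MTA_COLUMNS]


@dataclass
class SignificanceThresholds:
    moderate_neg_log10: float
    fdr_alpha: float
    fdr_neg_log10: float   # +inf when nothing passes BH
    n_moderate: int
    n_fdr: int


def derive_thresholds(
    scan: pd.DataFrame,
    fdr_alpha: float = DEFAULT_FDR_ALPHA,
    moderate_neg_log10: float = MODERATE_NEG_LOG10,
) -> SignificanceThresholds:
    """Benjamini–Hochberg over the pooled p-values of all marker ×
    eigenvector tests; the FDR line is −log₁₀ of the largest rejected p."""
    pvals = scan["p_value"].to_numpy(dtype=float)
    if len(pvals) == 0:
        raise ValueError("no p-values")
    reject, _, _, _ = multipletests(pvals, alpha=fdr_alpha, method="fdr_bh")
    if reject.any():
        fdr_line = float(-np.log10(pvals[reject].max()))
    else:
        fdr_line = float("inf")
    if np.isfinite(fdr_line) and fdr_line < moderate_neg_log10:
        warnings.warn("FDR line fell below the moderate threshold")
    return SignificanceThresholds(
        moderate_neg_log10=moderate_neg_log10,
        fdr_alpha=fdr_alpha,
        fdr_neg_log10=fdr_line,
        n_moderate=int((scan["neg_log10_p"] > moderate_neg_log10).sum()),
        n_fdr=int(reject.sum()),
    )


def significant_mtas(scan: pd.DataFrame,
                     threshold_neg_log10: float = MODERATE_NEG_LOG10) -> pd.DataFrame:
    """MTA records above a −log₁₀p threshold (strict)."""
    return scan[scan["neg_log10_p"] > threshold_neg_log10].reset_index(drop=True)
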