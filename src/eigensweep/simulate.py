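"""Structured-panel simulation with known truth.

Neutral markers follow the Balding–Nichols model: an ancestral allele
frequency p ~ U(0.05, 0.95) per marker, and each subpopulation's frequency
drawn from Beta(p(1−F)/F, (1−p)(1−F)/F) around it, so F controls
drift/divergence. Planted sweep loci are generated in small clustered
regions of linked divergent markers (a swept haplotype carries several
markers within the local LD span), with a fixed frequency separation of at
least ``sweep_delta`` between a landrace-like block of subpopulations and a
modern-like block. Admixed samples mix two random subpopulations 50/50
marker-wise. Missingness is MCAR on a subset of markers; duplicate markers
are exact copies with an id suffix; an optional heading-date covariate is a
linear function of one designated marker plus noise.

Neutral markers are unlinked. Linkage-disequilibrium tests use the separate
:func:`simulate_ld_panel`, a haplotype-copying emitter with a planted
exponential correlation decay along one chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .containers import (MISSING, WHEAT_CHROMOSOMES, GenotypeMatrix,
                         GeneticMap, SampleMetadata)

DEFAULT_CHROM_LENGTH = 152.0


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic panel.

    Defaults emulate a five-subpopulation durum-wheat panel of ~400
    genotypes (including an admixed fraction) at a desk-scale marker count;
    chromosome count and total map length follow a 14-chromosome A/B-genome
    map of ≈2128 cM.
    """

    n_subpops: int = 5
    samples_per_subpop: tuple[int, ...] = (70, 70, 70, 70, 70)
    n_admixed: int = 50
    n_markers: int = 5000
    chromosomes: dict = field(
        default_factory=lambda: {c: DEFAULT_CHROM_LENGTH for c in WHEAT_CHROMOSOMES})
    divergence_F: float | tuple[float, ...] = 0.05
    n_sweeps: int = 20
    sweep_cluster_size: int = 4
    sweep_region_span_cM: float = 1.0
    sweep_delta: float = 0.7
    n_landrace_subpops: int = 3   # subpops 1..k form the landrace-like block
    missing_rate: float = 0.10
    missing_marker_fraction: float = 0.30
    duplicate_fraction: float = 0.01
    unmapped_fraction: float = 0.02
    snp_fraction: float = 0.25
    with_covariate: bool = True
    seed: int = 0

    def validate(self) -> None:
        if len(self.samples_per_subpop) != self.n_subpops:
            raise ValueError("samples_per_subpop length must equal n_subpops")
        if not 0 < self.sweep_delta < 0.96:
            raise ValueError("sweep_delta must be in (0, 0.96): frequencies are "
                             "bounded away from fixation")
        if not 0 <= self.missing_rate <= 0.30:
            raise ValueError("missing_rate must be in [0, 0.3]")
        if self.n_sweeps > self.n_markers // 10:
            raise ValueError("too many sweep loci for the marker count")
        if not 1 <= self.n_landrace_subpops < self.n_subpops:
            raise ValueError("landrace block must be a proper non-empty subset")

    def f_values(self) -> np.ndarray:
        f = self.divergence_F
        if np.isscalar(f):
            return np.full(self.n_subpops, float(f))
        f = np.asarray(f, dtype=float)
        if len(f) != self.n_subpops:
            raise ValueError("divergence_F length must equal n_subpops")
        return f


@dataclass
class SimulationTruth:
    subpop_of_sample: pd.Series        # sample_id → SP label / 'admixed'
    ancestral_freq: pd.Series          # marker_id → p
    subpop_freq: pd.DataFrame          # marker_id × SP label
    sweep_marker_ids: list
    sweep_regions: pd.DataFrame        # region, chromosome, center_cM, marker ids
    duplicate_pairs: list              # (original, copy)
    covariate_marker: str | None
    sweep_positions: pd.DataFrame      # marker_id, chromosome, position_cM


def simulate_panel(config: SimulationConfig
                   ) -> tuple[GenotypeMatrix, GeneticMap, SampleMetadata, SimulationTruth]:
    """Generate the panel; bit-reproducible for a fixed config seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_sp = config.n_subpops
    sp_labels = [f"SP{i + 1}" for i in range(n_sp)]
    m = config.n_markers

    # --- map ---------------------------------------------------------------
    marker_ids = np.array([f"mk{i:06d}" for i in range(m)], dtype=object)
    chrom_names = list(config.chromosomes)
    chrom_len = np.array([config.chromosomes[c] for c in chrom_names])
    chrom_idx = rng.integers(0, len(chrom_names), size=m)
    pos = rng.uniform(0, chrom_len[chrom_idx])

    # --- sweep regions: clustered divergent loci ---------------------------
    n_regions = int(np.ceil(config.n_sweeps / config.sweep_cluster_size))
    sweep_idx = rng.choice(m, size=config.n_sweeps, replace=False)
    region_rows = []
    for r in range(n_regions):
        members = sweep_idx[r * config.sweep_cluster_size:(r + 1) * config.sweep_cluster_size]
        ci = rng.integers(0, len(chrom_names))
        span = config.sweep_region_span_cM
        center = rng.uniform(span, chrom_len[ci] - span)
        chrom_idx[members] = ci
        pos[members] = center + rng.uniform(-span / 2, span / 2, size=len(members))
        region_rows.append({"region": r, "chromosome": chrom_names[ci],
                            "center_cM": center,
                            "marker_ids": list(marker_ids[members])})

    # --- subpopulation frequencies -----------------------------------------
    p_anc = rng.uniform(0.05, 0.95, size=m)
    fv = config.f_values()
    freqs = np.empty((m, n_sp))
    for k in range(n_sp):
        f = fv[k]
        a = p_anc * (1 - f) / f
        b = (1 - p_anc) * (1 - f) / f
        freqs[:, k] = rng.beta(a, b)
    # sweep loci: fixed block separation ≥ sweep_delta
    land = np.arange(config.n_landrace_subpops)
    modern = np.arange(config.n_landrace_subpops, n_sp)
    for row in region_rows:
        idx = [int(np.flatnonzero(marker_ids == mid)[0]) for mid in row["marker_ids"]]
        p_low = rng.uniform(0.02, 0.98 - config.sweep_delta)
        p_high = p_low + config.sweep_delta
        if rng.random() < 0.5:
            p_low, p_high = p_high, p_low
        freqs[np.ix_(idx, land)] = p_low
        freqs[np.ix_(idx, modern)] = p_high

    # --- samples ------------------------------------------------------------
    sp_of = []
    for k, n_k in enumerate(config.samples_per_subpop):
        sp_of += [sp_labels[k]] * n_k
    sp_of += ["admixed"] * config.n_admixed
    n = len(sp_of)
    sample_ids = np.array([f"G{i + 1:04d}" for i in range(n)], dtype=object)

    calls = np.empty((m, n), dtype=np.int8)
    col = 0
    for k, n_k in enumerate(config.samples_per_subpop):
        calls[:, col:col + n_k] = (
            rng.random((m, n_k)) < freqs[:, [k]]).astype(np.int8)
        col += n_k
    era = ["landrace" if sp_labels.index(s) < config.n_landrace_subpops else "modern"
           for s in sp_of[:col]]
    for _ in range(config.n_admixed):
        pa, pb = rng.choice(n_sp, size=2, replace=False)
        pick = rng.random(m) < 0.5
        fmix = np.where(pick, freqs[:, pa], freqs[:, pb])
        calls[:, col] = (rng.random(m) < fmix).astype(np.int8)
        era.append("landrace" if pa < config.n_landrace_subpops else "modern")
        col += 1

    # --- missingness (MCAR on a marker subset) ------------------------------
    if config.missing_rate > 0 and config.missing_marker_fraction > 0:
        n_miss = int(round(config.missing_marker_fraction * m))
        miss_rows = rng.choice(m, size=n_miss, replace=False)
        mask = rng.random((n_miss, n)) < config.missing_rate
        calls[miss_rows] = np.where(mask, MISSING, calls[miss_rows])

    # --- marker types / allele labels ---------------------------------------
    is_snp = rng.random(m) < config.snp_fraction
    marker_type = np.where(is_snp, "SNP", "PAV").astype(object)
    bases = np.array(list("ACGT"))
    labels = []
    for i in range(m):
        if is_snp[i]:
            b = rng.choice(4, size=2, replace=False)
            labels.append((str(bases[b[0]]), str(bases[b[1]])))
        else:
            labels.append(("0", "1"))

    # --- duplicates: exact copies, typed PAV so the QC drop rule acts -------
    n_dup = int(round(config.duplicate_fraction * m))
    dup_pairs = []
    if n_dup:
        originals = rng.choice(np.setdiff1d(np.arange(m), sweep_idx),
                               size=n_dup, replace=False)
        dup_ids = np.array([f"{marker_ids[i]}_dup" for i in originals], dtype=object)
        calls = np.vstack([calls, calls[originals]])
        marker_ids = np.concatenate([marker_ids, dup_ids])
        marker_type = np.concatenate([marker_type, np.array(["PAV"] * n_dup, dtype=object)])
        labels += [("0", "1")] * n_dup
        chrom_idx = np.concatenate([chrom_idx, chrom_idx[originals]])
        pos = np.concatenate([pos, pos[originals]])
        dup_pairs = [(str(marker_ids[i]), str(d)) for i, d in zip(originals, dup_ids)]

    geno = GenotypeMatrix(marker_ids, sample_ids, calls, marker_type, labels)

    # --- map table (a fraction of markers stays unmapped) -------------------
    mapped = np.ones(len(marker_ids), dtype=bool)
    if config.unmapped_fraction > 0:
        n_unm = int(round(config.unmapped_fraction * len(marker_ids)))
        unm = rng.choice(np.setdiff1d(np.arange(len(marker_ids)), sweep_idx),
                         size=n_unm, replace=False)
        mapped[unm] = False
    gmap = GeneticMap(pd.DataFrame({
        "marker_id": marker_ids[mapped],
        "chromosome": [chrom_names[c] for c in chrom_idx[mapped]],
        "position_cM": pos[mapped],
    }), chromosomes=tuple(chrom_names))

    # --- metadata ------------------------------------------------------------
    origins = rng.choice(["east_med", "north_med", "west_med", "breeding_intl",
                          "north_america"], size=n)
    meta = pd.DataFrame({
        "sample_id": sample_ids,
        "era": era,
        "origin": origins,
        "subpopulation": sp_of,
    })
    cov_marker = None
    if config.with_covariate:
        ci = int(rng.choice(np.setdiff1d(np.arange(m), sweep_idx)))
        cov_marker = str(geno.marker_ids[ci])
        x = geno.calls[ci].astype(float)
        x[x == MISSING] = np.nanmean(np.where(x == MISSING, np.nan, x))
        meta["heading_date"] = 45.0 + 8.0 * x + rng.normal(0, 2.0, size=n)
    metadata = SampleMetadata(meta)

    truth = SimulationTruth(
        subpop_of_sample=pd.Series(sp_of, index=sample_ids),
        ancestral_freq=pd.Series(p_anc, index=marker_ids[:m]),
        subpop_freq=pd.DataFrame(freqs, index=marker_ids[:m], columns=sp_labels),
        sweep_marker_ids=[str(x) for x in marker_ids[sweep_idx]],
        sweep_regions=pd.DataFrame(region_rows),
        duplicate_pairs=dup_pairs,
        covariate_marker=cov_marker,
        sweep_positions=pd.DataFrame({
            "marker_id": marker_ids[sweep_idx],
            "chromosome": [chrom_names[c] for c in chrom_idx[sweep_idx]],
            "position_cM": pos[sweep_idx],
        }),
    )
    return geno, gmap, metadata, truth


def expected_gst(truth: SimulationTruth, neutral_only: bool = False) -> float:
    """G_ST implied by the generating subpopulation frequencies (the
    parametric truth the estimator is compared against)."""
    f = truth.subpop_freq
    if neutral_only:
        f = f.drop(index=truth.sweep_marker_ids)
    p = f.to_numpy()
    pbar = p.mean(axis=1)
    ht = (1 - pbar**2 - (1 - pbar) ** 2).mean()
    hs = (1 - p**2 - (1 - p) ** 2).mean()
    return float((ht - hs) / ht)


def simulate_ld_panel(
    n_samples: int = 150,
    n_markers: int = 200,
    chrom_length_cM: float = 40.0,
    tau_cM: float = 2.0,
    chromosome: str = "1A",
    seed: int = 0,
) -> tuple[GenotypeMatrix, GeneticMap]:
    """One-chromosome panel with planted exponential LD decay.

    Haplotype-copying emitter: along the sorted map, each sample copies its
    previous allele with probability exp(−d/τ) (d = inter-marker distance)
    and otherwise redraws from the chromosome-wide frequency, giving
    corr(x_i, x_j) = exp(−|cM_i − cM_j|/τ) and hence E[r²] ≈ exp(−2d/τ).
    """
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.uniform(0, chrom_length_cM, size=n_markers))
    p = rng.uniform(0.3, 0.7)
    calls = np.empty((n_markers, n_samples), dtype=np.int8)
    calls[0] = rng.random(n_samples) < p
    for j in range(1, n_markers):
        keep = rng.random(n_samples) < np.exp(-(pos[j] - pos[j - 1]) / tau_cM)
        fresh = (rng.random(n_samples) < p).astype(np.int8)
        calls[j] = np.where(keep, calls[j - 1], fresh)
    ids = np.array([f"ld{j:05d}" for j in range(n_markers)], dtype=object)
    geno = GenotypeMatrix(ids, np.array([f"S{i:04d}" for i in range(n_samples)], dtype=object),
                          calls, np.array(["PAV"] * n_markers, dtype=object))
    gmap = GeneticMap(pd.DataFrame({
        "marker_id": ids, "chromosome": chromosome, "position_cM": pos}))
    return geno, gmap


def theoretical_ld_decay(distances: np.ndarray, tau_cM: float, n_samples: int) -> float:
    """Planted decay distance for the copying emitter: where the noiseless
    expected-r² curve crosses its own mean over the realized pair distances.

    E[r²](d) ≈ ρ² + (1 − ρ²)²/n with ρ = exp(−d/τ) (the 1/n term is the
    finite-sample bias of squared correlation under near-independence).
    """
    d = np.asarray(distances, dtype=float)

    def curve(x: float) -> float:
        rho2 = np.exp(-2.0 * x / tau_cM)
        return rho2 + (1.0 - rho2) ** 2 / n_samples

    mean = float(np.mean(curve(d)))
    lo, hi = 0.0, float(d.max())
    if curve(lo) <= mean:
        return 0.0
    return float(optimize.brentq(lambda x: curve(x) - mean, lo, hi))


def truth_report(
    truth: SimulationTruth,
    hotspots: list,
    gst_estimate: float | None = None,
    duplicates_found: pd.DataFrame | None = None,
) -> dict:
    """Recovery metrics of a pipeline run against the generating truth.

    Sensitivity is the fraction of planted sweep markers lying inside any
    hotspot confidence interval on their chromosome; the false-hotspot rate
    is the fraction of hotspots containing no planted sweep.
    """
    sp = truth.sweep_positions
    n_sweeps = len(sp)
    inside = np.zeros(n_sweeps, dtype=bool)
    hot_has_sweep = np.zeros(len(hotspots), dtype=bool)
    for hi, h in enumerate(hotspots):
        on = (sp["chromosome"].to_numpy() == h.chromosome)
        in_ci = on & (sp["position_cM"].to_numpy() >= h.ci_left_cM) \
                   & (sp["position_cM"].to_numpy() <= h.ci_right_cM)
        inside |= in_ci
        hot_has_sweep[hi] = in_ci.any()
    out = {
        "n_planted_sweeps": n_sweeps,
        "sensitivity": float(inside.mean()) if n_sweeps else float("nan"),
        "sensitivity_defined": n_sweeps > 0,
        "n_hotspots": len(hotspots),
        "false_hotspot_rate": (float((~hot_has_sweep).mean()) if len(hotspots)
                               else float("nan")),
    }
    if gst_estimate is not None:
        out["gst_true"] = expected_gst(truth)
        out["gst_error"] = abs(gst_estimate - out["gst_true"])
    if duplicates_found is not None:
        planted = {frozenset(p) for p in truth.duplicate_pairs}
        found = {frozenset((a, b)) for a, b in
                 zip(duplicates_found["marker_a"], duplicates_found["marker_b"])}
        out["duplicate_recovery"] = (len(planted & found) / len(planted)
                                     if planted else float("nan"))
    return out
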