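"""Configuration-driven orchestration of the full scan.

Stage order: qc → diversity → ld → ordination → gwas → hotspots → sweeps.
Every stage writes its table(s) under the output directory and records a
SHA-256 of each file in ``manifest.json`` together with the normalized
configuration, so a run is reproducible from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import click
import numpy as np
import pandas as pd
import yaml

from . import diversity as div
from . import gwas, hotspots as hs, io, ld, ordination as ordn, sweeps
from . import qc as qc_mod
from .containers import GenotypeMatrix, GeneticMap, SampleMetadata
from .simulate import SimulationConfig, simulate_panel, truth_report

logger = logging.getLogger(__name__)

STAGES = ("qc", "diversity", "ld", "ordination", "gwas", "hotspots", "sweeps")


@dataclass
class PipelineConfig:
    """All tunables, defaulting to the study settings: MAF ≥ 5%, SNP
    missingness ≤ 30%, 50 cM LD window with p < 0.001, ten eigenvector
    phenotypes, six fixed-effect PCs, moderate line at −log₁₀p = 3, BH FDR
    at α = 0.05, top-marker cut at −log₁₀p = 5, allele rule at 80%."""

    geno_path: str | None = None
    map_path: str | None = None
    meta_path: str | None = None
    simulate: SimulationConfig | None = None
    maf_min: float = 0.05
    snp_missing_max: float = 0.30
    ld_window_cM: float = 50.0
    ld_p_cut: float = 1e-3
    n_eigen_phenotypes: int = 10
    n_pcs: int = 6
    moderate_neg_log10: float = 3.0
    fdr_alpha: float = 0.05
    top_marker_neg_log10: float = 5.0
    allele_threshold: float = 0.80
    decay_override_cM: float | None = None
    covariate: str | None = None
    seed: int = 0

    _RANGES = {
        "maf_min": (0.0, 0.5), "snp_missing_max": (0.0, 1.0),
        "ld_window_cM": (0.1, 1e4), "ld_p_cut": (0.0, 1.0),
        "fdr_alpha": (0.0, 1.0), "allele_threshold": (0.5, 1.0),
    }

    def validate(self) -> "PipelineConfig":
        for name, (lo, hi) in self._RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                default = dataclasses.fields(PipelineConfig)
                dflt = next(f.default for f in default if f.name == name)
                raise ValueError(
                    f"{name}={v} outside [{lo}, {hi}] (study default: {dflt})")
        if self.simulate is None and self.geno_path is None:
            raise ValueError("config needs either input paths or a simulate block")
        if self.decay_override_cM is not None and self.decay_override_cM <= 0:
            raise ValueError("decay_override_cM must be positive")
        return self


def validate_config(raw: dict | None) -> PipelineConfig:
    """Normalize a plain dict (e.g. parsed YAML) into a validated config;
    an empty dict yields the full default configuration with a default
    simulation block."""
    raw = dict(raw or {})
    sim = raw.pop("simulate", None)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config field(s): {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    if sim is not None:
        cfg.simulate = sim if isinstance(sim, SimulationConfig) else SimulationConfig(**sim)
    elif cfg.geno_path is None:
        cfg.simulate = SimulationConfig(seed=cfg.seed)
    if cfg.simulate is not None:
        cfg.simulate.validate()
    return cfg.validate()


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    if cfg.simulate is not None:
        d["simulate"] = dataclasses.asdict(cfg.simulate)
    return d


def run_pipeline(
    config: PipelineConfig,
    out_dir: str,
    stop_after: str | None = None,
) -> dict:
    """Run the stages in order, writing every table plus a manifest.

    Returns the in-memory results keyed by stage. Any stage error aborts
    with the stage name attached.
    """
    config.validate()
    os.makedirs(out_dir, exist_ok=True)
    manifest: dict = {"config": _config_dict(config), "files": {}, "numbers": {}}
    results: dict = {}

    def emit(name: str, table: pd.DataFrame, allow_empty: bool = False) -> None:
        path = os.path.join(out_dir, f"{name}.tsv")
        io.write_table(table, path, allow_empty=allow_empty)
        manifest["files"][f"{name}.tsv"] = _sha256(path)

    # --- inputs --------------------------------------------------------------
    truth = None
    if config.simulate is not None:
        geno, gmap, meta, truth = simulate_panel(config.simulate)
    else:
        geno, gmap, meta = io.read_genotypes(config.geno_path, config.map_path,
                                             config.meta_path)
    io.write_genotypes(geno, os.path.join(out_dir, "genotypes.tsv"))
    io.write_map(gmap, os.path.join(out_dir, "map.tsv"))
    io.write_metadata(meta, os.path.join(out_dir, "metadata.tsv"))
    for f in ("genotypes.tsv", "map.tsv", "metadata.tsv"):
        manifest["files"][f] = _sha256(os.path.join(out_dir, f))
    results.update(geno=geno, gmap=gmap, meta=meta, truth=truth)

    def stage_done(name: str) -> bool:
        if stop_after is not None and STAGES.index(stop_after) <= STAGES.index(name):
            _write_manifest(out_dir, manifest)
            return True
        return False

    try:
        # --- qc ---------------------------------------------------------------
        stage = "qc"
        filtered, report = qc_mod.filter_chain(
            geno, gmap, maf_min=config.maf_min, missing_max=config.snp_missing_max)
        emit("qc_report", report.stages)
        emit("qc_per_marker", report.per_marker)
        results["filtered"], results["qc_report"] = filtered, report
        manifest["numbers"]["markers_after_qc"] = filtered.n_markers
        if stage_done("qc"):
            return results

        # --- diversity ----------------------------------------------------------
        stage = "diversity"
        dtab = div.diversity_table(filtered, meta)
        emit("diversity_table", dtab)
        results["diversity_table"] = dtab
        manifest["numbers"]["GST_total"] = float(dtab.iloc[0]["GST"])
        if stage_done("diversity"):
            return results

        # --- ld -------------------------------------------------------------------
        stage = "ld"
        pairs, n_skipped = ld.pairwise_r2(filtered, gmap, window_cM=config.ld_window_cM)
        models, decay_tab = ld.decay_by_genome(pairs, p_cut=config.ld_p_cut)
        emit("ld_decay", decay_tab)
        decay = (config.decay_override_cM if config.decay_override_cM is not None
                 else ld.hotspot_window(models))
        results.update(ld_pairs=pairs, ld_models=models, decay_cM=decay)
        manifest["numbers"].update(ld_pairs=len(pairs), ld_pairs_skipped=n_skipped,
                                   decay_cM=decay,
                                   decay_overridden=config.decay_override_cM is not None)
        if stage_done("ld"):
            return results

        # --- ordination -------------------------------------------------------------
        stage = "ordination"
        dist = ordn.simple_matching_distance(filtered)
        pc = ordn.orient_axes(ordn.pcoa(dist, k_axes=config.n_eigen_phenotypes), meta)
        phen = ordn.eigen_phenotypes(pc, top_k=config.n_eigen_phenotypes)
        coords = pd.DataFrame(pc.coordinates, index=pc.sample_ids,
                              columns=[f"axis{k + 1}" for k in range(pc.n_axes)])
        emit("pcoa_coordinates", coords.reset_index(names="sample_id"))
        emit("eigenvalues", pd.DataFrame({
            "axis": np.arange(1, pc.n_axes + 1),
            "eigenvalue": pc.eigenvalues[:pc.n_axes],
            "pct_variance": pc.pct_variance}))
        emit("eigen_phenotypes", phen.reset_index(names="sample_id"))
        results.update(distance=dist, pcoa=pc, phenotypes=phen)
        if stage_done("ordination"):
            return results

        # --- gwas ---------------------------------------------------------------------
        stage = "gwas"
        kin = gwas.kinship(filtered)
        cov = meta.covariate(config.covariate) if config.covariate else None
        scan = gwas.mlm_scan(filtered, phen, kin, gmap=gmap, n_pcs=config.n_pcs,
                             covariates=cov)
        thr = gwas.derive_thresholds(scan, fdr_alpha=config.fdr_alpha,
                                     moderate_neg_log10=config.moderate_neg_log10)
        mtas = gwas.significant_mtas(scan, config.moderate_neg_log10)
        emit("mta_table", mtas, allow_empty=True)
        emit("manhattan", scan[["marker_id", "chromosome", "position_cM",
                                "eigenvector", "neg_log10_p"]])
        emit("thresholds", pd.DataFrame([dataclasses.asdict(thr)]))
        results.update(kinship=kin, scan=scan, thresholds=thr, mtas=mtas)
        manifest["numbers"].update(n_mtas_moderate=len(mtas), n_fdr=thr.n_fdr,
                                   fdr_neg_log10=thr.fdr_neg_log10)
        if stage_done("gwas"):
            return results

        # --- hotspots --------------------------------------------------------------------
        stage = "hotspots"
        hot, singles = hs.cluster_mtas(mtas, decay_cM=decay,
                                       fdr_neg_log10=thr.fdr_neg_log10)
        emit("hotspot_table", hs.hotspot_table(hot), allow_empty=True)
        summary = hs.hotspot_summary(hot, singles)
        results.update(hotspots=hot, singletons=singles, hotspot_summary=summary)
        manifest["numbers"].update(
            {k: v for k, v in summary.items() if not isinstance(v, dict)})
        if stage_done("hotspots"):
            return results

        # --- sweeps -----------------------------------------------------------------------
        stage = "sweeps"
        top = sweeps.select_top_markers(mtas, config.top_marker_neg_log10, hot)
        geno_sel = filtered.subset_markers(top["marker_id"].to_numpy())
        split = sweeps.split_groups(geno_sel, meta)
        pos = gmap.table.set_index("marker_id")["position_cM"]
        table = sweeps.allele_rule(
            filtered, split, top["marker_id"].to_numpy(),
            threshold=config.allele_threshold, positions=pos,
            hotspot_of=dict(zip(top["marker_id"], top["hotspot_id"])))
        emit("sweep_table", table, allow_empty=True)
        emit("group_composition", split.composition)
        results.update(top_markers=top, split=split, sweep_table=table)
        manifest["numbers"].update(n_top_markers=len(top),
                                   n_sweep_markers=int(table["passes_rule"].sum()))

        if truth is not None:
            rec = truth_report(truth, hot, gst_estimate=float(dtab.iloc[0]["GST"]))
            manifest["numbers"]["recovery"] = {
                k: v for k, v in rec.items() if not isinstance(v, dict)}
            results["recovery"] = rec
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    _write_manifest(out_dir, manifest)
    return results


def _write_manifest(out_dir: str, manifest: dict) -> None:
    path = os.path.join(out_dir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str, sort_keys=True)


# --------------------------------------------------------------------------- CLI

def _load_config(path: str | None) -> PipelineConfig:
    raw = {}
    if path:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


@click.group()
@click.option("-v", "--verbose", is_flag=True)
def cli(verbose: bool) -> None:
    """Selective-sweep labelling pipeline for structured inbred panels."""
    logging.basicConfig(level=logging.DEBUG if verbose else logging.INFO,
                        format="%(levelname)s %(name)s: %(message)s")


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--out", "out_dir", required=True, type=click.Path())
def run(config_path: str | None, out_dir: str) -> None:
    """Run the full analysis into OUT."""
    res = run_pipeline(_load_config(config_path), out_dir)
    summ = res.get("hotspot_summary", {})
    click.echo(f"hotspots: {summ.get('n_hotspots')} | "
               f"MTAs clustered: {summ.get('n_mtas_in_hotspots')} | "
               f"sweep markers: {int(res['sweep_table']['passes_rule'].sum())}")


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--out", "out_dir", required=True, type=click.Path())
def simulate(config_path: str | None, out_dir: str) -> None:
    """Write a synthetic panel (genotypes/map/metadata TSVs + truth JSON)."""
    cfg = _load_config(config_path)
    geno, gmap, meta, truth = simulate_panel(cfg.simulate or SimulationConfig(seed=cfg.seed))
    os.makedirs(out_dir, exist_ok=True)
    io.write_genotypes(geno, os.path.join(out_dir, "genotypes.tsv"))
    io.write_map(gmap, os.path.join(out_dir, "map.tsv"))
    io.write_metadata(meta, os.path.join(out_dir, "metadata.tsv"))
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump({
            "sweep_marker_ids": truth.sweep_marker_ids,
            "duplicate_pairs": truth.duplicate_pairs,
            "covariate_marker": truth.covariate_marker,
            "subpop_of_sample": truth.subpop_of_sample.to_dict(),
        }, fh, indent=2)
    click.echo(f"panel written to {out_dir}")


@cli.command()
@click.argument("name", type=click.Choice(STAGES))
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--out", "out_dir", required=True, type=click.Path())
def stage(name: str, config_path: str | None, out_dir: str) -> None:
    """Run the pipeline up to and including stage NAME."""
    run_pipeline(_load_config(config_path), out_dir, stop_after=name)
    click.echo(f"stopped after stage {name}")
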