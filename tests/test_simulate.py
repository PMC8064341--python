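import numpy as np
import pandas as pd
import pytest

from eigensweep.simulate import (
    SimulationConfig, expected_gst, simulate_ld_panel, simulate_panel,
    theoretical_ld_decay, truth_report,
)
from conftest import SMALL_CONFIG


def test_panel_is_deterministic():
    a = simulate_panel(SMALL_CONFIG)
    b = simulate_panel(SMALL_CONFIG)
    assert a[0].equals(b[0])
    pd.testing.assert_frame_equal(a[1].table, b[1].table)
    pd.testing.assert_frame_equal(a[2].table, b[2].table)


def test_different_seed_differs():
    import dataclasses
    other = dataclasses.replace(SMALL_CONFIG, seed=SMALL_CONFIG.seed + 1)
    a = simulate_panel(SMALL_CONFIG)[0]
    b = simulate_panel(other)[0]
    assert not a.equals(b)


def test_panel_shapes_and_bookkeeping(small_panel):
    geno, gmap, meta, truth = small_panel
    cfg = SMALL_CONFIG
    n_dup = int(round(cfg.duplicate_fraction * cfg.n_markers))
    assert geno.n_samples == sum(cfg.samples_per_subpop) + cfg.n_admixed
    assert geno.n_markers == cfg.n_markers + n_dup
    assert len(truth.duplicate_pairs) == n_dup
    assert all(c.endswith("_dup") for _, c in truth.duplicate_pairs)
    n_unmapped = int((~gmap.mapped_mask(geno.marker_ids)).sum())
    # duplicates of unmapped originals are also unmapped
    assert n_unmapped >= int(round(cfg.unmapped_fraction * cfg.n_markers))
    assert len(truth.sweep_marker_ids) == cfg.n_sweeps
    assert set(meta.table["era"]) == {"landrace", "modern"}


def test_duplicates_copy_calls(small_panel):
    geno, _, _, truth = small_panel
    idx = geno.marker_index()
    for orig, copy in truth.duplicate_pairs:
        assert np.array_equal(geno.calls[idx[orig]], geno.calls[idx[copy]])


def test_sweep_regions_are_tight(small_panel):
    _, _, _, truth = small_panel
    pos = truth.sweep_positions.set_index("marker_id")
    for _, region in truth.sweep_regions.iterrows():
        members = pos.loc[region["marker_ids"]]
        span = members["position_cM"].max() - members["position_cM"].min()
        assert span <= SMALL_CONFIG.sweep_region_span_cM + 1e-9
        assert members["chromosome"].nunique() == 1
        assert set(members["chromosome"]) == {region["chromosome"]}


def test_sweep_block_separation(small_panel):
    _, _, _, truth = small_panel
    f = truth.subpop_freq.loc[truth.sweep_marker_ids]
    k = SMALL_CONFIG.n_landrace_subpops
    landrace = f.iloc[:, :k].mean(axis=1)
    modern = f.iloc[:, k:].mean(axis=1)
    assert np.allclose(np.abs(landrace - modern), SMALL_CONFIG.sweep_delta, atol=1e-9)


def test_expected_gst_monotone_in_F():
    vals = []
    for f in (0.02, 0.05, 0.10, 0.20):
        cfg = SimulationConfig(n_markers=400, samples_per_subpop=(10,) * 5,
                               n_admixed=0, n_sweeps=4, divergence_F=f, seed=5)
        truth = simulate_panel(cfg)[3]
        vals.append(expected_gst(truth, neutral_only=True))
    assert all(a < b for a, b in zip(vals, vals[1:]))


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(sweep_delta=0.99).validate()
    with pytest.raises(ValueError):
        SimulationConfig(missing_rate=0.5).validate()


def test_ld_panel_determinism_and_decay_direction():
    a, _ = simulate_ld_panel(seed=2)
    b, _ = simulate_ld_panel(seed=2)
    assert a.equals(b)
    d1 = theoretical_ld_decay(np.linspace(0.01, 40, 500), tau_cM=1.0, n_samples=150)
    d2 = theoretical_ld_decay(np.linspace(0.01, 40, 500), tau_cM=4.0, n_samples=150)
    assert 0 < d1 < d2


def test_truth_report_counts_sweeps_inside_cis(small_panel):
    from eigensweep.hotspots import QTLHotspot
    _, _, _, truth = small_panel
    sp = truth.sweep_positions.iloc[0]
    hot = QTLHotspot(hotspot_id="eigenQTLx.1", chromosome=sp["chromosome"],
                     ci_left_cM=sp["position_cM"] - 1, ci_right_cM=sp["position_cM"] + 1,
                     members=pd.DataFrame({"marker_id": ["x"]}))
    rep = truth_report(truth, [hot])
    assert rep["n_planted_sweeps"] == SMALL_CONFIG.n_sweeps
    assert rep["sensitivity"] >= 1 / SMALL_CONFIG.n_sweeps
    assert rep["false_hotspot_rate"] == 0.0
    empty = truth_report(truth, [])
    assert empty["sensitivity"] == 0.0
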