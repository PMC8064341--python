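import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eigensweep import ld
from eigensweep.containers import MISSING
from eigensweep.simulate import simulate_ld_panel
from conftest import make_geno, make_map


def _pair_panel(rows, positions, chrom="1A"):
    g = make_geno(rows)
    gmap = make_map(list(g.marker_ids), [chrom] * len(rows), positions)
    return g, gmap


def test_perfect_and_inverted_ld_give_r2_one():
    base = [0, 1] * 6
    inv = [1 - c for c in base]
    g, gmap = _pair_panel([base, base, inv], [0.0, 1.0, 2.0])
    pairs, _ = ld.pairwise_r2(g, gmap)
    assert np.allclose(pairs["r2"], 1.0)
    # χ² = n·r² with 1 df
    assert pairs["p_value"].iloc[0] == pytest.approx(stats.chi2.sf(12.0, 1))


def test_r2_matches_pearson_on_complete_data():
    rng = np.random.default_rng(0)
    a = rng.integers(0, 2, 50)
    b = rng.integers(0, 2, 50)
    g, gmap = _pair_panel([a, b], [0.0, 1.0])
    pairs, _ = ld.pairwise_r2(g, gmap)
    expected = stats.pearsonr(a, b).statistic ** 2
    assert pairs["r2"].iloc[0] == pytest.approx(expected, abs=1e-12)


def test_r2_uses_jointly_nonmissing_samples_only():
    # identical where both observed; disagreements hidden behind missing calls
    a = [0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1, MISSING, MISSING]
    b = [0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 1, 0]
    g, gmap = _pair_panel([a, b], [0.0, 1.0])
    pairs, _ = ld.pairwise_r2(g, gmap)
    assert pairs["r2"].iloc[0] == pytest.approx(1.0)
    assert pairs["n_joint"].iloc[0] == 12


def test_min_joint_pairs_are_skipped():
    a = [0, 1] * 3 + [MISSING] * 8
    b = [0, 1] * 3 + [0] * 8
    g, gmap = _pair_panel([a, b], [0.0, 1.0])
    pairs, n_skipped = ld.pairwise_r2(g, gmap, min_joint=10)
    assert len(pairs) == 0 and n_skipped == 1


def test_window_limits_pairs():
    rows = [[0, 1] * 6] * 3
    g, gmap = _pair_panel(rows, [0.0, 10.0, 100.0])
    pairs, _ = ld.pairwise_r2(g, gmap, window_cM=50.0)
    got = {tuple(sorted(p)) for p in zip(pairs["marker_a"], pairs["marker_b"])}
    assert got == {("m0", "m1")}  # 100−10 = 90 > 50 excluded


def test_cross_chromosome_pairs_never_formed():
    g = make_geno([[0, 1] * 6, [0, 1] * 6])
    gmap = make_map(["m0", "m1"], ["1A", "2A"], [0.0, 1.0])
    pairs, _ = ld.pairwise_r2(g, gmap)
    assert len(pairs) == 0   # identical calls, but on different chromosomes


def test_genome_pooling_labels():
    geno, gmap = simulate_ld_panel(n_samples=60, n_markers=60, seed=0,
                                   chromosome="3B")
    pairs, _ = ld.pairwise_r2(geno, gmap)
    assert set(pairs["genome"]) == {"B"}


def test_fit_decay_guards():
    few = pd.DataFrame({"distance_cM": [1.0] * 50, "r2": [0.5] * 50,
                        "p_value": [0.1] * 50})
    with pytest.raises(ValueError, match="≥100 pairs"):
        ld.fit_decay(few)
    same = pd.DataFrame({"distance_cM": [1.0] * 150, "r2": [0.5] * 150,
                         "p_value": [0.1] * 150})
    with pytest.raises(ValueError, match="identical"):
        ld.fit_decay(same)


def test_fit_decay_on_planted_panel():
    geno, gmap = simulate_ld_panel(seed=1)
    pairs, _ = ld.pairwise_r2(geno, gmap)
    model = ld.fit_decay(pairs, genome="A")
    assert not model.starts_below_mean
    assert model.fitted_r2[0] > model.mean_r2       # high LD at short range
    assert 0 < model.decay_cM < pairs["distance_cM"].max()
    # fitted curve at the decay point is at/below the mean
    k = int(np.argmin(np.abs(model.grid_cM - model.decay_cM)))
    assert model.fitted_r2[k] <= model.mean_r2 + 1e-9


def test_decay_by_genome_summary(small_panel):
    geno, gmap, _, _ = small_panel
    sub = geno.subset_markers(gmap.mapped_mask(geno.marker_ids))
    pairs, _ = ld.pairwise_r2(sub, gmap)
    models, tab = ld.decay_by_genome(pairs)
    assert set(tab["genome"]) == {"A", "B"}
    assert (tab["n_pairs"] > 0).all()
    assert set(models) == {"A", "B"}


def test_hotspot_window_rounding():
    class M:
        def __init__(self, d):
            self.decay_cM = d
    assert ld.hotspot_window({"A": M(1.44), "B": M(0.2)}) == 1.5
    assert ld.hotspot_window({"A": M(0.01)}) == 0.5   # floor at one granule
    assert ld.hotspot_window({"A": M(2.0)}) == 2.0    # exact multiple unchanged
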