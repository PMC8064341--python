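"""Property-based invariants (hypothesis) for the numerical primitives."""

import numpy as np
import pandas as pd
from hypothesis import given, settings, strategies as st

from eigensweep import accounting, diversity as div, hotspots as hs, ld, qc, sweeps
from conftest import make_geno, make_map

settings.register_profile("suite", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("suite")

freq = st.floats(0.01, 0.99, allow_nan=False)


@given(st.lists(st.floats(0.001, 0.999), min_size=2, max_size=10, unique=True))
def test_nm_strictly_decreasing_in_gst(gsts):
    gsts = sorted(gsts)
    nms = [div.nm_from_gst(g) for g in gsts]
    assert all(a > b for a, b in zip(nms, nms[1:]))


@given(st.integers(2, 5), st.integers(1, 30), st.integers(0, 10_000))
def test_ht_identity_on_random_frequency_groups(n_groups, n_loci, seed):
    rng = np.random.default_rng(seed)
    # build a panel whose groups are large enough that freqs vary
    calls = (rng.random((n_loci, n_groups * 6)) < rng.uniform(0.1, 0.9, (n_loci, 1))
             ).astype(np.int8)
    g = make_geno(calls)
    groups = {f"G{k}": np.arange(k * 6, (k + 1) * 6) for k in range(n_groups)}
    row = div.diversity_decomposition(g, groups)
    assert abs(row["HT"] - (row["HS"] + row["DST"])) < 1e-12
    assert row["HS"] <= row["HT"] + 1e-12       # pooling never reduces diversity


@given(st.integers(0, 10_000))
def test_r2_invariant_under_allele_relabel(seed):
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 2, 40, dtype=np.int8)
    b = rng.integers(0, 2, 40, dtype=np.int8)
    g1 = make_geno([a, b])
    g2 = make_geno([1 - a, b])    # swap the coding of one marker
    gmap = make_map(["m0", "m1"], ["1A", "1A"], [0.0, 1.0])
    p1, _ = ld.pairwise_r2(g1, gmap)
    p2, _ = ld.pairwise_r2(g2, gmap)
    if len(p1):   # monomorphic draws yield no r²
        assert p1["r2"].iloc[0] == p2["r2"].iloc[0]


@given(st.integers(0, 200), st.lists(st.integers(0, 40), min_size=1, max_size=4))
def test_filter_bookkeeping_consistency(extra, drops):
    n_in = sum(drops) + extra
    out = qc.filter_bookkeeping(n_in, drops)
    assert out[-1] == n_in - sum(drops)
    assert all(a >= b for a, b in zip([n_in] + out, out))


@given(st.integers(0, 10_000), st.floats(0.2, 3.0))
def test_clustering_conserves_and_ignores_input_order(seed, decay):
    rng = np.random.default_rng(seed)
    n = rng.integers(2, 15)
    mtas = pd.DataFrame({
        "marker_id": [f"m{i}" for i in range(n)],
        "chromosome": rng.choice(["1A", "2B"], size=n),
        "position_cM": np.round(rng.uniform(0, 30, size=n), 3),
        "eigenvector": "EV1",
        "neg_log10_p": rng.uniform(3, 8, size=n),
    })
    hot1, single1 = hs.cluster_mtas(mtas, decay_cM=decay)
    shuffled = mtas.sample(frac=1, random_state=1).reset_index(drop=True)
    hot2, single2 = hs.cluster_mtas(shuffled, decay_cM=decay)
    # conservation: every MTA lands in exactly one hotspot or the singleton set
    assert sum(h.n_mtas for h in hot1) + len(single1) == n
    # order invariance of the partition
    part1 = sorted(tuple(sorted(h.members["marker_id"])) for h in hot1)
    part2 = sorted(tuple(sorted(h.members["marker_id"])) for h in hot2)
    assert part1 == part2
    assert sorted(single1["marker_id"]) == sorted(single2["marker_id"])


@given(st.integers(0, 10_000))
def test_clustering_monotone_in_decay(seed):
    rng = np.random.default_rng(seed)
    n = 10
    mtas = pd.DataFrame({
        "marker_id": [f"m{i}" for i in range(n)],
        "chromosome": "5A",
        "position_cM": np.sort(rng.uniform(0, 20, size=n)),
        "eigenvector": "EV1",
        "neg_log10_p": 4.0,
    })
    hot_small, _ = hs.cluster_mtas(mtas, decay_cM=0.5)
    hot_big, _ = hs.cluster_mtas(mtas, decay_cM=2.0)
    # a wider window can only merge clusters, never split them
    assert sum(h.n_mtas for h in hot_big) >= sum(h.n_mtas for h in hot_small)
    # refinement: every small-window hotspot sits inside one big-window hotspot
    for small in hot_small:
        members = set(small.members["marker_id"])
        assert any(members <= set(big.members["marker_id"]) for big in hot_big)


@given(st.lists(st.tuples(st.sampled_from("ACGT"), freq,
                          st.sampled_from("ACGT"), freq),
                min_size=1, max_size=20))
def test_allele_rule_monotone_in_threshold(rows):
    t = pd.DataFrame(rows, columns=["allele_group1", "freq_group1",
                                    "allele_group2", "freq_group2"])
    strict = sweeps.allele_rule_from_frequencies(t, threshold=0.9)["passes_rule"]
    lax = sweeps.allele_rule_from_frequencies(t, threshold=0.7)["passes_rule"]
    assert (~strict | lax).all()   # passing at 0.9 implies passing at 0.7


@given(st.integers(40, 400), st.integers(0, 40), st.integers(0, 40))
def test_gene_model_venn_sums(n_total, n_triple, n_pair):
    if n_triple + n_pair > n_total:
        n_total = n_triple + n_pair
    out = accounting.gene_model_venn(n_total, n_triple, {"ab": n_pair})
    assert out["n_unique"] == n_total - n_triple - n_pair
    assert 0 <= out["pct_unique"] <= 100 and 0 <= out["pct_triple_shared"] <= 100


@given(st.floats(0.05, 0.95), st.floats(0.05, 0.95))
def test_pic_bounded_by_he(p, q):
    pic, he = qc.pic_biallelic([p, q])
    assert (pic <= he).all() and (pic >= 0).all() and (he <= 0.5 + 1e-12).all()
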