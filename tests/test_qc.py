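import numpy as np
import pandas as pd
import pytest

from eigensweep import qc
from eigensweep.containers import MISSING
from eigensweep.simulate import SimulationConfig, simulate_panel
from conftest import make_geno, make_map


def test_allele_frequencies_with_missing(toy_geno):
    f = qc.allele_frequencies(toy_geno)
    assert f["p"].tolist() == pytest.approx([0.6, 1.0, 0.5, 0.4])
    assert f["maf"].tolist() == pytest.approx([0.4, 0.0, 0.5, 0.4])
    assert f["missing_rate"].tolist() == pytest.approx([0.0, 0.0, 0.2, 0.0])


def test_allele_frequencies_all_missing_flag():
    g = make_geno([[MISSING, MISSING]])
    f = qc.allele_frequencies(g)
    assert bool(f["all_missing"][0]) and np.isnan(f["p"][0])


def test_pic_formula_endpoints():
    pic, he = qc.pic_biallelic([0.0, 0.5, 1.0])
    assert he == pytest.approx([0.0, 0.5, 0.0])
    assert pic == pytest.approx([0.0, 0.375, 0.0])
    # PIC never exceeds gene diversity
    p = np.linspace(0, 1, 101)
    pic, he = qc.pic_biallelic(p)
    assert (pic <= he + 1e-15).all()


def test_find_duplicates_policy():
    # a==b exactly (PAV vs SNP: drop the PAV); c==d same type, c has more missing
    g = make_geno(
        [[0, 1, 0, 1, 0, 1, 0, 1, 0, 1],
         [0, 1, 0, 1, 0, 1, 0, 1, 0, 1],
         [1, 1, 0, 0, 1, 1, 0, 0, 1, MISSING],
         [1, 1, 0, 0, 1, 1, 0, 0, 1, 0]],
        marker_type=["PAV", "SNP", "SNP", "SNP"],
        marker_ids=["a", "b", "c", "d"],
    )
    dup = qc.find_duplicates(g)
    drops = dict(zip(zip(dup["marker_a"], dup["marker_b"]), dup["drop"]))
    assert drops[("a", "b")] == "a"      # PAV dropped in mixed pair
    assert drops[("c", "d")] == "c"      # more-missing member dropped


def test_find_duplicates_tie_breaks_lexicographically():
    g = make_geno([[0, 1] * 5, [0, 1] * 5], marker_ids=["zz", "aa"])
    dup = qc.find_duplicates(g)
    assert list(dup["drop"]) == ["zz"]


def test_find_duplicates_requires_overlap():
    # identical where jointly observed, but only 5/10 joint coverage
    row_a = [0, 1, 0, 1, 0] + [MISSING] * 5
    row_b = [0, 1, 0, 1, 0] + [0, 0, 0, 0, 0]
    g = make_geno([row_a, row_b])
    assert len(qc.find_duplicates(g, min_overlap=0.9)) == 0
    assert len(qc.find_duplicates(g, min_overlap=0.5)) == 1


def test_filter_chain_stage_order_and_reasons():
    n = 10
    ok = [0, 1] * (n // 2)
    g = make_geno(
        [ok,                                     # survives
         ok,                                     # unmapped
         [MISSING] * 4 + ok[4:],                 # SNP, missing 0.4 > 0.3
         [MISSING] * 4 + ok[4:],                 # PAV: exempt from missing rule, survives
         [0] * n,                                # monomorphic → low_maf
         ok],                                    # duplicate of m0 (same type, tie → larger id)
        marker_type=["PAV", "PAV", "SNP", "PAV", "PAV", "PAV"],
    )
    gmap = make_map([f"m{i}" for i in (0, 2, 3, 4, 5)], ["1A"] * 5,
                    [1.0, 2.0, 3.0, 4.0, 5.0])
    out, report = qc.filter_chain(g, gmap)
    reasons = dict(zip(report.per_marker["marker_id"],
                       report.per_marker["dropped_reason"]))
    assert reasons["m1"] == "unmapped"
    assert reasons["m2"] == "high_missing"
    assert reasons["m3"] is None            # PAV exempt from the SNP missing rule
    assert reasons["m4"] == "low_maf"
    assert reasons["m5"] == "duplicate"
    assert list(out.marker_ids) == ["m0", "m3"]
    assert list(report.stages["stage"]) == ["unmapped", "high_missing", "low_maf", "duplicate"]
    report.validate()


def test_filter_chain_all_dropped_raises():
    g = make_geno([[0] * 10])               # monomorphic only
    gmap = make_map(["m0"], ["1A"], [1.0])
    with pytest.raises(ValueError, match="no markers survive"):
        qc.filter_chain(g, gmap)


def test_qc_report_validate_catches_tampering():
    stages = pd.DataFrame({"stage": ["a", "b"], "markers_in": [10, 8],
                           "markers_dropped": [2, 1], "markers_out": [8, 6]})
    with pytest.raises(AssertionError):
        qc.QCReport(stages=stages, per_marker=pd.DataFrame()).validate()


def test_filter_bookkeeping_arithmetic_and_guard():
    assert qc.filter_bookkeeping(100, [10, 20]) == [90, 70]
    with pytest.raises(ValueError):
        qc.filter_bookkeeping(10, [11])


def test_duplicate_recovery_without_missingness():
    cfg = SimulationConfig(n_markers=600, samples_per_subpop=(25,) * 5,
                           n_admixed=10, missing_rate=0.0, n_sweeps=4,
                           duplicate_fraction=0.02, seed=3)
    geno, _, _, truth = simulate_panel(cfg)
    found = qc.find_duplicates(geno)
    found_pairs = {frozenset(p) for p in zip(found["marker_a"], found["marker_b"])}
    planted = {frozenset(p) for p in truth.duplicate_pairs}
    assert planted <= found_pairs  # every planted duplicate is recovered
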