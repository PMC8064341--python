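import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eigensweep import gwas
from eigensweep.containers import MISSING
from eigensweep.simulate import SimulationConfig, simulate_panel
from conftest import make_geno


def _identity_kinship(sample_ids):
    n = len(sample_ids)
    return gwas.KinshipMatrix(K=np.eye(n), sample_ids=np.asarray(sample_ids, dtype=object))


def _random_geno(n_markers, n_samples, seed=0):
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.2, 0.8, n_markers)
    calls = (rng.random((n_markers, n_samples)) < p[:, None]).astype(np.int8)
    return make_geno(calls, marker_ids=[f"g{i}" for i in range(n_markers)],
                     sample_ids=[f"s{j}" for j in range(n_samples)])


def test_imputed_dosage_fills_marker_mean():
    g = make_geno([[0, 1, 1, MISSING]])
    x = gwas.imputed_dosage(g)
    assert x.shape == (4, 1)
    assert x[3, 0] == pytest.approx(2 / 3)


def test_kinship_is_psd_and_aligned(small_panel):
    geno, _, _, _ = small_panel
    kin = gwas.kinship(geno)
    assert kin.K.shape == (geno.n_samples, geno.n_samples)
    assert np.array_equal(kin.sample_ids, geno.sample_ids)
    w = np.linalg.eigvalsh(kin.K)
    assert w.min() >= -1e-8
    assert np.allclose(kin.K, kin.K.T)


def test_kinship_separates_subpopulations(small_panel):
    geno, _, _, truth = small_panel
    kin = gwas.kinship(geno)
    sp = truth.subpop_of_sample.reindex(geno.sample_ids).to_numpy()
    same = sp[:, None] == sp[None, :]
    off_diag = ~np.eye(len(sp), dtype=bool)
    labelled = off_diag & (sp[:, None] != "admixed") & (sp[None, :] != "admixed")
    within = kin.K[same & labelled].mean()
    between = kin.K[~same & labelled].mean()
    assert within > between


def test_mlm_with_identity_kinship_equals_ols():
    g = _random_geno(80, 60, seed=1)
    rng = np.random.default_rng(2)
    y = rng.normal(size=60)
    phen = pd.DataFrame({"EV1": y}, index=g.sample_ids)
    scan = gwas.mlm_scan(g, phen, _identity_kinship(g.sample_ids), n_pcs=0)
    x = gwas.imputed_dosage(g)
    for i in [0, 17, 55]:
        xi = x[:, i]
        slope, _, r, p, _ = stats.linregress(xi, y)
        row = scan[scan["marker_id"] == f"g{i}"].iloc[0]
        assert row["p_value"] == pytest.approx(p, abs=1e-8)
        assert row["beta"] == pytest.approx(slope, rel=1e-6)


def test_scan_recovers_causal_marker():
    g = _random_geno(200, 120, seed=3)
    rng = np.random.default_rng(4)
    x = gwas.imputed_dosage(g)
    y = 2.0 * x[:, 42] + rng.normal(scale=0.5, size=120)
    phen = pd.DataFrame({"EV1": (y - y.mean()) / y.std()}, index=g.sample_ids)
    scan = gwas.mlm_scan(g, phen, _identity_kinship(g.sample_ids), n_pcs=0)
    best = scan.sort_values("neg_log10_p", ascending=False).iloc[0]
    assert best["marker_id"] == "g42"


def test_p3d_and_exact_reml_agree_at_identity_kinship():
    g = _random_geno(40, 50, seed=5)
    rng = np.random.default_rng(6)
    phen = pd.DataFrame({"EV1": rng.normal(size=50)}, index=g.sample_ids)
    kin = _identity_kinship(g.sample_ids)
    a = gwas.mlm_scan(g, phen, kin, n_pcs=0, p3d=True)
    b = gwas.mlm_scan(g, phen, kin, n_pcs=0, p3d=False)
    # at K = I the variance split is unidentified but the GLS fit is the
    # same OLS for any delta, so p-values must agree
    assert np.allclose(a["p_value"], b["p_value"], atol=1e-8)


def test_collinearity_guard_drops_self_pc(small_panel):
    from eigensweep import ordination as ordn
    geno, _, meta, _ = small_panel
    dist = ordn.simple_matching_distance(geno)
    pc = ordn.orient_axes(ordn.pcoa(dist, k_axes=4), meta)
    phen = ordn.eigen_phenotypes(pc, top_k=4)
    kin = gwas.kinship(geno)
    scan = gwas.mlm_scan(geno, phen, kin, n_pcs=4)
    used = scan.attrs["pcs_used"]
    # each eigenvector phenotype coincides with a genotype PC; the guard
    # must remove at least that one for the leading axes
    assert len(used["EV1"]) < 4
    off = gwas.mlm_scan(geno, phen, kin, n_pcs=4, collinearity_guard=None)
    assert len(off.attrs["pcs_used"]["EV1"]) == 4
    # with the guard the leading axis has real signal; without it, none
    assert scan[scan["eigenvector"] == "EV1"]["neg_log10_p"].max() \
        > off[off["eigenvector"] == "EV1"]["neg_log10_p"].max()


def test_scan_alignment_errors():
    g = _random_geno(10, 20)
    phen = pd.DataFrame({"EV1": np.zeros(20)}, index=[f"x{j}" for j in range(20)])
    with pytest.raises(ValueError, match="phenotype rows"):
        gwas.mlm_scan(g, phen, _identity_kinship(g.sample_ids), n_pcs=0)
    kin = _identity_kinship([f"x{j}" for j in range(20)])
    phen_ok = pd.DataFrame({"EV1": np.zeros(20)}, index=g.sample_ids)
    with pytest.raises(ValueError, match="kinship sample ids"):
        gwas.mlm_scan(g, phen_ok, kin, n_pcs=0)


def test_derive_thresholds_known_fixture():
    # 5 small p-values among 20; BH at alpha 0.05
    pvals = np.array([1e-6, 2e-6, 3e-6, 4e-6, 5e-6] + [0.5] * 15)
    scan = pd.DataFrame({"p_value": pvals, "neg_log10_p": -np.log10(pvals)})
    thr = gwas.derive_thresholds(scan, fdr_alpha=0.05)
    assert thr.n_fdr == 5
    assert thr.fdr_neg_log10 == pytest.approx(-np.log10(5e-6))


def test_derive_thresholds_no_rejections_gives_inf():
    scan = pd.DataFrame({"p_value": [0.4, 0.6, 0.9],
                         "neg_log10_p": -np.log10([0.4, 0.6, 0.9])})
    thr = gwas.derive_thresholds(scan)
    assert thr.fdr_neg_log10 == float("inf") and thr.n_fdr == 0


def test_significant_mtas_strict_threshold():
    scan = pd.DataFrame({"neg_log10_p": [2.9, 3.0, 3.1]})
    out = gwas.significant_mtas(scan, 3.0)
    assert out["neg_log10_p"].tolist() == [3.1]
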