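"""Association scan, BH step-up, RMIP resampling and stable-hit calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from statsmodels.stats.multitest import multipletests

from conftest import toy_genotypes
from gspanel.data import LineMeans
from gspanel.gwas import RmipResult, bh_fdr, classify_hits, rmip, scan
from gspanel.relatedness import standardize, structure_pca
from gspanel.simpanel import SimConfig, simulate_genotypes


def _random_panel(n, m, seed, line_ids=None):
    """Independent biallelic dosages (no LD), useful for null calibration."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.15, 0.5, size=m)
    dos = (rng.uniform(size=(n, m)) < p).astype(float) * 2.0
    geno = toy_genotypes(dos, line_ids=line_ids)
    from gspanel.relatedness import filter_maf
    return filter_maf(geno, 0.0)  # drop the occasional monomorphic draw


def _means(values, line_ids, trait="t", scope="overall"):
    return LineMeans(trait=trait, scope=scope,
                     means=pd.Series(values, index=line_ids))


def test_scan_matches_normal_equations_oracle():
    geno = _random_panel(12, 30, seed=3)
    std = standardize(geno)
    axes = structure_pca(std, k=2)
    rng = np.random.default_rng(4)
    y = rng.standard_normal(12)
    res = scan(_means(y, geno.line_ids), std, axes)
    C = np.column_stack([np.ones(12), axes.coords])
    for j in range(std.m):
        X = np.column_stack([C, std.W[:, j]])
        XtX = X.T @ X
        beta = np.linalg.solve(XtX, X.T @ y)
        resid = y - X @ beta
        df = 12 - X.shape[1]
        s2 = resid @ resid / df
        se = np.sqrt(s2 * np.linalg.inv(XtX)[-1, -1])
        row = res.table.iloc[j]
        assert abs(row["beta"] - beta[-1]) < 1e-8
        assert abs(row["se"] - se) < 1e-8


def test_perfect_signal_is_scan_minimum():
    geno = _random_panel(40, 50, seed=5)
    std = standardize(geno)
    y = geno.dosages[:, 17].copy()
    res = scan(_means(y, geno.line_ids), std, axes=None)
    tab = res.table
    assert tab.loc[tab["p"].idxmin(), "marker"] == geno.marker_ids[17]
    assert tab["p"].min() < 1e-20


def test_permutation_null_is_calibrated():
    geno = _random_panel(80, 5000, seed=6)
    std = standardize(geno)
    rng = np.random.default_rng(7)
    y = rng.standard_normal(80)  # independent of genotypes by construction
    res = scan(_means(y, geno.line_ids), std, structure_pca(std, k=5))
    frac = (res.table["p"] < 0.05).mean()
    assert 0.04 <= frac <= 0.06
    assert 0.9 <= res.lambda_gc <= 1.1


def test_collinear_marker_reported_missing():
    dos = np.array([[0, 0.0], [0, 1], [0, 2], [0, 1], [0, 0], [0, 2],
                    [0, 1], [0, 0], [0, 2], [0, 1], [0, 0], [0, 2]])
    dos[:, 0] = dos[:, 1]
    geno = toy_genotypes(dos)
    std = standardize(geno)
    # zero out one column post-standardization: residualizing leaves nothing
    std.W[:, 0] = 0.0
    res = scan(_means(np.arange(12.0), geno.line_ids), std, axes=None)
    assert np.isnan(res.table["p"].iloc[0])
    assert len(res.table) == 2  # counted, never dropped


def test_bh_step_up_enumeration_cases():
    q, rej = bh_fdr([0.001, 0.01, 0.03, 0.5], 0.2)
    assert rej.sum() == 3 and rej.tolist() == [True, True, True, False]
    _, rej = bh_fdr(np.ones(8), 0.2)
    assert rej.sum() == 0
    _, rej = bh_fdr([0.01], 0.2)
    assert rej[0]  # single test reduces to p <= q
    q, rej = bh_fdr([0.01, np.nan, 0.5], 0.05)
    assert np.isnan(q[1]) and not rej[1] and rej[0]


@given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1,
                max_size=60),
       st.sampled_from([0.01, 0.05, 0.2]))
def test_bh_agrees_with_statsmodels(pvals, q):
    p = np.array(pvals)
    qvals, rej = bh_fdr(p, q)
    sm_rej, sm_q, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    np.testing.assert_allclose(qvals, sm_q, atol=1e-12)
    assert (rej == sm_rej).all()
    # q-values dominate p-values and are monotone in p-rank
    assert (qvals >= p - 1e-12).all()
    order = np.argsort(p)
    assert (np.diff(qvals[order]) >= -1e-12).all()


def test_rmip_resample_size_and_perfect_hit():
    cfg = SimConfig(seed=31, n_lines=80, n_snps=300, selfing_generations=8)
    geno, _ = simulate_genotypes(cfg)
    y = geno.dosages[:, 50].copy()  # monogenic noiseless trait
    y = y + np.random.default_rng(0).normal(0, 1e-6, len(y))  # break ties
    r = rmip(_means(y, geno.line_ids), geno, n_resamples=20, seed=2)
    assert r.resample_size == 64  # floor(0.8 * 80)
    causal = geno.marker_ids[50]
    assert r.counts.at[causal, 0.2] == 20
    # monotone in the FDR level, holding the resamples fixed
    assert (r.counts[0.01] <= r.counts[0.05]).all()
    assert (r.counts[0.05] <= r.counts[0.2]).all()


def test_rmip_null_counts_stay_low():
    geno = _random_panel(60, 500, seed=8)
    y = np.random.default_rng(9).standard_normal(60)
    r = rmip(_means(y, geno.line_ids), geno, n_resamples=30, seed=3)
    assert (r.counts[0.2] >= 25).mean() < 0.01


def _mk_rmip(trait, scope, counts_by_level, n=100):
    markers = sorted({m for lev in counts_by_level.values() for m in lev})
    df = pd.DataFrame(0, index=pd.Index(markers, name="marker"),
                      columns=list(counts_by_level))
    for lev, d in counts_by_level.items():
        for m, c in d.items():
            df.at[m, lev] = c
    return RmipResult(counts=df, trait=trait, scope=scope, n_resamples=n,
                      resample_size=64, fdr_levels=tuple(counts_by_level))


def test_classify_hits_stability_rules():
    levels = [0.2, 0.05, 0.01]
    mk = lambda d: {lev: d for lev in levels}
    by_env = {
        "A": _mk_rmip("t", "A", {0.2: {"m1": 7, "m2": 9}, 0.05: {"m1": 2},
                                 0.01: {}}),
        "B": _mk_rmip("t", "B", {0.2: {"m1": 5}, 0.05: {}, 0.01: {}}),
        "C": _mk_rmip("t", "C", {0.2: {"m1": 12}, 0.05: {}, 0.01: {}}),
    }
    hits = {h.marker: h for h in classify_hits(by_env)}
    assert hits["m1"].stable and hits["m1"].environments == ["A", "B", "C"]
    assert hits["m1"].counts_by_env == {"A": 7, "B": 5, "C": 12}
    assert not hits["m2"].stable  # detected in one environment only
    # counts below 25 everywhere: every RMIP>=25 grid cell is empty
    for (fdr, rmin), envs in hits["m1"].grid.items():
        if rmin == 25:
            assert envs == []
    with pytest.raises(ValueError, match="mixed traits"):
        classify_hits({"A": _mk_rmip("t1", "A", mk({})),
                       "B": _mk_rmip("t2", "B", mk({}))})


def test_shared_qtl_is_classified_stable():
    from gspanel.simpanel import simulate_trials
    cfg = SimConfig(seed=33, n_lines=80, n_snps=600, n_locations=3, n_years=2,
                    qtls=[(300, 0.7)], var_ge=0.1, var_e=0.4)
    geno, _ = simulate_genotypes(cfg)
    plots, truth = simulate_trials(geno, cfg)
    raw = plots.df.groupby(["env", "line"])["value"].mean()
    by_env = {}
    for env in plots.environments:
        lm = LineMeans(trait="sim_trait", scope=env, means=raw.loc[env])
        by_env[env] = rmip(lm, geno, n_resamples=40, seed=5)
    hits = classify_hits(by_env)
    causal = geno.marker_ids[300]
    stable_markers = {h.marker for h in hits if h.stable}
    assert causal in stable_markers
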