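"""Cross-validation designs: fold structure, pair grids, transfer strata and
GWAS-hit augmentation."""

import numpy as np
import pandas as pd
import pytest

from gspanel.crossval import (
    CvResult,
    cv_between,
    cv_within,
    hit_deltas,
    make_folds,
    summarize_transfer,
)
from gspanel.data import LineMeans
from gspanel.gwas import StableHit
from gspanel.simpanel import SimConfig, simulate_genotypes, simulate_trials


def _env_means_from_raw(plots, trait="sim_trait"):
    raw = plots.df[plots.df["trait"] == trait].groupby(["env", "line"])["value"].mean()
    return {env: LineMeans(trait=trait, scope=env, means=raw.loc[env])
            for env in plots.environments}


def test_folds_are_64_train_16_test_and_reproducible():
    ids = [f"L{i:03d}" for i in range(80)]
    folds = make_folds(ids, n_iter=10, fraction=0.8, seed=5)
    for train, test in folds:
        assert len(train) == 64 and len(test) == 16
        assert not set(train) & set(test)
        assert sorted(train + test) == ids
    assert folds == make_folds(ids, 10, 0.8, seed=5)
    assert folds != make_folds(ids, 10, 0.8, seed=6)


def test_polygenic_noiseless_trait_predicts_near_perfectly():
    # trait = exact genomic value from all markers in a tightly related panel
    # (few founders, short map): the kernel model is the true model and the
    # only loss is shrinkage from the finite training set
    cfg = SimConfig(seed=51, n_lines=60, n_snps=500, n_founders=4,
                    n_chromosomes=2, map_length_per_chrom=0.8)
    geno, _ = simulate_genotypes(cfg)
    rng = np.random.default_rng(1)
    D = np.nan_to_num(geno.dosages)
    y = (D - D.mean(0)) @ rng.standard_normal(geno.n_markers)
    lm = LineMeans(trait="g", scope="overall",
                   means=pd.Series(y, index=geno.line_ids))
    cv = cv_within(lm, geno, n_iter=10, seed=2)
    assert cv.mean_r > 0.9
    assert len(cv.r_values) == 10


def test_between_environment_grid_has_all_ordered_pairs(panel80):
    _, geno, _, plots, _ = panel80
    env_means = _env_means_from_raw(plots)
    assert len(env_means) == 14
    pairs = cv_between(env_means, geno, n_iter=3, seed=3)
    assert len(pairs) == 196  # 14 x 14 ordered pairs, diagonal included
    hashes = {res.fold_hash for res in pairs.values()}
    assert len(hashes) == 1  # shared folds across every pair


def test_no_gxe_means_transfer_without_penalty():
    cfg = SimConfig(seed=52, n_lines=60, n_snps=400, n_locations=2, n_years=2,
                    var_ge=0.0, var_e=0.4)
    geno, _ = simulate_genotypes(cfg)
    plots, _ = simulate_trials(geno, cfg)
    pairs = cv_between(_env_means_from_raw(plots), geno, n_iter=8, seed=4)
    diag = np.mean([r.mean_r for (a, b), r in pairs.items() if a == b])
    off = np.mean([r.mean_r for (a, b), r in pairs.items() if a != b])
    assert abs(diag - off) < 0.05


def test_strong_gxe_degrades_transfer():
    cfg = SimConfig(seed=53, n_lines=60, n_snps=400, n_locations=2, n_years=2,
                    var_g=0.5, var_ge=1.0, var_e=0.4)
    geno, _ = simulate_genotypes(cfg)
    plots, _ = simulate_trials(geno, cfg)
    pairs = cv_between(_env_means_from_raw(plots), geno, n_iter=8, seed=4)
    diag = np.mean([r.mean_r for (a, b), r in pairs.items() if a == b])
    off = np.mean([r.mean_r for (a, b), r in pairs.items() if a != b])
    assert off < diag


def _pair_grid(values):
    """CvResult grid over 2 locations x 2 years with given mean abilities."""
    envs = ["A-2004", "A-2005", "B-2004", "B-2005"]
    out = {}
    for a in envs:
        for b in envs:
            r = values[(a, b)]
            out[(a, b)] = CvResult(trait="t", scope=f"{a}->{b}",
                                   r_values=np.array([r]), n_iterations=1,
                                   n_skipped=0, fold_hash="x")
    return out, pd.DataFrame({
        "env": envs, "location": [e.split("-")[0] for e in envs],
        "year": [int(e.split("-")[1]) for e in envs]})


def test_transfer_strata_match_enumeration_oracle():
    envs = ["A-2004", "A-2005", "B-2004", "B-2005"]
    rng = np.random.default_rng(7)
    values = {(a, b): float(rng.uniform(0.2, 0.8)) for a in envs for b in envs}
    pairs, meta = _pair_grid(values)
    ts = summarize_transfer(pairs, meta)
    same_loc = [values[(a, b)] for a in envs for b in envs
                if a != b and a[0] == b[0]]
    same_year = [values[(a, b)] for a in envs for b in envs
                 if a != b and a[-4:] == b[-4:]]
    diff_both = [values[(a, b)] for a in envs for b in envs
                 if a[0] != b[0] and a[-4:] != b[-4:]]
    baseline = np.mean([values[(e, e)] for e in envs])
    assert ts.baseline == pytest.approx(baseline)
    assert ts.strata_means["within_location_different_year"] == pytest.approx(np.mean(same_loc))
    assert ts.strata_means["within_year_different_location"] == pytest.approx(np.mean(same_year))
    assert ts.strata_means["different_year_and_location"] == pytest.approx(np.mean(diff_both))
    assert ts.strata_percent["within_location_different_year"] == pytest.approx(
        100 * np.mean(same_loc) / baseline)
    # 4 + 4 + 4 off-diagonal pairs partitioned exactly once
    assert len(same_loc) + len(same_year) + len(diff_both) == 12


def test_uniform_grid_gives_100_percent_everywhere():
    envs = ["A-2004", "A-2005", "B-2004", "B-2005"]
    pairs, meta = _pair_grid({(a, b): 0.5 for a in envs for b in envs})
    ts = summarize_transfer(pairs, meta)
    for pct in ts.strata_percent.values():
        assert pct == pytest.approx(100.0)
    assert ts.interpretation == "undetermined"


def test_zero_baseline_flags_percentages_missing():
    envs = ["A-2004", "A-2005", "B-2004", "B-2005"]
    vals = {(a, b): (0.0 if a == b else 0.3) for a in envs for b in envs}
    pairs, meta = _pair_grid(vals)
    ts = summarize_transfer(pairs, meta)
    assert all(np.isnan(p) for p in ts.strata_percent.values())


def _hit(marker, envs, grid_envs=None):
    grid = {cell: (grid_envs if grid_envs is not None else envs)
            for cell in [(0.2, 5), (0.2, 25), (0.05, 5), (0.05, 25),
                         (0.01, 5), (0.01, 25)]}
    return StableHit(marker=marker, trait="sim_trait", environments=envs,
                     counts_by_env={e: 10 for e in envs},
                     stable=len(envs) >= 3, grid=grid)


def test_causal_hit_improves_prediction_and_null_hit_does_not():
    cfg = SimConfig(seed=54, n_lines=60, n_snps=300, n_locations=3, n_years=1,
                    qtls=[(150, 0.8)], var_ge=0.05, var_e=0.3)
    geno, _ = simulate_genotypes(cfg)
    plots, _ = simulate_trials(geno, cfg)
    env_means = _env_means_from_raw(plots)
    envs = sorted(env_means)
    causal = geno.marker_ids[150]
    null_marker = geno.marker_ids[10]
    deltas, hist = hit_deltas([_hit(causal, envs), _hit(null_marker, envs)],
                              env_means, geno, n_iter=8, seed=9)
    causal_d = [d.delta for d in deltas if d.marker == causal]
    null_d = [d.delta for d in deltas if d.marker == null_marker]
    assert np.mean(causal_d) > 0
    assert abs(np.mean(null_d)) < 0.05
    assert set(hist.columns) >= {"fdr", "rmip_min", "share_improved"}
    # every evaluation used identical folds in baseline and augmented runs
    assert all(d.environment in envs for d in deltas)


def test_constant_test_fold_is_skipped_not_crashed():
    cfg = SimConfig(seed=55, n_lines=20, n_snps=200)
    geno, _ = simulate_genotypes(cfg)
    vals = pd.Series(1.0, index=geno.line_ids)  # constant trait
    vals.iloc[0] = 2.0
    lm = LineMeans(trait="t", scope="overall", means=vals)
    cv = cv_within(lm, geno, n_iter=4, seed=1)
    assert cv.n_skipped >= 1
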