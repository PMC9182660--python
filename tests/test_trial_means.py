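"""Mixed-model means and heritability against closed-form and GLS oracles."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_balanced_plots
from gspanel.data import PlotRecords
from gspanel.reml import VarCompModel, fit_reml
from gspanel.simpanel import SimConfig, simulate_genotypes, simulate_trials
from gspanel.trial_means import (
    VarianceComponents,
    estimate_heritability,
    exclude_low_h2,
    fit_environment_means,
    fit_overall_means,
)


def _dense_gls_means(df, sigma2, cell_coding=False):
    """Direct-matrix-inversion GLS oracle at given variance components."""
    if cell_coding:
        cells = sorted(set(zip(df["line"], df["env"])), key=lambda t: (t[1], t[0]))
        cidx = {c: i for i, c in enumerate(cells)}
        X = np.zeros((len(df), len(cells)))
        for i, (l, e) in enumerate(zip(df["line"], df["env"])):
            X[i, cidx[(l, e)]] = 1.0
        labels = cells
    else:
        lines = sorted(df["line"].unique())
        lidx = {l: i for i, l in enumerate(lines)}
        X = np.zeros((len(df), len(lines)))
        for i, l in enumerate(df["line"]):
            X[i, lidx[l]] = 1.0
        labels = lines

    def zzt(lab):
        z = pd.get_dummies(lab).to_numpy(dtype=float)
        return z @ z.T

    V = sigma2["residual"] * np.eye(len(df))
    if sigma2.get("rep", 0) > 0:
        V += sigma2["rep"] * zzt(df["env"] + "/" + df["rep"].astype(str))
    if sigma2.get("block", 0) > 0:
        V += sigma2["block"] * zzt(df["env"] + "/" + df["rep"].astype(str)
                                   + "/" + df["block"].astype(str))
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ df["value"].to_numpy())
    return dict(zip(labels, beta))


def test_balanced_env_means_are_arithmetic_averages():
    plots, _, lines = make_balanced_plots(complete_blocks=True)
    env = plots.environments[0]
    lm = fit_environment_means(plots, env, "trait")
    raw = plots.for_trait("trait", env).groupby("line")["value"].mean()
    np.testing.assert_allclose(lm.means.reindex(raw.index), raw, atol=1e-8)


def test_unbalanced_env_means_match_gls_oracle():
    plots, _, _ = make_balanced_plots(n_lines=6, n_loc=1, n_years=1,
                                      complete_blocks=False)
    df = plots.df.drop(index=[3]).reset_index(drop=True)  # delete one plot
    plots_u = PlotRecords(df.drop(columns="env"))
    env = plots_u.environments[0]
    lm, fit = fit_environment_means(plots_u, env, "trait", return_details=True)
    oracle = _dense_gls_means(plots_u.for_trait("trait", env), fit.sigma2)
    for line, val in oracle.items():
        assert abs(lm.means[line] - val) < 1e-8


def test_zero_variance_components_reduce_to_ols():
    plots, _, _ = make_balanced_plots(n_lines=6, n_loc=1, n_years=1,
                                      complete_blocks=False, seed=3)
    env = plots.environments[0]
    lm = fit_environment_means(plots, env, "trait", random_effects=())
    raw = plots.for_trait("trait", env).groupby("line")["value"].mean()
    np.testing.assert_allclose(lm.means.reindex(raw.index), raw, atol=1e-10)


def test_overall_means_average_environment_means():
    plots, _, _ = make_balanced_plots(n_loc=2, n_years=2, complete_blocks=True)
    om = fit_overall_means(plots, "trait")
    env_avg = sum(
        fit_environment_means(plots, e, "trait").means
        for e in plots.environments
    ) / len(plots.environments)
    np.testing.assert_allclose(om.means, env_avg.reindex(om.means.index),
                               atol=1e-8)


def test_overall_means_match_gls_oracle_when_unbalanced():
    plots, _, _ = make_balanced_plots(n_lines=6, n_loc=2, n_years=1,
                                      complete_blocks=False, seed=5)
    df = plots.df.drop(index=[1, 17]).reset_index(drop=True)
    plots_u = PlotRecords(df.drop(columns="env"))
    om, fit = fit_overall_means(plots_u, "trait", return_details=True)
    cells = _dense_gls_means(plots_u.for_trait("trait"), fit.sigma2,
                             cell_coding=True)
    per_line = {}
    for (line, env), v in cells.items():
        per_line.setdefault(line, []).append(v)
    for line, vals in per_line.items():
        assert abs(om.means[line] - np.mean(vals)) < 1e-8


def test_single_environment_reduces_to_environment_fit():
    plots, _, _ = make_balanced_plots(n_loc=1, n_years=1, complete_blocks=False)
    env = plots.environments[0]
    om = fit_overall_means(plots, "trait")
    em = fit_environment_means(plots, env, "trait")
    np.testing.assert_allclose(om.means, em.means.reindex(om.means.index),
                               atol=1e-8)


def test_absent_trait_yields_declared_missing_result():
    plots, _, _ = make_balanced_plots()
    lm = fit_environment_means(plots, plots.environments[0], "no_such_trait")
    assert lm.means.empty


def test_reml_matches_balanced_anova_ems_closed_form():
    """On a balanced two-way layout the REML maximizer coincides with the
    ANOVA expected-mean-squares solution when all components are interior."""
    cfg = SimConfig(seed=12, n_lines=25, n_snps=100, n_locations=3, n_years=2,
                    var_g=1.0, var_ge=0.6, var_env=0.8, var_e=1.0,
                    var_rep=0, var_block=0)
    geno, _ = simulate_genotypes(cfg)
    plots, _ = simulate_trials(geno, cfg)
    df = plots.for_trait("sim_trait")
    g_n, e_n, r_n = cfg.n_lines, cfg.n_environments, cfg.n_reps

    # EMS oracle from the classic balanced decomposition
    cell = df.groupby(["line", "env"])["value"].mean().unstack()
    mse = df.groupby(["line", "env"])["value"].var(ddof=1).mean()
    ms_ge = ((cell.sub(cell.mean(0), axis=1).sub(cell.mean(1), axis=0)
              + cell.values.mean()) ** 2).values.sum() * r_n / ((g_n - 1) * (e_n - 1))
    ms_g = cell.mean(1).var(ddof=1) * r_n * e_n
    ms_env = cell.mean(0).var(ddof=1) * r_n * g_n
    oracle = {
        "residual": mse,
        "line_env": (ms_ge - mse) / r_n,
        "line": (ms_g - ms_ge) / (r_n * e_n),
        "env": (ms_env - ms_ge) / (r_n * g_n),
    }

    nested = {
        "env": df["env"].to_numpy(),
        "line_env": (df["line"] + "@" + df["env"]).to_numpy(),
    }
    groups = pd.Categorical(df["env"]).codes
    model = VarCompModel(df["value"].to_numpy(), groups, nested=nested,
                         crossed=("line", df["line"].to_numpy()),
                         cell_factor="line_env")
    fit = fit_reml(model, polish=True)
    for name, val in oracle.items():
        assert abs(fit.sigma2[name] - val) < 1e-6, name


def test_reml_optimum_beats_random_ratio_points():
    plots, _, _ = make_balanced_plots(n_lines=10, seed=8, complete_blocks=False)
    df = plots.for_trait("trait")
    nested = {"line": df["line"].to_numpy(),
              "rep": (df["env"] + df["rep"].astype(str)).to_numpy()}
    model = VarCompModel(df["value"].to_numpy(), np.zeros(len(df)),
                         nested=nested)
    fit = fit_reml(model)
    rng = np.random.default_rng(0)
    for _ in range(20):
        gam = rng.uniform(0.01, 5.0, size=2)
        assert model._profile_eval(gam)[0] >= fit.neg2_reml - 1e-8


def test_noiseless_limit_gives_unit_heritability():
    cfg = SimConfig(seed=13, n_lines=20, n_snps=100, n_locations=2, n_years=2,
                    var_ge=0, var_e=0, var_rep=0, var_block=0)
    geno, _ = simulate_genotypes(cfg)
    plots, _ = simulate_trials(geno, cfg)
    vc = estimate_heritability(plots, "sim_trait", "overall", se=False)
    assert vc.H2 > 1 - 1e-6


def test_h2_recovers_closed_form_expectation():
    cfg = SimConfig(seed=14, n_lines=150, n_founders=8, n_snps=200,
                    var_g=1.0, var_ge=0.5, var_e=1.0, var_rep=0, var_block=0)
    geno, _ = simulate_genotypes(cfg)
    plots, _ = simulate_trials(geno, cfg)
    vc = estimate_heritability(plots, "sim_trait", "overall", se=False,
                               polish=False)
    expected = 1.0 / (1.0 + 0.5 / 14 + 1.0 / 28)
    assert abs(vc.H2 - expected) < 0.05


def test_h2_standard_error_is_sane(small_panel):
    _, _, _, plots, _ = small_panel
    vc = estimate_heritability(plots, "sim_trait", "overall")
    assert np.isfinite(vc.H2_se) and 0 < vc.H2_se < 0.5


def test_per_environment_h2_below_overall_on_average(small_panel):
    _, _, _, plots, _ = small_panel
    overall = estimate_heritability(plots, "sim_trait", "overall", se=False)
    env_h2 = [
        estimate_heritability(plots, "sim_trait", e, se=False).H2
        for e in plots.environments
    ]
    assert np.mean(env_h2) < overall.H2


@pytest.mark.parametrize("h2,expected", [(0.005, True), (0.01, False),
                                         (0.22, False)])
def test_low_heritability_exclusion_rule(h2, expected):
    vc = VarianceComponents(trait="t", scope="E", sigma2_g=h2,
                            sigma2_ge=np.nan, sigma2_rep=0, sigma2_block=0,
                            sigma2_e=1 - h2, n_env=1, n_rep=2, H2=h2,
                            H2_se=0.01)
    assert exclude_low_h2(vc) is expected
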