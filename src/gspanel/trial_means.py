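"""Line means and family-mean broad-sense heritability from plot records.

The analysis is two-stage: plot data enter linear mixed models once, here,
and every genomic analysis downstream (GWAS, GBLUP) consumes only the
resulting line means.

*Means.*  Per environment, genotype is fixed with replicate and incomplete
block (nested in replicate) random; the reported mean of a line is its
generalized-least-squares genotype estimate.  For the overall scope the model
carries genotype, environment and genotype x environment as fixed effects (a
cell-means parameterization) with replicate-within-environment and
block-within-replicate random, and a line's overall mean is the average of
its estimable cell means over the environments in which it was observed.

*Heritability.*  An all-random model (line, line x environment for the
overall scope, replicate, block, residual) is fitted by REML, and the
family-mean broad-sense heritability is

    H2 = sigma2_G / (sigma2_G + sigma2_GE / n_env + sigma2_e / (n_env * n_rep))

for the overall scope and ``sigma2_G / (sigma2_G + sigma2_e / n_rep)`` within
a single environment, with ``n_env`` and ``n_rep`` as harmonic means under
imbalance.  The standard error comes from the delta method on the asymptotic
covariance of the variance components.  Design variances (replicate, block)
are excluded from the denominator: they cancel from genotype-mean
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import LineMeans, PlotRecords
from .reml import VarCompModel, fit_reml

__all__ = [
    "VarianceComponents",
    "fit_environment_means",
    "fit_overall_means",
    "estimate_heritability",
    "exclude_low_h2",
]


@dataclass
class VarianceComponents:
    """REML variance components and family-mean heritability for one scope."""

    trait: str
    scope: str  # "overall" or an environment id
    sigma2_g: float
    sigma2_ge: float  # NaN for single-environment scope
    sigma2_rep: float
    sigma2_block: float
    sigma2_e: float
    n_env: float  # harmonic-mean environments per line
    n_rep: float  # harmonic-mean plots per line-environment cell
    H2: float
    H2_se: float

    def __post_init__(self) -> None:
        for name in ("sigma2_g", "sigma2_rep", "sigma2_block", "sigma2_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (np.isnan(self.H2) or 0.0 <= self.H2 <= 1.0 + 1e-12):
            raise ValueError("H2 must lie in [0, 1]")


def _harmonic(counts) -> float:
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts > 0]
    return float(stats.hmean(counts)) if counts.size else np.nan


def _check_estimable(df: pd.DataFrame) -> None:
    if df["line"].nunique() < 2:
        raise ValueError("need data on at least 2 lines")


def fit_environment_means(
    plots: PlotRecords,
    env: str,
    trait: str,
    random_effects: tuple = ("rep", "block"),
    return_details: bool = False,
):
    """Mixed-model genotype means for one environment.

    Returns a :class:`LineMeans` (empty when the trait was not measured in
    the environment — a declared-missing result, not an exception).  With
    ``random_effects=()`` the fit reduces to ordinary least squares on
    genotype indicators.
    """
    df = plots.for_trait(trait, env)
    if df.empty:
        return LineMeans(trait=trait, scope=env, means=pd.Series(dtype=float))
    _check_estimable(df)
    lines = sorted(df["line"].unique())
    li = pd.Categorical(df["line"], categories=lines).codes
    X = np.zeros((len(df), len(lines)))
    X[np.arange(len(df)), li] = 1.0
    if len(df) <= len(lines):
        raise ValueError(
            "singular design: no residual degrees of freedom beyond the "
            "genotype factor"
        )
    nested = {}
    if "rep" in random_effects:
        nested["rep"] = df["rep"].to_numpy()
    if "block" in random_effects:
        nested["block"] = (df["rep"].astype(str) + "/" + df["block"].astype(str)).to_numpy()
    model = VarCompModel(df["value"].to_numpy(), np.zeros(len(df)),
                         nested=nested, X=X)
    fit = fit_reml(model)
    counts = df.groupby("line").size().reindex(lines)
    means = LineMeans(trait=trait, scope=env,
                      means=pd.Series(fit.beta, index=lines), counts=counts)
    return (means, fit) if return_details else means


def fit_overall_means(
    plots: PlotRecords,
    trait: str,
    random_effects: tuple = ("rep", "block"),
    return_details: bool = False,
):
    """Genotype means across all environments (estimable-function average).

    Fits genotype, environment and genotype x environment as fixed (cell
    means) with replicate and block random, then averages each line's cell
    estimates over the environments where it was observed.  Lines observed
    nowhere are simply absent from the result.
    """
    df = plots.for_trait(trait)
    if df.empty:
        return LineMeans(trait=trait, scope="overall", means=pd.Series(dtype=float))
    _check_estimable(df)
    envs = sorted(df["env"].unique())
    env_codes = pd.Categorical(df["env"], categories=envs).codes

    x_blocks, cell_labels = [], []
    # VarCompModel indexes groups in code order; build one cell-indicator
    # block per environment over that environment's rows
    for j, env in enumerate(envs):
        idx = np.flatnonzero(env_codes == j)
        sub = df.iloc[idx]
        cell_lines = sorted(sub["line"].unique())
        ci = pd.Categorical(sub["line"], categories=cell_lines).codes
        x_blocks.append(np.asarray(ci, dtype=np.intp))
        cell_labels.extend((line, env) for line in cell_lines)

    nested = {}
    if "rep" in random_effects:
        nested["rep"] = (df["env"] + "/" + df["rep"].astype(str)).to_numpy()
    if "block" in random_effects:
        nested["block"] = (df["env"] + "/" + df["rep"].astype(str) + "/"
                           + df["block"].astype(str)).to_numpy()
    model = VarCompModel(df["value"].to_numpy(), env_codes, nested=nested,
                         X=None, x_blocks=x_blocks)
    fit = fit_reml(model)

    cells = pd.Series(fit.beta, index=pd.MultiIndex.from_tuples(
        cell_labels, names=["line", "env"]))
    means = cells.groupby(level="line").mean()
    counts = df.groupby("line").size().reindex(means.index)
    lm = LineMeans(trait=trait, scope="overall", means=means, counts=counts)
    return (lm, fit) if return_details else lm


def _delta_se(h2_grad: dict, names: list, cov: np.ndarray) -> float:
    g = np.array([h2_grad.get(nm, 0.0) for nm in names])
    var = float(g @ cov @ g)
    return float(np.sqrt(var)) if var > 0 else 0.0


def estimate_heritability(
    plots: PlotRecords,
    trait: str,
    scope: str = "overall",
    design_effects: tuple = ("rep", "block"),
    se: bool = True,
    polish: bool = True,
) -> VarianceComponents:
    """Family-mean broad-sense heritability for the overall scope or one
    environment, with a delta-method standard error.

    ``design_effects`` controls which trial-design factors enter the random
    model alongside line (and line x environment for the overall scope);
    pass ``()`` when replicate/block labels are absent or uninformative.
    ``se=False`` skips the (numeric-Hessian) standard error for speed.
    """
    overall = scope == "overall"
    df = plots.for_trait(trait, None if overall else scope)
    if df.empty:
        raise ValueError(f"no data for trait {trait!r} in scope {scope!r}")
    _check_estimable(df)

    nested = {}
    if overall:
        nested["env"] = df["env"].to_numpy()
        nested["line_env"] = (df["line"] + "@" + df["env"]).to_numpy()
    if "rep" in design_effects:
        nested["rep"] = (df["env"] + "/" + df["rep"].astype(str)).to_numpy()
    if "block" in design_effects:
        nested["block"] = (df["env"] + "/" + df["rep"].astype(str) + "/"
                           + df["block"].astype(str)).to_numpy()
    if overall:
        groups = pd.Categorical(df["env"]).codes
        model = VarCompModel(df["value"].to_numpy(), groups, nested=nested,
                             crossed=("line", df["line"].to_numpy()),
                             cell_factor="line_env")
    else:
        nested["line"] = df["line"].to_numpy()
        model = VarCompModel(df["value"].to_numpy(), np.zeros(len(df)),
                             nested=nested)
    fit = fit_reml(model, polish=polish)

    s2g = fit.sigma2.get("line", 0.0)
    s2ge = fit.sigma2.get("line_env", 0.0) if overall else np.nan
    s2e = fit.sigma2["residual"]

    cell_counts = df.groupby(["line", "env"]).size()
    n_rep = _harmonic(cell_counts.to_numpy())
    env_counts = df.groupby("line")["env"].nunique()
    n_env = _harmonic(env_counts.to_numpy()) if overall else 1.0

    if overall:
        denom = s2g + s2ge / n_env + s2e / (n_env * n_rep)
    else:
        denom = s2g + s2e / n_rep
    h2 = s2g / denom if denom > 0 else np.nan

    h2_se = np.nan
    if se and denom > 0:
        names, cov = fit.cov_sigma2()
        if overall:
            grad = {
                "line": (denom - s2g) / denom ** 2,
                "line_env": -s2g / (n_env * denom ** 2),
                "residual": -s2g / (n_env * n_rep * denom ** 2),
            }
        else:
            grad = {
                "line": (denom - s2g) / denom ** 2,
                "residual": -s2g / (n_rep * denom ** 2),
            }
        h2_se = _delta_se(grad, names, cov)

    return VarianceComponents(
        trait=trait, scope=scope,
        sigma2_g=s2g, sigma2_ge=s2ge,
        sigma2_rep=fit.sigma2.get("rep", 0.0),
        sigma2_block=fit.sigma2.get("block", 0.0),
        sigma2_e=s2e, n_env=n_env, n_rep=n_rep,
        H2=float(np.clip(h2, 0.0, 1.0)) if np.isfinite(h2) else np.nan,
        H2_se=h2_se,
    )


def exclude_low_h2(components: VarianceComponents, threshold: float = 0.01) -> bool:
    """True when the trait should be dropped from single-environment analysis
    (strictly ``H2 < threshold``)."""
    return bool(components.H2 < threshold)
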