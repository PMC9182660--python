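"""Single-marker association scans, FDR control and the RMIP stability screen.

For a small, related panel a single GWAS pass is fragile: which markers clear
the significance filter depends heavily on which lines happen to be in the
data.  The resample model inclusion probability (RMIP) quantifies that
fragility: the scan is repeated on many random subsets of the lines (80% by
default), each subset re-filtered for minor allele frequency, re-standardized
and given fresh structure covariates, and a marker's RMIP count is the number
of subsets in which it passed the Benjamini-Hochberg filter.  Marker-trait
associations are then called *stable* when they recur across environments
(at least three, at the RMIP >= 5 / FDR 20% level), with a 6-cell threshold
grid ({FDR 20%, 5%, 1%} x {RMIP >= 5, >= 25}) recorded throughout.

The scan itself is ordinary least squares of a line-mean trait on each
marker dosage plus ``k`` principal-component covariates, with a two-sided t
test on the marker coefficient.  The genomic inflation factor of each scan
is kept as a diagnostic; p-values are never rescaled by it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import GenotypeTable, LineMeans
from .relatedness import (
    StandardizedGenotypes,
    StructureAxes,
    filter_maf,
    genomic_inflation,
    standardize,
    structure_pca,
)

__all__ = [
    "GwasResult",
    "RmipResult",
    "StableHit",
    "scan",
    "bh_fdr",
    "rmip",
    "classify_hits",
    "THRESHOLD_GRID",
]

#: the 6-cell threshold grid: (FDR level, minimum RMIP count)
THRESHOLD_GRID = [(0.20, 5), (0.20, 25), (0.05, 5), (0.05, 25), (0.01, 5), (0.01, 25)]
FDR_LEVELS = (0.20, 0.05, 0.01)


@dataclass
class GwasResult:
    """Per-marker association statistics for one scan."""

    table: pd.DataFrame  # marker, beta, se, t, p, q (NaN p for collinear markers)
    trait: str
    scope: str
    n_lines: int
    n_markers: int
    n_pcs: int
    lambda_gc: float


@dataclass
class RmipResult:
    """Resample inclusion counts for one (trait, scope) at each FDR level."""

    counts: pd.DataFrame  # index marker, one column per FDR level
    trait: str
    scope: str
    n_resamples: int
    resample_size: int
    fdr_levels: tuple
    n_degenerate: int = 0

    def at_level(self, fdr_level: float) -> pd.Series:
        return self.counts[fdr_level]


@dataclass
class StableHit:
    """A marker-trait association and the environments supporting it."""

    marker: str
    trait: str
    environments: list  # detected in, at the base (FDR 20%, RMIP >= 5) cell
    counts_by_env: dict  # env -> RMIP count at FDR 20%
    stable: bool
    grid: dict = field(default_factory=dict)  # (fdr, rmip_min) -> envs detected


def _residualize(M: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Project the columns of M off the column space of C (via QR)."""
    Q, _ = np.linalg.qr(C)
    return M - Q @ (Q.T @ M)


def scan(
    means: LineMeans,
    std: StandardizedGenotypes,
    axes: StructureAxes | None = None,
) -> GwasResult:
    """OLS association scan of a trait on each marker plus structure PCs.

    Markers collinear with the covariates are reported with a missing
    p-value (counted, never dropped).  Requires >= 10 lines shared between
    the means and the genotypes.
    """
    common = [l for l in std.line_ids if l in set(means.means.dropna().index)]
    if len(common) < 10:
        raise ValueError(f"only {len(common)} lines shared; need >= 10")
    idx = np.array([std.line_ids.index(l) for l in common])
    y = means.means.reindex(common).to_numpy(dtype=float)
    W = std.W[idx]
    n, m = W.shape

    C = np.ones((n, 1))
    k = 0
    if axes is not None:
        aidx = np.array([axes.line_ids.index(l) for l in common])
        C = np.column_stack([C, axes.coords[aidx]])
        k = axes.coords.shape[1]
    df_resid = n - C.shape[1] - 1
    if df_resid < 1:
        raise ValueError("not enough lines for the covariate set")

    yr = _residualize(y[:, None], C)[:, 0]
    Wr = _residualize(W, C)
    ss_w = np.einsum("ij,ij->j", Wr, Wr)
    ok = ss_w > 1e-10 * n
    ss_y = yr @ yr
    wy = Wr.T @ yr

    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta[ok] = wy[ok] / ss_w[ok]
        rss = ss_y - wy[ok] ** 2 / ss_w[ok]
        rss = np.maximum(rss, 0.0)
        se[ok] = np.sqrt(rss / df_resid / ss_w[ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = np.full(m, np.nan)
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df_resid)
    p[ok] = np.maximum(p[ok], np.finfo(float).tiny)  # keep p in (0, 1]

    q, _ = bh_fdr(p, 0.05)
    lam = genomic_inflation(p[ok]) if ok.any() else np.nan
    table = pd.DataFrame(
        {"marker": std.kept_marker_ids, "beta": beta, "se": se, "t": t,
         "p": p, "q": q}
    )
    return GwasResult(table=table, trait=means.trait, scope=means.scope,
                      n_lines=n, n_markers=m, n_pcs=k, lambda_gc=lam)


def bh_fdr(pvalues, q: float) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (q-values, rejection flags).

    Rejects the ``i`` smallest p-values with ``p_(i) <= i*q/m`` for the
    largest such ``i``; q-values are the monotone cumulative-minimum
    transform of ``m * p_(i) / i``.  Missing p-values are excluded from
    ``m`` and reported unrejected with missing q.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    p = np.asarray(pvalues, dtype=float)
    qvals = np.full(p.shape, np.nan)
    reject = np.zeros(p.shape, dtype=bool)
    ok = ~np.isnan(p)
    m = int(ok.sum())
    if m == 0:
        return qvals, reject
    po = p[ok]
    order = np.argsort(po, kind="stable")
    ranked = po[order] * m / np.arange(1, m + 1)
    qv = np.minimum.accumulate(ranked[::-1])[::-1]
    qv = np.minimum(qv, 1.0)
    rej_sorted = qv <= q
    qfull = np.empty(m)
    qfull[order] = qv
    rfull = np.empty(m, dtype=bool)
    rfull[order] = rej_sorted
    qvals[ok] = qfull
    reject[ok] = rfull
    return qvals, reject


def rmip(
    means: LineMeans,
    geno: GenotypeTable,
    n_resamples: int = 100,
    fraction: float = 0.8,
    fdr_levels: tuple = FDR_LEVELS,
    maf_threshold: float = 0.05,
    n_pcs: int = 5,
    seed: int = 0,
    panel_axes: StructureAxes | None = None,
) -> RmipResult:
    """Resample model inclusion counts for one trait/scope.

    Each of ``n_resamples`` draws takes ``floor(fraction * n)`` lines without
    replacement, re-filters markers for MAF within the subset, re-standardizes,
    recomputes ``n_pcs`` structure covariates on the subset (pass
    ``panel_axes`` to reuse panel-wide PCs instead), scans, and applies the
    BH filter at every requested FDR level.  A subset in which all markers
    fail the MAF filter is recorded as degenerate and skipped; count
    denominators are unchanged.
    """
    lines = [l for l in geno.line_ids if l in set(means.means.dropna().index)]
    n = len(lines)
    if n < 10:
        raise ValueError(f"panel has {n} usable lines; need >= 10")
    size = int(np.floor(fraction * n))
    rng = np.random.default_rng(seed)

    counts = pd.DataFrame(0, index=pd.Index(geno.marker_ids, name="marker"),
                          columns=list(fdr_levels))
    n_degenerate = 0
    for _ in range(n_resamples):
        sub = [lines[i] for i in rng.choice(n, size=size, replace=False)]
        try:
            g_sub = filter_maf(geno, maf_threshold, line_subset=sub)
        except ValueError:
            n_degenerate += 1
            continue
        std = standardize(g_sub)
        if panel_axes is not None:
            axes = panel_axes
        else:
            k = min(n_pcs, len(sub) - 2)
            axes = structure_pca(std, k=k) if k > 0 else None
        res = scan(means, std, axes)
        p = res.table["p"].to_numpy()
        for lev in fdr_levels:
            _, rej = bh_fdr(p, lev)
            hit_markers = res.table.loc[rej, "marker"]
            counts.loc[hit_markers, lev] += 1
    return RmipResult(counts=counts, trait=means.trait, scope=means.scope,
                      n_resamples=n_resamples, resample_size=size,
                      fdr_levels=tuple(fdr_levels), n_degenerate=n_degenerate)


def classify_hits(
    rmip_by_env: dict,
    min_envs: int = 3,
    base_fdr: float = 0.20,
    base_rmip: int = 5,
    grid=THRESHOLD_GRID,
) -> list[StableHit]:
    """Collect per-environment RMIP results into stable marker-trait hits.

    ``rmip_by_env`` maps environment id to that environment's
    :class:`RmipResult` (all for the same trait).  A marker is *stable* when
    detected (count >= ``base_rmip`` at FDR ``base_fdr``) in at least
    ``min_envs`` environments; the detected-environment sets for every
    threshold-grid cell are recorded alongside.
    """
    if not rmip_by_env:
        raise ValueError("need at least one environment's RMIP result")
    traits = {r.trait for r in rmip_by_env.values()}
    if len(traits) > 1:
        raise ValueError(f"mixed traits in one classification: {sorted(traits)}")
    trait = traits.pop()

    hits: list[StableHit] = []
    markers = sorted(set().union(*(r.counts.index for r in rmip_by_env.values())))
    for marker in markers:
        per_cell: dict = {}
        for (fdr, rmin) in grid:
            envs = [
                env for env, r in sorted(rmip_by_env.items())
                if fdr in r.counts.columns
                and marker in r.counts.index
                and r.counts.at[marker, fdr] >= rmin
            ]
            per_cell[(fdr, rmin)] = envs
        base_envs = per_cell.get((base_fdr, base_rmip), [])
        if not base_envs:
            continue
        hits.append(
            StableHit(
                marker=marker, trait=trait, environments=base_envs,
                counts_by_env={
                    env: int(rmip_by_env[env].counts.at[marker, base_fdr])
                    for env in base_envs
                },
                stable=len(base_envs) >= min_envs,
                grid=per_cell,
            )
        )
    return hits
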