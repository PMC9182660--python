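"""Cross-validation designs for genomic prediction evaluation.

Three designs mirror how a breeder would assess a genomic selection model:

* **within** — random 80/20 line splits of one set of means, repeated; the
  marker set is re-filtered for MAF within each training fold and the kernel
  rebuilt before fitting, so the test lines never inform marker selection.
* **between** — models trained on the training lines' means in environment
  ``i`` are evaluated on the held-out lines' means in environment ``j`` for
  all ordered pairs (the diagonal is the within-environment baseline).  The
  same line folds are reused across all pairs within an iteration.
* **augmentation** — for each stable GWAS hit, the within-environment CV is
  re-run with the hit as a fixed effect on *identical folds* and the change
  in prediction ability recorded.

Prediction ability is the Pearson correlation between predicted and observed
test-line means; its theoretical ceiling is sqrt(H2).  Folds are expanded
from one master seed via a counter so any run can be replayed exactly.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import GenotypeTable, LineMeans
from .gblup import fit, fit_with_hit, predict, scale_trait
from .gwas import THRESHOLD_GRID
from .relatedness import compute_grm, standardize

__all__ = [
    "CvResult",
    "TransferSummary",
    "HitDelta",
    "make_folds",
    "cv_within",
    "cv_between",
    "summarize_transfer",
    "hit_deltas",
]


@dataclass
class CvResult:
    """Prediction-ability summary for one trait and scope (or env pair)."""

    trait: str
    scope: str  # "overall", an env id, or "train_env->test_env"
    r_values: np.ndarray  # per completed iteration
    n_iterations: int  # configured count
    n_skipped: int  # degenerate folds
    fold_hash: str  # fingerprint of the fold sequence used

    @property
    def mean_r(self) -> float:
        return float(np.mean(self.r_values)) if len(self.r_values) else np.nan

    @property
    def sd_r(self) -> float:
        return float(np.std(self.r_values, ddof=1)) if len(self.r_values) > 1 else np.nan


@dataclass
class TransferSummary:
    """Between-environment ability by stratum, as a share of the baseline."""

    trait: str
    baseline: float  # mean diagonal (within-environment) ability
    strata_means: dict  # stratum -> mean ability (NaN when no pairs)
    strata_percent: dict  # stratum -> 100 * mean / baseline (NaN if baseline<=0)
    interpretation: str  # "within location is easier" / "within year is easier" / "undetermined"


@dataclass
class HitDelta:
    """Change in prediction ability from adding one GWAS hit."""

    marker: str
    trait: str
    environment: str
    cell: tuple  # (fdr, rmip_min) threshold-grid cell
    r_baseline: float
    r_augmented: float

    @property
    def delta(self) -> float:
        return self.r_augmented - self.r_baseline


STRATA = ("within_location_different_year", "within_year_different_location",
          "different_year_and_location")


def make_folds(line_ids, n_iter: int, fraction: float, seed: int):
    """Deterministic train/test line splits; iteration ``i`` uses the child
    seed ``seed + i`` of one master sequence."""
    line_ids = list(line_ids)
    n = len(line_ids)
    n_train = int(np.floor(fraction * n))
    folds = []
    for i in range(n_iter):
        rng = np.random.default_rng([seed, i])
        perm = rng.permutation(n)
        train = [line_ids[j] for j in sorted(perm[:n_train])]
        test = [line_ids[j] for j in sorted(perm[n_train:])]
        folds.append((train, test))
    return folds


def fold_hash(folds) -> str:
    h = hashlib.sha256()
    for train, test in folds:
        h.update(("|".join(train) + "#" + "|".join(test)).encode())
    return h.hexdigest()[:16]


def _fold_kernel(geno: GenotypeTable, train, test, maf_threshold: float):
    """MAF-filter on the training lines, then build K blocks for the fold.

    Markers are selected on the training set only; the centered/scaled matrix
    is computed over train+test lines with that marker set, and the training
    and cross blocks are sliced out of one panel kernel.
    """
    maf = geno.minor_allele_freq(train)
    keep = np.nan_to_num(maf, nan=0.0) > maf_threshold
    if not keep.any():
        raise ValueError("no markers pass the training-set MAF filter")
    g = geno.subset(lines=list(train) + list(test), markers=keep)
    std = standardize(g)
    grm = compute_grm(std)
    K_train = grm.submatrix(train)
    K_cross = grm.submatrix(test, train)
    return g, K_train, K_cross


def _pearson(a, b) -> float:
    if len(a) < 3 or np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(stats.pearsonr(a, b)[0])


def cv_within(
    means: LineMeans,
    geno: GenotypeTable,
    n_iter: int = 100,
    train_fraction: float = 0.8,
    seed: int = 0,
    maf_threshold: float = 0.05,
    folds=None,
    hit_dosages: pd.Series | None = None,
) -> CvResult:
    """Random 80/20 cross-validation of GBLUP on one set of line means.

    Pass ``folds`` (from :func:`make_folds`) to share splits across runs —
    the augmentation analysis depends on this.  ``hit_dosages`` (marker
    dosage per line) adds the fixed-effect marker to every fold's model.
    Folds whose test means are constant are skipped and counted.
    """
    avail = [l for l in geno.line_ids if l in set(means.means.dropna().index)]
    if len(avail) < 10:
        raise ValueError(f"only {len(avail)} lines with both genotype and mean")
    if folds is None:
        folds = make_folds(avail, n_iter, train_fraction, seed)
    rs, skipped = [], 0
    for train, test in folds:
        train = [l for l in train if l in avail]
        test = [l for l in test if l in avail]
        y_train = means.means.reindex(train).to_numpy(dtype=float)
        y_test = means.means.reindex(test).to_numpy(dtype=float)
        if len(test) < 3 or np.unique(y_test).size < 2 or np.unique(y_train).size < 2:
            skipped += 1
            continue
        try:
            g, K_train, K_cross = _fold_kernel(geno, train, test, maf_threshold)
        except ValueError:
            skipped += 1
            continue
        yt = scale_trait(y_train, line_ids=train)
        if hit_dosages is not None:
            dos_train = hit_dosages.reindex(train).to_numpy(dtype=float)
            dos_test = hit_dosages.reindex(test).to_numpy(dtype=float)
            try:
                model = fit_with_hit(K_train, yt, dos_train)
            except ValueError:  # hit monomorphic in this fold
                skipped += 1
                continue
            pred = predict(model, K_cross, marker_dosages=dos_test)
        else:
            model = fit(K_train, yt)
            pred = predict(model, K_cross)
        y_test_scaled = (y_test - yt.center) / yt.scale
        r = _pearson(pred, y_test_scaled)
        if np.isnan(r):
            skipped += 1
            continue
        rs.append(r)
    return CvResult(trait=means.trait, scope=means.scope, r_values=np.array(rs),
                    n_iterations=len(folds), n_skipped=skipped,
                    fold_hash=fold_hash(folds))


def cv_between(
    env_means: dict,
    geno: GenotypeTable,
    n_iter: int = 100,
    train_fraction: float = 0.8,
    seed: int = 0,
    maf_threshold: float = 0.05,
) -> dict:
    """Train in each environment, test held-out lines in every environment.

    ``env_means`` maps environment id to that environment's
    :class:`LineMeans`.  Returns ``{(train_env, test_env): CvResult}`` with
    all ``n_env**2`` ordered pairs; the diagonal equals within-environment
    cross-validation on that environment's means.  A trait missing in either
    environment yields a pair with no iterations (reported missing, not
    dropped).  Line folds are shared across all pairs within an iteration.
    """
    if len(env_means) < 2:
        raise ValueError("need at least 2 environments")
    envs = sorted(env_means)
    panel = list(geno.line_ids)
    folds = make_folds(panel, n_iter, train_fraction, seed)
    fh = fold_hash(folds)
    trait = next(iter(env_means.values())).trait

    rs: dict = {(a, b): [] for a in envs for b in envs}
    skipped: dict = {(a, b): 0 for a in envs for b in envs}
    for train, test in folds:
        fitted = {}
        for tr_env in envs:
            m_tr = env_means[tr_env].means.dropna()
            tr_lines = [l for l in train if l in m_tr.index]
            if len(tr_lines) < 5 or np.unique(m_tr.reindex(tr_lines)).size < 2:
                fitted[tr_env] = None
                continue
            try:
                g, K_train, K_cross = _fold_kernel(geno, tr_lines, test, maf_threshold)
            except ValueError:
                fitted[tr_env] = None
                continue
            yt = scale_trait(m_tr.reindex(tr_lines).to_numpy(), line_ids=tr_lines)
            model = fit(K_train, yt)
            pred_all = predict(model, K_cross)  # over all test lines
            fitted[tr_env] = (dict(zip(test, pred_all)), yt)
        for tr_env in envs:
            if fitted[tr_env] is None:
                for te_env in envs:
                    skipped[(tr_env, te_env)] += 1
                continue
            preds, yt = fitted[tr_env]
            for te_env in envs:
                m_te = env_means[te_env].means.dropna()
                te_lines = [l for l in test if l in m_te.index]
                if len(te_lines) < 3:
                    skipped[(tr_env, te_env)] += 1
                    continue
                obs = (m_te.reindex(te_lines).to_numpy() - yt.center) / yt.scale
                r = _pearson(np.array([preds[l] for l in te_lines]), obs)
                if np.isnan(r):
                    skipped[(tr_env, te_env)] += 1
                else:
                    rs[(tr_env, te_env)].append(r)

    return {
        pair: CvResult(trait=trait, scope=f"{pair[0]}->{pair[1]}",
                       r_values=np.array(vals), n_iterations=n_iter,
                       n_skipped=skipped[pair], fold_hash=fh)
        for pair, vals in rs.items()
    }


def summarize_transfer(pair_results: dict, env_meta: pd.DataFrame) -> TransferSummary:
    """Aggregate the between-environment grid into transfer strata.

    ``env_meta`` needs columns ``env, location, year``.  Off-diagonal pairs
    are partitioned exactly once into the three strata; each stratum's mean
    ability is also expressed as a percent of the diagonal baseline (flagged
    missing when the baseline is not positive).
    """
    meta = env_meta.set_index("env")
    diag = [res.mean_r for (a, b), res in pair_results.items()
            if a == b and len(res.r_values)]
    baseline = float(np.mean(diag)) if diag else np.nan
    buckets = {s: [] for s in STRATA}
    for (a, b), res in pair_results.items():
        if a == b or not len(res.r_values):
            continue
        same_loc = meta.at[a, "location"] == meta.at[b, "location"]
        same_year = meta.at[a, "year"] == meta.at[b, "year"]
        if same_loc and not same_year:
            buckets["within_location_different_year"].append(res.mean_r)
        elif same_year and not same_loc:
            buckets["within_year_different_location"].append(res.mean_r)
        elif not same_loc and not same_year:
            buckets["different_year_and_location"].append(res.mean_r)
        # same location and same year off-diagonal cannot occur: env = loc-year
    means = {s: (float(np.mean(v)) if v else np.nan) for s, v in buckets.items()}
    if baseline > 0:
        pct = {s: (100.0 * m / baseline if np.isfinite(m) else np.nan)
               for s, m in means.items()}
    else:
        pct = {s: np.nan for s in means}
    wl = means["within_location_different_year"]
    wy = means["within_year_different_location"]
    if np.isnan(wl) or np.isnan(wy) or wl == wy:
        interp = "undetermined"
    elif wl > wy:
        interp = "within location is easier"
    else:
        interp = "within year is easier"
    trait = next(iter(pair_results.values())).trait
    return TransferSummary(trait=trait, baseline=baseline, strata_means=means,
                           strata_percent=pct, interpretation=interp)


def hit_deltas(
    stable_hits: list,
    env_means: dict,
    geno: GenotypeTable,
    n_iter: int = 20,
    train_fraction: float = 0.8,
    seed: int = 0,
    maf_threshold: float = 0.05,
    grid=THRESHOLD_GRID,
) -> tuple[list, pd.DataFrame]:
    """Change in prediction ability from each hit, per threshold-grid cell.

    For every grid cell, the hits detected in >= 3 environments under that
    cell are evaluated in each of their detected environments: the
    within-environment CV is run with and without the hit as a fixed effect
    on identical folds, and ``delta r`` recorded.  Returns the deltas plus a
    per-cell summary table (number of hit-environment evaluations and the
    share with ``delta r > 0``), the histogram-style surface of the
    augmentation analysis.
    """
    deltas: list = []
    baseline_cache: dict = {}
    for hit in stable_hits:
        if hit.marker not in geno.marker_ids:
            continue
        j = geno.marker_ids.index(hit.marker)
        dosages = pd.Series(geno.dosages[:, j], index=geno.line_ids)
        for cell in grid:
            cell_envs = hit.grid.get(cell, [])
            if len(cell_envs) < 3:
                continue
            for env in cell_envs:
                if env not in env_means:
                    continue
                means = env_means[env]
                key = env
                if key not in baseline_cache:
                    avail = [l for l in geno.line_ids
                             if l in set(means.means.dropna().index)]
                    folds = make_folds(avail, n_iter, train_fraction, seed)
                    base = cv_within(means, geno, seed=seed, folds=folds,
                                     maf_threshold=maf_threshold)
                    baseline_cache[key] = (folds, base)
                folds, base = baseline_cache[key]
                aug = cv_within(means, geno, seed=seed, folds=folds,
                                maf_threshold=maf_threshold, hit_dosages=dosages)
                assert aug.fold_hash == base.fold_hash
                if np.isnan(base.mean_r) or np.isnan(aug.mean_r):
                    continue
                deltas.append(HitDelta(marker=hit.marker, trait=hit.trait,
                                       environment=env, cell=cell,
                                       r_baseline=base.mean_r,
                                       r_augmented=aug.mean_r))
    rows = []
    for cell in grid:
        cell_d = [d.delta for d in deltas if d.cell == cell]
        rows.append({
            "fdr": cell[0], "rmip_min": cell[1], "n_evaluations": len(cell_d),
            "share_improved": (float(np.mean(np.array(cell_d) > 0))
                               if cell_d else np.nan),
            "mean_delta": float(np.mean(cell_d)) if cell_d else np.nan,
        })
    return deltas, pd.DataFrame(rows)
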