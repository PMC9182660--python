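"""Marker filtering, standardization, genomic relationships and structure.

The genomic relationship matrix (GRM) used throughout is the correlation-type
kernel ``K = W W' / m`` where ``W`` is the centered, scaled (sample standard
deviation, ``ddof=1``) dosage matrix and ``m`` the number of markers kept.
Under this scaling ``mean(diag(K)) = (n - 1) / n`` identically.  Population
structure is summarized by the leading principal components of ``K`` and the
adequacy of the correction is monitored with the genomic inflation factor
``lambda_gc``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import GenotypeTable

__all__ = [
    "StandardizedGenotypes",
    "Grm",
    "StructureAxes",
    "filter_maf",
    "standardize",
    "compute_grm",
    "structure_pca",
    "genomic_inflation",
]


@dataclass
class StandardizedGenotypes:
    """Centered, scaled dosages with the imputation record."""

    W: np.ndarray  # (n_lines, m)
    line_ids: list[str]
    kept_marker_ids: list[str]
    impute_means: np.ndarray  # per-marker mean dosage used for missing calls

    @property
    def m(self) -> int:
        return len(self.kept_marker_ids)


@dataclass
class Grm:
    """Line x line genomic relationship matrix ``K = W W' / m``."""

    K: np.ndarray
    line_ids: list[str]
    m: int

    def index(self, line_ids) -> np.ndarray:
        lookup = {l: i for i, l in enumerate(self.line_ids)}
        try:
            return np.array([lookup[l] for l in line_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"line {exc.args[0]!r} not in GRM") from None

    def submatrix(self, rows, cols=None) -> np.ndarray:
        ri = self.index(rows)
        ci = ri if cols is None else self.index(cols)
        return self.K[np.ix_(ri, ci)]


@dataclass
class StructureAxes:
    """Principal-component coordinates (eigenvectors scaled by sqrt(eigenvalue))."""

    coords: np.ndarray  # (n_lines, k)
    eigenvalues: np.ndarray  # (k,)
    line_ids: list[str]


def filter_maf(geno: GenotypeTable, threshold: float = 0.05,
               line_subset=None) -> GenotypeTable:
    """Drop markers whose minor allele frequency is <= ``threshold``.

    Frequency is the mean non-missing dosage / 2 folded at 0.5, computed
    within ``line_subset`` when given (the retention rule is strict:
    only MAF strictly above the threshold survives).
    """
    if not 0 <= threshold < 0.5:
        raise ValueError("threshold must be in [0, 0.5)")
    maf = geno.minor_allele_freq(line_subset)
    keep = np.nan_to_num(maf, nan=0.0) > threshold
    if not keep.any():
        raise ValueError(
            "all markers removed by the MAF filter; lower the threshold or "
            "check the line subset"
        )
    out = geno.subset(markers=keep)
    if line_subset is not None:
        out = out.subset(lines=line_subset)
    return out


def standardize(geno: GenotypeTable) -> StandardizedGenotypes:
    """Mean-impute missing calls per marker, then center and scale each column.

    Scaling uses the sample standard deviation (``ddof=1``).  Zero-variance
    (monomorphic) columns are rejected: run :func:`filter_maf` first.
    """
    D = geno.dosages.copy()
    n = D.shape[0]
    n_obs = np.sum(~np.isnan(D), axis=0)
    if (n_obs == 0).any():
        j = int(np.argmax(n_obs == 0))
        raise ValueError(f"marker {geno.marker_ids[j]!r} has no observed calls")
    mu = np.nanmean(D, axis=0)
    r, c = np.where(np.isnan(D))
    D[r, c] = mu[c]
    center = D.mean(axis=0)
    sd = D.std(axis=0, ddof=1)
    if (sd <= 0).any():
        j = int(np.argmax(sd <= 0))
        raise ValueError(
            f"marker {geno.marker_ids[j]!r} has zero variance; filter first"
        )
    W = (D - center) / sd
    return StandardizedGenotypes(
        W=W, line_ids=list(geno.line_ids),
        kept_marker_ids=list(geno.marker_ids), impute_means=mu,
    )


def compute_grm(std: StandardizedGenotypes) -> Grm:
    """``K = W W' / m`` over the kept markers."""
    if std.m < 1:
        raise ValueError("need at least one marker")
    K = std.W @ std.W.T / std.m
    K = (K + K.T) / 2.0  # enforce exact symmetry against rounding
    return Grm(K=K, line_ids=list(std.line_ids), m=std.m)


def structure_pca(std: StandardizedGenotypes, k: int = 5) -> StructureAxes:
    """Leading principal components of the GRM for structure correction.

    Coordinates are eigenvectors scaled by the square root of their
    eigenvalue, with a deterministic sign convention (the largest-magnitude
    loading of each axis is made positive).
    """
    n = len(std.line_ids)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of lines ({n})")
    K = compute_grm(std).K
    evals, evecs = np.linalg.eigh(K)
    order = np.argsort(evals)[::-1][:k]
    evals = evals[order]
    evecs = evecs[:, order]
    for j in range(k):
        i = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    coords = evecs * np.sqrt(np.maximum(evals, 0.0))
    return StructureAxes(coords=coords, eigenvalues=evals,
                         line_ids=list(std.line_ids))


_CHI2_MEDIAN_1DF = stats.chi2.ppf(0.5, df=1)  # 0.454936...


def genomic_inflation(pvalues) -> float:
    """Genomic inflation factor: median 1-df chi-square statistic / null median.

    ``lambda_gc`` near 1 indicates the structure correction leaves the bulk of
    the test statistics at their null calibration.  Missing p-values are
    ignored; an empty input is an error.
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)  # quantile of 1 - p
    return float(np.median(chi2) / _CHI2_MEDIAN_1DF)
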