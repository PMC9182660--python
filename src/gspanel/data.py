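"""Core data containers shared across the pipeline.

Two raw inputs drive everything downstream: a table of additively coded SNP
dosages for a panel of inbred lines (:class:`GenotypeTable`) and plot-level
phenotype records from multi-environment field trials (:class:`PlotRecords`).
An *environment* is a location-year combination, e.g. ``"Florence-2006"``;
replicates are nested in environments and incomplete blocks in replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeTable", "PlotRecords", "LineMeans", "env_id"]

#: column order expected of a plot-record frame (plus one or more trait columns
#: when in wide form; the canonical long form has "trait" and "value")
PLOT_COLUMNS = ["line", "location", "year", "rep", "block", "trait", "value"]


def env_id(location: str, year: int | str) -> str:
    """Build the canonical environment identifier ``"<location>-<year>"``."""
    return f"{location}-{year}"


@dataclass
class GenotypeTable:
    """Panel of lines x SNP dosages plus a marker map.

    Dosages count copies of the counted allele (0, 1 or 2); missing calls are
    ``NaN``.  Markers are kept sorted by (chromosome, position).
    """

    line_ids: list[str]
    marker_ids: list[str]
    chrom: np.ndarray  # per-marker chromosome label (str)
    pos: np.ndarray  # per-marker 1-based bp position (int)
    dosages: np.ndarray  # (n_lines, n_markers) float, NaN = missing

    def __post_init__(self) -> None:
        self.line_ids = list(self.line_ids)
        self.marker_ids = list(self.marker_ids)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosages = np.asarray(self.dosages, dtype=float)

    # -- basic properties -------------------------------------------------
    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def validate(self) -> None:
        """Check the container invariants; raise ``ValueError`` on violation."""
        if len(set(self.line_ids)) != self.n_lines:
            raise ValueError("duplicate line ids")
        if len(set(self.marker_ids)) != self.n_markers:
            raise ValueError("duplicate marker ids")
        if self.dosages.shape != (self.n_lines, self.n_markers):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{self.n_lines} lines x {self.n_markers} markers"
            )
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            bad = vals[~np.isin(vals, (0.0, 1.0, 2.0))][0]
            raise ValueError(f"dosage entries must be 0/1/2/missing, found {bad!r}")
        # markers sorted by (chrom, pos); chromosome labels compare as strings
        order = np.lexsort((self.pos, self.chrom.astype(str)))
        if not np.array_equal(order, np.arange(self.n_markers)):
            raise ValueError("markers must be sorted by (chrom, pos)")

    # -- subsetting -------------------------------------------------------
    def line_index(self, line_ids) -> np.ndarray:
        lookup = {l: i for i, l in enumerate(self.line_ids)}
        try:
            return np.array([lookup[l] for l in line_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message only
            raise KeyError(f"unknown line id {exc.args[0]!r}") from None

    def subset(self, lines=None, markers=None) -> "GenotypeTable":
        """Return a copy restricted to the given line ids and/or marker mask.

        ``markers`` is a boolean mask or integer index array over markers; the
        relative marker order (and thus map sorting) is preserved.
        """
        li = np.arange(self.n_lines) if lines is None else self.line_index(lines)
        if markers is None:
            mi = np.arange(self.n_markers)
        else:
            mi = np.asarray(markers)
            if mi.dtype == bool:
                mi = np.flatnonzero(mi)
        return GenotypeTable(
            line_ids=[self.line_ids[i] for i in li],
            marker_ids=[self.marker_ids[j] for j in mi],
            chrom=self.chrom[mi],
            pos=self.pos[mi],
            dosages=self.dosages[np.ix_(li, mi)].copy(),
        )

    def allele_freq(self, lines=None) -> np.ndarray:
        """Counted-allele frequency per marker (mean dosage / 2) over non-missing
        calls, optionally within a line subset."""
        d = self.dosages if lines is None else self.dosages[self.line_index(lines)]
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def minor_allele_freq(self, lines=None) -> np.ndarray:
        """Allele frequency folded at 0.5 (monomorphic markers give 0)."""
        p = self.allele_freq(lines)
        return np.minimum(p, 1.0 - p)


@dataclass
class PlotRecords:
    """Plot-level multi-environment phenotype records in long form.

    Wraps a DataFrame with columns ``line, location, year, rep, block, trait,
    value``.  The key (line, environment, rep, trait) must be unique and every
    block label is local to its replicate (i.e. the full block identity is the
    (env, rep, block) triple).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PLOT_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"plot records missing columns {missing}")
        df = self.df.copy()
        df["year"] = df["year"].astype(int)
        df["value"] = pd.to_numeric(df["value"], errors="raise")
        df["env"] = df["location"].astype(str) + "-" + df["year"].astype(str)
        self.df = df.reset_index(drop=True)

    def validate(self) -> None:
        key = ["line", "env", "rep", "trait"]
        dup = self.df.duplicated(subset=key)
        if dup.any():
            first = self.df.loc[dup.idxmax(), key].tolist()
            raise ValueError(f"duplicate plot record key {first}")
        vals = self.df["value"]
        if np.isinf(vals.fillna(0.0)).any():
            raise ValueError("plot values must be finite or missing")

    # -- accessors ---------------------------------------------------------
    @property
    def environments(self) -> list[str]:
        return sorted(self.df["env"].unique())

    @property
    def traits(self) -> list[str]:
        return sorted(self.df["trait"].unique())

    @property
    def lines(self) -> list[str]:
        return sorted(self.df["line"].unique())

    def env_meta(self) -> pd.DataFrame:
        """One row per environment with its location and year."""
        meta = (
            self.df[["env", "location", "year"]]
            .drop_duplicates()
            .sort_values("env")
            .reset_index(drop=True)
        )
        return meta

    def for_trait(self, trait: str, env: str | None = None) -> pd.DataFrame:
        """Rows for one trait (optionally one environment), missing values dropped."""
        sel = self.df[self.df["trait"] == trait]
        if env is not None:
            sel = sel[sel["env"] == env]
        return sel.dropna(subset=["value"]).reset_index(drop=True)


@dataclass
class LineMeans:
    """Estimated line means for one trait in one scope.

    ``scope`` is ``"overall"`` or an environment id.  Lines with no data in
    the scope are absent from the series (never zero-filled).
    """

    trait: str
    scope: str
    means: pd.Series  # index = line ids
    counts: pd.Series = field(default=None)  # contributing plots per line

    def __post_init__(self) -> None:
        self.means = pd.Series(self.means, dtype=float)
        if self.means.index.has_duplicates:
            raise ValueError("duplicate line ids in line means")
        if self.counts is None:
            self.counts = pd.Series(np.nan, index=self.means.index)
        else:
            self.counts = pd.Series(self.counts).reindex(self.means.index)

    @property
    def line_ids(self) -> list[str]:
        return list(self.means.index)

    def aligned(self, line_ids) -> np.ndarray:
        """Values for the requested lines (NaN where absent)."""
        return self.means.reindex(line_ids).to_numpy()
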