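"""Readers and writers for the pipeline's file formats.

Genotypes travel as PLINK ``recode A``-style ``.raw`` dosage tables (FID IID
PAT MAT SEX PHENOTYPE then one ``<marker>_<allele>`` column per SNP) plus a
4-column ``.map`` (chrom, id, genetic position, bp position); a read-only
VCF path derives dosages from GT fields.  Phenotypes, means, variance
components, scan results and CV summaries are tab-separated text with ``.``
for missing values and a ``#`` header comment carrying the tool version and,
when available, the run-configuration hash, so outputs round-trip and
identify themselves.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import __version__
from .data import GenotypeTable, PlotRecords

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "write_table",
    "read_table",
]

_RAW_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
MISSING = "."


def _strip_allele(col: str) -> str:
    """``SNP1_A`` -> ``SNP1`` (PLINK appends the counted allele)."""
    return col.rsplit("_", 1)[0] if "_" in col else col


def read_genotypes(path, map_path=None, fmt: str = "plink_raw") -> GenotypeTable:
    """Read a dosage table (PLINK ``.raw`` or VCF) into a GenotypeTable."""
    if fmt == "plink_raw":
        return _read_raw(path, map_path)
    if fmt == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_raw(path, map_path=None) -> GenotypeTable:
    with open(path) as fh:
        header = fh.readline().split()
        if header[: len(_RAW_META)] != _RAW_META:
            raise ValueError(
                f"{path}: header must start with {' '.join(_RAW_META)}"
            )
        marker_ids = [_strip_allele(c) for c in header[len(_RAW_META):]]
        n_cols = len(header)
        line_ids, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != n_cols:
                raise ValueError(
                    f"{path}:{lineno}: expected {n_cols} fields, got {len(tok)}"
                )
            iid = tok[1]
            if iid in line_ids:
                raise ValueError(f"{path}:{lineno}: duplicate IID {iid!r}")
            line_ids.append(iid)
            vals = np.empty(len(marker_ids))
            for j, t in enumerate(tok[len(_RAW_META):]):
                if t in ("NA", MISSING):
                    vals[j] = np.nan
                elif t in ("0", "1", "2"):
                    vals[j] = float(t)
                else:
                    raise ValueError(
                        f"{path}:{lineno}: bad dosage {t!r} in column "
                        f"{marker_ids[j]!r} (must be 0/1/2/NA)"
                    )
            rows.append(vals)
    dosages = np.array(rows) if rows else np.empty((0, len(marker_ids)))

    if map_path is not None:
        mp = pd.read_csv(map_path, sep=r"\s+", header=None,
                         names=["chrom", "marker", "cm", "pos"], dtype={"chrom": str})
        mp = mp.set_index("marker")
        missing = [m for m in marker_ids if m not in mp.index]
        if missing:
            raise ValueError(f"{map_path}: no map entry for marker {missing[0]!r}")
        chrom = mp.loc[marker_ids, "chrom"].to_numpy(dtype=object)
        pos = mp.loc[marker_ids, "pos"].to_numpy(dtype=np.int64)
    else:
        chrom = np.array(["0"] * len(marker_ids), dtype=object)
        pos = np.arange(1, len(marker_ids) + 1, dtype=np.int64)

    geno = GenotypeTable(line_ids, marker_ids, chrom, pos, dosages)
    order = np.lexsort((geno.pos, geno.chrom.astype(str)))
    geno = geno.subset(markers=order)
    geno.validate()
    return geno


def _read_vcf(path) -> GenotypeTable:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("VCF support needs the cyvcf2 package") from exc
    vcf = VCF(str(path))
    line_ids = list(vcf.samples)
    marker_ids, chrom, pos, rows = [], [], [], []
    for var in vcf:
        gts = var.genotype.array()
        if gts.shape[1] < 3:
            raise ValueError(f"{path}: {var.ID or var.POS}: calls must be diploid")
        alleles = gts[:, :2]
        dos = np.where((alleles < 0).any(axis=1), np.nan,
                       alleles.clip(min=0).sum(axis=1).astype(float))
        if np.nanmax(dos, initial=0) > 2:
            raise ValueError(f"{path}: {var.ID or var.POS}: multi-allelic call")
        marker_ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        chrom.append(var.CHROM)
        pos.append(var.POS)
        rows.append(dos)
    dosages = np.array(rows).T if rows else np.empty((len(line_ids), 0))
    geno = GenotypeTable(line_ids, marker_ids, np.array(chrom, dtype=object),
                         np.array(pos), dosages)
    order = np.lexsort((geno.pos, geno.chrom.astype(str)))
    geno = geno.subset(markers=order)
    geno.validate()
    return geno


def write_genotypes(geno: GenotypeTable, raw_path, map_path) -> None:
    """Write PLINK-compatible ``.raw`` + ``.map`` text files."""
    with open(raw_path, "w") as fh:
        cols = [f"{m}_A" for m in geno.marker_ids]
        fh.write(" ".join(_RAW_META + cols) + "\n")
        for i, lid in enumerate(geno.line_ids):
            vals = [
                "NA" if np.isnan(v) else str(int(v)) for v in geno.dosages[i]
            ]
            fh.write(" ".join([lid, lid, "0", "0", "0", "-9"] + vals) + "\n")
    with open(map_path, "w") as fh:
        for m, c, p in zip(geno.marker_ids, geno.chrom, geno.pos):
            fh.write(f"{c}\t{m}\t0\t{p}\n")


def read_phenotypes(path) -> PlotRecords:
    """Read plot records from TSV (long or wide trait layout).

    The header must begin ``line location year rep block``; remaining
    columns are either ``trait value`` (long form) or one column per trait
    (wide form, blank/``.`` cells meaning not measured).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"line": str},
                     na_values=[MISSING, ""])
    required = ["line", "location", "year", "rep", "block"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    rest = [c for c in df.columns if c not in required]
    if rest == ["trait", "value"]:
        long = df
    else:
        long = df.melt(id_vars=required, value_vars=rest,
                       var_name="trait", value_name="value")
    try:
        long["value"] = pd.to_numeric(long["value"])
    except (ValueError, TypeError) as exc:
        bad = long[pd.to_numeric(long["value"], errors="coerce").isna()
                   & long["value"].notna()].iloc[0]
        raise ValueError(
            f"{path}: non-numeric value {bad['value']!r} for line "
            f"{bad['line']!r}, trait {bad['trait']!r}"
        ) from exc
    plots = PlotRecords(long[required + ["trait", "value"]])
    plots.validate()
    return plots


def write_phenotypes(plots: PlotRecords, path, comment: str | None = None) -> None:
    df = plots.df[["line", "location", "year", "rep", "block", "trait", "value"]]
    write_table(df, path, comment=comment)


def write_table(df: pd.DataFrame, path, comment: str | None = None) -> None:
    """TSV writer with a version header comment and ``.`` for missing."""
    with open(path, "w") as fh:
        fh.write(f"# gspanel {__version__}" + (f" {comment}" if comment else "") + "\n")
        df.to_csv(fh, sep="\t", index=False, na_rep=MISSING)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=[MISSING])
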