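"""Pipeline driver: run the full evaluation from one configuration.

Stages run in dependency order — simulate (or load) -> means/heritability ->
GRM/PCA -> GWAS/RMIP/classification -> cross-validation/transfer/
augmentation — and every output file is recorded with a content hash in a
JSON manifest, together with stage timings and the effective seeds, so a run
can be replayed and checked bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .crossval import cv_between, cv_within, hit_deltas, summarize_transfer
from .data import PlotRecords
from .gwas import FDR_LEVELS, classify_hits, rmip, scan
from .io import (
    read_genotypes,
    read_phenotypes,
    write_genotypes,
    write_phenotypes,
    write_table,
)
from .relatedness import filter_maf, standardize, compute_grm, structure_pca
from .simpanel import SimConfig, simulate_genotypes, simulate_trials
from .trial_means import (
    estimate_heritability,
    exclude_low_h2,
    fit_environment_means,
    fit_overall_means,
)

__all__ = ["RunConfig", "run_pipeline", "DEFAULT_STAGES"]

DEFAULT_STAGES = ("simulate", "means", "heritability", "grm", "gwas", "rmip",
                  "classify", "crossval", "augment")

_DEPENDS = {
    "means": ("simulate",),
    "heritability": ("simulate",),
    "grm": ("simulate",),
    "gwas": ("means", "grm"),
    "rmip": ("means",),
    "classify": ("rmip",),
    "crossval": ("means", "grm"),
    "augment": ("classify", "crossval"),
}


@dataclass
class RunConfig:
    """Everything a pipeline run needs; loadable from YAML."""

    outdir: str = "gspanel_out"
    stages: tuple = DEFAULT_STAGES
    seed: int = 0
    # either simulate ...
    sim: SimConfig | None = None
    traits: list = field(default_factory=lambda: [{"name": "sim_trait"}])
    # ... or load from files
    genotypes: str | None = None
    marker_map: str | None = None
    phenotypes: str | None = None
    # thresholds
    maf: float = 0.05
    n_pcs: int = 5
    fdr_levels: tuple = FDR_LEVELS
    rmip_resamples: int = 100
    rmip_min: int = 5
    min_envs: int = 3
    cv_iterations: int = 100
    between_iterations: int = 20
    augment_iterations: int = 20

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim is not None:
            if "qtls" in sim:
                sim["qtls"] = [tuple(q) for q in sim["qtls"]]
            if "founder_maf_range" in sim:
                sim["founder_maf_range"] = tuple(sim["founder_maf_range"])
            cfg.sim = SimConfig(**sim)
        cfg.stages = tuple(cfg.stages)
        cfg.fdr_levels = tuple(cfg.fdr_levels)
        return cfg

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        if self.sim is not None:
            d["sim"] = dataclasses.asdict(self.sim)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def validate(self) -> None:
        for s in self.stages:
            if s not in DEFAULT_STAGES:
                raise ValueError(f"unknown stage {s!r}")
            for dep in _DEPENDS.get(s, ()):
                if dep == "simulate":
                    if "simulate" not in self.stages and self.genotypes is None:
                        raise ValueError(f"stage {s!r} needs genotype input")
                elif dep not in self.stages:
                    raise ValueError(f"stage {s!r} requires stage {dep!r}")
        if "simulate" in self.stages and self.sim is None:
            self.sim = SimConfig(seed=self.seed)
        if not 0 <= self.maf < 0.5:
            raise ValueError("maf threshold must be in [0, 0.5)")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages and return (and write) the run manifest."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    comment = f"config={chash}"
    manifest = {"version": __version__, "config_hash": chash,
                "seed": config.seed, "stages": {}, "files": {}}

    def record(name: str, path: Path):
        manifest["files"][name] = {"path": str(path), "sha256": _sha256(path)}

    def stage(name):
        t0 = time.perf_counter()
        entry = manifest["stages"].setdefault(name, {})
        return lambda: entry.update(
            {"seconds": round(time.perf_counter() - t0, 3)}
        )

    # ---------------- simulate / load ----------------
    done = stage("simulate")
    plots_by_trait: dict[str, PlotRecords] = {}
    if "simulate" in config.stages:
        geno, pedigree = simulate_genotypes(config.sim)
        frames = []
        for i, tr in enumerate(config.traits):
            tcfg = dataclasses.replace(
                config.sim,
                seed=config.sim.seed + 1000 + i,
                **{k: v for k, v in tr.items() if k.startswith("var_")},
            )
            if "qtls" in tr:
                tcfg = dataclasses.replace(tcfg, qtls=[tuple(q) for q in tr["qtls"]])
            p, truth = simulate_trials(geno, tcfg, trait=tr["name"])
            frames.append(p.df.drop(columns="env"))
            truth.breeding_values.rename("tbv").to_frame().reset_index(names="line") \
                .pipe(write_table, out / f"truth_tbv_{tr['name']}.tsv", comment=comment)
        plots = PlotRecords(pd.concat(frames, ignore_index=True))
        write_genotypes(geno, out / "panel.raw", out / "panel.map")
        write_table(pedigree, out / "pedigree.tsv", comment=comment)
        write_phenotypes(plots, out / "plots.tsv", comment=comment)
        record("genotypes", out / "panel.raw")
        record("plots", out / "plots.tsv")
        manifest["stages"]["simulate"]["seed"] = config.sim.seed
    else:
        geno = read_genotypes(config.genotypes, config.marker_map)
        plots = read_phenotypes(config.phenotypes)
    done()
    traits = sorted(plots.traits)
    envs = plots.environments

    # ---------------- means ----------------
    overall_means, env_means = {}, {t: {} for t in traits}
    if "means" in config.stages:
        done = stage("means")
        rows = []
        for t in traits:
            lm = fit_overall_means(plots, t)
            overall_means[t] = lm
            rows += [(t, "overall", l, v, c) for (l, v), c in
                     zip(lm.means.items(), lm.counts)]
            for env in envs:
                em = fit_environment_means(plots, env, t)
                env_means[t][env] = em
                rows += [(t, env, l, v, c) for (l, v), c in
                         zip(em.means.items(), em.counts)]
        write_table(pd.DataFrame(rows, columns=["trait", "scope", "line", "mean",
                                                "n_plots"]),
                    out / "line_means.tsv", comment=comment)
        record("line_means", out / "line_means.tsv")
        done()

    # ---------------- heritability ----------------
    h2_excluded = {t: set() for t in traits}
    if "heritability" in config.stages:
        done = stage("heritability")
        rows = []
        for t in traits:
            vc = estimate_heritability(plots, t, "overall")
            rows.append((t, "overall", vc.sigma2_g, vc.sigma2_ge, vc.sigma2_rep,
                         vc.sigma2_block, vc.sigma2_e, vc.n_env, vc.n_rep,
                         vc.H2, vc.H2_se, False))
            for env in envs:
                if plots.for_trait(t, env).empty:
                    continue
                vce = estimate_heritability(plots, t, env)
                excl = exclude_low_h2(vce)
                if excl:
                    h2_excluded[t].add(env)
                rows.append((t, env, vce.sigma2_g, np.nan, vce.sigma2_rep,
                             vce.sigma2_block, vce.sigma2_e, 1, vce.n_rep,
                             vce.H2, vce.H2_se, excl))
        write_table(
            pd.DataFrame(rows, columns=[
                "trait", "scope", "sigma2_g", "sigma2_ge", "sigma2_rep",
                "sigma2_block", "sigma2_e", "n_env", "n_rep", "H2", "H2_se",
                "excluded"]),
            out / "heritability.tsv", comment=comment)
        record("heritability", out / "heritability.tsv")
        done()

    # ---------------- grm / pca ----------------
    grm = axes = std = None
    if "grm" in config.stages:
        done = stage("grm")
        filt = filter_maf(geno, config.maf)
        std = standardize(filt)
        grm = compute_grm(std)
        axes = structure_pca(std, k=min(config.n_pcs, std.W.shape[0] - 1))
        kdf = pd.DataFrame(grm.K, index=grm.line_ids, columns=grm.line_ids)
        write_table(kdf.reset_index(names="line"), out / "grm.tsv", comment=comment)
        pdf = pd.DataFrame(axes.coords, index=axes.line_ids,
                           columns=[f"PC{i+1}" for i in range(axes.coords.shape[1])])
        write_table(pdf.reset_index(names="line"), out / "pca.tsv", comment=comment)
        record("grm", out / "grm.tsv")
        record("pca", out / "pca.tsv")
        done()

    # ---------------- gwas scans (diagnostic single pass) ----------------
    if "gwas" in config.stages:
        done = stage("gwas")
        rows = []
        lam_rows = []
        for t in traits:
            res = scan(overall_means[t], std, axes)
            tab = res.table.assign(trait=t, scope="overall")
            rows.append(tab)
            # genomic-inflation diagnostic across PC counts
            for k in range(0, min(11, std.W.shape[0] - 3)):
                ax_k = structure_pca(std, k=k) if k else None
                lam = scan(overall_means[t], std, ax_k).lambda_gc
                lam_rows.append((t, k, lam))
        write_table(pd.concat(rows, ignore_index=True)[
            ["trait", "scope", "marker", "beta", "se", "t", "p", "q"]],
            out / "gwas_scan.tsv", comment=comment)
        write_table(pd.DataFrame(lam_rows, columns=["trait", "n_pcs", "lambda_gc"]),
                    out / "lambda_diagnostic.tsv", comment=comment)
        record("gwas_scan", out / "gwas_scan.tsv")
        done()

    # ---------------- rmip ----------------
    rmip_results = {t: {} for t in traits}
    if "rmip" in config.stages:
        done = stage("rmip")
        rows = []
        for ti, t in enumerate(traits):
            scopes = {"overall": overall_means[t]}
            scopes.update({e: m for e, m in env_means[t].items()
                           if e not in h2_excluded[t] and len(m.means)})
            for si, (scope_name, m) in enumerate(sorted(scopes.items())):
                r = rmip(m, geno, n_resamples=config.rmip_resamples,
                         fdr_levels=config.fdr_levels, maf_threshold=config.maf,
                         n_pcs=config.n_pcs,
                         seed=config.seed + 7919 * ti + 104729 * si)
                if scope_name != "overall":
                    rmip_results[t][scope_name] = r
                nz = r.counts[(r.counts > 0).any(axis=1)]
                for marker, row in nz.iterrows():
                    rows.append((t, scope_name, marker,
                                 *[int(row[lev]) for lev in config.fdr_levels]))
        cols = ["trait", "scope", "marker"] + [f"count_fdr{int(l*100)}"
                                               for l in config.fdr_levels]
        write_table(pd.DataFrame(rows, columns=cols), out / "rmip.tsv",
                    comment=comment)
        record("rmip", out / "rmip.tsv")
        done()

    # ---------------- classify ----------------
    hits_by_trait = {}
    if "classify" in config.stages:
        done = stage("classify")
        rows = []
        for t in traits:
            if not rmip_results[t]:
                hits_by_trait[t] = []
                continue
            hits = classify_hits(rmip_results[t], min_envs=config.min_envs,
                                 base_rmip=config.rmip_min)
            hits_by_trait[t] = hits
            for h in hits:
                row = {"trait": t, "marker": h.marker, "stable": h.stable,
                       "n_envs": len(h.environments),
                       "environments": ",".join(h.environments)}
                for (fdr, rmin), envs_cell in h.grid.items():
                    row[f"fdr{int(fdr*100)}_rmip{rmin}"] = len(envs_cell)
                rows.append(row)
        write_table(pd.DataFrame(rows), out / "stable_hits.tsv", comment=comment)
        record("stable_hits", out / "stable_hits.tsv")
        done()

    # ---------------- crossval ----------------
    env_pair_results = {}
    if "crossval" in config.stages:
        done = stage("crossval")
        rows, srows = [], []
        for t in traits:
            cv = cv_within(overall_means[t], geno, n_iter=config.cv_iterations,
                           seed=config.seed, maf_threshold=config.maf)
            srows.append((t, "overall", cv.mean_r, cv.sd_r, len(cv.r_values)))
            rows += [(t, "overall", i, r) for i, r in enumerate(cv.r_values)]
            usable = {e: m for e, m in env_means[t].items()
                      if len(m.means) and e not in h2_excluded[t]}
            if len(usable) >= 2:
                pairs = cv_between(usable, geno, n_iter=config.between_iterations,
                                   seed=config.seed, maf_threshold=config.maf)
                env_pair_results[t] = pairs
                for (a, b), res in sorted(pairs.items()):
                    srows.append((t, f"{a}->{b}", res.mean_r, res.sd_r,
                                  len(res.r_values)))
                ts = summarize_transfer(pairs, plots.env_meta())
                for s in ts.strata_means:
                    srows.append((t, f"stratum:{s}", ts.strata_means[s], np.nan,
                                  np.nan))
                write_table(pd.DataFrame(
                    [(t, s, ts.strata_means[s], ts.strata_percent[s],
                      ts.baseline, ts.interpretation) for s in ts.strata_means],
                    columns=["trait", "stratum", "mean_r", "percent_of_within",
                             "within_baseline", "interpretation"]),
                    out / f"transfer_{t}.tsv", comment=comment)
        write_table(pd.DataFrame(rows, columns=["trait", "scope", "iteration", "r"]),
                    out / "cv_iterations.tsv", comment=comment)
        write_table(pd.DataFrame(srows, columns=["trait", "scope", "mean_r",
                                                 "sd_r", "n_iter"]),
                    out / "cv_summary.tsv", comment=comment)
        record("cv_summary", out / "cv_summary.tsv")
        done()

    # ---------------- augmentation ----------------
    if "augment" in config.stages:
        done = stage("augment")
        rows, hrows = [], []
        for t in traits:
            hits = [h for h in hits_by_trait.get(t, []) if h.stable]
            if not hits:
                continue
            usable = {e: m for e, m in env_means[t].items() if len(m.means)}
            deltas, hist = hit_deltas(hits, usable, geno,
                                      n_iter=config.augment_iterations,
                                      seed=config.seed, maf_threshold=config.maf)
            for d in deltas:
                rows.append((t, d.marker, d.environment, d.cell[0], d.cell[1],
                             d.r_baseline, d.r_augmented, d.delta))
            hrows.append(hist.assign(trait=t))
        write_table(pd.DataFrame(rows, columns=[
            "trait", "marker", "environment", "fdr", "rmip_min", "r_baseline",
            "r_augmented", "delta_r"]), out / "hit_deltas.tsv", comment=comment)
        if hrows:
            write_table(pd.concat(hrows, ignore_index=True),
                        out / "hit_delta_summary.tsv", comment=comment)
            record("hit_delta_summary", out / "hit_delta_summary.tsv")
        record("hit_deltas", out / "hit_deltas.tsv")
        done()

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
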