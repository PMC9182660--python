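"""Shared fixtures: small simulated panels reused across test modules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from gspanel.data import GenotypeTable, PlotRecords
from gspanel.simpanel import SimConfig, simulate_genotypes, simulate_trials

settings.register_profile("deterministic", derandomize=True, max_examples=25)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_panel():
    """40-line, 400-SNP panel with 6 environments; cheap enough for reuse."""
    cfg = SimConfig(seed=42, n_lines=40, n_snps=400, n_locations=3, n_years=2)
    geno, pedigree = simulate_genotypes(cfg)
    plots, truth = simulate_trials(geno, cfg)
    return cfg, geno, pedigree, plots, truth


@pytest.fixture(scope="session")
def panel80():
    """Study-shaped panel: 80 lines, 2000 SNPs, 14 location-year trials."""
    cfg = SimConfig(seed=7)
    geno, pedigree = simulate_genotypes(cfg)
    plots, truth = simulate_trials(geno, cfg)
    return cfg, geno, pedigree, plots, truth


def make_balanced_plots(n_lines=8, n_loc=2, n_years=2, n_reps=2, seed=0,
                        var_g=1.0, var_env=0.5, var_ge=0.3, var_e=0.4,
                        complete_blocks=True):
    """Hand-rolled balanced trial table with complete blocks (block == rep),
    so GLS genotype means coincide with arithmetic means."""
    rng = np.random.default_rng(seed)
    lines = [f"L{i:02d}" for i in range(n_lines)]
    g = rng.normal(0, np.sqrt(var_g), n_lines)
    rows = []
    for loc in range(n_loc):
        for yr in range(n_years):
            e = rng.normal(0, np.sqrt(var_env))
            ge = rng.normal(0, np.sqrt(var_ge), n_lines)
            for rep in range(n_reps):
                for i, line in enumerate(lines):
                    eps = rng.normal(0, np.sqrt(var_e))
                    block = "blk1" if complete_blocks else f"blk{i % 2 + 1}"
                    rows.append((line, f"Loc{loc+1}", 2004 + yr, f"rep{rep+1}",
                                 block, "trait", g[i] + e + ge[i] + eps))
    df = pd.DataFrame(rows, columns=["line", "location", "year", "rep",
                                     "block", "trait", "value"])
    return PlotRecords(df), g, lines


def toy_genotypes(dosages, line_ids=None, marker_ids=None):
    """GenotypeTable from a raw dosage array (single chromosome)."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    line_ids = line_ids or [f"L{i}" for i in range(n)]
    marker_ids = marker_ids or [f"snp{j}" for j in range(m)]
    return GenotypeTable(line_ids, marker_ids,
                         np.array(["1"] * m, dtype=object),
                         np.arange(1, m + 1), dosages)
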