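"""Synthetic breeding-panel generator.

Emulates the data a closed, inbreeding-based breeding program produces: a
panel of related inbred lines genotyped at SNPs with linkage disequilibrium,
and multi-environment trial phenotypes with known genotype, environment,
genotype x environment, replicate, block and residual variance components
(plus optional major QTLs).  The generator exists so that every downstream
stage — mixed-model means, heritability, GWAS stability screening, and GBLUP
cross-validation — is testable against a recorded truth without any external
download.

Genetics model
--------------
Founders are fully inbred lines whose haplotypes are drawn marker-by-marker
with allele frequencies uniform on a configurable range.  Progeny come from a
fixed crossing recipe: two large founder-pair sib families (reproducing the
full-/half-sib blocks typical of such panels) plus round-robin crosses among
the remaining founders.  Gametes recombine under a no-interference model
(crossover count Poisson in the map length, i.e. Haldane), and each cross is
advanced by single-seed descent through a configurable number of selfing
generations, so residual heterozygosity decays as ``2**(-t)``.

Trial model
-----------
A plot value is ``mu + g_i + e_j + (ge)_ij + r_k(j) + b_l(k) + eps`` with the
genetic value ``g_i`` built from the marker dosages (optional major QTLs plus
a polygenic tail using every marker) and the remaining effects drawn i.i.d.
normal with the configured variances.  Genetic effects are rescaled so the
*realized* panel variance of ``g`` equals ``var_g`` exactly, which makes
parameter-recovery checks sharp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GenotypeTable, PlotRecords, env_id

__all__ = ["SimConfig", "TruthRecord", "simulate_genotypes", "simulate_trials"]


@dataclass
class SimConfig:
    """Configuration for a synthetic panel and its trials.

    Variances are on the plot-value scale.  ``qtls`` lists ``(marker_index,
    proportion_of_genetic_variance)`` pairs; the leftover proportion goes to
    the polygenic tail.  ``n_environments`` must equal
    ``n_locations * n_years``.  The seed fully determines all output.
    """

    n_founders: int = 8
    n_lines: int = 80
    n_chromosomes: int = 5
    n_snps: int = 2000
    map_length_per_chrom: float = 1.5  # Morgans
    selfing_generations: int = 6
    founder_maf_range: tuple[float, float] = (0.1, 0.5)
    n_locations: int = 7
    n_years: int = 2
    n_reps: int = 2
    n_blocks_per_rep: int = 4
    var_g: float = 1.0
    var_ge: float = 0.5
    var_env: float = 1.0
    var_rep: float = 0.1
    var_block: float = 0.1
    var_e: float = 1.0
    qtls: list = field(default_factory=list)
    missing_rate: float = 0.0
    sib_family_size: int | None = None  # default: n_lines // 4 per family
    seed: int = 0

    @property
    def n_environments(self) -> int:
        return self.n_locations * self.n_years

    def validate(self) -> None:
        for name in ("var_g", "var_ge", "var_env", "var_rep", "var_block", "var_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        props = [p for _, p in self.qtls]
        if any(p < 0 for p in props) or sum(props) > 1.0 + 1e-12:
            raise ValueError("QTL variance proportions must be >= 0 and sum to <= 1")
        lo, hi = self.founder_maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("founder_maf_range must lie in (0, 0.5]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_founders < 2 or self.n_lines < 2:
            raise ValueError("need at least 2 founders and 2 lines")
        if self.n_lines < self.n_founders:
            raise ValueError("n_lines must be >= n_founders")
        per_chrom = self.n_snps / self.n_chromosomes
        if self.map_length_per_chrom == 0 and per_chrom > 1:
            raise ValueError(
                "zero map length with more than one marker per chromosome: "
                "all markers would be perfectly linked"
            )


@dataclass
class TruthRecord:
    """Every effect sampled while simulating trials, for oracle tests."""

    trait: str
    breeding_values: pd.Series  # g_i per line
    marker_effects: pd.Series  # per-marker additive effect on centered dosage
    env_effects: pd.Series  # e_j per environment
    ge_effects: pd.DataFrame  # lines x environments
    rep_effects: pd.Series  # index (env, rep)
    block_effects: pd.Series  # index (env, rep, block)
    var_components: dict  # configured variances


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

_CM_PER_MORGAN = 100.0
_BP_PER_CM = 400_000  # fixed map-to-physical constant; positions are labels only


def _split_markers(n_snps: int, n_chrom: int) -> list[int]:
    base = n_snps // n_chrom
    counts = [base + (1 if c < n_snps % n_chrom else 0) for c in range(n_chrom)]
    return counts


def _gamete(haplos: list[np.ndarray], gpos: list[np.ndarray], lengths: list[float],
            rng: np.random.Generator) -> list[np.ndarray]:
    """One recombinant gamete from an individual's two haplotypes.

    ``haplos`` holds per-chromosome (2, n_markers) arrays; crossovers fall as
    a Poisson process along the genetic map (no interference).
    """
    out = []
    for (h, pos, length) in zip(haplos, gpos, lengths):
        n_x = rng.poisson(length)
        start = rng.integers(2)
        if n_x == 0 or len(pos) == 1:
            out.append(h[start].copy())
            continue
        xovers = np.sort(rng.uniform(0.0, length, size=n_x))
        # phase at each marker = start + number of crossovers to its left
        phase = (start + np.searchsorted(xovers, pos)) % 2
        out.append(np.where(phase == 0, h[0], h[1]))
    return out


def _crossing_plan(cfg: SimConfig) -> list[tuple[int, int, str]]:
    """(parent1, parent2, family label) per progeny line.

    Two founder-pair full-sib families first, then round-robin crosses among
    the remaining founders until ``n_lines`` is reached.
    """
    fam_size = cfg.sib_family_size
    if fam_size is None:
        fam_size = max(2, cfg.n_lines // 4)
    plan: list[tuple[int, int, str]] = []
    if cfg.n_founders >= 4:
        sib_pairs = [(0, 1), (2, 3)]
    else:
        sib_pairs = [(0, 1)]
    for fi, (a, b) in enumerate(sib_pairs):
        for _ in range(min(fam_size, cfg.n_lines - len(plan))):
            plan.append((a, b, f"FAM{fi + 1}"))
    rest = list(range(2 * len(sib_pairs), cfg.n_founders)) or list(range(cfg.n_founders))
    i = 0
    while len(plan) < cfg.n_lines:
        a = rest[i % len(rest)]
        b = rest[(i + 1) % len(rest)]
        if a == b:  # single leftover founder: cross back into the sib parents
            b = (a + 1) % cfg.n_founders
        plan.append((a, b, "ADMIX"))
        i += 1
    return plan


def simulate_genotypes(cfg: SimConfig) -> tuple[GenotypeTable, pd.DataFrame]:
    """Simulate the inbred panel's dosage table and return it with a pedigree.

    Returns ``(geno, pedigree)`` where the pedigree frame has one row per line
    with its two founder parents and family label.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    counts = _split_markers(cfg.n_snps, cfg.n_chromosomes)
    lengths = [cfg.map_length_per_chrom] * cfg.n_chromosomes
    gpos = [np.sort(rng.uniform(0.0, L, size=c)) for c, L in zip(counts, lengths)]

    # founder haplotypes: inbred, allele frequency per marker in the MAF range
    lo, hi = cfg.founder_maf_range
    freqs = [rng.uniform(lo, hi, size=c) for c in counts]
    founders = []
    for _ in range(cfg.n_founders):
        founders.append([
            (rng.uniform(size=c) < f).astype(np.int8) for c, f in zip(counts, freqs)
        ])

    plan = _crossing_plan(cfg)
    lines: list[list[np.ndarray]] = []  # per line: per chrom (2, m) haplotypes
    for (a, b, _fam) in plan:
        # founders are fully homozygous, so the F1 is deterministic given parents
        h = [np.stack([fa, fb]) for fa, fb in zip(founders[a], founders[b])]
        for _ in range(cfg.selfing_generations):  # single-seed descent
            g1 = _gamete(h, gpos, lengths, rng)
            g2 = _gamete(h, gpos, lengths, rng)
            h = [np.stack([x, y]) for x, y in zip(g1, g2)]
        lines.append(h)

    dosages = np.empty((cfg.n_lines, cfg.n_snps), dtype=float)
    for i, h in enumerate(lines):
        dosages[i] = np.concatenate([hc.sum(axis=0) for hc in h])

    if cfg.missing_rate > 0:
        mask = rng.uniform(size=dosages.shape) < cfg.missing_rate
        dosages[mask] = np.nan

    marker_ids, chrom, pos = [], [], []
    for c, (cnt, gp) in enumerate(zip(counts, gpos), start=1):
        chrom.extend([f"chr{c:02d}"] * cnt)
        bp = np.round(gp * _CM_PER_MORGAN * _BP_PER_CM).astype(np.int64) + 1
        bp = np.maximum.accumulate(bp + np.arange(cnt))  # strictly informative labels
        pos.extend(bp.tolist())
        marker_ids.extend([f"chr{c:02d}_snp{j + 1:05d}" for j in range(cnt)])

    line_ids = [f"L{i + 1:03d}" for i in range(cfg.n_lines)]
    geno = GenotypeTable(line_ids, marker_ids, np.array(chrom, dtype=object),
                         np.array(pos), dosages)
    geno.validate()
    pedigree = pd.DataFrame(
        {
            "line": line_ids,
            "parent1": [f"F{a + 1}" for a, _, _ in plan],
            "parent2": [f"F{b + 1}" for _, b, _ in plan],
            "family": [fam for _, _, fam in plan],
        }
    )
    return geno, pedigree


# ---------------------------------------------------------------------------
# trials
# ---------------------------------------------------------------------------

def simulate_trials(
    geno: GenotypeTable,
    cfg: SimConfig,
    trait: str = "sim_trait",
) -> tuple[PlotRecords, TruthRecord]:
    """Simulate plot-level phenotypes for every line in every environment.

    The design is ``n_reps`` complete replicates of the panel per environment,
    each replicate partitioned at random into ``n_blocks_per_rep`` incomplete
    blocks.  Trait randomness is drawn from a stream seeded independently of
    the genotype stream (same master seed) so genotype and trial simulation
    compose deterministically.
    """
    cfg.validate()
    if geno.n_lines < 2:
        raise ValueError("need at least 2 lines")
    rng = np.random.default_rng([cfg.seed, 9001])

    n, m = geno.n_lines, geno.n_markers
    # mean-impute missing dosages for genetic-value construction
    D = geno.dosages.copy()
    col_mean = np.nanmean(D, axis=0)
    nan_r, nan_c = np.where(np.isnan(D))
    D[nan_r, nan_c] = col_mean[nan_c]
    Xc = D - D.mean(axis=0)

    qtl_props = sum(p for _, p in cfg.qtls)
    marker_effects = np.zeros(m)
    g = np.zeros(n)
    if cfg.var_g > 0:
        for idx, prop in cfg.qtls:
            if not 0 <= idx < m:
                raise ValueError(f"QTL marker index {idx} out of range (m={m})")
            if prop == 0:
                continue
            v = Xc[:, idx].var(ddof=1)
            if v <= 0:
                raise ValueError(f"QTL marker index {idx} is monomorphic")
            eff = np.sqrt(prop * cfg.var_g / v)  # effect per unit centered dosage
            marker_effects[idx] += eff
            g = g + eff * Xc[:, idx]
        poly_prop = 1.0 - qtl_props
        if poly_prop > 1e-12:
            a = rng.standard_normal(m)
            u = Xc @ a
            scale = np.sqrt(poly_prop * cfg.var_g / u.var(ddof=1))
            marker_effects += a * scale
            g = g + u * scale

    envs = [env_id(f"Loc{l + 1}", 2004 + y)
            for l in range(cfg.n_locations) for y in range(cfg.n_years)]
    locs = [f"Loc{l + 1}" for l in range(cfg.n_locations) for _ in range(cfg.n_years)]
    years = [2004 + y for _ in range(cfg.n_locations) for y in range(cfg.n_years)]
    n_env = len(envs)

    def draw(sd2, size):
        return rng.normal(0.0, np.sqrt(sd2), size=size) if sd2 > 0 else np.zeros(size)

    e_j = draw(cfg.var_env, n_env)
    ge = draw(cfg.var_ge, (n, n_env))
    r_kj = draw(cfg.var_rep, (n_env, cfg.n_reps))
    b = draw(cfg.var_block, (n_env, cfg.n_reps, cfg.n_blocks_per_rep))

    rows = []
    line_ids = geno.line_ids
    for j, env in enumerate(envs):
        loc, yr = locs[j], years[j]
        for k in range(cfg.n_reps):
            # random partition of the panel into incomplete blocks
            perm = rng.permutation(n)
            block_of = np.empty(n, dtype=int)
            for bi, chunk in enumerate(np.array_split(perm, cfg.n_blocks_per_rep)):
                block_of[chunk] = bi
            eps = draw(cfg.var_e, n)
            vals = g + e_j[j] + ge[:, j] + r_kj[j, k] + b[j, k, block_of] + eps
            for i in range(n):
                rows.append(
                    (line_ids[i], loc, yr, f"rep{k + 1}", f"blk{block_of[i] + 1}",
                     trait, vals[i])
                )

    plots = PlotRecords(pd.DataFrame(rows, columns=[
        "line", "location", "year", "rep", "block", "trait", "value"]))
    plots.validate()

    truth = TruthRecord(
        trait=trait,
        breeding_values=pd.Series(g, index=line_ids),
        marker_effects=pd.Series(marker_effects, index=geno.marker_ids),
        env_effects=pd.Series(e_j, index=envs),
        ge_effects=pd.DataFrame(ge, index=line_ids, columns=envs),
        rep_effects=pd.Series(
            r_kj.ravel(),
            index=pd.MultiIndex.from_product([envs, [f"rep{k + 1}" for k in range(cfg.n_reps)]]),
        ),
        block_effects=pd.Series(
            b.ravel(),
            index=pd.MultiIndex.from_product(
                [envs, [f"rep{k + 1}" for k in range(cfg.n_reps)],
                 [f"blk{l + 1}" for l in range(cfg.n_blocks_per_rep)]]
            ),
        ),
        var_components={
            "var_g": cfg.var_g, "var_ge": cfg.var_ge, "var_env": cfg.var_env,
            "var_rep": cfg.var_rep, "var_block": cfg.var_block, "var_e": cfg.var_e,
        },
    )
    return plots, truth
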