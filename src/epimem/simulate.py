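"""Seeded synthetic data: toy genomes, probe designs, bimodal signals with
planted differentially methylated windows, and nucleoside/biomass tables
with genotype-by-environment structure.

Everything is a deterministic function of its config (including the seed),
so two calls with the same config produce byte-identical tables.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from epimem.config import HplcSimConfig, SimConfig
from epimem.io import SignalMatrix
from epimem.windows import tile_chromosome, assign_window_ids

FAVORABLE = "favorable"
UNFAVORABLE = "unfavorable"

PROBE_LENGTH = 60
TE_LENGTH = 1_000


class PlacementError(ValueError):
    """Gene density too high to place genes without overlap."""


def chromosome_names(config: SimConfig) -> list[str]:
    return [f"chr{i + 1}" for i in range(config.n_chromosomes)]


def chromosome_lengths(config: SimConfig) -> dict[str, int]:
    return {c: config.chromosome_length for c in chromosome_names(config)}


def _place_genes(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Non-overlapping gene bodies via slot sampling; each gene owns a slot
    of (flank + body + flank) bp so promoter/downstream regions never
    collide either."""
    slot = 2 * config.flank_length + config.gene_body_length
    slots_per_chrom = config.chromosome_length // slot
    chroms = chromosome_names(config)
    per_chrom = [config.n_genes // len(chroms)] * len(chroms)
    for i in range(config.n_genes % len(chroms)):
        per_chrom[i] += 1
    rows = []
    gene_no = 0
    for chrom, n in zip(chroms, per_chrom):
        if n > slots_per_chrom:
            raise PlacementError(
                f"{chrom}: {n} genes do not fit in {slots_per_chrom} slots of {slot} bp")
        chosen = np.sort(rng.choice(slots_per_chrom, size=n, replace=False))
        for s in chosen:
            start = int(s) * slot + config.flank_length
            rows.append({
                "chrom": chrom, "start": start, "end": start + config.gene_body_length,
                "gene_id": f"g{gene_no:05d}", "score": 0, "strand": "+",
            })
            gene_no += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "score", "strand"])


def _gene_probes(genes: pd.DataFrame, config: SimConfig,
                 rng: np.random.Generator) -> list[dict]:
    """Five probes per gene: 1 in the upstream promoter flank, 3 in the
    body, 1 in the downstream flank (gene-linked, intergenic category)."""
    rows = []
    fl, L = config.flank_length, PROBE_LENGTH
    for g in genes.itertuples():
        prom_start = int(rng.integers(g.start - fl, g.start - L + 1))
        rows.append({"chrom": g.chrom, "start": prom_start, "end": prom_start + L,
                     "category": "PROMOTER", "gene_id": g.gene_id})
        body_starts = np.sort(rng.integers(g.start, g.end - L + 1, size=3))
        for bs in body_starts:
            rows.append({"chrom": g.chrom, "start": int(bs), "end": int(bs) + L,
                         "category": "BODY", "gene_id": g.gene_id})
        down_start = int(rng.integers(g.end, g.end + fl - L + 1))
        rows.append({"chrom": g.chrom, "start": down_start, "end": down_start + L,
                     "category": "INTERGENIC", "gene_id": g.gene_id})
    return rows


def _background_probes(config: SimConfig, rng: np.random.Generator) -> list[dict]:
    rows = []
    n_windows = -(-config.chromosome_length // config.window_size)
    n_bg = config.background_probes_per_window * n_windows
    for chrom in chromosome_names(config):
        starts = np.sort(rng.integers(0, config.chromosome_length - PROBE_LENGTH, size=n_bg))
        for s in starts:
            rows.append({"chrom": chrom, "start": int(s), "end": int(s) + PROBE_LENGTH,
                         "category": "INTERGENIC", "gene_id": pd.NA})
    return rows


def _apply_te_overlap(probes: pd.DataFrame, config: SimConfig,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Drop TE intervals on each chromosome and relabel overlapped probes."""
    if config.te_fraction == 0:
        return probes
    n_te = int(config.te_fraction * config.chromosome_length / TE_LENGTH)
    relabel = {"BODY": "BODY+TE", "PROMOTER": "PROM+TE", "INTERGENIC": "TE"}
    probes = probes.copy()
    for chrom in chromosome_names(config):
        te_starts = np.sort(rng.integers(0, config.chromosome_length - TE_LENGTH, size=n_te))
        te_ends = te_starts + TE_LENGTH
        mask = probes["chrom"] == chrom
        mids = ((probes.loc[mask, "start"] + probes.loc[mask, "end"]) // 2).to_numpy()
        idx = np.searchsorted(te_starts, mids, side="right") - 1
        inside = (idx >= 0) & (mids < te_ends[np.clip(idx, 0, None)])
        hit_index = probes.index[mask][inside]
        probes.loc[hit_index, "category"] = probes.loc[hit_index, "category"].map(relabel)
    return probes


def simulate_probe_design(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the probe and gene annotation tables.

    Returns ``(probes, genes)``: probes with columns (probe_id, chrom,
    start, end, category, gene_id) sorted by position, genes BED6-style.
    """
    rng = np.random.default_rng(config.seed)
    genes = _place_genes(config, rng)
    rows = _gene_probes(genes, config, rng) + _background_probes(config, rng)
    probes = pd.DataFrame(rows, columns=["chrom", "start", "end", "category", "gene_id"])
    probes = _apply_te_overlap(probes, config, rng)
    probes = probes.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    probes.insert(0, "probe_id", [f"p{i:06d}" for i in range(len(probes))])
    probes["gene_id"] = probes["gene_id"].astype("string")
    return probes, genes


def make_truth_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Pick planted DMR windows and directions; covers every genome window."""
    rows = []
    for chrom, length in chromosome_lengths(config).items():
        for wid, start, end in tile_chromosome(chrom, length, config.window_size):
            rows.append({"window_id": wid, "chrom": chrom, "start": start, "end": end})
    truth = pd.DataFrame(rows)
    n_windows = len(truth)
    n_planted = int(round(config.dmr_fraction * n_windows))
    if config.dmr_fraction > 0 and n_planted < 1:
        warnings.warn("dmr_fraction too small for this genome; planting zero DMRs",
                      stacklevel=2)
    planted = rng.choice(n_windows, size=n_planted, replace=False)
    truth["is_dmr"] = False
    truth.loc[planted, "is_dmr"] = True
    directions = np.where(rng.random(n_planted) < config.p_hyper, "hyper", "hypo")
    truth["planted_direction"] = "none"
    truth.loc[planted, "planted_direction"] = directions
    return truth


def simulate_signals(probes: pd.DataFrame, config: SimConfig
                     ) -> tuple[dict[str, SignalMatrix], pd.DataFrame]:
    """Draw bimodal probe signals and plant window-level shifts.

    Each probe's base signal comes from the two-component Gaussian mixture
    (high component with probability ``p_high``) and is shared by both
    conditions; probes inside planted DMR windows get +/-delta added in the
    unfavorable condition only; each replicate adds N(0, sigma_rep) noise.

    Returns ``({condition: SignalMatrix}, truth_table)``.
    """
    if probes.empty:
        raise ValueError("probe table is empty")
    rng = np.random.default_rng(config.seed + 1)  # independent of the design stream
    truth = make_truth_table(config, rng)

    n = len(probes)
    high = rng.random(n) < config.p_high
    base = np.where(high,
                    rng.normal(config.mu_high, config.sigma_high, size=n),
                    rng.normal(config.mu_low, config.sigma_low, size=n))

    window_of = assign_window_ids(probes, chromosome_lengths(config), config.window_size)
    shift_by_window = truth.set_index("window_id")["planted_direction"].map(
        {"hyper": config.delta, "hypo": -config.delta, "none": 0.0})
    probe_shift = window_of.map(shift_by_window).to_numpy(dtype=float)

    matrices: dict[str, SignalMatrix] = {}
    for condition in (FAVORABLE, UNFAVORABLE):
        cond_base = base + probe_shift if condition == UNFAVORABLE else base
        cols = {}
        sample_rows = []
        for rep in range(1, config.n_replicates + 1):
            sid = f"{condition}_{rep}"
            cols[sid] = cond_base + rng.normal(0.0, config.sigma_rep, size=n)
            sample_rows.append({"sample_id": sid, "condition": condition, "replicate": rep})
        values = pd.DataFrame(cols, index=pd.Index(probes["probe_id"], name="probe_id"))
        matrices[condition] = SignalMatrix(values=values, samples=pd.DataFrame(sample_rows))
    return matrices, truth


def combine_matrices(matrices: dict[str, SignalMatrix]) -> SignalMatrix:
    """One matrix holding every condition's samples side by side."""
    values = pd.concat([m.values for m in matrices.values()], axis=1)
    samples = pd.concat([m.samples for m in matrices.values()], ignore_index=True)
    return SignalMatrix(values=values, samples=samples)


def simulate_hplc(config: HplcSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Nucleoside quantities and biomass with G-by-E structure.

    Latent per-cell %mC = base + genotype + environment + GxE; individuals
    add biological noise, technical (hydrolysis x run) records add
    measurement noise. Biomass is generated per condition so the
    genotype-mean %mC-biomass Pearson correlation targets the configured
    value: positive for the first (favorable) condition, negative for the
    others.
    """
    rng = np.random.default_rng(config.seed)
    genotypes = [f"G{i + 1:02d}" for i in range(config.n_genotypes)]
    g_eff = rng.normal(0.0, config.genotype_sd, size=config.n_genotypes)
    e_eff = np.arange(len(config.conditions)) * config.env_effect
    gxe = rng.normal(0.0, config.gxe_sd, size=(config.n_genotypes, len(config.conditions)))

    cell_mean = config.base_mC + g_eff[:, None] + e_eff[None, :] + gxe

    nuc_rows = []
    clipped_any = False
    for gi, genotype in enumerate(genotypes):
        for ci, condition in enumerate(config.conditions):
            for ind in range(1, config.n_individuals + 1):
                ind_pct = cell_mean[gi, ci] + rng.normal(0.0, config.noise_sd)
                for hyd in range(1, config.n_hydrolysis + 1):
                    for run in range(1, config.n_runs + 1):
                        pct = ind_pct + rng.normal(0.0, config.technical_sd)
                        clipped = not 0.0 <= pct <= 100.0
                        clipped_any = clipped_any or clipped
                        pct = float(np.clip(pct, 0.0, 100.0))
                        mc = config.total_nucleoside * pct / 100.0
                        nuc_rows.append({
                            "genotype": genotype, "condition": condition,
                            "individual": f"{genotype}_{condition}_i{ind}",
                            "hydrolysis": hyd, "run": run,
                            "C_amount": config.total_nucleoside - mc, "mC_amount": mc,
                            "clipped": clipped,
                        })
    nucleosides = pd.DataFrame(nuc_rows)
    if clipped_any:
        warnings.warn("some simulated %mC values were clipped to [0, 100]", stacklevel=2)

    bio_rows = []
    for ci, condition in enumerate(config.conditions):
        r = config.biomass_r_favorable if ci == 0 else config.biomass_r_unfavorable
        x = cell_mean[:, ci]
        xs = (x - x.mean()) / max(x.std(), 1e-12)
        z = rng.normal(size=config.n_genotypes)
        z = (z - z.mean()) / max(z.std(), 1e-12)
        z = z - xs * (z @ xs) / (xs @ xs)  # orthogonalize so sample r is on target
        z = z / max(z.std(), 1e-12)
        y = r * xs + np.sqrt(max(0.0, 1.0 - r * r)) * z
        biomass = 100.0 + 15.0 * y
        for genotype, b in zip(genotypes, biomass):
            bio_rows.append({"genotype": genotype, "condition": condition,
                             "biomass": float(b)})
    return nucleosides, pd.DataFrame(bio_rows)
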