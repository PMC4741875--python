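"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the shapes of the study's external data sources on a
toy diploid-free genome: a SNP panel with dbSNP-style flanking sequence and
ancestral alleles (flank composition CpG-enriched inside islands, so
cg-loss variants dominate there), PLINK-style LD pairs whose r-squared
values are *realized* from simulated haplotype pools rather than asserted,
outcome labels drawn from the logistic enrichment model with planted
coefficients, and a paired normal/tumor methylation track with a planted
methylation reduction at CpG-destroying mutation sites.

Every generator is a pure function of its :class:`SynthConfig`: the seed is
mandatory and each generator derives an independent, fixed random stream
from it, so re-running with the same config reproduces the outputs
byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit

from . import classifier
from .annotation import build_region_index
from .classifier import BASES, CgClass
from .errors import ConfigError
from .ld import r2_from_haplotype_counts

_BASE_ARR = np.array(list(BASES))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

# fixed per-generator random streams derived from the seed
_STREAM_PANEL, _STREAM_LD, _STREAM_OUTCOME, _STREAM_METH, _STREAM_COV = range(5)


@dataclass
class SynthConfig:
    """Parameters of the synthetic study conditions.

    Scales default to the study's test dimensions (a 50,000-SNP proxy-sized
    panel, 300 matched draws of 500-SNP sets) at desk-run size; effect
    sizes default to the planted values the enrichment and methylation
    analyses are designed around (cgSNPt OR 1.5 pooled, category contrast
    1.5 vs 1.1, a 0.20 methylation drop at CpG-destroying mutations).
    """

    seed: int = 0
    # SNP panel / toy genome
    n_snps: int = 50_000
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    island_length: int = 1_000
    island_fraction: float = 0.01
    cpg_prior_island: float = 0.45
    cpg_prior_shore: float = 0.25
    cpg_prior_open: float = 0.10
    gc_island: float = 0.60
    gc_shore: float = 0.50
    gc_open: float = 0.40
    flank_len: int = 8
    ancestral_missing_rate: float = 0.02
    maf_beta_a: float = 0.8
    maf_beta_b: float = 1.4
    maf_cgsnp_shift: float = 0.3
    transition_prob: float = 2.0 / 3.0
    # LD blocks
    block_size: int = 10
    haplotype_pool_size: int = 120
    n_founders: int = 3
    flip_prob: float = 0.02
    # planted logistic outcome model
    beta0: float = -3.0
    beta_cgsnpt: float = math.log(1.5)
    beta_maf: float = 0.5
    beta_tags: float = 0.02
    trait_categories: Dict[str, float] = field(
        default_factory=lambda: {"cancer": 1.5, "obesity": 1.1, "neurological": 1.1}
    )
    # paired methylation tracks
    meth_genome_length: int = 2_000_000
    n_meth_cpgs: int = 20_000
    n_cgmuts: int = 53
    n_noncg_muts: int = 20
    meth_beta_a: float = 6.0
    meth_beta_b: float = 2.0
    meth_delta_mean: float = 0.20
    meth_noise_sd: float = 0.07
    meth_background_sd: float = 0.02

    def __post_init__(self) -> None:
        probs = (
            self.island_fraction,
            self.cpg_prior_island,
            self.cpg_prior_shore,
            self.cpg_prior_open,
            self.ancestral_missing_rate,
            self.flip_prob,
            self.transition_prob,
        )
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ConfigError("probabilities must lie in [0, 1]")
        counts = (
            self.n_snps,
            self.n_chroms,
            self.chrom_length,
            self.block_size,
            self.haplotype_pool_size,
            self.n_founders,
            self.n_meth_cpgs,
            self.n_cgmuts,
        )
        if any(c <= 0 for c in counts):
            raise ConfigError("counts and sizes must be positive")
        if self.n_cgmuts > self.n_meth_cpgs:
            raise ConfigError("n_cgmuts exceeds the number of CpG sites")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class SnpPanel:
    """A generated SNP panel plus the interval tracks and ground truth."""

    snps: pd.DataFrame
    islands: pd.DataFrame
    chrom_lengths: Dict[str, int]
    truth: pd.DataFrame  # snp_id, true_cg_class, cpg_region


def _region_bases(rng: np.random.Generator, gc: float, shape) -> np.ndarray:
    """Random base matrix with the given G+C content."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASE_ARR[rng.choice(4, size=shape, p=p)]


def _place_islands(
    cfg: SynthConfig, rng: np.random.Generator
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    chrom_lengths = {
        f"chr{i + 1}": cfg.chrom_length for i in range(cfg.n_chroms)
    }
    rows = []
    n_per_chrom = max(
        1, int(cfg.island_fraction * cfg.chrom_length / cfg.island_length)
    )
    for chrom in chrom_lengths:
        starts = np.sort(
            rng.choice(
                cfg.chrom_length - cfg.island_length, size=n_per_chrom, replace=False
            )
        )
        last_end = -1
        for s in starts:
            if s <= last_end:  # drop overlapping placements
                continue
            rows.append({"chrom": chrom, "start": int(s), "end": int(s + cfg.island_length)})
            last_end = s + cfg.island_length
    return pd.DataFrame(rows), chrom_lengths


def generate_snp_panel(config: SynthConfig) -> SnpPanel:
    """SNP panel with flanks, ancestral alleles, MAF, and planted region bias.

    Inside islands the ancestral context carries a pre-existing CpG
    overlapping the variant with elevated probability, so cg-loss variants
    dominate there; in open sea the prior is low and gains/losses are near
    balanced.  MAF is Beta-distributed on (0, 0.5] with a mild upward shift
    for cgSNPs (so MAF genuinely confounds the enrichment model), and the
    ancestral state is masked at the configured missingness rate.
    """
    rng = config.rng(_STREAM_PANEL)
    islands, chrom_lengths = _place_islands(config, rng)
    index = build_region_index(islands, chrom_lengths=chrom_lengths)

    # positions, proportional per chromosome
    per_chrom = np.full(config.n_chroms, config.n_snps // config.n_chroms)
    per_chrom[: config.n_snps % config.n_chroms] += 1
    chroms: List[str] = []
    positions: List[np.ndarray] = []
    regions: List[np.ndarray] = []
    for chrom, count in zip(chrom_lengths, per_chrom):
        pos = np.sort(rng.choice(config.chrom_length, size=count, replace=False))
        chroms.extend([chrom] * count)
        positions.append(pos)
        regions.append(index.locate_many(chrom, pos))
    pos_all = np.concatenate(positions)
    region_all = np.concatenate(regions)
    n = len(pos_all)

    cpg_prior = np.select(
        [region_all == "island", region_all == "shore"],
        [config.cpg_prior_island, config.cpg_prior_shore],
        config.cpg_prior_open,
    )
    gc = np.select(
        [region_all == "island", region_all == "shore"],
        [config.gc_island, config.gc_shore],
        config.gc_open,
    )

    k = config.flank_len
    flanks = np.empty((n, 2 * k), dtype="<U1")
    anc = np.empty(n, dtype="<U1")
    for gc_val in np.unique(gc):
        mask = gc == gc_val
        m = int(mask.sum())
        flanks[mask] = _region_bases(rng, float(gc_val), (m, 2 * k))
        anc[mask] = _region_bases(rng, float(gc_val), m)

    plant = rng.random(n) < cpg_prior
    c_side = rng.random(n) < 0.5
    anc[plant & c_side] = "C"
    flanks[plant & c_side, k] = "G"  # first base of flank3
    anc[plant & ~c_side] = "G"
    flanks[plant & ~c_side, k - 1] = "C"  # last base of flank5

    # derived allele: transition with the configured probability
    derived = np.empty(n, dtype="<U1")
    is_transition = rng.random(n) < config.transition_prob
    pick = rng.integers(0, 2, size=n)
    transversions = {
        "A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G")
    }
    for i in range(n):
        a = anc[i]
        derived[i] = _TRANSITION[a] if is_transition[i] else transversions[a][pick[i]]

    lookup = classifier._oriented_lookup()
    left = flanks[:, k - 1]
    right = flanks[:, k]
    cg_class = np.array(
        [
            lookup[(left[i], anc[i], derived[i], anc[i], right[i])]
            for i in range(n)
        ],
        dtype=object,
    )
    is_cg = np.isin(
        cg_class,
        [CgClass.CG_GAIN.value, CgClass.CG_LOSS.value, CgClass.CG_UNORIENTED.value],
    )

    maf = 0.5 * rng.beta(
        config.maf_beta_a + config.maf_cgsnp_shift * is_cg, config.maf_beta_b, size=n
    )
    maf = np.clip(maf, 1e-4, 0.5)

    missing = rng.random(n) < config.ancestral_missing_rate
    swap = rng.random(n) < 0.5
    allele_a = np.where(swap, derived, anc)
    allele_b = np.where(swap, anc, derived)
    ancestral = np.where(missing, "", anc)

    snp_ids = np.array([f"s{i:07d}" for i in range(n)])
    flank5 = ["".join(row[:k]) for row in flanks]
    flank3 = ["".join(row[k:]) for row in flanks]
    snps = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": chroms,
            "pos": pos_all,
            "strand": "+",
            "allele_a": allele_a,
            "allele_b": allele_b,
            "ancestral": ancestral,
            "maf": np.round(maf, 6),
            "flank5": flank5,
            "flank3": flank3,
        }
    )
    # truth re-derives orientation with the masked ancestral state
    true_class = cg_class.copy()
    cg_poly = is_cg
    true_class[missing & cg_poly] = CgClass.CG_UNORIENTED.value
    truth = pd.DataFrame(
        {"snp_id": snp_ids, "true_cg_class": true_class, "cpg_region": region_all}
    )
    return SnpPanel(
        snps=snps, islands=islands, chrom_lengths=chrom_lengths, truth=truth
    )


def generate_ld_blocks(
    panel: SnpPanel,
    config: SynthConfig,
    return_pools: bool = False,
):
    """PLINK-style LD pairs realized from simulated haplotype pools.

    SNPs are grouped, in genome order, into blocks of ``block_size``; each
    block's haplotypes are drawn from ``n_founders`` founder haplotypes
    with per-site flip noise, monomorphic sites re-polymorphised by a
    single flip.  Emitted r-squared values are computed from the pool with
    :func:`cpgvar.ld.r2_from_haplotype_counts`, so they are realizable and
    internally consistent by construction; cross-block r2 is 0 (no pair
    emitted).
    """
    rng = config.rng(_STREAM_LD)
    snps = panel.snps.sort_values(["chrom", "pos", "snp_id"])
    rows = []
    pools = {}
    pool_n = config.haplotype_pool_size
    for chrom, group in snps.groupby("chrom", sort=True):
        ids = group["snp_id"].to_numpy()
        for start in range(0, len(ids), config.block_size):
            block_ids = ids[start : start + config.block_size]
            m = len(block_ids)
            if m < 2:
                continue
            founders = rng.integers(0, 2, size=(config.n_founders, m))
            assignment = rng.integers(0, config.n_founders, size=pool_n)
            hap = founders[assignment].astype(bool)
            flips = rng.random((pool_n, m)) < config.flip_prob
            hap = hap ^ flips
            for j in range(m):
                # monomorphic site: redraw its founder pattern (keeps block
                # structure); fall back to a single flip if the pool itself
                # is degenerate
                for _ in range(20):
                    if hap[:, j].min() != hap[:, j].max():
                        break
                    founders[:, j] = rng.integers(0, 2, size=config.n_founders)
                    hap[:, j] = founders[assignment, j].astype(bool) ^ flips[:, j]
                else:
                    hap[rng.integers(0, pool_n), j] ^= True
            if return_pools:
                pools[(chrom, start)] = (block_ids, hap.copy())
            for i in range(m):
                for j in range(i + 1, m):
                    x, y = hap[:, i], hap[:, j]
                    n11 = int(np.sum(x & y))
                    n10 = int(np.sum(x & ~y))
                    n01 = int(np.sum(~x & y))
                    n00 = int(np.sum(~x & ~y))
                    r2 = r2_from_haplotype_counts(n11, n10, n01, n00)
                    rows.append((block_ids[i], block_ids[j], round(r2, 6)))
    ld = pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"])
    if return_pools:
        return ld, pools
    return ld


def plant_outcomes(
    proxies: pd.DataFrame,
    config: SynthConfig,
    kind: str = "trait",
    p_bin_edges: Tuple[float, ...] = (5, 6, 7, 8, 11, 14, 17, 20),
) -> Tuple[pd.DataFrame, dict]:
    """Outcome labels drawn from the planted logistic model.

    ``proxies`` needs ``snp_id, is_cgsnpt, maf, n_tagged``.  For
    ``kind="trait"`` each SNP is assigned a trait category and the planted
    cgSNPt log-odds is ln(category OR); for ``kind="eqtl"`` the pooled
    ``beta_cgsnpt`` applies.  Positives receive synthetic reported
    p-values spread uniformly over the significance bins (these exercise
    bin logic only; they are not test statistics).  Returns the outcome
    table and the planted truth (betas, per-SNP category, outcome vector).
    """
    if kind not in ("trait", "eqtl"):
        raise ConfigError(f"unknown outcome kind {kind!r}")
    rng = config.rng(_STREAM_OUTCOME if kind == "trait" else _STREAM_OUTCOME + 10)
    n = len(proxies)
    x = proxies["is_cgsnpt"].to_numpy().astype(float)
    maf = proxies["maf"].to_numpy().astype(float)
    tags = proxies["n_tagged"].to_numpy().astype(float)

    if kind == "trait" and config.trait_categories:
        names = sorted(config.trait_categories)
        cat_idx = rng.integers(0, len(names), size=n)
        category = np.array(names, dtype=object)[cat_idx]
        beta_cg = np.log(
            np.array([config.trait_categories[c] for c in category], dtype=float)
        )
    else:
        category = np.full(n, "", dtype=object)
        beta_cg = np.full(n, config.beta_cgsnpt)

    eta = config.beta0 + beta_cg * x + config.beta_maf * maf + config.beta_tags * tags
    y = rng.random(n) < expit(eta)

    pos = np.flatnonzero(y)
    edges = np.asarray(p_bin_edges, dtype=float)
    bin_idx = rng.integers(0, len(edges), size=len(pos))
    lo = edges[bin_idx]
    hi = np.append(edges[1:], edges[-1] + 10.0)[bin_idx]
    neglog = lo + rng.random(len(pos)) * (hi - lo)
    reported_p = 10.0 ** (-neglog)

    outcomes = pd.DataFrame(
        {
            "snp_id": proxies["snp_id"].to_numpy()[pos],
            "outcome": kind,
            "trait": [f"{c or kind}_trait" for c in category[pos]],
            "category": category[pos],
            "reported_p": reported_p,
        }
    )
    truth = {
        "beta0": config.beta0,
        "beta_maf": config.beta_maf,
        "beta_tags": config.beta_tags,
        "beta_cgsnpt": config.beta_cgsnpt,
        "category_or": dict(config.trait_categories) if kind == "trait" else None,
        "y": y,
        "category": category,
    }
    return outcomes, truth


def generate_proxy_covariates(
    n: int,
    config: Optional[SynthConfig] = None,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Fast covariate-only proxy panel for calibration studies.

    Draws MAF, tag counts, and a cgSNPt indicator whose probability rises
    mildly with both matching factors (so matched resampling and covariate
    adjustment are genuinely exercised), without building flanking
    sequence.  Used for replicate-heavy recovery and type-I simulations.
    """
    config = config or SynthConfig(seed=seed if seed is not None else 0)
    rng = (
        np.random.default_rng([int(seed), _STREAM_COV])
        if seed is not None
        else config.rng(_STREAM_COV)
    )
    maf = 0.5 * rng.beta(config.maf_beta_a, config.maf_beta_b, size=n)
    maf = np.clip(maf, 1e-4, 0.5)
    tags = rng.poisson(3.0, size=n)
    p_cg = np.clip(0.30 + 0.5 * maf + 0.01 * tags, 0.0, 0.95)
    is_cgsnpt = rng.random(n) < p_cg
    return pd.DataFrame(
        {
            "snp_id": [f"s{i:07d}" for i in range(n)],
            "maf": maf,
            "n_tagged": tags,
            "is_cgsnpt": is_cgsnpt,
        }
    )


@dataclass
class MethylationPair:
    """Paired tracks, mutation list, and planted per-site deltas."""

    normal: pd.DataFrame
    tumor: pd.DataFrame
    mutations: pd.DataFrame
    truth: pd.DataFrame  # chrom, cpg_pos, planted_delta


def generate_methylation_pair(config: SynthConfig) -> MethylationPair:
    """Paired normal/tumor methylation with a planted drop at cgMut sites.

    CpG cytosine positions are placed on a toy chromosome; normal levels
    come from a Beta(``meth_beta_a``, ``meth_beta_b``) distribution and the
    tumor track adds symmetric Normal(0, ``meth_background_sd``) noise,
    except at ``n_cgmuts`` randomly chosen CpGs where a C-to-T mutation
    abolishes the site and the tumor level is reduced by
    Normal(``meth_delta_mean``, ``meth_noise_sd``) (levels clipped to
    [0, 1]).  ``n_noncg_muts`` decoy substitutions that touch no CpG are
    appended to exercise mutation filtering.
    """
    rng = config.rng(_STREAM_METH)
    chrom = "chr1"
    pos = np.sort(
        rng.choice(
            np.arange(10, config.meth_genome_length - 10, 2),
            size=config.n_meth_cpgs,
            replace=False,
        )
    )
    normal = np.clip(
        rng.beta(config.meth_beta_a, config.meth_beta_b, size=config.n_meth_cpgs),
        0.0,
        1.0,
    )
    tumor = np.clip(
        normal + rng.normal(0.0, config.meth_background_sd, size=config.n_meth_cpgs),
        0.0,
        1.0,
    )

    mut_sites = np.sort(
        rng.choice(config.n_meth_cpgs, size=config.n_cgmuts, replace=False)
    )
    deltas = rng.normal(config.meth_delta_mean, config.meth_noise_sd, size=config.n_cgmuts)
    tumor[mut_sites] = np.clip(normal[mut_sites] - deltas, 0.0, 1.0)

    flank_pad = "".join(rng.choice(["A", "T"], size=4))
    mut_rows = []
    for site in mut_sites:
        left = str(rng.choice(["A", "T", "G"]))  # avoid a second CpG on the left
        mut_rows.append(
            {
                "chrom": chrom,
                "pos": int(pos[site]),
                "ref": "C",
                "alt": "T",
                "flank5": flank_pad + left,
                "flank3": "G" + flank_pad,
            }
        )
    cpg_set = set(pos.tolist())
    n_added = 0
    while n_added < config.n_noncg_muts:
        p = int(rng.integers(10, config.meth_genome_length - 10))
        if p in cpg_set or (p - 1) in cpg_set or (p + 1) in cpg_set:
            continue
        mut_rows.append(
            {
                "chrom": chrom,
                "pos": p,
                "ref": "A",
                "alt": "T",
                "flank5": flank_pad + "A",
                "flank3": "A" + flank_pad,
            }
        )
        n_added += 1
    mutations = pd.DataFrame(mut_rows)

    normal_df = pd.DataFrame({"chrom": chrom, "pos": pos, "level": np.round(normal, 6)})
    tumor_df = pd.DataFrame({"chrom": chrom, "pos": pos, "level": np.round(tumor, 6)})
    truth = pd.DataFrame(
        {
            "chrom": chrom,
            "cpg_pos": pos[mut_sites],
            "planted_delta": deltas,
        }
    )
    return MethylationPair(
        normal=normal_df, tumor=tumor_df, mutations=mutations, truth=truth
    )
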