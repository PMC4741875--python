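"""Paired-sample methylation differences at CpG-destroying somatic mutations.

A somatic substitution that abolishes a CpG (a cg-loss mutation, cgMut,
classified with the reference allele as the initial state) removes the
methylatable cytosine in the tumor.  The analysis compares, per CpG site,
methylation in the normal sample minus the paired tumor sample:

* at the mutated CpG cytosines themselves (the SITE bin), and
* at intact nearby CpG sites grouped into distance annuli
  (0, 10], (10, 50], (50, 100], (100, 500], (500, 1000], (1000, 2000] bp,

summarised as the 10th/25th/50th/75th/90th percentiles per bin.  A
site-specific methylation drop with a flat neighbourhood indicates the
mutation, not global tumor/normal differences, drives the change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import _IntervalSet, merge_intervals
from .classifier import CgClass, classify_substitution, orient_gain_loss, SubstitutionClass
from .errors import ConfigError, EmptySummaryError, SchemaError

logger = logging.getLogger(__name__)

DEFAULT_BIN_EDGES: Tuple[int, ...] = (10, 50, 100, 500, 1000, 2000)
SITE_BIN = "site"


def _annulus_labels(edges: Sequence[int]) -> List[str]:
    lows = [0] + list(edges[:-1])
    return [f"({lo},{hi}]" for lo, hi in zip(lows, edges)]


def find_cgmuts(
    mutations: pd.DataFrame,
    restrict_to: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """CpG-abolishing mutations with the position of the lost cytosine.

    ``mutations`` needs ``chrom, pos (0-based), ref, alt, flank5, flank3``.
    A mutation qualifies when classifying it with the reference allele as
    the ancestral state yields CG_LOSS.  The returned frame adds
    ``cpg_pos``: the 0-based position of the CpG cytosine (the mutated base
    for C>N at a CpG; one base left for G>N hits on the G).  Mutations with
    unresolvable context are skipped with a warning; ``restrict_to`` (an
    interval track, e.g. exons) filters by mutation position.
    """
    keep_rows = []
    region = None
    if restrict_to is not None:
        region = _IntervalSet(
            {
                chrom: merge_intervals(zip(g["start"], g["end"]))
                for chrom, g in restrict_to.groupby("chrom")
            }
        )
    n_skipped = 0
    for row in mutations.itertuples(index=False):
        left = row.flank5[-1] if row.flank5 else "N"
        right = row.flank3[0] if row.flank3 else "N"
        valid = {"A", "C", "G", "T"}
        if left not in valid or right not in valid or row.ref not in valid or row.alt not in valid:
            n_skipped += 1
            continue
        if region is not None and not region.contains(row.chrom, np.asarray([row.pos]))[0]:
            continue
        sub = classify_substitution(left, row.ref, row.alt, right)
        cg = orient_gain_loss(sub, row.ref, row.alt, row.ref, left, right)
        if cg is not CgClass.CG_LOSS:
            continue
        # locate the abolished CpG's cytosine
        if row.ref == "C" and right == "G":
            cpg_pos = row.pos
        elif row.ref == "G" and left == "C":
            cpg_pos = row.pos - 1
        else:  # unreachable for a CG_LOSS call
            n_skipped += 1
            continue
        rec = row._asdict()
        rec["cpg_pos"] = cpg_pos
        rec["cg_class"] = cg.value
        keep_rows.append(rec)
    if n_skipped:
        logger.warning("%d mutations skipped (unresolvable context)", n_skipped)
    if not keep_rows:
        return pd.DataFrame(
            columns=list(mutations.columns) + ["cpg_pos", "cg_class"]
        )
    return pd.DataFrame(keep_rows)


def _track_maps(track: pd.DataFrame) -> Dict[str, pd.Series]:
    """chrom -> Series(level, index=pos) with positions unique and sorted."""
    out = {}
    for chrom, g in track.groupby("chrom"):
        if g["pos"].duplicated().any():
            raise SchemaError(f"duplicate methylation positions on {chrom}")
        out[chrom] = pd.Series(
            g["level"].to_numpy(), index=g["pos"].to_numpy()
        ).sort_index()
    return out


def site_differences(
    cgmuts: pd.DataFrame,
    normal: pd.DataFrame,
    tumor: pd.DataFrame,
) -> pd.DataFrame:
    """Normal-minus-tumor methylation at each cgMut's CpG cytosine.

    Sites absent from the normal track are skipped with a warning; sites
    absent from the tumor track are dropped and counted.  Returns a frame
    with ``chrom, cpg_pos, normal, tumor, diff``.
    """
    n_map = _track_maps(normal)
    t_map = _track_maps(tumor)
    rows = []
    n_no_normal = n_no_tumor = 0
    for row in cgmuts.itertuples(index=False):
        n_series = n_map.get(row.chrom)
        if n_series is None or row.cpg_pos not in n_series.index:
            n_no_normal += 1
            continue
        t_series = t_map.get(row.chrom)
        if t_series is None or row.cpg_pos not in t_series.index:
            n_no_tumor += 1
            continue
        n_level = float(n_series.loc[row.cpg_pos])
        t_level = float(t_series.loc[row.cpg_pos])
        rows.append(
            {
                "chrom": row.chrom,
                "cpg_pos": row.cpg_pos,
                "normal": n_level,
                "tumor": t_level,
                "diff": n_level - t_level,
            }
        )
    if n_no_normal:
        logger.warning("%d cgMut sites absent from the normal track", n_no_normal)
    if n_no_tumor:
        logger.warning("%d cgMut sites absent from the tumor track", n_no_tumor)
    return pd.DataFrame(rows, columns=["chrom", "cpg_pos", "normal", "tumor", "diff"])


def summarize_distribution(differences: Sequence[float]) -> dict:
    """Percentile summary (p10/p25/p50/p75/p90, linear interpolation) plus
    the fraction of sites with normal > tumor."""
    diffs = np.asarray(differences, dtype=float)
    if diffs.size == 0:
        raise EmptySummaryError("no methylation differences to summarize")
    p10, p25, p50, p75, p90 = np.percentile(diffs, [10, 25, 50, 75, 90])
    return {
        "n_sites": int(diffs.size),
        "p10": float(p10),
        "p25": float(p25),
        "p50": float(p50),
        "p75": float(p75),
        "p90": float(p90),
        "frac_normal_gt_tumor": float((diffs > 0).mean()),
    }


def bin_nearby(
    cgmuts: pd.DataFrame,
    normal: pd.DataFrame,
    tumor: pd.DataFrame,
    edges: Sequence[int] = DEFAULT_BIN_EDGES,
) -> pd.DataFrame:
    """Per-distance-bin summary of normal-minus-tumor differences.

    The mutated CpG cytosines form the SITE bin; every other CpG present in
    *both* tracks is assigned to the annulus of its minimum distance to any
    cgMut cytosine on the same chromosome (half-open annuli (lo, hi]); sites
    beyond the last edge are excluded.  Returns one row per bin with
    percentiles from :func:`summarize_distribution` (empty bins are
    reported with n_sites = 0 and NaN percentiles).
    """
    edges = list(edges)
    if any(e <= 0 for e in edges) or any(
        b <= a for a, b in zip(edges, edges[1:])
    ):
        raise ConfigError("distance bin edges must be positive and strictly increasing")
    n_map = _track_maps(normal)
    t_map = _track_maps(tumor)
    mut_pos: Dict[str, np.ndarray] = {
        chrom: np.sort(g["cpg_pos"].unique())
        for chrom, g in cgmuts.groupby("chrom")
    }
    labels = _annulus_labels(edges)
    diffs_by_bin: Dict[str, List[float]] = {SITE_BIN: [], **{l: [] for l in labels}}

    site_frame = site_differences(cgmuts, normal, tumor)
    diffs_by_bin[SITE_BIN] = site_frame["diff"].tolist()

    site_set = {
        (row.chrom, row.cpg_pos) for row in cgmuts.itertuples(index=False)
    }
    bounds = np.asarray(edges)
    for chrom, n_series in n_map.items():
        muts = mut_pos.get(chrom)
        if muts is None or len(muts) == 0:
            continue
        t_series = t_map.get(chrom)
        if t_series is None:
            continue
        common = n_series.index.intersection(t_series.index)
        pos = common.to_numpy()
        # minimum distance to any cgMut cytosine
        ins = np.searchsorted(muts, pos)
        left = np.where(ins > 0, pos - muts[np.maximum(ins - 1, 0)], np.iinfo(np.int64).max)
        right = np.where(
            ins < len(muts), muts[np.minimum(ins, len(muts) - 1)] - pos, np.iinfo(np.int64).max
        )
        dist = np.minimum(np.abs(left), np.abs(right))
        diff = n_series.loc[common].to_numpy() - t_series.loc[common].to_numpy()
        for p, d, dv in zip(pos, dist, diff):
            if (chrom, p) in site_set:
                continue
            if d == 0 or d > bounds[-1]:
                continue
            bin_idx = int(np.searchsorted(bounds, d, side="left"))
            diffs_by_bin[labels[bin_idx]].append(float(dv))

    rows = []
    for label in [SITE_BIN] + labels:
        vals = diffs_by_bin[label]
        if vals:
            summary = summarize_distribution(vals)
        else:
            summary = {
                "n_sites": 0,
                "p10": np.nan,
                "p25": np.nan,
                "p50": np.nan,
                "p75": np.nan,
                "p90": np.nan,
                "frac_normal_gt_tumor": np.nan,
            }
        rows.append({"bin": label, **summary})
    return pd.DataFrame(rows)
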