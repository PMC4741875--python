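"""Genomic-context annotation: CpG island / shore / open sea and gene context.

Islands are taken from an interval track (merged before use).  Shores are
the +/- ``shore_width`` (default 2 kb) flanks of the merged islands, minus
any island overlap; everything farther than ``shore_width`` from an island
is open sea.  Gene context is genebody / promoter / intergenic, where a
promoter is the ``promoter_width`` (default 2 kb) region upstream of a
gene's strand-aware 5' end; a position inside any gene body is GENEBODY
regardless of neighbouring promoters.

All coordinates are 0-based half-open.  Interval lookups use sorted merged
arrays and binary search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigError, SchemaError

logger = logging.getLogger(__name__)


class CpgRegion(Enum):
    ISLAND = "island"
    SHORE = "shore"
    OPEN_SEA = "open_sea"


class GeneRegion(Enum):
    GENEBODY = "genebody"
    PROMOTER = "promoter"
    INTERGENIC = "intergenic"


def merge_intervals(intervals: Iterable[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Merge overlapping or touching half-open intervals into a sorted list."""
    ivs = sorted(intervals)
    merged: List[Tuple[int, int]] = []
    for start, end in ivs:
        if start >= end:
            raise SchemaError(f"interval with start >= end: [{start}, {end})")
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def subtract_intervals(
    base: Sequence[Tuple[int, int]], remove: Sequence[Tuple[int, int]]
) -> List[Tuple[int, int]]:
    """``base`` minus ``remove``; both must be merged/sorted."""
    out: List[Tuple[int, int]] = []
    j = 0
    for start, end in base:
        cur = start
        while j < len(remove) and remove[j][1] <= cur:
            j += 1
        k = j
        while k < len(remove) and remove[k][0] < end:
            rs, re = remove[k]
            if rs > cur:
                out.append((cur, rs))
            cur = max(cur, re)
            if cur >= end:
                break
            k += 1
        if cur < end:
            out.append((cur, end))
    return out


class _IntervalSet:
    """Sorted disjoint intervals per chromosome with O(log n) membership."""

    def __init__(self, per_chrom: Dict[str, List[Tuple[int, int]]]):
        self._starts: Dict[str, np.ndarray] = {}
        self._ends: Dict[str, np.ndarray] = {}
        for chrom, ivs in per_chrom.items():
            arr = np.asarray(ivs, dtype=np.int64).reshape(-1, 2)
            self._starts[chrom] = arr[:, 0]
            self._ends[chrom] = arr[:, 1]

    def contains(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        pos = np.atleast_1d(np.asarray(pos, dtype=np.int64))
        starts = self._starts.get(chrom)
        if starts is None or len(starts) == 0:
            return np.zeros(len(pos), dtype=bool)
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = idx >= 0
        hit = np.zeros(len(pos), dtype=bool)
        hit[ok] = pos[ok] < self._ends[chrom][idx[ok]]
        return hit

    def intervals(self, chrom: str) -> List[Tuple[int, int]]:
        starts = self._starts.get(chrom)
        if starts is None:
            return []
        return list(zip(starts.tolist(), self._ends[chrom].tolist()))

    @property
    def chroms(self) -> List[str]:
        return list(self._starts)


@dataclass
class RegionIndex:
    """Island/shore membership index for CpG-context labelling."""

    islands: _IntervalSet
    shores: _IntervalSet
    shore_width: int

    def locate(self, chrom: str, pos: int) -> CpgRegion:
        labels = self.locate_many(chrom, np.asarray([pos]))
        return CpgRegion(labels[0])

    def locate_many(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Vectorised labels (CpgRegion values as strings) for one chromosome."""
        pos = np.asarray(pos, dtype=np.int64)
        if chrom not in self.islands.chroms and chrom not in self.shores.chroms:
            logger.warning("chromosome %s absent from island track; open sea", chrom)
            return np.full(len(pos), CpgRegion.OPEN_SEA.value, dtype=object)
        out = np.full(len(pos), CpgRegion.OPEN_SEA.value, dtype=object)
        shore = self.shores.contains(chrom, pos)
        out[shore] = CpgRegion.SHORE.value
        island = self.islands.contains(chrom, pos)
        out[island] = CpgRegion.ISLAND.value
        return out


def build_region_index(
    islands: pd.DataFrame,
    shore_width: int = 2000,
    chrom_lengths: Optional[Dict[str, int]] = None,
) -> RegionIndex:
    """Build the island/shore index from an island track.

    ``islands`` needs columns ``chrom, start, end`` (0-based half-open).
    Islands are merged first; shores are the +/- ``shore_width`` flanks of
    the merged islands minus island overlap, so shore zones of nearby
    islands merge and never shadow island labels.  Shores are truncated at
    position 0 and, when ``chrom_lengths`` is given, at chromosome ends.
    """
    if shore_width < 0:
        raise ConfigError(f"shore_width must be >= 0, got {shore_width}")
    island_map: Dict[str, List[Tuple[int, int]]] = {}
    shore_map: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, group in islands.groupby("chrom", sort=True):
        merged = merge_intervals(zip(group["start"], group["end"]))
        island_map[chrom] = merged
        limit = None if chrom_lengths is None else chrom_lengths.get(chrom)
        flanks = []
        for start, end in merged:
            lo = max(0, start - shore_width)
            hi = end + shore_width if limit is None else min(limit, end + shore_width)
            if lo < start:
                flanks.append((lo, start))
            if end < hi:
                flanks.append((end, hi))
        shore_map[chrom] = subtract_intervals(merge_intervals(flanks), merged) if flanks else []
    return RegionIndex(
        islands=_IntervalSet(island_map),
        shores=_IntervalSet(shore_map),
        shore_width=shore_width,
    )


@dataclass
class GeneIndex:
    """Genebody/promoter membership index."""

    bodies: _IntervalSet
    promoters: _IntervalSet
    promoter_width: int

    def locate(self, chrom: str, pos: int) -> GeneRegion:
        labels = self.locate_many(chrom, np.asarray([pos]))
        return GeneRegion(labels[0])

    def locate_many(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        pos = np.asarray(pos, dtype=np.int64)
        out = np.full(len(pos), GeneRegion.INTERGENIC.value, dtype=object)
        out[self.promoters.contains(chrom, pos)] = GeneRegion.PROMOTER.value
        out[self.bodies.contains(chrom, pos)] = GeneRegion.GENEBODY.value
        return out


def build_gene_index(
    genes: pd.DataFrame,
    promoter_width: int = 2000,
    chrom_lengths: Optional[Dict[str, int]] = None,
) -> GeneIndex:
    """Build the genebody/promoter index from a stranded gene track.

    A promoter is the ``promoter_width`` bases upstream of the gene's 5'
    end: left of ``start`` for + strand genes, right of ``end`` for -
    strand genes.  Genebody takes precedence over promoter everywhere.
    """
    if promoter_width < 0:
        raise ConfigError(f"promoter_width must be >= 0, got {promoter_width}")
    if "strand" not in genes.columns or genes["strand"].isna().any():
        raise SchemaError("gene track requires a strand column with no missing values")
    bad = ~genes["strand"].isin(["+", "-"])
    if bad.any():
        raise SchemaError(f"invalid strand value(s): {genes.loc[bad, 'strand'].unique()}")
    body_map: Dict[str, List[Tuple[int, int]]] = {}
    prom_map: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, group in genes.groupby("chrom", sort=True):
        body_map[chrom] = merge_intervals(zip(group["start"], group["end"]))
        limit = None if chrom_lengths is None else chrom_lengths.get(chrom)
        proms = []
        for start, end, strand in zip(group["start"], group["end"], group["strand"]):
            if strand == "+":
                lo, hi = max(0, start - promoter_width), start
            else:
                lo = end
                hi = end + promoter_width if limit is None else min(limit, end + promoter_width)
            if lo < hi:
                proms.append((lo, hi))
        prom_map[chrom] = merge_intervals(proms) if proms else []
    return GeneIndex(
        bodies=_IntervalSet(body_map),
        promoters=_IntervalSet(prom_map),
        promoter_width=promoter_width,
    )


def gene_context(
    pos: int,
    chrom: str,
    genes: pd.DataFrame,
    promoter_width: int = 2000,
) -> GeneRegion:
    """One-off gene-context lookup (builds a throwaway index)."""
    return build_gene_index(genes, promoter_width).locate(chrom, pos)


def annotate_frame(
    snps: pd.DataFrame,
    region_index: RegionIndex,
    gene_index: Optional[GeneIndex] = None,
) -> pd.DataFrame:
    """Append ``cpg_region`` (and ``gene_region`` if a gene index is given)
    columns to a SNP table with ``chrom`` and ``pos`` columns."""
    out = snps.copy()
    cpg = np.empty(len(out), dtype=object)
    gene = np.empty(len(out), dtype=object)
    for chrom, group in out.groupby("chrom", sort=False):
        pos = group["pos"].to_numpy()
        idx = group.index.to_numpy()
        loc = out.index.get_indexer(idx)
        cpg[loc] = region_index.locate_many(chrom, pos)
        if gene_index is not None:
            gene[loc] = gene_index.locate_many(chrom, pos)
    out["cpg_region"] = cpg
    if gene_index is not None:
        out["gene_region"] = gene
    return out
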