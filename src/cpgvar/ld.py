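"""Pairwise linkage disequilibrium: r-squared, tag counts, cgSNPt status,
and greedy LD pruning.

The unit of the downstream enrichment test is the *proxy SNP*: a SNP
retained after LD pruning.  A proxy is a *cgSNPt* if it is itself a cgSNP
or is in strong LD (r-squared strictly above the threshold, 0.8 by default)
with at least one cgSNP — such pairs are treated as sharing trait/eQTL
annotation.  ``n_tagged`` counts the *other* SNPs a proxy tags at the same
strict threshold; it enters the enrichment model as a confounder.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, Mapping, Sequence, Set, Tuple

import pandas as pd

from .classifier import CGSNP_CLASSES, CgClass
from .errors import UndefinedLdError

logger = logging.getLogger(__name__)

_CGSNP_VALUES = frozenset(c.value for c in CGSNP_CLASSES)


def r2_from_haplotype_counts(n_AB: int, n_Ab: int, n_aB: int, n_ab: int) -> float:
    """Squared allelic correlation r2 = D^2 / (pA pa pB pb) from the four
    haplotype counts of two biallelic loci.

    Raises :class:`UndefinedLdError` when either locus is monomorphic in
    the counts (the denominator vanishes).
    """
    n = n_AB + n_Ab + n_aB + n_ab
    if n <= 0:
        raise UndefinedLdError("haplotype counts sum to zero")
    if min(n_AB, n_Ab, n_aB, n_ab) < 0:
        raise ValueError("haplotype counts must be non-negative")
    p_A = (n_AB + n_Ab) / n
    p_B = (n_AB + n_aB) / n
    denom = p_A * (1 - p_A) * p_B * (1 - p_B)
    if denom == 0:
        raise UndefinedLdError("monomorphic locus: r2 undefined")
    d = n_AB / n - p_A * p_B
    return (d * d) / denom


class LdIndex:
    """Symmetric sparse map of pairwise r2 values.

    Absent pairs are treated as r2 = 0.  Self pairs are rejected; a pair
    loaded in both orientations collapses to a single entry (the last value
    read wins).
    """

    def __init__(self) -> None:
        self._adj: Dict[str, Dict[str, float]] = {}

    @classmethod
    def from_pairs(cls, pairs: Iterable[Tuple[str, str, float]]) -> "LdIndex":
        index = cls()
        for a, b, r2 in pairs:
            index.add(a, b, r2)
        return index

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "LdIndex":
        """Build from a DataFrame with ``snp_a, snp_b, r2`` columns."""
        return cls.from_pairs(
            zip(frame["snp_a"], frame["snp_b"], frame["r2"])
        )

    def add(self, a: str, b: str, r2: float) -> None:
        if a == b:
            raise ValueError(f"self LD pair for {a!r}")
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"r2 {r2} outside [0, 1] for pair ({a}, {b})")
        self._adj.setdefault(a, {})[b] = r2
        self._adj.setdefault(b, {})[a] = r2

    def neighbors(self, snp_id: str) -> Mapping[str, float]:
        return self._adj.get(snp_id, {})

    def r2(self, a: str, b: str) -> float:
        return self._adj.get(a, {}).get(b, 0.0)

    def __len__(self) -> int:
        return sum(len(v) for v in self._adj.values()) // 2

    def ids(self) -> Set[str]:
        return set(self._adj)


def tag_count(snp_id: str, ld_index: LdIndex, threshold: float = 0.8) -> int:
    """Number of distinct *other* SNPs with r2 strictly above ``threshold``."""
    if snp_id not in ld_index.ids():
        return 0
    return sum(1 for r2 in ld_index.neighbors(snp_id).values() if r2 > threshold)


def cgsnpt_status(
    snp_id: str,
    cg_classes: Mapping[str, str],
    ld_index: LdIndex,
    threshold: float = 0.8,
) -> bool:
    """True iff the SNP is a cgSNP (gain, loss, or unoriented) or tags at
    least one cgSNP at r2 strictly above ``threshold``."""
    if cg_classes.get(snp_id) in _CGSNP_VALUES:
        return True
    for other, r2 in ld_index.neighbors(snp_id).items():
        if r2 > threshold and cg_classes.get(other) in _CGSNP_VALUES:
            return True
    return False


def ld_prune(
    snp_ids: Sequence[str], ld_index: LdIndex, threshold: float = 0.8
) -> list:
    """Greedy LD pruning over a deterministically ordered SNP list.

    Scans ``snp_ids`` in the given order (callers should order by chrom,
    pos, id) and retains a SNP iff its r2 with every already-retained SNP
    is <= ``threshold``.  The result is deterministic given the ordering,
    and maximal: every dropped SNP exceeds the threshold with some retained
    SNP.
    """
    retained: list = []
    retained_set: Set[str] = set()
    for snp_id in snp_ids:
        conflict = any(
            r2 > threshold and other in retained_set
            for other, r2 in ld_index.neighbors(snp_id).items()
        )
        if not conflict:
            retained.append(snp_id)
            retained_set.add(snp_id)
    return retained


def annotate_proxies(
    classified: pd.DataFrame,
    ld_index: LdIndex,
    threshold: float = 0.8,
) -> pd.DataFrame:
    """Per-SNP proxy annotation: cgSNP status, cgSNPt status, tag count.

    ``classified`` needs ``snp_id``, ``cg_class`` and ``maf`` columns; tag
    counts and cgSNPt status are computed on the full panel (pruning, if
    any, selects rows of the returned frame afterwards).
    """
    cg_map = dict(zip(classified["snp_id"], classified["cg_class"]))
    is_cgsnp = classified["cg_class"].isin(_CGSNP_VALUES).to_numpy()
    n_tagged = [
        tag_count(s, ld_index, threshold) for s in classified["snp_id"]
    ]
    is_cgsnpt = [
        bool(cg) or cgsnpt_status(s, cg_map, ld_index, threshold)
        for s, cg in zip(classified["snp_id"], is_cgsnp)
    ]
    out = classified[["snp_id", "maf"]].copy()
    out["is_cgsnp"] = is_cgsnp
    out["is_cgsnpt"] = is_cgsnpt
    out["n_tagged"] = n_tagged
    return out
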