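"""Classification of single-base substitutions by their effect on CpG sites.

A SNP whose two alleles differ in whether a CpG dinucleotide overlaps the
variant position is a CpG-site-related SNP (cgSNP).  Because a CpG can only
involve the variant base and one immediate neighbour, classification needs
exactly the trinucleotide context: the base 5' of the variant, the two
alleles, and the base 3' of the variant.  With a known ancestral allele a
cgSNP is oriented as a *gain* (the derived allele creates the CpG) or a
*loss* (the derived allele abolishes it).  Substitutions for which *both*
alleles carry a CpG — necessarily at different, adjacent dinucleotides, as
in C[C/G]G — merely shift the CpG by one base and are excluded from cgSNPs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from typing import Iterable, Optional

import pandas as pd

from .errors import (
    DegenerateVariantError,
    InconsistentAncestralError,
    InvalidBaseError,
)

BASES = ("A", "C", "G", "T")
_BASE_SET = frozenset(BASES)
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class SubstitutionClass(Enum):
    """Unoriented effect of a substitution on CpG presence in its context."""

    NON_CG = "non_cg"
    CG_POLYMORPHIC = "cg_polymorphic"
    CG_SHIFT = "cg_shift"


class CgClass(Enum):
    """Oriented cgSNP class."""

    NON_CG = "non_cg"
    CG_GAIN = "cg_gain"
    CG_LOSS = "cg_loss"
    CG_UNORIENTED = "cg_unoriented"
    CG_SHIFT_EXCLUDED = "cg_shift_excluded"


#: Classes counted as cgSNPs downstream (shift variants are excluded).
CGSNP_CLASSES = frozenset(
    {CgClass.CG_GAIN, CgClass.CG_LOSS, CgClass.CG_UNORIENTED}
)


def _check_base(b: str, what: str = "base") -> str:
    if b not in _BASE_SET:
        raise InvalidBaseError(f"invalid {what}: {b!r} (expected one of A,C,G,T)")
    return b


def complement(base: str) -> str:
    return _COMPLEMENT[_check_base(base)]


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class SnpRecord:
    """One biallelic substitution with its immediate sequence context.

    ``pos`` is 0-based internally; TSV readers/writers convert.  ``flank5``
    ends with the base immediately 5' of the variant, ``flank3`` starts with
    the base immediately 3'.  ``ancestral`` is ``None`` when the ancestral
    state is unknown.
    """

    snp_id: str
    chrom: str
    pos: int
    strand: str
    allele_a: str
    allele_b: str
    ancestral: Optional[str]
    maf: float
    flank5: str
    flank3: str

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise DegenerateVariantError(
                f"{self.snp_id}: alleles are identical ({self.allele_a})"
            )
        _check_base(self.allele_a, "allele")
        _check_base(self.allele_b, "allele")
        if self.ancestral is not None and self.ancestral not in (
            self.allele_a,
            self.allele_b,
        ):
            raise InconsistentAncestralError(
                f"{self.snp_id}: ancestral {self.ancestral!r} matches neither allele"
            )
        if not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"{self.snp_id}: MAF {self.maf} outside [0, 0.5]")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.snp_id}: strand must be '+' or '-'")
        if not self.flank5 or not self.flank3:
            raise ValueError(f"{self.snp_id}: flanks must be non-empty")

    @property
    def left(self) -> str:
        """Base immediately 5' of the variant."""
        return self.flank5[-1]

    @property
    def right(self) -> str:
        """Base immediately 3' of the variant."""
        return self.flank3[0]

    def reverse_complemented(self) -> "SnpRecord":
        """The same variant described on the opposite strand."""
        return SnpRecord(
            snp_id=self.snp_id,
            chrom=self.chrom,
            pos=self.pos,
            strand="-" if self.strand == "+" else "+",
            allele_a=complement(self.allele_a),
            allele_b=complement(self.allele_b),
            ancestral=None if self.ancestral is None else complement(self.ancestral),
            maf=self.maf,
            flank5=reverse_complement(self.flank3),
            flank3=reverse_complement(self.flank5),
        )


@dataclass(frozen=True)
class Classification:
    """Result of classifying one record: oriented class plus an optional warning."""

    cg_class: CgClass
    warning: Optional[str] = None


def cpg_present(left: str, center: str, right: str) -> bool:
    """True iff the trinucleotide ``left center right`` contains a CpG
    overlapping the center base (either ``left-center`` = CG or
    ``center-right`` = CG)."""
    _check_base(left)
    _check_base(center)
    _check_base(right)
    return (left == "C" and center == "G") or (center == "C" and right == "G")


def classify_substitution(
    left: str, allele_a: str, allele_b: str, right: str
) -> SubstitutionClass:
    """Unoriented CpG effect of a biallelic substitution in context.

    CG_POLYMORPHIC: exactly one allele yields a CpG overlapping the site.
    CG_SHIFT: both alleles do (at different dinucleotides, e.g. C[C/G]G).
    NON_CG: neither does.
    """
    if allele_a == allele_b:
        raise DegenerateVariantError(f"alleles are identical: {allele_a}")
    a_cpg = cpg_present(left, allele_a, right)
    b_cpg = cpg_present(left, allele_b, right)
    if a_cpg and b_cpg:
        return SubstitutionClass.CG_SHIFT
    if a_cpg or b_cpg:
        return SubstitutionClass.CG_POLYMORPHIC
    return SubstitutionClass.NON_CG


def orient_gain_loss(
    sub_class: SubstitutionClass,
    allele_a: str,
    allele_b: str,
    ancestral: Optional[str],
    left: str,
    right: str,
) -> CgClass:
    """Orient a CpG-polymorphic substitution by its ancestral allele.

    Taking the ancestral trinucleotide as the initial state: the variant is
    a CG_GAIN if the derived allele creates the CpG, a CG_LOSS if the
    ancestral state carried it.  With no ancestral information the variant
    stays CG_UNORIENTED (still a cgSNP).  NON_CG and CG_SHIFT inputs pass
    through unchanged (shift variants become CG_SHIFT_EXCLUDED).
    """
    if sub_class is SubstitutionClass.NON_CG:
        return CgClass.NON_CG
    if sub_class is SubstitutionClass.CG_SHIFT:
        return CgClass.CG_SHIFT_EXCLUDED
    if ancestral is None:
        return CgClass.CG_UNORIENTED
    if ancestral not in (allele_a, allele_b):
        raise InconsistentAncestralError(
            f"ancestral {ancestral!r} is neither allele ({allele_a}/{allele_b})"
        )
    if cpg_present(left, ancestral, right):
        return CgClass.CG_LOSS
    return CgClass.CG_GAIN


def classify_snp_record(snp: SnpRecord) -> Classification:
    """Classify one SNP record from its adjacent context bases.

    Only the base immediately 5' and immediately 3' of the variant are used;
    longer flanks are accepted.  An ambiguity code (N or any IUPAC letter)
    in either context base makes the site unclassifiable: it is returned as
    NON_CG with a machine-readable warning rather than raising, so
    genome-scale runs do not abort.
    """
    left, right = snp.left, snp.right
    if left not in _BASE_SET or right not in _BASE_SET:
        return Classification(
            CgClass.NON_CG,
            warning=f"ambiguous_context:{left}{right}",
        )
    sub = classify_substitution(left, snp.allele_a, snp.allele_b, right)
    cg = orient_gain_loss(sub, snp.allele_a, snp.allele_b, snp.ancestral, left, right)
    return Classification(cg)


@lru_cache(maxsize=1)
def _oriented_lookup() -> dict:
    """Lookup (left, allele_a, allele_b, ancestral-or-'', right) -> CgClass value."""
    table = {}
    for left, a, b, right in itertools.product(BASES, BASES, BASES, BASES):
        if a == b:
            continue
        sub = classify_substitution(left, a, b, right)
        for anc in (a, b, None):
            key = (left, a, b, "" if anc is None else anc, right)
            table[key] = orient_gain_loss(sub, a, b, anc, left, right).value
    return table


def classify_frame(snps: pd.DataFrame) -> pd.DataFrame:
    """Vectorised classification of a SNP table.

    Expects columns ``allele_a, allele_b, ancestral, flank5, flank3``
    (``ancestral`` empty/NaN when unknown).  Returns a copy with ``cg_class``
    (CgClass values as strings) and ``warning`` columns appended.
    """
    lookup = _oriented_lookup()
    classes = []
    warnings = []
    anc_col = snps["ancestral"].fillna("")
    for a, b, anc, f5, f3 in zip(
        snps["allele_a"], snps["allele_b"], anc_col, snps["flank5"], snps["flank3"]
    ):
        key = (f5[-1], a, b, anc, f3[0])
        cls = lookup.get(key)
        if cls is None:
            classes.append(CgClass.NON_CG.value)
            warnings.append(f"ambiguous_context:{f5[-1]}{f3[0]}")
        else:
            classes.append(cls)
            warnings.append("")
    out = snps.copy()
    out["cg_class"] = classes
    out["warning"] = warnings
    return out


def enumerate_scenarios() -> pd.DataFrame:
    """Exhaustive table of all 4 x 4 x 3 x 4 = 192 ordered substitution
    scenarios ``(left, ancestral, derived, right)`` with their oriented class.

    Every ancestral/derived ordered pair appears once, so each unordered
    cgSNP corresponds to one CG_GAIN row and one mirror CG_LOSS row; the two
    counts are equal by construction.  The table carries an ``is_shift``
    flag for the CpG-shift scenarios, which are excluded from cgSNPs.
    """
    rows = []
    for left, anc, der, right in itertools.product(BASES, BASES, BASES, BASES):
        if anc == der:
            continue
        sub = classify_substitution(left, anc, der, right)
        cg = orient_gain_loss(sub, anc, der, anc, left, right)
        rows.append(
            {
                "left_base": left,
                "ancestral_allele": anc,
                "derived_allele": der,
                "right_base": right,
                "cg_class": cg.value,
                "is_shift": cg is CgClass.CG_SHIFT_EXCLUDED,
            }
        )
    return pd.DataFrame(rows)


def scenario_counts(table: Optional[pd.DataFrame] = None) -> dict:
    """Summary counts of the scenario enumeration."""
    if table is None:
        table = enumerate_scenarios()
    counts = table["cg_class"].value_counts()
    n_gain = int(counts.get(CgClass.CG_GAIN.value, 0))
    n_loss = int(counts.get(CgClass.CG_LOSS.value, 0))
    return {
        "n_total": int(len(table)),
        "n_gain": n_gain,
        "n_loss": n_loss,
        "n_gain_loss": n_gain + n_loss,
        "n_shift": int(counts.get(CgClass.CG_SHIFT_EXCLUDED.value, 0)),
        "n_non_cg": int(counts.get(CgClass.NON_CG.value, 0)),
    }


def summarize_classes(
    classified: pd.DataFrame, group_by: str = "cpg_region"
) -> pd.DataFrame:
    """Per-region counts and percentages of cg-gain and cg-loss SNPs.

    The denominator for the percentages is the total number of cgSNPs in
    the region — gains + losses + unoriented — so the two percentages need
    not sum to 100 when some cgSNPs lack ancestral information.  A
    ``Global`` row aggregates over all regions.
    """
    if classified.empty:
        return pd.DataFrame(
            columns=[group_by, "n_cgsnp", "n_gain", "pct_gain", "n_loss", "pct_loss"]
        )

    def _one(group: pd.DataFrame, label: str) -> dict:
        cls = group["cg_class"]
        n_gain = int((cls == CgClass.CG_GAIN.value).sum())
        n_loss = int((cls == CgClass.CG_LOSS.value).sum())
        n_unor = int((cls == CgClass.CG_UNORIENTED.value).sum())
        n_cg = n_gain + n_loss + n_unor
        return {
            group_by: label,
            "n_cgsnp": n_cg,
            "n_gain": n_gain,
            "pct_gain": 100.0 * n_gain / n_cg if n_cg else 0.0,
            "n_loss": n_loss,
            "pct_loss": 100.0 * n_loss / n_cg if n_cg else 0.0,
        }

    rows = [
        _one(group, str(label))
        for label, group in classified.groupby(group_by, sort=True)
    ]
    rows.append(_one(classified, "Global"))
    return pd.DataFrame(rows)
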