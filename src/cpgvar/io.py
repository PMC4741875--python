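"""Readers and writers for the pipeline's tabular formats.

All bespoke tables are tab-separated with a header row.  Coordinates are
0-based half-open inside the package; SNP, methylation, and mutation TSVs
carry 1-based positions (converted at the boundary), BED is 0-based
half-open as the format dictates.  Malformed rows are rejected with their
line numbers; biallelic-substitution filters (indels, multiallelic sites)
skip rows with a count instead of aborting.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .errors import SchemaError

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

SNP_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "strand",
    "allele_a",
    "allele_b",
    "ancestral",
    "maf",
    "flank5",
    "flank3",
]
_VALID_BASES = {"A", "C", "G", "T"}


def _require_columns(frame: pd.DataFrame, required, path: PathLike) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_snp_table(path: PathLike) -> Tuple[pd.DataFrame, int]:
    """Read a SNP TSV (1-based ``pos`` converted to 0-based).

    Rows that are not simple biallelic substitutions (multi-base alleles,
    identical alleles, non-ACGT allele codes) are skipped and counted;
    returns ``(frame, n_skipped)``.  ``ancestral`` uses ``.`` or empty for
    missing.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(frame, SNP_COLUMNS, path)
    frame["ancestral"] = frame["ancestral"].replace(".", "")
    ok_alleles = (
        frame["allele_a"].isin(_VALID_BASES)
        & frame["allele_b"].isin(_VALID_BASES)
        & (frame["allele_a"] != frame["allele_b"])
    )
    anc_ok = (frame["ancestral"] == "") | (
        (frame["ancestral"] == frame["allele_a"])
        | (frame["ancestral"] == frame["allele_b"])
    )
    keep = ok_alleles & anc_ok
    n_skipped = int((~keep).sum())
    if n_skipped:
        logger.info(
            "%s: skipped %d non-biallelic-substitution row(s)", path, n_skipped
        )
    frame = frame.loc[keep].copy()
    try:
        frame["pos"] = frame["pos"].astype(np.int64) - 1
        frame["maf"] = frame["maf"].astype(float)
    except ValueError as exc:
        raise SchemaError(f"{path}: non-numeric pos or maf: {exc}") from exc
    if ((frame["maf"] < 0) | (frame["maf"] > 0.5)).any():
        raise SchemaError(f"{path}: maf outside [0, 0.5]")
    if (frame["pos"] < 0).any():
        raise SchemaError(f"{path}: pos must be >= 1 (1-based)")
    return frame.reset_index(drop=True), n_skipped


def write_snp_table(frame: pd.DataFrame, path: PathLike) -> None:
    """Write a SNP TSV (0-based ``pos`` converted back to 1-based); any
    extra columns (``cg_class``, region labels...) are emitted after the
    core schema columns."""
    out = frame.copy()
    out["pos"] = out["pos"].astype(np.int64) + 1
    out["ancestral"] = out["ancestral"].replace("", ".").fillna(".")
    extra = [c for c in out.columns if c not in SNP_COLUMNS]
    out[SNP_COLUMNS + extra].to_csv(path, sep="\t", index=False)


def read_bed(path: PathLike, require_strand: bool = False) -> pd.DataFrame:
    """Read a BED track (0-based half-open) into ``chrom, start, end,
    name, strand`` columns.  Requires 6 columns when ``require_strand``."""
    rows = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SchemaError(f"{path}:{lineno}: fewer than 3 BED columns")
            if require_strand and len(fields) < 6:
                raise SchemaError(f"{path}:{lineno}: strand requires 6 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise SchemaError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise SchemaError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            strand = fields[5] if len(fields) >= 6 else None
            if require_strand and strand not in ("+", "-"):
                raise SchemaError(f"{path}:{lineno}: invalid strand {strand!r}")
            rows.append(
                {
                    "chrom": fields[0],
                    "start": start,
                    "end": end,
                    "name": fields[3] if len(fields) >= 4 else "",
                    "strand": strand,
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])


def write_bed(frame: pd.DataFrame, path: PathLike) -> None:
    out = frame.copy()
    cols = ["chrom", "start", "end"]
    if "name" in out.columns:
        cols.append("name")
        if "strand" in out.columns and out["strand"].notna().all():
            out["score"] = 0
            cols += ["score", "strand"]
    out[cols].to_csv(path, sep="\t", index=False, header=False)


_LD_ALIASES = {"snp_a": {"snp_a", "SNP_A"}, "snp_b": {"snp_b", "SNP_B"}, "r2": {"r2", "R2"}}


def read_ld_table(path: PathLike) -> pd.DataFrame:
    """Read a PLINK ``--r2``-style pair table.

    Accepts the PLINK column layout (CHR_A BP_A SNP_A CHR_B BP_B SNP_B R2)
    or a plain ``snp_a/snp_b/r2`` header; extra columns are ignored.
    Reversed duplicate pairs collapse silently to a single symmetric entry
    (the last value read wins).
    """
    frame = pd.read_csv(path, sep=r"\s+", dtype=str)
    rename = {}
    for canon, aliases in _LD_ALIASES.items():
        found = [c for c in frame.columns if c in aliases]
        if not found:
            raise SchemaError(f"{path}: missing LD column {canon} (or PLINK alias)")
        rename[found[0]] = canon
    frame = frame.rename(columns=rename)[["snp_a", "snp_b", "r2"]]
    try:
        frame["r2"] = frame["r2"].astype(float)
    except ValueError as exc:
        raise SchemaError(f"{path}: non-numeric r2: {exc}") from exc
    if ((frame["r2"] < 0) | (frame["r2"] > 1)).any():
        raise SchemaError(f"{path}: r2 outside [0, 1]")
    if (frame["snp_a"] == frame["snp_b"]).any():
        raise SchemaError(f"{path}: self LD pair")
    key = frame.apply(lambda r: tuple(sorted((r["snp_a"], r["snp_b"]))), axis=1)
    frame = frame.assign(_key=key).drop_duplicates("_key", keep="last")
    return frame.drop(columns="_key").reset_index(drop=True)


def write_ld_table(frame: pd.DataFrame, path: PathLike) -> None:
    frame[["snp_a", "snp_b", "r2"]].to_csv(path, sep="\t", index=False)


OUTCOME_COLUMNS = ["snp_id", "outcome", "trait", "category", "reported_p"]


def read_outcomes(path: PathLike) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(frame, OUTCOME_COLUMNS, path)
    bad = ~frame["outcome"].isin(["eqtl", "trait"])
    if bad.any():
        raise SchemaError(f"{path}: outcome must be 'eqtl' or 'trait'")
    frame["reported_p"] = frame["reported_p"].replace("", "nan").astype(float)
    return frame


def write_outcomes(frame: pd.DataFrame, path: PathLike) -> None:
    frame[OUTCOME_COLUMNS].to_csv(path, sep="\t", index=False)


def read_methylation_track(path: PathLike) -> pd.DataFrame:
    """Read a bedGraph-like methylation TSV: chrom, pos (1-based CpG
    cytosine), level in [0, 1].  Positions converted to 0-based."""
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(frame, ["chrom", "pos", "level"], path)
    frame["pos"] = frame["pos"].astype(np.int64) - 1
    frame["level"] = frame["level"].astype(float)
    if ((frame["level"] < 0) | (frame["level"] > 1)).any():
        raise SchemaError(f"{path}: methylation level outside [0, 1]")
    return frame


def write_methylation_track(frame: pd.DataFrame, path: PathLike) -> None:
    out = frame.copy()
    out["pos"] = out["pos"].astype(np.int64) + 1
    out[["chrom", "pos", "level"]].to_csv(path, sep="\t", index=False)


MUTATION_COLUMNS = ["chrom", "pos", "ref", "alt", "flank5", "flank3"]


def read_mutations(path: PathLike) -> pd.DataFrame:
    """Read a somatic mutation TSV (1-based ``pos`` converted to 0-based)."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(frame, MUTATION_COLUMNS, path)
    frame["pos"] = frame["pos"].astype(np.int64) - 1
    return frame


def write_mutations(frame: pd.DataFrame, path: PathLike) -> None:
    out = frame[MUTATION_COLUMNS].copy()
    out["pos"] = out["pos"].astype(np.int64) + 1
    out.to_csv(path, sep="\t", index=False)


def read_proxies(path: PathLike) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    _require_columns(frame, ["snp_id", "maf", "is_cgsnp", "is_cgsnpt", "n_tagged"], path)
    frame["is_cgsnp"] = frame["is_cgsnp"].astype(bool)
    frame["is_cgsnpt"] = frame["is_cgsnpt"].astype(bool)
    return frame


def write_proxies(frame: pd.DataFrame, path: PathLike) -> None:
    frame.to_csv(path, sep="\t", index=False)


def write_results_json(results: dict, path: PathLike) -> None:
    def _default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON serializable: {type(obj)}")

    Path(path).write_text(json.dumps(results, indent=2, default=_default) + "\n")


def read_results_json(path: PathLike) -> dict:
    return json.loads(Path(path).read_text())
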