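"""Enrichment of cgSNPts among eQTLs / trait-associated SNPs.

Two complementary tests, run on the proxy-SNP panel:

* a covariate-adjusted logistic regression
      ln(P/(1-P)) = b0 + b_cgsnpt * X_cgsnpt + b_maf * X_maf + b_tags * X_tags
  where P is the probability of the proxy being outcome-positive (eQTL or
  trait-associated), X_cgsnpt is the binary cgSNPt indicator, and minor
  allele frequency plus tag count are confounder covariates; the reported
  effect is OR = exp(b_cgsnpt) with a 95% Wald interval;

* a matched-resampling test: proxies are stratified on (MAF bin x tag-count
  bin), and null SNP sets matching the index set's per-stratum composition
  exactly are drawn repeatedly without replacement from the non-index pool.
  The empirical p-value is the fraction of draws whose cgSNPt count meets
  or exceeds the observed count (ties count toward p — conservative).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .errors import (
    CollinearityError,
    ConfigError,
    InfeasibleMatchingError,
    SchemaError,
    SeparationError,
)

logger = logging.getLogger(__name__)

#: -log10(p) lower edges of the 8 reported-p-value bins (last bin open-ended).
DEFAULT_P_BIN_EDGES: Tuple[float, ...] = (5, 6, 7, 8, 11, 14, 17, 20)


@dataclass(frozen=True)
class EnrichmentResult:
    """Fitted logistic enrichment model for the cgSNPt indicator."""

    beta0: float
    beta_cgsnpt: float
    beta_maf: float
    beta_tags: float
    or_cgsnpt: float
    ci_low: float
    ci_high: float
    p_wald: float
    n: int
    n_positive: int
    converged: bool

    def as_dict(self) -> dict:
        return {
            "beta0": self.beta0,
            "beta_cgsnpt": self.beta_cgsnpt,
            "beta_maf": self.beta_maf,
            "beta_tags": self.beta_tags,
            "or_cgsnpt": self.or_cgsnpt,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_wald": self.p_wald,
            "n": self.n,
            "n_positive": self.n_positive,
            "converged": self.converged,
        }


def fit_enrichment_model(data: pd.DataFrame) -> EnrichmentResult:
    """Maximum-likelihood fit of the logistic enrichment model.

    ``data`` needs columns ``y`` (binary outcome), ``x_cgsnpt`` (binary),
    ``x_maf`` and ``x_tags``.  Raises :class:`CollinearityError` when the
    outcome or the cgSNPt indicator has a single state, and
    :class:`SeparationError` on perfect separation or non-convergence.
    """
    y = np.asarray(data["y"], dtype=float)
    if len(np.unique(y)) < 2:
        raise CollinearityError("outcome y has a single state; fit not identified")
    x_cg = np.asarray(data["x_cgsnpt"], dtype=float)
    if len(np.unique(x_cg)) < 2:
        raise CollinearityError("x_cgsnpt is constant; OR not identified")
    X = np.column_stack(
        [
            np.ones(len(y)),
            x_cg,
            np.asarray(data["x_maf"], dtype=float),
            np.asarray(data["x_tags"], dtype=float),
        ]
    )
    if not np.isfinite(X).all():
        raise SchemaError("non-finite covariate values in enrichment input")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    converged = bool(fit.mle_retvals.get("converged", False))
    if not converged:
        raise SeparationError("logistic fit did not converge (possible separation)")
    beta = fit.params
    se = fit.bse
    return EnrichmentResult(
        beta0=float(beta[0]),
        beta_cgsnpt=float(beta[1]),
        beta_maf=float(beta[2]),
        beta_tags=float(beta[3]),
        or_cgsnpt=float(np.exp(beta[1])),
        ci_low=float(np.exp(beta[1] - 1.96 * se[1])),
        ci_high=float(np.exp(beta[1] + 1.96 * se[1])),
        p_wald=float(fit.pvalues[1]),
        n=int(len(y)),
        n_positive=int(y.sum()),
        converged=converged,
    )


@dataclass(frozen=True)
class StratumScheme:
    """Binning of proxies on the matching factors MAF and tag count.

    Defaults: MAF bins of width 0.05 over [0, 0.5] (upper edge inclusive)
    and tag-count bins {0}, {1-2}, {3-5}, {6-10}, {>10}.
    """

    maf_edges: Tuple[float, ...] = tuple(np.round(np.arange(0.0, 0.55, 0.05), 3))
    tag_edges: Tuple[int, ...] = (1, 3, 6, 11)

    def __post_init__(self) -> None:
        if list(self.maf_edges) != sorted(set(self.maf_edges)):
            raise ConfigError("maf_edges must be strictly increasing")
        if list(self.tag_edges) != sorted(set(self.tag_edges)):
            raise ConfigError("tag_edges must be strictly increasing")

    @property
    def n_maf_bins(self) -> int:
        return len(self.maf_edges) - 1

    @property
    def n_tag_bins(self) -> int:
        return len(self.tag_edges) + 1


def assign_strata(proxies: pd.DataFrame, scheme: Optional[StratumScheme] = None) -> pd.Series:
    """Deterministic (MAF bin x tag bin) stratum code per proxy SNP.

    MAF bins are half-open [lo, hi) except the last, which includes its
    upper edge so MAF = 0.5 is covered.  Raises :class:`ConfigError` when
    a value falls outside the scheme.
    """
    scheme = scheme or StratumScheme()
    maf = np.asarray(proxies["maf"], dtype=float)
    tags = np.asarray(proxies["n_tagged"], dtype=np.int64)
    edges = np.asarray(scheme.maf_edges, dtype=float)
    if maf.size and (maf.min() < edges[0] or maf.max() > edges[-1]):
        raise ConfigError("MAF value outside the stratum scheme edges")
    if tags.size and tags.min() < 0:
        raise ConfigError("negative tag count")
    maf_bin = np.clip(np.searchsorted(edges, maf, side="right") - 1, 0, scheme.n_maf_bins - 1)
    tag_bin = np.searchsorted(np.asarray(scheme.tag_edges), tags, side="right")
    codes = maf_bin * scheme.n_tag_bins + tag_bin
    return pd.Series(codes, index=proxies.index, name="stratum")


@dataclass
class SimulationResult:
    """Matched-resampling null for the cgSNPt count of an index SNP set."""

    observed_count: int
    null_counts: np.ndarray
    empirical_p: float
    p_label: str
    n_draws: int
    index_size: int
    draws: Optional[List[np.ndarray]] = None  # per-draw proxy row positions

    def as_dict(self) -> dict:
        return {
            "observed_count": self.observed_count,
            "empirical_p": self.empirical_p,
            "p_label": self.p_label,
            "n_draws": self.n_draws,
            "index_size": self.index_size,
            "null_counts": [int(c) for c in self.null_counts],
        }


def matched_simulation_test(
    index_ids: Sequence[str],
    proxies: pd.DataFrame,
    strata: pd.Series,
    n_draws: int = 300,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    plus_one: bool = False,
    return_draws: bool = False,
) -> SimulationResult:
    """Stratified matched-resampling test of cgSNPt enrichment.

    Each of the ``n_draws`` null sets reproduces the index set's per-stratum
    composition exactly, sampling without replacement from the non-index
    proxies of each stratum.  ``empirical_p`` is the proportion of draws
    whose cgSNPt count >= the observed count; when no draw reaches it the
    label reports "< 1/n_draws".  ``plus_one`` switches to the
    (exceed+1)/(n_draws+1) estimator.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    ids = np.asarray(proxies["snp_id"])
    cgsnpt = np.asarray(proxies["is_cgsnpt"], dtype=bool)
    codes = np.asarray(strata, dtype=np.int64)
    if len(codes) != len(ids):
        raise SchemaError("strata length does not match proxies")
    pos_of = {s: i for i, s in enumerate(ids)}
    try:
        index_pos = np.asarray([pos_of[s] for s in index_ids], dtype=np.int64)
    except KeyError as exc:
        raise SchemaError(f"index SNP {exc} absent from proxy panel") from exc
    observed = int(cgsnpt[index_pos].sum())

    in_index = np.zeros(len(ids), dtype=bool)
    in_index[index_pos] = True
    need: Dict[int, int] = {}
    for c in codes[index_pos]:
        need[int(c)] = need.get(int(c), 0) + 1

    null_counts = np.zeros(n_draws, dtype=np.int64)
    draw_members: Optional[List[List[np.ndarray]]] = (
        [[] for _ in range(n_draws)] if return_draws else None
    )
    for code in sorted(need):
        k = need[code]
        pool = np.flatnonzero((codes == code) & ~in_index)
        if len(pool) < k:
            raise InfeasibleMatchingError(
                f"stratum {code}: pool size {len(pool)} < required {k}"
            )
        # all draws for this stratum at once: rank random keys, keep k smallest
        keys = rng.random((n_draws, len(pool)))
        picked = np.argpartition(keys, k - 1, axis=1)[:, :k]
        chosen = pool[picked]  # (n_draws, k)
        null_counts += cgsnpt[chosen].sum(axis=1)
        if draw_members is not None:
            for d in range(n_draws):
                draw_members[d].append(chosen[d])

    exceed = int((null_counts >= observed).sum())
    if plus_one:
        p = (exceed + 1) / (n_draws + 1)
        label = f"{p:.4g}"
    else:
        p = exceed / n_draws
        label = f"< {1.0 / n_draws:.4g}" if exceed == 0 else f"{p:.4g}"
    draws = (
        [np.concatenate(parts) for parts in draw_members]
        if draw_members is not None
        else None
    )
    return SimulationResult(
        observed_count=observed,
        null_counts=null_counts,
        empirical_p=float(p),
        p_label=label,
        n_draws=n_draws,
        index_size=len(index_pos),
        draws=draws,
    )


def feasible_index(
    candidate_ids: Sequence[str],
    proxies: pd.DataFrame,
    strata: pd.Series,
    index_size: int,
) -> List[str]:
    """Select an index set whose matched resampling is feasible.

    Walks ``candidate_ids`` in order (e.g. ranked by signal) and accepts a
    SNP only while its stratum can still supply as many non-index pool SNPs
    as index members (index count <= half the stratum), so every stratum of
    the returned set has a sufficient sampling pool.  SNPs in strata too
    small to match are passed over.
    """
    codes = dict(zip(proxies["snp_id"], np.asarray(strata, dtype=np.int64)))
    sizes = pd.Series(np.asarray(strata)).value_counts().to_dict()
    taken: Dict[int, int] = {}
    out: List[str] = []
    for snp in candidate_ids:
        code = codes.get(snp)
        if code is None:
            continue
        n_taken = taken.get(code, 0)
        if 2 * (n_taken + 1) <= sizes[int(code)]:
            out.append(snp)
            taken[code] = n_taken + 1
            if len(out) == index_size:
                break
    return out


def bin_by_reported_p(
    trait_snps: pd.DataFrame,
    edges_neglog10: Sequence[float] = DEFAULT_P_BIN_EDGES,
) -> "pd.core.groupby.generic.DataFrameGroupBy":
    """Assign trait-associated SNPs to significance bins on -log10(p).

    Bins are [e1, e2), ..., [e_last, inf); the first edge doubles as the
    catalog filter, so SNPs with reported p above 10**-e1 are dropped (with
    a log message).  Returns the input with a ``p_bin`` label column.
    """
    edges = np.asarray(edges_neglog10, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ConfigError("p-value bin edges must be strictly increasing")
    p = np.asarray(trait_snps["reported_p"], dtype=float)
    if np.any((p <= 0) | (p > 1)) or not np.isfinite(p).all():
        raise SchemaError("reported_p values must lie in (0, 1]")
    neglog = -np.log10(p)
    keep = neglog >= edges[0]
    if not keep.all():
        logger.info("dropping %d SNPs above the p < 1e-%g filter", int((~keep).sum()), edges[0])
    out = trait_snps.loc[keep].copy()
    idx = np.searchsorted(edges, neglog[keep], side="right") - 1
    labels = [f"E-{edges[i]:g}~" for i in idx]
    out["p_bin"] = labels
    return out


def bin_labels(edges_neglog10: Sequence[float] = DEFAULT_P_BIN_EDGES) -> List[str]:
    return [f"E-{e:g}~" for e in edges_neglog10]


def _fit_for_positives(
    positive_ids: Iterable[str], proxies: pd.DataFrame
) -> EnrichmentResult:
    pos = set(positive_ids)
    data = pd.DataFrame(
        {
            "y": proxies["snp_id"].isin(pos).astype(int),
            "x_cgsnpt": proxies["is_cgsnpt"].astype(int),
            "x_maf": proxies["maf"],
            "x_tags": proxies["n_tagged"],
        }
    )
    return fit_enrichment_model(data)


def binned_enrichment(
    trait_snps: pd.DataFrame,
    proxies: pd.DataFrame,
    edges_neglog10: Sequence[float] = DEFAULT_P_BIN_EDGES,
) -> Dict[str, EnrichmentResult]:
    """One logistic enrichment fit per reported-p bin.

    Positives are the bin's SNPs; negatives are all proxies never reported
    as associated with any trait.  Empty bins are skipped with a warning.
    """
    binned = bin_by_reported_p(trait_snps, edges_neglog10)
    associated = set(trait_snps["snp_id"])
    background = proxies[~proxies["snp_id"].isin(associated)]
    results: Dict[str, EnrichmentResult] = {}
    for label in bin_labels(edges_neglog10):
        members = binned.loc[binned["p_bin"] == label, "snp_id"]
        members = members[members.isin(set(proxies["snp_id"]))]
        if members.empty:
            logger.warning("p bin %s is empty; enrichment skipped", label)
            continue
        subset = pd.concat(
            [proxies[proxies["snp_id"].isin(set(members))], background]
        )
        results[label] = _fit_for_positives(members, subset)
    return results


def category_enrichment(
    trait_snps: pd.DataFrame,
    proxies: pd.DataFrame,
) -> Dict[str, EnrichmentResult]:
    """Per-trait-category enrichment fits plus a pooled fit.

    For each category, positives are that category's SNPs and negatives are
    all proxies never associated with any trait; the ``pooled`` entry uses
    every associated SNP as positive.  Categories without positives on the
    proxy panel are skipped with a warning.
    """
    panel_ids = set(proxies["snp_id"])
    associated = set(trait_snps["snp_id"])
    background = proxies[~proxies["snp_id"].isin(associated)]
    results: Dict[str, EnrichmentResult] = {}
    pooled_ids = [s for s in associated if s in panel_ids]
    if pooled_ids:
        subset = pd.concat(
            [proxies[proxies["snp_id"].isin(set(pooled_ids))], background]
        )
        results["pooled"] = _fit_for_positives(pooled_ids, subset)
    for category, group in trait_snps.groupby("category", sort=True):
        members = [s for s in set(group["snp_id"]) if s in panel_ids]
        if not members:
            logger.warning("category %s has no positives on the panel; skipped", category)
            continue
        subset = pd.concat(
            [proxies[proxies["snp_id"].isin(set(members))], background]
        )
        results[str(category)] = _fit_for_positives(members, subset)
    return results
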