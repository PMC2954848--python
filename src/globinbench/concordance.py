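"""Signed gene-signature comparison.

A signature is a signed gene list (gene id, up/down direction, optional
log-ratio and p-value), here carried as a DataFrame. Comparisons cover:
identifier matching against a platform gene universe (case-insensitive,
duplicates collapsed to the smallest-p entry), direction concordance
between a reference and an observed signature with an exact Fisher test on
the 2x2 direction table, set-overlap significance by the hypergeometric
exact test, and Pearson correlation of per-gene log2 ratios between two
analyses (e.g. a 1% tissue spike versus pure tissue).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ParameterError

__all__ = [
    "OverlapResult",
    "validate_signature",
    "match_genes",
    "direction_concordance",
    "overlap_fisher",
    "ratio_correlation",
]

DIRECTIONS = ("up", "down")


@dataclasses.dataclass(frozen=True)
class OverlapResult:
    """2x2 table, exact Fisher p, and (where defined) direction agreement."""

    contingency: np.ndarray
    fisher_p: float
    concordant_fraction: float
    n_matched: int
    flag: str = "ok"


def validate_signature(sig: pd.DataFrame) -> pd.DataFrame:
    """Check the signature table and normalize directions to lower case."""
    if "gene_id" not in sig.columns or "direction" not in sig.columns:
        raise ParameterError("signature needs gene_id and direction columns")
    sig = sig.copy()
    sig["direction"] = sig["direction"].astype(str).str.lower()
    bad = set(sig["direction"].unique()) - set(DIRECTIONS)
    if bad:
        raise ParameterError(f"unknown direction label(s): {sorted(bad)}")
    if "log_ratio" in sig.columns:
        lr = sig["log_ratio"].to_numpy(dtype=float)
        sign = np.where(sig["direction"] == "up", 1.0, -1.0)
        inconsistent = np.isfinite(lr) & (lr != 0) & (np.sign(lr) != sign)
        if inconsistent.any():
            g = sig["gene_id"].to_numpy()[inconsistent][0]
            raise ParameterError(
                f"direction inconsistent with log_ratio sign for gene {g!r}")
    return sig


def match_genes(sig: pd.DataFrame,
                platform_genes: set) -> tuple[pd.DataFrame, list]:
    """Match signature ids to a platform universe, case-insensitively.

    Duplicate (case-folded) signature entries collapse to the smallest-p
    entry, or the first when no p-value column is present. Returns the
    matched signature (platform casing for gene ids) and the list of
    unmatched signature ids.
    """
    if len(sig) == 0:
        warnings.warn("empty signature: nothing to match")
        return sig.copy(), []
    sig = validate_signature(sig)
    platform = {str(g).lower(): g for g in platform_genes}

    sig = sig.assign(_key=sig["gene_id"].astype(str).str.lower())
    if "p_value" in sig.columns:
        sig = sig.sort_values("p_value", kind="stable", na_position="last")
    sig = sig.drop_duplicates("_key", keep="first")

    matched_mask = sig["_key"].isin(platform)
    unmatched = sig.loc[~matched_mask, "gene_id"].tolist()
    matched = sig[matched_mask].copy()
    matched["gene_id"] = matched["_key"].map(platform)
    return matched.drop(columns="_key").reset_index(drop=True), unmatched


def direction_concordance(reference: pd.DataFrame, observed: pd.DataFrame,
                          p_threshold: float = 1.0) -> OverlapResult:
    """Direction agreement between two signatures sharing an id space.

    Genes present in both signatures qualify when the observed p-value is
    below ``p_threshold`` (a threshold of 1 keeps every matched gene).
    Returns the reference-by-observed 2x2 direction table, its two-sided
    Fisher exact p, and the concordant fraction.
    """
    ref = validate_signature(reference)
    obs = validate_signature(observed)
    ref_part = pd.DataFrame({
        "_key": ref["gene_id"].astype(str).str.lower(),
        "direction_ref": ref["direction"]})
    obs_part = pd.DataFrame({
        "_key": obs["gene_id"].astype(str).str.lower(),
        "direction_obs": obs["direction"]})
    if "p_value" in obs.columns:
        obs_part["p_value_obs"] = obs["p_value"].to_numpy()
    merged = ref_part.merge(obs_part, on="_key")
    if p_threshold < 1.0:
        if "p_value_obs" not in merged.columns:
            raise ParameterError(
                "observed signature has no p_value column to threshold on")
        merged = merged[merged["p_value_obs"] < p_threshold]

    n = len(merged)
    if n == 0:
        return OverlapResult(np.zeros((2, 2), dtype=int), 1.0, np.nan, 0,
                             flag="no_qualifying_genes")
    table = np.zeros((2, 2), dtype=int)
    for i, dr in enumerate(DIRECTIONS):
        for j, do in enumerate(DIRECTIONS):
            table[i, j] = int(((merged["direction_ref"] == dr)
                               & (merged["direction_obs"] == do)).sum())
    fisher_p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    concordant = float((table[0, 0] + table[1, 1]) / n)
    return OverlapResult(table, fisher_p, concordant, n)


def overlap_fisher(set_a: set, set_b: set, universe: set) -> OverlapResult:
    """Two-sided Fisher exact test for the overlap of two gene sets.

    The 2x2 table counts membership in ``set_a`` by membership in ``set_b``
    over ``universe``; the p-value sums hypergeometric probabilities of all
    tables at most as probable as the observed one.
    """
    if not universe:
        raise ParameterError("universe must be non-empty")
    set_a, set_b = set(set_a), set(set_b)
    if not set_a <= universe or not set_b <= universe:
        raise ParameterError("both sets must be subsets of the universe")
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]], dtype=int)
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return OverlapResult(table, p, np.nan, a)


def ratio_correlation(ratios_a: pd.Series,
                      ratios_b: pd.Series) -> tuple[float, int, str]:
    """Pearson r between two per-gene log2-ratio vectors on shared genes.

    Series are aligned on their gene-id index; at least 3 shared finite
    pairs are required. Returns ``(r, n_used, flag)``; a constant vector
    gives ``r = NaN`` with flag ``"constant_vector"``.
    """
    joined = pd.concat([ratios_a.rename("a"), ratios_b.rename("b")],
                       axis=1, join="inner").dropna()
    n = len(joined)
    if n < 3:
        raise ParameterError("need at least 3 shared genes")
    a = joined["a"].to_numpy(dtype=float)
    b = joined["b"].to_numpy(dtype=float)
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        return np.nan, n, "constant_vector"
    r = float(stats.pearsonr(a, b)[0])
    return r, n, "ok"
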