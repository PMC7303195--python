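"""eQTL joining, Benjamini-Hochberg FDR control, and cis/trans classification."""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .fragments import GeneModel, Variant
from .pairs import SpatialPair

log = logging.getLogger(__name__)

__all__ = [
    "EQTL_COLUMNS",
    "lookup_associations",
    "bh_fdr",
    "classify_cis_trans",
    "significant_spatial_eqtls",
    "fit_eqtl",
    "read_eqtl_tsv",
]

EQTL_COLUMNS = ["tissue", "rsid", "gene_id", "slope", "pval"]


def read_eqtl_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"tissue": str, "rsid": str, "gene_id": str})
    missing = set(EQTL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"eQTL table missing columns: {sorted(missing)}")
    return df


def lookup_associations(
    pairs: list[SpatialPair], table: pd.DataFrame
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """All (tissue, rsid, gene) rows whose (rsid, gene) is a spatial pair.

    Returns the retrieved records plus the pairs found nowhere in the table
    ("untested").
    """
    wanted = {(p.rsid, p.gene_id) for p in pairs}
    keys = list(zip(table["rsid"], table["gene_id"]))
    mask = [k in wanted for k in keys]
    records = table.loc[mask].copy()
    tested = set(zip(records["rsid"], records["gene_id"]))
    untested = sorted(wanted - tested)
    return records, untested


def bh_fdr(
    pvals, alpha: float = 0.05, strict: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: q_(i) = min_{j>=i} m*p_(j)/j, capped at 1.

    ``strict`` selects q < alpha (default, matching "FDR < 0.05" semantics);
    otherwise q <= alpha.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    sig = q < alpha if strict else q <= alpha
    return q, sig


def classify_cis_trans(
    variant: Variant, gene: GeneModel, window: int = 1_000_000
) -> str:
    """cis iff same chromosome and |variant - TSS| <= window, else trans."""
    if variant.chrom != gene.chrom:
        return "trans"
    return "cis" if abs(variant.pos0 - gene.tss) <= window else "trans"


def significant_spatial_eqtls(
    pairs: list[SpatialPair],
    table: pd.DataFrame,
    variants: list[Variant],
    genes: list[GeneModel],
    alpha: float = 0.05,
    cis_window: int = 1_000_000,
    strict: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join spatial pairs to associations, BH-adjust jointly, and classify.

    One BH family is formed over ALL retrieved (tissue, rsid, gene) records.
    Returns (full adjusted table, significant subset); both carry qval,
    significant, regulation_class, and direction columns.
    """
    records, untested = lookup_associations(pairs, table)
    if untested:
        log.info("%d spatial pairs had no association rows", len(untested))
    if records.empty:
        warnings.warn("no associations retrieved for any spatial pair", stacklevel=2)
        empty = records.assign(
            qval=pd.Series(dtype=float),
            significant=pd.Series(dtype=bool),
            regulation_class=pd.Series(dtype=str),
            direction=pd.Series(dtype=str),
        )
        return empty, empty.copy()

    if alpha == 0:
        # degenerate level: adjusted p-values still computed, nothing passes
        q, _ = bh_fdr(records["pval"].to_numpy())
        sig = np.zeros(len(records), dtype=bool)
    else:
        q, sig = bh_fdr(records["pval"].to_numpy(), alpha=alpha, strict=strict)
    records = records.assign(qval=q, significant=sig)

    var_by_rsid = {v.rsid: v for v in variants}
    gene_by_id = {g.gene_id: g for g in genes}
    classes = []
    for rsid, gene_id in zip(records["rsid"], records["gene_id"]):
        classes.append(
            classify_cis_trans(var_by_rsid[rsid], gene_by_id[gene_id], cis_window)
        )
    records["regulation_class"] = classes
    records["direction"] = np.where(records["slope"] > 0, "up", "down")
    significant = records[records["significant"]].copy()
    return records, significant


def fit_eqtl(genotype, expression) -> tuple[float, float]:
    """OLS slope of expression on genotype (0/1/2) with a two-sided t-test
    p-value (n-2 df). Constant expression gives (0.0, 1.0); constant
    genotype is undefined and raises."""
    g = np.asarray(genotype, dtype=float)
    y = np.asarray(expression, dtype=float)
    if g.shape != y.shape or g.ndim != 1:
        raise ValueError("genotype and expression must be equal-length vectors")
    if g.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(g) == 0:
        raise ValueError("zero genotype variance: association undefined")
    if np.ptp(y) == 0:
        return 0.0, 1.0
    res = stats.linregress(g, y)
    return float(res.slope), float(res.pvalue)
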