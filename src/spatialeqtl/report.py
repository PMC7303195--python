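"""Summaries of significant tissue-specific interactions and gene-set enrichment."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .eqtl import bh_fdr

__all__ = [
    "InteractionRecord",
    "SummaryCounts",
    "EnrichmentResult",
    "summarise_interactions",
    "interaction_matrix",
    "direction_tally",
    "shared_regulation",
    "enrichment",
    "read_gmt",
    "records_from_frame",
]


@dataclass(frozen=True)
class InteractionRecord:
    """One tissue x gene x SNP cell of the interaction table."""

    tissue: str
    gene: str
    rsid: str
    effect_size: float


@dataclass
class SummaryCounts:
    n_records: int
    n_pairs: int  # distinct (rsid, gene)
    n_tissues: int
    n_snps: int
    n_genes: int
    per_tissue: dict[str, int] = field(default_factory=dict)
    per_snp_genes: dict[str, set[str]] = field(default_factory=dict)
    up_snps_per_tissue: dict[str, set[str]] = field(default_factory=dict)
    down_snps_per_tissue: dict[str, set[str]] = field(default_factory=dict)


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    overlap: int
    term_size: int
    query_size: int
    universe_size: int
    pval: float
    adj_p: float


def _validate(records: list[InteractionRecord]) -> None:
    seen = set()
    for r in records:
        key = (r.tissue, r.gene, r.rsid)
        if key in seen:
            raise ValueError(f"duplicate interaction record {key}")
        seen.add(key)


def summarise_interactions(records: list[InteractionRecord]) -> SummaryCounts:
    """Deterministic, order-invariant counts over interaction records."""
    _validate(records)
    per_tissue: dict[str, int] = {}
    per_snp_genes: dict[str, set[str]] = {}
    up: dict[str, set[str]] = {}
    down: dict[str, set[str]] = {}
    for r in records:
        per_tissue[r.tissue] = per_tissue.get(r.tissue, 0) + 1
        per_snp_genes.setdefault(r.rsid, set()).add(r.gene)
        target = up if r.effect_size > 0 else down
        target.setdefault(r.tissue, set()).add(r.rsid)
    return SummaryCounts(
        n_records=len(records),
        n_pairs=len({(r.rsid, r.gene) for r in records}),
        n_tissues=len(per_tissue),
        n_snps=len(per_snp_genes),
        n_genes=len({r.gene for r in records}),
        per_tissue=per_tissue,
        per_snp_genes=per_snp_genes,
        up_snps_per_tissue=up,
        down_snps_per_tissue=down,
    )


def interaction_matrix(records: list[InteractionRecord]) -> pd.DataFrame:
    """Wide tissue x gene matrix with 'rsid:effect;...' cells."""
    _validate(records)
    cells: dict[tuple[str, str], list[str]] = {}
    for r in sorted(records, key=lambda r: (r.tissue, r.gene, r.rsid)):
        cells.setdefault((r.tissue, r.gene), []).append(f"{r.rsid}:{r.effect_size:g}")
    tissues = sorted({t for t, _ in cells})
    genes = sorted({g for _, g in cells})
    data = {
        g: [";".join(cells.get((t, g), [])) for t in tissues] for g in genes
    }
    return pd.DataFrame(data, index=pd.Index(tissues, name="tissue"))


def direction_tally(
    records: list[InteractionRecord], tissue: str
) -> tuple[set[str], set[str]]:
    """(upregulating, downregulating) SNP sets for one tissue.

    A SNP is in the down-set iff it has >= 1 record with negative effect in
    that tissue (up-set analogously); a SNP may appear in both.
    """
    _validate(records)
    in_tissue = [r for r in records if r.tissue == tissue]
    if not in_tissue:
        raise ValueError(f"tissue {tissue!r} not present in records")
    up = {r.rsid for r in in_tissue if r.effect_size > 0}
    down = {r.rsid for r in in_tissue if r.effect_size < 0}
    return up, down


def shared_regulation(
    records: list[InteractionRecord],
) -> tuple[dict[str, set[str]], list[tuple[str, str, set[str]]]]:
    """Per-SNP gene sets plus the gene co-regulation graph.

    Edges are (geneA, geneB, shared SNP set) for gene pairs regulated by at
    least one common SNP, geneA < geneB lexicographically.
    """
    _validate(records)
    snp_genes: dict[str, set[str]] = {}
    for r in records:
        snp_genes.setdefault(r.rsid, set()).add(r.gene)
    edge_snps: dict[tuple[str, str], set[str]] = {}
    for rsid, genes in snp_genes.items():
        gs = sorted(genes)
        for i, ga in enumerate(gs):
            for gb in gs[i + 1 :]:
                edge_snps.setdefault((ga, gb), set()).add(rsid)
    edges = [(a, b, snps) for (a, b), snps in sorted(edge_snps.items())]
    return snp_genes, edges


def enrichment(
    query: set[str],
    terms: dict[str, set[str]],
    universe: set[str],
    term_names: dict[str, str] | None = None,
    alpha: float = 0.05,
    correction: str = "bh",
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation test per term.

    pval = P(X >= k) for X ~ Hypergeom(N=|universe|, K=|term|, n=|query|);
    adjusted by BH (default) or Bonferroni; sorted by adjusted p.
    """
    stray = query - universe
    if stray:
        raise ValueError(f"query genes absent from universe: {sorted(stray)}")
    for tid, members in terms.items():
        if members - universe:
            raise ValueError(f"term {tid} contains genes outside the universe")
    names = term_names or {}
    N, n = len(universe), len(query)
    results = []
    pvals = []
    for tid in sorted(terms):
        members = terms[tid]
        K = len(members)
        k = len(query & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        p = min(max(p, 0.0), 1.0) or 1.0  # clamp; k=0 gives exactly 1
        pvals.append(p)
        results.append(
            EnrichmentResult(tid, names.get(tid, tid), k, K, n, N, p, adj_p=1.0)
        )
    if results:
        if correction == "bh":
            adj, _ = bh_fdr(pvals, alpha=alpha)
        elif correction == "bonferroni":
            adj = [min(1.0, p * len(pvals)) for p in pvals]
        else:
            raise ValueError(f"unknown correction {correction!r}")
        for r, a in zip(results, adj):
            r.adj_p = float(a)
    return sorted(results, key=lambda r: (r.adj_p, r.pval, r.term_id))


def read_gmt(path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """GMT term sets: term_id <TAB> description <TAB> gene1 <TAB> ..."""
    terms: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            terms[parts[0]] = {g for g in parts[2:] if g}
            names[parts[0]] = parts[1]
    return terms, names


def records_from_frame(df: pd.DataFrame) -> list[InteractionRecord]:
    """Build interaction records from a (tissue, gene, rsid, effect_size) frame."""
    return [
        InteractionRecord(str(r.tissue), str(r.gene), str(r.rsid), float(r.effect_size))
        for r in df.itertuples()
    ]
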