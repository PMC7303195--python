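"""Hi-C fragment-pair contact indexing and spatial SNP-gene pair calling."""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

from .fragments import Fragment, GeneModel, Variant

log = logging.getLogger(__name__)

FragKey = tuple[str, int]  # (chrom, fragment index)

__all__ = [
    "ContactRecord",
    "SpatialPair",
    "ContactIndex",
    "build_contact_index",
    "interacting_fragments",
    "map_fragments_to_genes",
    "spatial_snp_gene_pairs",
    "read_contacts_tsv",
    "write_contacts_tsv",
    "write_pairs_tsv",
]


@dataclass(frozen=True)
class ContactRecord:
    """One fragment-pair contact observed in a Hi-C library.

    Pairs are unordered: (a, b) is the same contact as (b, a). Self-pairs
    (a == b) are permitted in input but ignored for pair calling.
    """

    library_id: str
    frag_a: FragKey
    frag_b: FragKey


@dataclass
class SpatialPair:
    rsid: str
    gene_id: str
    supporting_libraries: set[str]
    n_contacts: int

    def __post_init__(self) -> None:
        if not self.supporting_libraries:
            raise ValueError("a spatial pair needs at least one supporting library")
        if self.n_contacts < len(self.supporting_libraries):
            raise ValueError("n_contacts below number of supporting libraries")


class ContactIndex:
    """Symmetric fragment-contact adjacency: key -> partner -> evidence."""

    def __init__(self) -> None:
        self._adj: dict[FragKey, dict[FragKey, set[str]]] = defaultdict(dict)
        self._counts: dict[FragKey, dict[FragKey, int]] = defaultdict(
            lambda: defaultdict(int)
        )

    def add(self, record: ContactRecord) -> None:
        a, b = record.frag_a, record.frag_b
        for x, y in ((a, b), (b, a)) if a != b else ((a, b),):
            self._adj[x].setdefault(y, set()).add(record.library_id)
            self._counts[x][y] += 1

    def partners(self, frag: FragKey) -> dict[FragKey, tuple[set[str], int]]:
        """All partners of ``frag`` with (library set, contact count)."""
        return {
            p: (libs, self._counts[frag][p])
            for p, libs in self._adj.get(frag, {}).items()
        }


def build_contact_index(
    records: list[ContactRecord],
    known_fragments: set[FragKey] | None = None,
) -> tuple[ContactIndex, dict]:
    """Index contact records; skip (with QC counts) records whose fragments
    are absent from ``known_fragments`` when a fragment table is given."""
    index = ContactIndex()
    skipped = 0
    per_library: dict[str, int] = defaultdict(int)
    for rec in records:
        if known_fragments is not None and (
            rec.frag_a not in known_fragments or rec.frag_b not in known_fragments
        ):
            skipped += 1
            continue
        index.add(rec)
        per_library[rec.library_id] += 1
    if skipped:
        log.warning("skipped %d contacts referencing unknown fragments", skipped)
    qc = {"n_records": len(records), "skipped": skipped, "per_library": dict(per_library)}
    return index, qc


def interacting_fragments(
    index: ContactIndex, frag: FragKey, min_libraries: int = 1
) -> dict[FragKey, tuple[set[str], int]]:
    """Partner fragments of ``frag`` supported by >= min_libraries libraries."""
    return {
        p: (libs, n)
        for p, (libs, n) in index.partners(frag).items()
        if len(libs) >= min_libraries and p != frag
    }


def map_fragments_to_genes(
    fragments: list[Fragment], genes: list[GeneModel]
) -> dict[FragKey, set[str]]:
    """Genes whose body overlaps each fragment by >= 1 bp (half-open)."""
    by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for g in genes:
        by_chrom[g.chrom].append(g)
    out: dict[FragKey, set[str]] = {}
    for f in fragments:
        hits = {
            g.gene_id
            for g in by_chrom.get(f.chrom, [])
            if g.start < f.end and f.start < g.end
        }
        if hits:
            out[f.key] = hits
    return out


def spatial_snp_gene_pairs(
    variants: list[Variant],
    index: ContactIndex,
    fragments_by_chrom: dict[str, list[Fragment]],
    genes: list[GeneModel],
    min_libraries: int = 1,
    include_self_fragment_pairs: bool = False,
) -> list[SpatialPair]:
    """Call spatial SNP-gene pairs: a variant's fragment must contact a
    fragment that overlaps the gene body.

    ``min_libraries`` applies to the union of supporting libraries over all
    partner fragments overlapping the gene. A variant whose own fragment
    overlaps a gene does not create a pair by containment alone unless
    ``include_self_fragment_pairs`` is set (sentinel library "self").
    """
    all_fragments = [f for frags in fragments_by_chrom.values() for f in frags]
    frag_genes = map_fragments_to_genes(all_fragments, genes)

    pairs: list[SpatialPair] = []
    for v in variants:
        if v.fragment_index is None:
            continue
        key: FragKey = (v.chrom, v.fragment_index)
        gene_libs: dict[str, set[str]] = defaultdict(set)
        gene_counts: dict[str, int] = defaultdict(int)
        for partner, (libs, n) in interacting_fragments(index, key, 1).items():
            for gene_id in frag_genes.get(partner, ()):
                gene_libs[gene_id] |= libs
                gene_counts[gene_id] += n
        if include_self_fragment_pairs:
            for gene_id in frag_genes.get(key, ()):
                gene_libs[gene_id].add("self")
        for gene_id in sorted(gene_libs):
            libs = gene_libs[gene_id]
            if len(libs - {"self"}) >= min_libraries or (
                include_self_fragment_pairs and "self" in libs
            ):
                pairs.append(
                    SpatialPair(
                        rsid=v.rsid,
                        gene_id=gene_id,
                        supporting_libraries=libs,
                        n_contacts=max(gene_counts[gene_id], len(libs)),
                    )
                )
    return pairs


def read_contacts_tsv(path) -> list[ContactRecord]:
    records: list[ContactRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["library_id", "chrom_a", "frag_a", "chrom_b", "frag_b"]
        if header != expected:
            raise ValueError(f"bad contacts header {header}; expected {expected}")
        for line in fh:
            if not line.strip():
                continue
            lib, ca, fa, cb, fb = line.rstrip("\n").split("\t")
            records.append(ContactRecord(lib, (ca, int(fa)), (cb, int(fb))))
    return records


def write_contacts_tsv(records: list[ContactRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("library_id\tchrom_a\tfrag_a\tchrom_b\tfrag_b\n")
        for r in records:
            fh.write(
                f"{r.library_id}\t{r.frag_a[0]}\t{r.frag_a[1]}\t{r.frag_b[0]}\t{r.frag_b[1]}\n"
            )


def write_pairs_tsv(pairs: list[SpatialPair], path) -> None:
    with open(path, "w") as fh:
        fh.write("rsid\tgene_id\tn_libraries\tn_contacts\n")
        for p in sorted(pairs, key=lambda p: (p.rsid, p.gene_id)):
            fh.write(
                f"{p.rsid}\t{p.gene_id}\t{len(p.supporting_libraries)}\t{p.n_contacts}\n"
            )
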