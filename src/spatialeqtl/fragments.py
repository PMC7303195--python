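"""Restriction digestion, fragment assignment, and variant functional annotation.

Coordinate conventions: all internal intervals are 0-based half-open.
Variant positions are 1-based in I/O (VCF convention), gene model I/O is
1-based inclusive (GTF convention), fragment BED output is 0-based half-open.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

__all__ = [
    "RestrictionEnzyme",
    "ENZYMES",
    "get_enzyme",
    "Fragment",
    "Variant",
    "GeneModel",
    "digest",
    "digest_genome",
    "assign_variants_to_fragments",
    "annotate_variant",
    "write_fragments_bed",
    "read_fragments_bed",
]

VALID_CATEGORIES = frozenset(
    {
        "exonic",
        "intronic",
        "ncRNA_intronic",
        "UTR3",
        "UTR5",
        "upstream",
        "downstream",
        "intergenic",
    }
)


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme defined by its recognition site and cut offset.

    ``cut_offset`` is the number of bases from the start of the recognition
    site to the cut position on the plus strand, e.g. MboI (^GATC) cuts at
    offset 0 and HindIII (A^AGCTT) at offset 1.
    """

    name: str
    recognition_site: str
    cut_offset: int

    def __post_init__(self) -> None:
        site = self.recognition_site.upper()
        if not site or set(site) - set("ACGT"):
            raise ValueError(f"invalid recognition site {self.recognition_site!r}")
        if not 0 <= self.cut_offset <= len(site):
            raise ValueError(
                f"cut_offset {self.cut_offset} outside recognition site of length {len(site)}"
            )
        object.__setattr__(self, "recognition_site", site)


ENZYMES: dict[str, RestrictionEnzyme] = {
    "MboI": RestrictionEnzyme("MboI", "GATC", 0),
    "HindIII": RestrictionEnzyme("HindIII", "AAGCTT", 1),
}


def get_enzyme(name: str) -> RestrictionEnzyme:
    """Look up a built-in enzyme by name (case-sensitive)."""
    try:
        return ENZYMES[name]
    except KeyError:
        raise KeyError(
            f"unknown enzyme {name!r}; built-ins: {sorted(ENZYMES)}"
        ) from None


@dataclass(frozen=True)
class Fragment:
    chrom: str
    start: int  # 0-based
    end: int  # exclusive
    index: int  # ordinal along the chromosome

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty fragment [{self.start}, {self.end})")

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.index)


@dataclass
class Variant:
    rsid: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    category: str | None = None
    fragment_index: int | None = None

    @property
    def pos0(self) -> int:
        """0-based position."""
        return self.pos - 1


@dataclass
class GeneModel:
    """A gene with exon structure, held in 0-based half-open coordinates."""

    gene_id: str
    chrom: str
    start: int  # 0-based
    end: int  # exclusive
    strand: str
    name: str = ""
    exons: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    coding: bool = True
    pli: float | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.name:
            self.name = self.gene_id
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(f"exon [{s},{e}) outside gene body of {self.gene_id}")

    @property
    def tss(self) -> int:
        """Strand-aware transcription start (0-based base position)."""
        return self.start if self.strand == "+" else self.end - 1

    def contains(self, pos0: int) -> bool:
        return self.start <= pos0 < self.end


def digest(sequence: str, enzyme: RestrictionEnzyme, chrom: str = "chr") -> list[Fragment]:
    """Digest one chromosome sequence into restriction fragments.

    Cut positions are ``site_start + cut_offset`` for every occurrence of
    the recognition site, scanning overlapping occurrences. Fragments are
    the intervals between consecutive cuts plus the leading and trailing
    intervals; degenerate zero-length intervals are dropped.
    """
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    seq = sequence.upper()
    site = enzyme.recognition_site
    cuts: list[int] = []
    i = seq.find(site)
    while i != -1:
        cuts.append(i + enzyme.cut_offset)
        i = seq.find(site, i + 1)  # overlapping occurrences all counted

    boundaries = [0]
    for c in cuts:
        if c != boundaries[-1]:
            boundaries.append(c)
    if boundaries[-1] != len(seq):
        boundaries.append(len(seq))

    return [
        Fragment(chrom, s, e, idx)
        for idx, (s, e) in enumerate(zip(boundaries[:-1], boundaries[1:]))
    ]


def digest_genome(
    genome: dict[str, str], enzyme: RestrictionEnzyme
) -> dict[str, list[Fragment]]:
    """Digest every chromosome of a genome; chromosomes keep input order."""
    return {chrom: digest(seq, enzyme, chrom) for chrom, seq in genome.items()}


def assign_variants_to_fragments(
    variants: list[Variant], fragments_by_chrom: dict[str, list[Fragment]]
) -> list[Variant]:
    """Set ``fragment_index`` on each variant; return unmapped variants.

    A variant at 1-based position p belongs to the fragment whose half-open
    interval contains p-1. Variants on chromosomes absent from the digestion
    are reported back (not fatal).
    """
    starts = {
        chrom: [f.start for f in frags] for chrom, frags in fragments_by_chrom.items()
    }
    unmapped: list[Variant] = []
    for v in variants:
        frags = fragments_by_chrom.get(v.chrom)
        if frags is None:
            unmapped.append(v)
            continue
        i = bisect.bisect_right(starts[v.chrom], v.pos0) - 1
        if i < 0 or not (frags[i].start <= v.pos0 < frags[i].end):
            unmapped.append(v)
            continue
        v.fragment_index = frags[i].index
    return unmapped


_PRECEDENCE = {
    "exonic": 0,
    "UTR5": 1,
    "UTR3": 1,
    "intronic": 2,
    "ncRNA_intronic": 2,
    "upstream": 3,
    "downstream": 3,
    "intergenic": 4,
}


def _in_intervals(pos0: int, intervals: list[tuple[int, int]]) -> bool:
    return any(s <= pos0 < e for s, e in intervals)


def _categorise_for_gene(pos0: int, gene: GeneModel, upstream_window: int) -> str | None:
    if gene.contains(pos0):
        if not gene.coding:
            return "ncRNA_intronic"
        if _in_intervals(pos0, gene.utr5):
            return "UTR5"
        if _in_intervals(pos0, gene.utr3):
            return "UTR3"
        if _in_intervals(pos0, gene.exons):
            return "exonic"
        return "intronic"
    # strand-aware flanks
    if gene.strand == "+":
        before, after = "upstream", "downstream"
    else:
        before, after = "downstream", "upstream"
    if gene.start - upstream_window <= pos0 < gene.start:
        return before
    if gene.end <= pos0 < gene.end + upstream_window:
        return after
    return None


def annotate_variant(
    variant: Variant, genes: list[GeneModel], upstream_window: int = 1000
) -> str:
    """Assign a functional category by precedence over all overlapping genes.

    Precedence: exonic > UTR5/UTR3 > intronic (ncRNA_intronic for non-coding
    hosts) > upstream/downstream (within ``upstream_window``) > intergenic.
    """
    best: str | None = None
    for gene in genes:
        if gene.chrom != variant.chrom:
            continue
        cat = _categorise_for_gene(variant.pos0, gene, upstream_window)
        if cat is not None and (best is None or _PRECEDENCE[cat] < _PRECEDENCE[best]):
            best = cat
    return best or "intergenic"


def write_fragments_bed(fragments_by_chrom: dict[str, list[Fragment]], path) -> None:
    with open(path, "w") as fh:
        for chrom in fragments_by_chrom:
            for f in fragments_by_chrom[chrom]:
                fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.index}\n")


def read_fragments_bed(path) -> dict[str, list[Fragment]]:
    out: dict[str, list[Fragment]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, index = line.rstrip("\n").split("\t")
            out.setdefault(chrom, []).append(
                Fragment(chrom, int(start), int(end), int(index))
            )
    return out
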