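"""Readers and writers for the plain-text interchange formats.

FASTA via Biopython; variants are VCF-like TSV (1-based positions); gene
models are a GTF-like TSV (1-based inclusive coordinates, one row per
feature: gene / exon / UTR5 / UTR3).
"""

from __future__ import annotations

import math

import pandas as pd
from Bio import SeqIO

from .fragments import GeneModel, Variant

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_variants_tsv",
    "write_variants_tsv",
    "read_gene_models_tsv",
    "write_gene_models_tsv",
]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_variants_tsv(path) -> list[Variant]:
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str, "chrom": str, "ref": str, "alt": str})
    required = {"rsid", "chrom", "pos", "ref", "alt"}
    if missing := required - set(df.columns):
        raise ValueError(f"variants table missing columns: {sorted(missing)}")
    out = []
    for r in df.itertuples():
        v = Variant(r.rsid, r.chrom, int(r.pos), r.ref, r.alt)
        if "category" in df.columns and isinstance(r.category, str):
            v.category = r.category
        out.append(v)
    return out


def write_variants_tsv(variants: list[Variant], path, include_category: bool = False) -> None:
    cols = "rsid\tchrom\tpos\tref\talt"
    if include_category:
        cols += "\tcategory\tfragment_index"
    with open(path, "w") as fh:
        fh.write(cols + "\n")
        for v in variants:
            row = f"{v.rsid}\t{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}"
            if include_category:
                frag = "" if v.fragment_index is None else v.fragment_index
                row += f"\t{v.category or ''}\t{frag}"
            fh.write(row + "\n")


def _fmt_interval_1based(iv: tuple[int, int]) -> tuple[int, int]:
    return iv[0] + 1, iv[1]


def write_gene_models_tsv(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tname\tchrom\tstart\tend\tstrand\tfeature\tcoding\tpli\n")
        for g in genes:
            s1, e1 = _fmt_interval_1based((g.start, g.end))
            pli = "" if g.pli is None else f"{g.pli:g}"
            fh.write(
                f"{g.gene_id}\t{g.name}\t{g.chrom}\t{s1}\t{e1}\t{g.strand}\tgene\t{int(g.coding)}\t{pli}\n"
            )
            for feature, ivs in (("exon", g.exons), ("UTR5", g.utr5), ("UTR3", g.utr3)):
                for iv in ivs:
                    s1, e1 = _fmt_interval_1based(iv)
                    fh.write(
                        f"{g.gene_id}\t{g.name}\t{g.chrom}\t{s1}\t{e1}\t{g.strand}\t{feature}\t\t\n"
                    )


def read_gene_models_tsv(path) -> list[GeneModel]:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"gene_id": str, "name": str, "chrom": str, "strand": str, "feature": str},
    )
    genes: dict[str, GeneModel] = {}
    features: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for r in df.itertuples():
        start0, end0 = int(r.start) - 1, int(r.end)  # 1-based inclusive -> half-open
        if r.feature == "gene":
            pli = None
            if "pli" in df.columns and not (
                isinstance(r.pli, float) and math.isnan(r.pli)
            ):
                pli = float(r.pli)
            genes[r.gene_id] = GeneModel(
                gene_id=r.gene_id,
                name=r.name if isinstance(r.name, str) else r.gene_id,
                chrom=r.chrom,
                start=start0,
                end=end0,
                strand=r.strand,
                coding=bool(int(r.coding)) if not _isnan(r.coding) else True,
                pli=pli,
            )
        else:
            features.setdefault(r.gene_id, {}).setdefault(r.feature, []).append(
                (start0, end0)
            )
    for gid, feats in features.items():
        if gid not in genes:
            raise ValueError(f"feature rows for unknown gene {gid}")
        genes[gid].exons = sorted(feats.get("exon", []))
        genes[gid].utr5 = sorted(feats.get("UTR5", []))
        genes[gid].utr3 = sorted(feats.get("UTR3", []))
    return list(genes.values())


def _isnan(x) -> bool:
    return isinstance(x, float) and math.isnan(x)
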