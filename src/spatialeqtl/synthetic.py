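"""Synthetic pipeline inputs with planted ground truth, plus the packaged
ADH interaction fixture.

Every artifact draws from its own labelled RNG substream derived from the
master seed, so adding one artifact never perturbs the others and a fixed
config reproduces byte-identical outputs.
"""

from __future__ import annotations

import bisect
import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
import pandas as pd

from . import io as seio
from .annotation import PWM, HistoneMarkRecord
from .fragments import (
    Fragment,
    GeneModel,
    Variant,
    assign_variants_to_fragments,
    digest_genome,
    get_enzyme,
)
from .pairs import ContactRecord
from .report import InteractionRecord

__all__ = [
    "SyntheticConfig",
    "GroundTruthManifest",
    "SyntheticDataset",
    "generate_toy_genome",
    "generate_hic_contacts",
    "generate_eqtl_table",
    "generate_annotation_tracks",
    "generate_dataset",
    "write_dataset",
    "load_adh_fixture",
    "ADH_FIXTURE_SHA256",
    "adh_fixture_path",
]

_BASES = np.array(list("ACGT"))
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Pinned checksum of the packaged interaction-table fixture.
ADH_FIXTURE_SHA256 = "7b689f2e35f84b07b9dfd1626ee4b2ee3b2909e1002c8545d11d1f8dbad81d3f"


class SizingError(ValueError):
    """The configured chromosome length cannot host the requested content."""


class ManifestError(ValueError):
    """A planted link references content absent from the toy genome."""


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 100_000
    enzyme_name: str = "MboI"
    n_genes: int = 6
    n_variants: int = 12
    n_tissues: int = 4
    #: (variant index, gene index, tissue index, slope)
    planted_links: list[tuple[int, int, int, float]] = field(default_factory=list)
    background_contact_rate: float = 0.0
    null_p_distribution: str = "uniform(0,1)"
    n_libraries: int = 4
    n_haplotypes: int = 100
    gene_length: int = 2000
    #: variant-index groups realised as duplicated haplotype columns
    ld_blocks: list[list[int]] = field(default_factory=list)
    #: (variant index, motif name, sign "+"/"-")
    motif_disruptions: list[tuple[int, str, str]] = field(default_factory=list)
    #: (variant index, tissue, mark)
    planted_marks: list[tuple[int, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        enzyme = get_enzyme(self.enzyme_name)
        expected_fragment = 4 ** len(enzyme.recognition_site)
        if self.chrom_length < 10 * expected_fragment:
            raise SizingError(
                f"chrom_length {self.chrom_length} < 10x expected fragment length "
                f"{expected_fragment} for {self.enzyme_name}"
            )
        if not 0.0 <= self.background_contact_rate <= 1.0:
            raise ValueError("background_contact_rate must lie in [0, 1]")
        for link in self.planted_links:
            if link[3] == 0:
                raise ValueError(f"planted slope must be nonzero: {link}")
        if self.null_p_distribution != "uniform(0,1)":
            raise ValueError("only uniform(0,1) null p-values are supported")

    @property
    def tissues(self) -> list[str]:
        return [f"tissue{i}" for i in range(self.n_tissues)]

    def rng(self, label: str) -> np.random.Generator:
        """Labelled substream of the master seed."""
        return np.random.default_rng([self.seed, zlib.crc32(label.encode())])


@dataclass
class GroundTruthManifest:
    planted_pairs: set[tuple[str, str]] = field(default_factory=set)
    planted_eqtls: set[tuple[str, str, str]] = field(default_factory=set)
    planted_slopes: dict[tuple[str, str, str], float] = field(default_factory=dict)
    ld_blocks: list[list[str]] = field(default_factory=list)
    motif_disruptions: list[tuple[str, str, str]] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "planted_pairs": sorted(list(p) for p in self.planted_pairs),
            "planted_eqtls": sorted(list(t) for t in self.planted_eqtls),
            "planted_slopes": {
                "|".join(k): v for k, v in sorted(self.planted_slopes.items())
            },
            "ld_blocks": self.ld_blocks,
            "motif_disruptions": [list(t) for t in self.motif_disruptions],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruthManifest":
        try:
            with open(path) as fh:
                payload = json.load(fh)
        except (OSError, json.JSONDecodeError) as exc:
            raise ManifestError(f"cannot load manifest {path}: {exc}") from exc
        return cls(
            planted_pairs={tuple(p) for p in payload["planted_pairs"]},
            planted_eqtls={tuple(t) for t in payload["planted_eqtls"]},
            planted_slopes={
                tuple(k.split("|")): v for k, v in payload["planted_slopes"].items()
            },
            ld_blocks=payload["ld_blocks"],
            motif_disruptions=[tuple(t) for t in payload["motif_disruptions"]],
        )


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    variants: list[Variant]
    fragments: dict[str, list[Fragment]]
    contacts: list[ContactRecord]
    eqtl_table: pd.DataFrame
    marks: list[HistoneMarkRecord]
    pwms: list[PWM]
    haplotypes: pd.DataFrame
    manifest: GroundTruthManifest


# ---------------------------------------------------------------------------
# genome, genes, variants


def generate_toy_genome(
    config: SyntheticConfig,
) -> tuple[dict[str, str], list[GeneModel], list[Variant]]:
    """Random A/C/G/T chromosomes with placed genes and variants.

    Each chromosome is guaranteed to digest into >= 20 fragments (extra
    recognition sites are injected when a random sequence falls short).
    Variant reference alleles equal the reference base at their position.
    """
    rng = config.rng("genome")
    enzyme = get_enzyme(config.enzyme_name)
    genome: dict[str, str] = {}
    for c in range(config.n_chromosomes):
        seq = "".join(rng.choice(_BASES, size=config.chrom_length))
        if seq.count(enzyme.recognition_site) < 21:
            seq = _inject_sites(seq, enzyme.recognition_site, 21)
        genome[f"chr{c + 1}"] = seq

    genes = _place_genes(genome, config)
    variants = _place_variants(genome, genes, config)
    return genome, genes, variants


def _inject_sites(seq: str, site: str, n: int) -> str:
    step = len(seq) // (n + 1)
    if step <= len(site):
        raise SizingError("chromosome too short to inject recognition sites")
    chars = list(seq)
    for i in range(1, n + 1):
        p = i * step
        chars[p : p + len(site)] = site
    return "".join(chars)


def _place_genes(genome: dict[str, str], config: SyntheticConfig) -> list[GeneModel]:
    rng = config.rng("genes")
    chroms = list(genome)
    per_chrom: dict[str, int] = {c: 0 for c in chroms}
    for i in range(config.n_genes):
        per_chrom[chroms[i % len(chroms)]] += 1

    genes: list[GeneModel] = []
    gi = 0
    L = config.gene_length
    for chrom in chroms:
        k = per_chrom[chrom]
        if k == 0:
            continue
        slot = config.chrom_length // (k + 1)
        if slot <= 2 * L:
            raise SizingError(
                f"chrom_length {config.chrom_length} too small for {k} genes of length {L}"
            )
        for j in range(k):
            centre = (j + 1) * slot + int(rng.integers(-L // 4, L // 4 + 1))
            start = max(0, centre - L // 2)
            end = min(config.chrom_length, start + L)
            strand = "+" if rng.random() < 0.5 else "-"
            exon_len = L // 4
            exons = [(start, start + exon_len), (end - exon_len, end)]
            utr_len = max(10, exon_len // 5)
            if strand == "+":
                utr5 = [(start, start + utr_len)]
                utr3 = [(end - utr_len, end)]
            else:
                utr5 = [(end - utr_len, end)]
                utr3 = [(start, start + utr_len)]
            genes.append(
                GeneModel(
                    gene_id=f"GENE{gi:03d}",
                    name=f"GENE{gi:03d}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    exons=exons,
                    utr5=utr5,
                    utr3=utr3,
                    coding=True,
                    pli=round(float(rng.random()), 2),
                )
            )
            gi += 1
    return genes


def _place_variants(
    genome: dict[str, str], genes: list[GeneModel], config: SyntheticConfig
) -> list[Variant]:
    # Each variant gets its own fragment, and never a gene-overlapping one:
    # gene-overlapping fragments serve as planted contact partners, so keeping
    # variants out of them makes zero-noise pair recovery exact.
    rng = config.rng("variants")
    total = config.n_chromosomes * config.chrom_length
    if config.n_variants > total // 100:
        raise SizingError("too many variants for the configured genome size")
    fragments = digest_genome(genome, get_enzyme(config.enzyme_name))
    gene_frag_idx: dict[str, set[int]] = {c: set() for c in genome}
    for g in genes:
        for f in fragments[g.chrom]:
            if f.start < g.end and g.start < f.end:
                gene_frag_idx[g.chrom].add(f.index)
    disrupted = {vi for vi, _, _ in config.motif_disruptions}
    chroms = list(genome)
    frag_starts = {c: [f.start for f in fragments[c]] for c in chroms}
    variants: list[Variant] = []
    used: set[tuple[str, int]] = set()  # occupied (chrom, fragment index)
    for i in range(config.n_variants):
        for _attempt in range(1000):
            chrom = chroms[int(rng.integers(len(chroms)))]
            pos = int(rng.integers(1, config.chrom_length + 1))  # 1-based
            fi = bisect.bisect_right(frag_starts[chrom], pos - 1) - 1
            if fi in gene_frag_idx[chrom] or (chrom, fi) in used:
                continue
            used.add((chrom, fi))
            break
        else:
            raise SizingError("cannot place variants in distinct gene-free fragments")
        ref = genome[chrom][pos - 1]
        choices = [b for b in "ACGT" if b != ref]
        if i in disrupted:
            # keep alt distinct from complement(ref) so strand-max scoring
            # cannot rescue the disrupted allele
            choices = [b for b in choices if b != _COMPLEMENT[ref]]
        alt = choices[int(rng.integers(len(choices)))]
        variants.append(Variant(rsid=f"rs{1000 + i}", chrom=chrom, pos=pos, ref=ref, alt=alt))
    return variants


# ---------------------------------------------------------------------------
# Hi-C contacts


def generate_hic_contacts(
    fragments: dict[str, list[Fragment]],
    variants: list[Variant],
    genes: list[GeneModel],
    config: SyntheticConfig,
) -> tuple[list[ContactRecord], GroundTruthManifest]:
    """Contacts guaranteeing each planted link, plus background noise.

    Each planted (variant, gene) link yields one contact joining the
    variant's fragment to a different fragment overlapping the gene body.
    Background contacts per library are Binomial(total fragments, rate)
    uniformly random fragment pairs.
    """
    rng = config.rng("contacts")
    unassigned = [v for v in variants if v.fragment_index is None]
    if unassigned:
        assign_variants_to_fragments(unassigned, fragments)

    manifest = GroundTruthManifest()
    contacts: list[ContactRecord] = []
    tissues = config.tissues
    for k, (vi, gi, ti, slope) in enumerate(config.planted_links):
        if not (0 <= vi < len(variants)) or not (0 <= gi < len(genes)):
            raise ManifestError(f"planted link {config.planted_links[k]} out of range")
        if not (0 <= ti < config.n_tissues):
            raise ManifestError(f"planted link tissue index {ti} out of range")
        v, g = variants[vi], genes[gi]
        if v.fragment_index is None:
            raise ManifestError(f"variant {v.rsid} has no fragment on the toy genome")
        vkey = (v.chrom, v.fragment_index)
        gene_frags = [
            f.key
            for f in fragments[g.chrom]
            if f.start < g.end and g.start < f.end and f.key != vkey
        ]
        if not gene_frags:
            raise ManifestError(
                f"gene {g.gene_id} offers no partner fragment distinct from {v.rsid}'s"
            )
        library = f"lib{(k % config.n_libraries) + 1:02d}"
        contacts.append(ContactRecord(library, vkey, gene_frags[0]))
        manifest.planted_pairs.add((v.rsid, g.gene_id))
        triple = (v.rsid, g.gene_id, tissues[ti])
        manifest.planted_eqtls.add(triple)
        manifest.planted_slopes[triple] = slope

    all_keys = [f.key for frags in fragments.values() for f in frags]
    for lib_idx in range(config.n_libraries):
        n_bg = int(rng.binomial(len(all_keys), config.background_contact_rate))
        for _ in range(n_bg):
            a = all_keys[int(rng.integers(len(all_keys)))]
            b = all_keys[int(rng.integers(len(all_keys)))]
            contacts.append(ContactRecord(f"lib{lib_idx + 1:02d}", a, b))

    manifest.ld_blocks = [
        [variants[vi].rsid for vi in block] for block in config.ld_blocks
    ]
    manifest.motif_disruptions = [
        (variants[vi].rsid, motif, sign) for vi, motif, sign in config.motif_disruptions
    ]
    return contacts, manifest


# ---------------------------------------------------------------------------
# eQTL associations


def generate_eqtl_table(
    manifest: GroundTruthManifest, config: SyntheticConfig
) -> pd.DataFrame:
    """Associations for every planted spatial pair across every tissue.

    Planted triples get p < 1e-6 and the planted slope; everything else gets
    p ~ uniform(0,1] and small-noise slopes.
    """
    rng = config.rng("eqtl")
    rows = []
    for rsid, gene_id in sorted(manifest.planted_pairs):
        for tissue in config.tissues:
            triple = (rsid, gene_id, tissue)
            if triple in manifest.planted_eqtls:
                pval = float(10.0 ** rng.uniform(-12.0, -8.0))
                slope = manifest.planted_slopes[triple]
            else:
                pval = float(1.0 - rng.random())  # (0, 1]
                slope = float(rng.normal(0.0, 0.05))
            rows.append(
                {"tissue": tissue, "rsid": rsid, "gene_id": gene_id,
                 "slope": slope, "pval": pval}
            )
    return pd.DataFrame(rows, columns=["tissue", "rsid", "gene_id", "slope", "pval"])


# ---------------------------------------------------------------------------
# annotation tracks


def generate_annotation_tracks(
    manifest: GroundTruthManifest,
    variants: list[Variant],
    config: SyntheticConfig,
) -> tuple[list[HistoneMarkRecord], list[PWM], pd.DataFrame]:
    """Histone marks over chosen variants, disruption PWMs, and a haplotype
    panel realising the planted LD blocks (r^2 = 1 within a block by column
    duplication)."""
    by_rsid = {v.rsid: v for v in variants}

    marks: list[HistoneMarkRecord] = []
    for vi, tissue, mark in config.planted_marks:
        v = variants[vi]
        marks.append(
            HistoneMarkRecord(v.chrom, max(0, v.pos0 - 50), v.pos0 + 50, tissue, mark)
        )

    pwms: list[PWM] = []
    for rsid, motif, sign in manifest.motif_disruptions:
        v = by_rsid[rsid]
        favoured = v.ref if sign == "-" else v.alt
        probs = np.full((1, 4), 0.03)
        probs[0, "ACGT".index(favoured)] = 0.91
        pwms.append(PWM(motif, probs))

    rng = config.rng("haplotypes")
    n = config.n_haplotypes
    columns: dict[str, np.ndarray] = {}
    for v in variants:
        freq = rng.uniform(0.2, 0.8)
        col = (rng.random(n) < freq).astype(int)
        if col.min() == col.max():
            col[0] = 1 - col[0]
        columns[v.rsid] = col
    for block in manifest.ld_blocks:
        lead = columns[block[0]]
        for rsid in block[1:]:
            columns[rsid] = lead.copy()
    haplotypes = pd.DataFrame(columns)
    return marks, pwms, haplotypes


# ---------------------------------------------------------------------------
# orchestration


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Build the full synthetic input set from one config."""
    genome, genes, variants = generate_toy_genome(config)
    fragments = digest_genome(genome, get_enzyme(config.enzyme_name))
    assign_variants_to_fragments(variants, fragments)
    contacts, manifest = generate_hic_contacts(fragments, variants, genes, config)
    eqtl_table = generate_eqtl_table(manifest, config)
    marks, pwms, haplotypes = generate_annotation_tracks(manifest, variants, config)
    return SyntheticDataset(
        config=config,
        genome=genome,
        genes=genes,
        variants=variants,
        fragments=fragments,
        contacts=contacts,
        eqtl_table=eqtl_table,
        marks=marks,
        pwms=pwms,
        haplotypes=haplotypes,
        manifest=manifest,
    )


def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    """Write every artifact of a synthetic dataset as plain text."""
    from pathlib import Path

    from . import annotation as ann
    from . import pairs as sp

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seio.write_fasta(dataset.genome, out / "genome.fa")
    seio.write_gene_models_tsv(dataset.genes, out / "genes.tsv")
    seio.write_variants_tsv(dataset.variants, out / "variants.tsv")
    sp.write_contacts_tsv(dataset.contacts, out / "contacts.tsv")
    dataset.eqtl_table.to_csv(out / "eqtl.tsv", sep="\t", index=False)
    ann.write_marks_tsv(dataset.marks, out / "marks.tsv")
    ann.write_pwms(dataset.pwms, out / "pwms.txt")
    dataset.haplotypes.to_csv(out / "haplotypes.tsv", sep="\t", index=False)
    dataset.manifest.to_json(out / "manifest.json")
    cfg = asdict(dataset.config)
    with open(out / "config.json", "w") as fh:
        json.dump(cfg, fh, indent=1, sort_keys=True, default=list)
        fh.write("\n")


# ---------------------------------------------------------------------------
# packaged fixture


def adh_fixture_path():
    return resources.files("spatialeqtl.data") / "adh_interactions.tsv"


def load_adh_fixture() -> list[InteractionRecord]:
    """The packaged tissue x gene x SNP interaction table for the ADH locus."""
    path = adh_fixture_path()
    try:
        raw = path.read_bytes()
    except (OSError, FileNotFoundError) as exc:
        raise FileNotFoundError(f"interaction fixture missing: {exc}") from exc
    digest = hashlib.sha256(raw).hexdigest()
    if digest != ADH_FIXTURE_SHA256:
        raise ValueError(
            f"interaction fixture checksum mismatch: {digest} != {ADH_FIXTURE_SHA256}"
        )
    df = pd.read_csv(path, sep="\t")
    required = {"tissue", "gene", "rsid", "effect_size"}
    if missing := required - set(df.columns):
        raise ValueError(f"fixture malformed; missing columns {sorted(missing)}")
    records = [
        InteractionRecord(r.tissue, r.gene, r.rsid, float(r.effect_size))
        for r in df.itertuples()
    ]
    allowed = {"ADH1A", "ADH1B", "ADH1C", "ADH4"}
    if stray := {r.gene for r in records} - allowed:
        raise ValueError(f"fixture contains unexpected genes {sorted(stray)}")
    return records
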