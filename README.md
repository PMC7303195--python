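# spatialeqtl

A tested pipeline for spatial eQTL mapping: disease-associated SNPs are
intersected with Hi-C-derived restriction-fragment contacts and
tissue-stratified eQTL associations, followed by joint Benjamini–Hochberg FDR
control, cis/trans classification, regulatory annotation (histone marks, PWM
allele scoring, LD), and tissue × gene summarisation. A synthetic-data module
generates every input with planted ground truth so the whole pipeline is
testable offline, and a packaged fixture transcribes a published ADH-locus
interaction table for exact count checks.

## Layout

| module | role |
| --- | --- |
| `spatialeqtl.fragments` | restriction digestion (MboI, HindIII, user-defined), fragment assignment, functional categories |
| `spatialeqtl.pairs` | Hi-C contact index, fragment–gene overlap, spatial SNP–gene pair calling |
| `spatialeqtl.eqtl` | association lookup, BH FDR (one joint family), cis/trans (TSS-anchored 1 Mb window), OLS eQTL fit |
| `spatialeqtl.annotation` | histone-mark overlap with enhancer/promoter grouping, PWM ref/alt allele scoring, r²/D′ from haplotypes |
| `spatialeqtl.report` | interaction summaries, direction tallies, co-regulation graph, hypergeometric enrichment |
| `spatialeqtl.synthetic` | synthetic genomes/contacts/eQTLs/tracks with planted ground truth; packaged ADH fixture |
| `spatialeqtl.cli` | `spatialeqtl` CLI, YAML run config, provenance manifest |

## CLI

```bash
# generate a synthetic input set with two planted SNP-gene-tissue links
spatialeqtl simulate --seed 0 --outdir sim --link 0,0,0,0.5 --link 1,1,1,-0.7

# run the full pipeline from a YAML config
cat > run.yaml <<EOF
genome: sim/genome.fa
genes: sim/genes.tsv
variants: sim/variants.tsv
contacts: sim/contacts.tsv
eqtl: sim/eqtl.tsv
outdir: out
EOF
spatialeqtl run-all --config run.yaml

# digest a FASTA into restriction fragments
spatialeqtl digest --genome sim/genome.fa --enzyme MboI --out fragments.bed

# summary counts of the packaged ADH interaction fixture
spatialeqtl report
```

Pipeline outputs (`fragments.bed`, `pairs.tsv`, `eqtl_full.tsv`,
`eqtl_significant.tsv`, `summary.json`, annotation TSVs, `provenance.json`)
are deterministic: rerunning with the same config and inputs is
byte-identical.

## Conventions

Internal coordinates are 0-based half-open. Variant I/O is 1-based (VCF),
gene-model I/O is 1-based inclusive (GTF-like), BED output is 0-based
half-open. A variant at a cut coordinate belongs to the downstream fragment.
BH significance uses strict `q < alpha` by default.
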