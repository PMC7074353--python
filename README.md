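# mitoprofile

Descriptive profiling of annotated circular mitochondrial genomes:

- **organization** — junction arithmetic on a circular gene table: overlaps
  (negative gaps), intergenic spacers, strand partition, per-class length
  totals, stop-codon/residue accounting, and a declared-length audit;
- **composition** — base counts, A+T%, AT-skew `(A−T)/(A+T)` and GC-skew
  `(G−C)/(G+C)` for the whole genome, the protein-coding genes (sense
  strand), their three codon positions, and the tRNA/rRNA classes;
- **codon usage** — CDS extraction on either strand (incomplete T/TA stops
  supported), start/stop classification, codon counts and RSCU under the
  invertebrate mitochondrial genetic code (NCBI transl_table 5);
- **substitution rates** — pairwise ka/ks in the Nei–Gojobori (1986)
  counting style (pathway averaging, stop-codon exclusion) with
  Jukes–Cantor correction, plus per-taxon means over an alignment;
- **simulate** — a seeded generator of annotated circular genomes and of
  star-tree coding alignments with known synonymous/nonsynonymous ground
  truth, so the whole pipeline is testable without downloads.

Inputs are plain text: GenBank flat files (subset: LOCUS/FEATURES/ORIGIN),
FASTA, and a tab-separated gene table with header
`Gene Strand Location Length Anticodon StartCodon StopCodon OVL_ITS`
(1-based inclusive coordinates, strands `H`/`L`). A reference gene table
for a carabid beetle mitogenome ships in `src/mitoprofile/data/`.

## CLI

```sh
# full report (TSVs + JSON) from a GenBank record
mitoprofile profile --genbank genome.gb --out-dir report/

# organization only, annotation-only mode (no sequence needed)
mitoprofile organization --gene-table genes.tsv --genome-length 16646

# composition / RSCU from FASTA + gene table
mitoprofile composition --fasta genome.fasta --gene-table genes.tsv
mitoprofile rscu --fasta genome.fasta --gene-table genes.tsv

# per-taxon mean ka/ks from an in-frame FASTA alignment
mitoprofile kaks --alignment pcg_alignment.fasta [--reference taxon_1]

# synthetic fixture bundle (GenBank + FASTA + TSV + manifest), seeded
mitoprofile simulate --seed 1 --out-dir fixtures/
```

All subcommands log to stderr and write data to stdout or `--out-dir`,
and are deterministic for fixed inputs and seed.

## Library use

```python
from mitoprofile import (
    read_gene_table, summarize_organization,
    composition_table, extract_cds, rscu, taxon_mean_rates,
)

table = read_gene_table("genes.tsv", genome_length=16646, circular=True)
summary = summarize_organization(table)
summary.overlap_total_bp, summary.spacer_total_bp, summary.largest_spacer
```
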