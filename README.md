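# retrodate

Dating and annotation of gene retrocopies. The package implements, as a
tested reusable pipeline, the comparative analysis used to date a young,
fixed human retrocopy against its polymorphic parent gene:

- **gene_coords** — gene models and HGVS-style coding coordinates
  (`c.-212`, `c.759`, `c.*543`, `c.502-64`), codon mapping, and coarse
  protein-effect labels.
- **pairalign** — global alignment of near-identical paralogs (affine
  gaps, Biopython engine, pinned megablast-like scoring) and extraction of
  a normalized variant list (substitutions, indels, mononucleotide
  repeat-length variants; ancestral allele first).
- **varclass** — the core classification stage: polymorphic vs. fixed
  within each paralog from observed site panels, ancestral vs. derived by
  outgroup unanimity, reconstruction of the parent allele at
  retrotransposition time, and counting fixed differences (k) over a
  comparison mask (L).
- **clock** — molecular-clock dating `t = k/(L·r)` with rate-interval
  propagation, phylogenetic presence/absence bounds, and their
  intersection.
- **paralog_reads** — diagnostic sites within a family of near-identical
  paralogs and conclusive short-read assignment
  (unique/tied/unassigned, gapless placement, both orientations).
- **retro_features** — retrocopy insertion hallmarks: target-site
  duplication, poly(A) remnant, intron loss, orientation relative to a
  host element, strand-aware IUPAC motif scanning.
- **popfreq** — allele frequencies from per-population genotype count
  tables.
- **synthetic** — truth-annotated synthetic histories (parent gene,
  outgroups, retrocopy of known age with TSD/poly(A)/reverse insertion,
  panel polymorphism, a segregating parent-allele deletion, short reads)
  plus parameter-recovery experiments.
- **pipeline / io / cli** — plumbing: plain-text formats (FASTA, FASTQ,
  TSV, BED sidecars, YAML config) and the end-to-end runner.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds one test per acceptance criterion,
including the oracle-equivalence property suites and the 1000-replicate
parameter-recovery experiment.

## CLI

```sh
retrodate simulate --seed 7 --out bundle/        # write a synthetic bundle
retrodate run bundle/ --out results/             # full pipeline -> summary.json
retrodate date -k 2 -L 1622 --rate 1.25e-9 --rate-low 0.5e-9 --rate-high 1.35e-9
retrodate variants two_seqs.fasta gene.model.tsv
retrodate classify panels.tsv
retrodate features locus.fasta element.bed
retrodate assign-reads reads.fasta family.fasta --focal target
retrodate popfreq counts.tsv
```

Every subcommand honors `--seed`, `--config`, `--verbose`, and `--out`.
The pipeline is deterministic: a bundle simulated from a fixed seed yields
bitwise-identical outputs on every run.

## Bundle layout

`retrodate simulate` / `retrodate run` exchange a directory of plain-text
files: `parent_gene.fasta` + `parent_gene.model.tsv` (sequence plus exon
intervals and reading-frame bounds), `parent_references.fasta` (two
pre-aligned reference haplotypes, `-` marks the segregating deletion),
`outgroups.fasta`, `retro_locus.fasta` + `retro_element.bed`,
`panels.tsv` (per-site allele observations for both paralogs),
`reads.fasta`, and truth tables for validation.
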