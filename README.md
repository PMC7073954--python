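# kmercn

Paralog-sensitive copy-number estimation from unique k-mer depth — a
mapping-free pipeline that turns short-read data into windowed diploid
copy-number tracks, including for duplicated (paralogous) sequence that
read mappers cannot resolve.

The pipeline has three stages:

1. **search** — build a catalog of analyzable k-mers from a reference
   FASTA: k-mers (default k=30) with a single exact occurrence in the
   genome and strictly fewer than 100 occurrences of substitution
   variants within edit distance 2 are retained, then annotated with
   flanking GC content and membership in user-supplied copy-number-
   invariant ("control") regions.
2. **count** — stream reads (FASTQ/FASTA/raw, auto-detected) from
   standard input and tabulate the occurrence count of every catalog
   k-mer, treating a k-mer and its reverse complement as one entity.
3. **est** — fit per-GC-bin depth-correction factors on control k-mers,
   correct all counts, scale by the control mean so control depth maps to
   copy number 2, and emit BED tracks in windows of 1000 consecutive
   catalog k-mers.

K-mers are packed 2 bits/base into 64-bit words (A=0, C=1, T=2, G=3 from
ASCII bits 1–2; complement is `code ^ 2`), hashed with DJB2 and stored in
an open-addressing table whose probe direction depends on which half of
the array the hash lands in.

Multi-sample utilities (`summarize`, `gene-cn`, `hub`) compute per-sample
MAD/outlier QC, cross-sample per-window ranges, gene-level copy numbers
(median of ≥3 intersecting windows, longest isoform per gene, male chrX
non-PAR values doubled), and UCSC-style track-hub directories with
rounded-copy-number heatmaps.

A deterministic simulator (`kmercn simulate`, `kmercn.simulate`) generates
toy references with implanted diverged duplications, diploid CNV
genotypes, GC-biased error-carrying reads, and truth tracks, so the whole
pipeline can be built and tested without downloading anything.

## CLI walkthrough

```sh
# generate a ready-to-run synthetic fixture
kmercn simulate --preset paralog-demo -o demo --seed 7 --length 200000

# optional: derive the control include-BED from exclusion BEDs
kmercn prepare-control --genome chrom.sizes --exclude segdups.bed \
    --exclude known_cnvs.bed -o include.bed

# 1. index the reference
kmercn search demo/reference.fa --control demo/control.bed \
    -k 30 -e 2 --max-near 100 --gc-window 400 -o demo/ref.idx

# 2. count k-mers in reads (stdin; use --input for a file)
kmercn count demo/ref.idx -o demo/sim1.counts < demo/reads.fastq
# for BAM/CRAM input:  samtools fasta -F 3840 in.cram | kmercn count ref.idx -o out.counts

# 3. estimate copy number in 1000-k-mer windows
kmercn est demo/ref.idx demo/sim1.counts -o demo/sim1.cn.bed -w 1000 \
    --heatmap demo/sim1.heat.bed

# multi-sample summaries
kmercn summarize demo/sim1.cn.bed -o summary.tsv --ranges ranges.tsv
kmercn gene-cn demo/sim1.cn.bed --genes demo/genes.tsv \
    --samples demo/samples.tsv -o gene_cn.tsv
kmercn hub demo/sim1.cn.bed --samples demo/samples.tsv -o hub/
```

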