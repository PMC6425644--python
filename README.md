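# repeatlens

Copy-number genotyping of tandem repeats from split long-read alignments.

Given tandem-repeat annotations (UCSC RepeatMasker `rmsk.txt` or a BED-like
custom file), optional gene annotations (UCSC `refFlat.txt`), and
read-to-genome alignments in MAF (two-row blocks with per-alignment
`mismap=` probabilities and lowercase soft-masking, as produced by a
split-read aligner), `repeatlens`:

1. discards ambiguous (`mismap > 1e-6`) and mostly-soft-masked alignments
   (no segment reaching the score threshold under gentle masking),
2. joins colinear alignment parts separated by ≤ 1 Mb,
3. predicts, per read and repeat, an integer copy-number change (expansion
   positive) from alignment gaps near the repeat — or from the unaligned
   span between two flanking alignments,
4. reports changes per strand (systematic sequencing errors can be
   strand-specific, producing bimodal distributions that are *not* two
   alleles),
5. ranks repeats by a priority score
   `(change in bases)/(reference length + 30) × region multiplier`
   (coding 50, UTR 20, promoter 15, ncRNA exon 15, intron 5; × 2 for coding
   polyglutamine/polyalanine units), and
6. joins multiple datasets case-vs-control with cubic-mean scores,
   `max(d − max(h, 0), 0)`, to de-prioritize benign variation.

A synthetic-data module generates loci, reads with planted copy changes
(plus uniform or strand-systematic error models, chimeric reads, and split
alignment geometries), and ground-truth MAF from edit scripts, so the whole
pipeline is testable without an aligner or downloads.

## Command line

```sh
# genome-wide, including homopolymers, with gene-based ranking
repeatlens copy -u 1 -g refFlat.txt rmsk.txt alns.maf -o out.tsv

# custom disease-locus file, no ranking
repeatlens copy disease-tr.txt alns.maf

# joint prioritization: case files, a literal ':', control files
repeatlens join case.tsv : control1.tsv control2.tsv control3.tsv

# text histograms (optionally -i out.png)
repeatlens plot out.tsv

# generate a synthetic dataset (reference/reads FASTA, BED, MAF, truth TSV)
repeatlens simulate -o simdir -n 100 --seed 1
```

Output is a headered TSV: `chrom start end unit geneLabel forwardChanges
reverseChanges [score]`, with change lists comma-joined per strand; rows
round-trip through `repeatlens.io_cli.read_results`, which is how `join`
consumes them. Coordinates are 0-based half-open throughout.

## Library layout

| module | contents |
|---|---|
| `repeatlens.annotations` | rmsk/BED repeat parsing, refFlat gene models, genomic-context classification |
| `repeatlens.maf_io` | MAF reading/writing, gap-run extraction, gentle-masked max-segment scoring |
| `repeatlens.copy_number` | filtering, colinear joining, single-/multi-alignment copy-change prediction |
| `repeatlens.prioritize` | top-change selection, priority score, ranking, cubic-mean case/control join |
| `repeatlens.io_cli` | result TSV format, histograms, CLI |
| `repeatlens.synthetic` | locus/read/error simulation and ground-truth MAF generation |

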