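# ribodeconv

Recover ribosome A-site positions from ribosome profiling (ribo-seq) data by
deconvolving the positional blur that imperfect RNase digestion imprints on
5'-end read pileups.

Observed pileups, stratified by read length, are modeled as the convolution
of a hidden per-transcript position signal with a length-specific digestion
kernel over offsets [-15, 15]. The package:

- builds and filters length-stratified 5'-end profiles from transcriptome
  SAM/BAM alignments (`ribodeconv.profiles`);
- estimates per-length blur kernels from start-codon-anchored meta-profiles
  with an EM-like loop whose kernel update is non-negative least squares
  (`ribodeconv.metablur`);
- recovers the hidden consensus signal per transcript with an EM-like,
  ridge-damped (LSQR, damp=1) total-least-squares procedure
  (`ribodeconv.deblur`);
- merges the per-length recovered signals into sub-codon A-site profiles and
  computes frame statistics, including synthetic +1 frameshift experiments
  (`ribodeconv.asite`);
- estimates per-codon decoding times as the skewness of lognormal fits to
  normalized A-site counts and compares Watson-Crick vs wobble decoding
  within same-tRNA codon pairs (`ribodeconv.cdt`);
- generates fully ground-truthed synthetic datasets — signals, kernels,
  multinomial reads, SAM files, planted dwell times and frameshifts — for
  download-free end-to-end validation (`ribodeconv.synthetic`).

## Command-line usage

All stages are subcommands of one entry point. A complete synthetic run:

```sh
ribodeconv simulate --out bundle --sam            # ground-truth fixture
ribodeconv build-profiles --bam bundle/reads.sam \
    --annot bundle/annotations.tsv --out profiles.tsv
ribodeconv estimate-blur --profiles profiles.tsv \
    --annot bundle/annotations.tsv --out blur.tsv
ribodeconv deblur --profiles profiles.tsv --annot bundle/annotations.tsv \
    --blur blur.tsv --out deblurred.tsv
ribodeconv asite --deblurred deblurred.tsv --out asite.tsv \
    --frame-stats-out frames.tsv
ribodeconv cdt --asite asite.tsv --fasta bundle/cds.fasta --out cdt.tsv \
    --wobble-out wobble.tsv
```

Inputs for real data are a transcriptome-coordinate SAM/BAM of uniquely
mapped ribo-seq reads, an annotation TSV (`transcript_id`, `cds_start`,
`cds_end`, `length`; 0-based, end-exclusive, CDS including the stop codon),
and a CDS FASTA (DNA or RNA alphabet). Optional TSVs supply per-codon tAI or
usage values (`--tai`) and custom wobble codon pairs (`--pairs`); a yeast
wobble-pair table is bundled.

All interchange files are plain TSV/FASTA/JSON. Positions are nt offsets
relative to the first base of the start codon; frame 0 is the A-site frame
of a correctly placed ribosome.

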