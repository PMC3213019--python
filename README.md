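# proteorf

Proteogenomic genome re-annotation from shotgun MS/MS peptide evidence.

Gene annotation for non-model organisms is incomplete: gene models
mis-place intron–exon boundaries, and real protein-coding regions are
missed entirely. Tandem mass spectrometry sees the expressed proteome
directly, so peptides confidently identified against a **six-frame
translation** of the genome — but absent from the annotated protein
database — pinpoint exactly these errors. `proteorf` implements the
desk side of that workflow for proteomics and genome-annotation groups:

- **`sixframe`** — six-frame translation and stop-to-stop ORF extraction
  (default minimum 35 aa, no start-codon requirement) with genome
  coordinates that round-trip through re-translation.
- **`digest_decoy`** — tryptic in-silico digestion (cleave after K/R,
  not before P) and decoy databases built by scrambling residues
  between fixed tryptic cleavage sites, preserving every tryptic
  peptide's composition and monoisotopic mass.
- **`protein_set`** — priority-ordered merging of protein releases
  (e.g. RefSeq > official gene set > GenBank > predictions) with
  exact-duplicate removal and provenance reporting.
- **`peptide_map`** — two-pass peptide partitioning: *pre-existing*
  peptides locate in the annotated database (score ≥ 27 by default);
  peptides absent from it but locating in an ORF (score ≥ 25) become
  *new* after quality filters (fully tryptic, > 5 residues, not
  touching an ORF terminus, not contaminant-only).
- **`classify`** — ORF verdicts from aggregated evidence: **Group A**
  (pre-existing *and* new peptides → correction of an annotated gene,
  typically a region falsely called an intron), **Group B** (new
  peptides only → novel protein); ORFs with fewer than two unique
  peptides are rejected. Accepted ORFs are truncated to the span of
  their outermost peptide matches and emitted as FASTA/GFF3.
- **`fdr`** — decoy-counting FDR at PSM, peptide and protein level:
  FDR(t) = #decoys(score ≥ t) / #targets(score ≥ t), with a q-value
  style monotone envelope for threshold selection.
- **`consensus_library`** — consensus spectra from replicate
  identifications by a support-fraction vote; MSP output.
- **`synthetic`** — seeded toy genomes with planted annotation errors
  (mis-annotated introns, missing genes) and simulated peptide
  observations, providing ground truth for the whole pipeline.

## Worked example

`examples/reannotate_synthetic_genome.py` plants three mis-annotated
introns and two missing genes in a 20-gene toy genome and runs the full
pipeline:

```text
observed target peptides : 127
  pre-existing (in annotated db) : 108
  new (ORF-only, post-filters)   : 17
ORFs with evidence : 20
  Group A (corrections of annotated genes) : 3
  Group B (novel proteins)                 : 2
  ctg000-1_190: corrects ANN_gene000; intron-interior evidence at residues 113-144
  ctg001-2_236: corrects ANN_gene001; intron-interior evidence at residues 93-113
  ctg002-0_239: corrects ANN_gene002; intron-interior evidence at residues 52-80
```

All three intron errors surface as Group A ORFs linked back to the
flawed gene model by shared pre-existing peptides, with the
intron-interior residue ranges that the new peptides prove are
expressed; both missing genes surface as Group B. The other
`examples/*.py` scripts demonstrate decoy construction, FDR
thresholding, database merging and consensus building the same way.

A thin CLI mirrors the library (`proteorf translate | digest | decoy |
merge-fasta | map-peptides | classify-orfs | fdr | consensus |
simulate`); run `proteorf --help`.

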