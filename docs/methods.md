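# Methods

## The re-annotation procedure

The toolkit operationalizes a two-pass proteogenomic search. Identified
peptides are first looked up in the annotated protein database; those
present (at a search-score cutoff of 27, the scale of a Mascot ion
score) are *pre-existing* peptides. Peptides absent from the annotated
database are searched against the ORFs of a six-frame genome
translation at a more permissive cutoff of 25 — deliberately loose, as
an initial filter over a very large genomic search space — and become
*new* peptides after quality exclusions. Both classes are then
re-located against the ORF set, and each ORF is judged on its combined
evidence:

| unique peptides | has new | has pre-existing | verdict |
|---|---|---|---|
| < 2 | — | — | rejected (single hit) |
| ≥ 2 | no | yes | rejected (no novelty signal) |
| ≥ 2 | yes | yes | **Group A** — correction of an annotated gene |
| ≥ 2 | yes | no | **Group B** — novel protein |

Group A ORFs most commonly reflect intron–exon boundaries called in the
wrong place: the new peptides fall in a region previously annotated as
intronic. Because the peptides are the only boundary evidence
available, accepted ORFs are truncated to the span of the outermost
peptide matches before being added to a protein database; no attempt is
made to re-predict splice sites.

### Quality filters for new peptides

A hit backs a new peptide only if it is fully tryptic (both termini at
a genuine cleavage boundary, honoring the proline rule), longer than 5
residues, and not touching the first or last residue of the ORF
(frame-truncation artifacts). A peptide whose only protein-database
locations are contaminant entries (keratins, digestion enzymes) is
excluded outright. Each filter is a pure per-hit predicate, so the
outcome is independent of application order. Sub-threshold and
contaminant-only peptides land in the `unmatched` partition so that the
three classes remain exhaustive over observed target peptides.

## ORF model

ORFs are maximal stop-to-stop runs of at least 35 residues, with no
start-codon requirement: proteogenomic searches conventionally use
stop-bounded ORFs to avoid missing non-canonical or mis-predicted
starts (an optional methionine-trim mode is provided). Translation uses
the standard nuclear genetic code. Codons containing N translate to X,
and ORFs are split at X exactly as at a stop — fabricating residues
across ambiguous sequence would risk phantom peptide matches. Segments
that hit a contig end without a bounding stop are emitted and flagged
`touches_contig_end`; the end-of-sequence peptide filter downstream
depends on that flag's semantics. Coordinates are forward-strand,
0-based half-open internally and converted to 1-based closed only in
the GFF3 writer. ORF identifiers follow
`{contig}{strand}{frame}_{start}`, a declared, stable convention.

## Decoy construction

Decoys scramble residues *between fixed tryptic cleavage sites*. The
implementation pins K, R and P in place and permutes only the remaining
residues within each 0-missed-cleavage segment. Permuting K/R (even
proline-shielded ones) or letting a proline drift to a segment start
could create or destroy cleavage sites, silently changing the decoy's
peptide set; pinning all three letters guarantees the decoy has exactly
the target's cleavage pattern, hence per-peptide length, composition
and monoisotopic mass — the invariant that makes segment-shuffled
decoys a fair null for peptide-spectrum matching. Decoy peptides that
collide with target peptides are kept (re-shuffling would break
determinism) but counted and logged. Seeding is mandatory; there is no
wall-clock default.

## FDR estimation

The estimator is the plain decoy/target count ratio at a threshold,
inclusive of ties. It reproduces published Mayu-style PSM arithmetic
exactly (110 / 1,339,586 = 8.21 × 10⁻⁵). Mayu's hypergeometric
protein-level correction is not implemented; peptide- and protein-level
values from pipelines applying such corrections are therefore matched
only approximately by the simple ratio (e.g. 51 / 27,725 = 0.00184
against a corrected published 0.00180). Threshold selection applies a
q-value-style monotone envelope (minimum raw ratio over all thresholds
at or below a score), which removes non-monotone ratio artifacts; the
raw ratio is reported alongside. When the requested FDR is unattainable
the strictest threshold is returned with a warning rather than an
error.

## Consensus spectra

Replicate peaks are pooled and clustered greedily by m/z within a
tolerance (default 0.05 Th): the most intense unassigned peak seeds
each cluster, ties broken by lower m/z, making the result independent
of replicate order. A cluster is retained when at least `vote_frac`
(default 0.6) of replicates contribute to it; consensus m/z is the
intensity-weighted mean and intensity the mean over supporting
replicates (split peaks within one replicate are summed first).
Production library builders do not publish their exact voting weights;
this support-fraction vote is a deliberate, clearly labeled stand-in
that keeps the retain-repeated-peaks behaviour while being
deterministic and analyzable (noise retention follows a binomial law,
which the tests check). Mean rather than summed intensity is used so
consensus intensities stay on the scale of a single spectrum.

## Synthetic ground truth

The generator builds one gene per contig (mirroring a largely
unscaffolded assembly): a random 150–400 nt flank, a stop-free coding
sequence of 80–150 codons, a stop codon, and a second flank, on a
random strand. Proteins are uniform over the 20 residues and
reverse-translated uniformly over synonymous codons; no codon-usage or
composition realism is claimed. Mis-annotated-intron genes omit from
the annotation an interior block consisting of three consecutive
observable tryptic peptides (≥ 15 residues by construction); missing
genes are dropped from the annotation entirely. Proteins are rejection
sampled until they carry at least six observable (fully tryptic, 6–30
residue) peptides, at least four of them interior, so that planted
errors are detectable at sub-unit coverage.

Simulated observations sample, per protein, an exact-count random
subset of `round(coverage × n)` of its n observable peptides — exact
coverage per protein rather than Bernoulli coverage in expectation —
with 1 + Poisson replicate spectra per peptide. Target scores are
N(60, 8²) and null/decoy scores N(15, 4²): well separated around the
27/25 cutoffs, and simple enough that true FDR is available in closed
form for calibration checks. One decoy observation (shuffled peptide,
null score) is emitted per target observation.

What passing synthetic tests do **not** show: robustness to spliced
genes (no introns are simulated — the planted "intron" is an annotation
error, not a real splice), to sequence homology and repeats (random
sequences make cross-gene peptide collisions vanishingly rare, while
real genomes share domains), to modified peptides, chimeric spectra, or
realistic score distributions. Results on real data depend on the
upstream search engine's behaviour, which this toolkit deliberately
does not model.

## Problem sizes and numerical choices

Default test and acceptance runs use a 20-gene genome (3 planted intron
errors, 2 missing genes, coverage 0.8), 100 × 10 kb random contigs for
the ORF oracle comparison, 1,000 random proteins for the decoy audit
and 10,000 identifications for the 20-point FDR calibration sweep —
sizes chosen so the whole suite completes in seconds while every code
path is exercised at meaningful scale. FDR calibration is accepted
within 3 binomial standard errors of the realized false fraction plus a
one-count discreteness allowance. Score thresholds are inclusive
(score ≥ cutoff passes). I and L are distinct during peptide location
by default (`il_equivalent` collapses them). Database merging compares
literal full-length sequences, case-normalized, trailing stop
characters stripped.

## Known limitations

- Single-contig reasoning only: one protein spanning several contigs is
  reported as separate ORFs.
- No spliced-ORF prediction and no intron–exon boundary re-estimation.
- The simple-ratio FDR understates nothing but does not reproduce
  corrected protein-level estimates from Mayu-like tools.
- Consensus building assumes replicates are already grouped by peptide
  ion; it performs no clustering of unidentified spectra.
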