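"""Seeded toy genomes with planted annotation errors and simulated PSM lists.

The generator builds the two mis-annotation scenarios the re-annotation
workflow is designed to detect, with full ground truth:

* ``missed_intron_exon`` — the annotated protein release omits an
  internal block of a true protein (a region falsely called an intron).
  Peptides from the block are absent from the annotated database and
  surface as "new" peptides on the gene's ORF, alongside pre-existing
  peptides from the retained region: a Group A correction.
* ``missing_gene`` — the gene is absent from the annotated release
  entirely; every observed peptide is new: a Group B novel protein.

Each gene sits on its own contig (mirroring a largely unscaffolded
assembly), embedded in random intergenic flanks whose frames contain
stop codons at natural random frequency. Simulated observations are
tryptic peptides of the true proteins with well-separated target/decoy
score distributions, so FDR ground truth is computable in closed form.
No biological realism beyond this is claimed: codon usage is uniform
over synonymous codons and residue usage is uniform over the 20 amino
acids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from Bio.Data.CodonTable import unambiguous_dna_by_id

from .digest_decoy import digest
from .fdr import ScoredId
from .peptide_map import PeptideObservation
from .protein_set import ProteinEntry
from .sixframe import GenomeContig, reverse_complement

__all__ = [
    "GeneLocus",
    "PlantedError",
    "SyntheticTruth",
    "ScoreParams",
    "generate_genome",
    "simulate_observations",
    "simulate_scored_ids",
    "true_fdr",
]

_TABLE = unambiguous_dna_by_id[1]
_CODONS_FOR: dict[str, list[str]] = {}
for codon, aa in _TABLE.forward_table.items():
    _CODONS_FOR.setdefault(aa, []).append(codon)
_STOP_CODONS = tuple(_TABLE.stop_codons)
_AA20 = sorted(_CODONS_FOR)  # the 20 standard residues


@dataclass(frozen=True)
class GeneLocus:
    """Genomic placement of a true protein's coding sequence."""

    contig_id: str
    strand: str
    nt_start: int
    nt_end: int


@dataclass(frozen=True)
class PlantedError:
    """One deliberately introduced annotation flaw.

    ``region`` is the 0-based half-open residue range of the true protein
    omitted from the annotation (missed_intron_exon) or the whole protein
    (missing_gene).
    """

    type: str  # "missed_intron_exon" | "missing_gene"
    gene_id: str
    region: tuple[int, int]


@dataclass(frozen=True)
class SyntheticTruth:
    """Toy genome plus true and deliberately flawed protein releases."""

    genome: tuple[GenomeContig, ...]
    true_proteins: tuple[ProteinEntry, ...]
    annotated_proteins: tuple[ProteinEntry, ...]
    planted_errors: tuple[PlantedError, ...]
    loci: dict[str, GeneLocus] = field(default_factory=dict)


@dataclass(frozen=True)
class ScoreParams:
    """Search-score model: well-separated Gaussian target and null scores.

    Defaults put essentially all true-peptide scores above a cutoff of
    27 and essentially all null scores below 25, emulating the score
    separation of a confidently filtered search.
    """

    target_mean: float = 60.0
    target_sd: float = 8.0
    decoy_mean: float = 15.0
    decoy_sd: float = 4.0


def _observable_peptides(sequence: str, min_len: int = 6, max_len: int = 30) -> list:
    """Fully tryptic, 0-missed-cleavage peptides in the observable length range."""
    return [
        p for p in digest(sequence, 0) if min_len <= len(p.sequence) <= max_len
    ]


def _sample_protein(
    rng: np.random.Generator,
    n_codons: int,
    need_block: bool,
) -> tuple[str, tuple[int, int] | None]:
    """Random protein with usable tryptic structure; optionally an interior
    run of >=3 consecutive observable peptides to plant as a fake intron."""
    while True:
        seq = "".join(rng.choice(_AA20, size=n_codons))
        peps = digest(seq, 0)
        observable = [
            p for p in peps if 6 <= len(p.sequence) <= 30
        ]
        # interior = not the protein's first or last tryptic fragment
        interior = [
            p for p in observable
            if p.start_in_parent > 0 and p.start_in_parent + len(p.sequence) < len(seq)
        ]
        if len(observable) < 6 or len(interior) < 4:
            continue
        if not need_block:
            return seq, None
        # find 3 consecutive tryptic fragments, all observable and interior
        by_start = {p.start_in_parent: p for p in peps}
        starts = sorted(by_start)
        for i in range(1, len(starts) - 3):
            run = [by_start[starts[j]] for j in range(i, i + 3)]
            if all(6 <= len(p.sequence) <= 30 for p in run):
                a = run[0].start_in_parent
                b = run[-1].start_in_parent + len(run[-1].sequence)
                if b - a >= 15 and b < len(seq):
                    # keep at least one observable peptide outside the block
                    outside = [
                        p for p in observable
                        if p.start_in_parent + len(p.sequence) <= a or p.start_in_parent >= b
                    ]
                    if outside:
                        return seq, (a, b)
        # no suitable block: resample


def _reverse_translate(rng: np.random.Generator, protein: str) -> str:
    return "".join(rng.choice(_CODONS_FOR[aa]) for aa in protein)


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(("A", "C", "G", "T"), size=n))


def generate_genome(
    n_genes: int = 20,
    n_missed_intron: int = 3,
    n_missing_gene: int = 2,
    seed: int = 0,
    min_codons: int = 80,
    max_codons: int = 150,
) -> SyntheticTruth:
    """Generate a toy genome with planted annotation errors.

    Deterministic per seed. Each gene occupies one contig: a random
    left flank, a stop-free (in-frame) coding sequence of
    ``min_codons``..``max_codons`` codons, a stop codon, and a random
    right flank; strand is random. The first ``n_missed_intron`` genes
    get annotations missing an interior block of >= 15 residues; the
    next ``n_missing_gene`` genes are dropped from the annotation.
    """
    if n_missed_intron + n_missing_gene > n_genes:
        raise ValueError("more planted errors than genes")
    rng = np.random.default_rng(seed)
    contigs: list[GenomeContig] = []
    true_proteins: list[ProteinEntry] = []
    annotated: list[ProteinEntry] = []
    errors: list[PlantedError] = []
    loci: dict[str, GeneLocus] = {}
    for g in range(n_genes):
        gene_id = f"gene{g:03d}"
        contig_id = f"ctg{g:03d}"
        kind = (
            "missed_intron_exon"
            if g < n_missed_intron
            else "missing_gene"
            if g < n_missed_intron + n_missing_gene
            else "correct"
        )
        n_codons = int(rng.integers(min_codons, max_codons + 1))
        protein, block = _sample_protein(rng, n_codons, need_block=kind == "missed_intron_exon")
        cds = _reverse_translate(rng, protein)
        stop = str(rng.choice(_STOP_CODONS))
        left = _random_nt(rng, int(rng.integers(150, 401)))
        right = _random_nt(rng, int(rng.integers(150, 401)))
        strand = "+" if rng.random() < 0.5 else "-"
        forward = left + cds + stop + right
        if strand == "-":
            sequence = reverse_complement(forward)
            nt_start = len(right) + 3  # forward-strand coords of the CDS
            nt_end = nt_start + len(cds)
        else:
            sequence = forward
            nt_start = len(left)
            nt_end = nt_start + len(cds)
        contigs.append(GenomeContig(contig_id, sequence))
        loci[gene_id] = GeneLocus(contig_id, strand, nt_start, nt_end)
        true_proteins.append(
            ProteinEntry(gene_id, protein, source="truth", description=f"{contig_id}({strand})")
        )
        if kind == "missing_gene":
            errors.append(PlantedError("missing_gene", gene_id, (0, len(protein))))
            continue
        if kind == "missed_intron_exon":
            a, b = block  # type: ignore[misc]
            errors.append(PlantedError("missed_intron_exon", gene_id, (a, b)))
            ann_seq = protein[:a] + protein[b:]
        else:
            ann_seq = protein
        annotated.append(
            ProteinEntry(f"ANN_{gene_id}", ann_seq, source="refseq", description=gene_id)
        )
    return SyntheticTruth(
        genome=tuple(contigs),
        true_proteins=tuple(true_proteins),
        annotated_proteins=tuple(annotated),
        planted_errors=tuple(errors),
        loci=loci,
    )


def simulate_observations(
    truth: SyntheticTruth,
    coverage: float = 0.8,
    score_params: ScoreParams = ScoreParams(),
    seed: int = 0,
    mean_replicates: float = 1.5,
) -> list[PeptideObservation]:
    """Simulate target and decoy PSMs from the true proteome.

    For each true protein the observable tryptic peptides (fully
    tryptic, 6-30 residues) are enumerated and an exact-count random
    subset of ``round(coverage * n)`` of them is observed, so the stated
    coverage holds per protein rather than only in expectation. Each
    observed peptide yields 1 + Poisson(``mean_replicates`` - 1)
    replicate spectra with Gaussian target scores. An equal number of
    decoy-labeled observations is generated from per-peptide shuffled
    sequences with null-distributed scores.
    """
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    rng = np.random.default_rng(seed)
    observations: list[PeptideObservation] = []
    spectrum = 0
    target_peptides: list[str] = []
    for protein in truth.true_proteins:
        peps = [p.sequence for p in _observable_peptides(protein.sequence)]
        if not peps:
            continue
        n_obs = max(1, round(coverage * len(peps))) if coverage < 1 else len(peps)
        chosen_idx = rng.choice(len(peps), size=n_obs, replace=False)
        for idx in sorted(chosen_idx):
            pep = peps[idx]
            target_peptides.append(pep)
            n_spec = 1 + int(rng.poisson(max(mean_replicates - 1, 0)))
            for _ in range(n_spec):
                spectrum += 1
                observations.append(
                    PeptideObservation(
                        spectrum_id=f"spec{spectrum:06d}",
                        peptide=pep,
                        score=float(rng.normal(score_params.target_mean, score_params.target_sd)),
                        sample_id=protein.accession,
                        is_decoy=False,
                    )
                )
    n_targets = len(observations)
    for i in range(n_targets):
        src = target_peptides[int(rng.integers(len(target_peptides)))]
        core = list(src[:-1])
        rng.shuffle(core)
        decoy_pep = "".join(core) + src[-1]  # keep tryptic terminus
        spectrum += 1
        observations.append(
            PeptideObservation(
                spectrum_id=f"spec{spectrum:06d}",
                peptide=decoy_pep,
                score=float(rng.normal(score_params.decoy_mean, score_params.decoy_sd)),
                sample_id="decoy",
                is_decoy=True,
            )
        )
    return observations


def simulate_scored_ids(
    n: int,
    pi0: float = 0.1,
    score_params: ScoreParams = ScoreParams(),
    seed: int = 0,
) -> tuple[list[ScoredId], np.ndarray]:
    """Simulate ``n`` target identifications plus matched decoys.

    A fraction ``pi0`` of targets is false (scores drawn from the null
    distribution); the decoy list has exactly one decoy per false
    target, drawn from the same null — the regime in which the
    decoy-ratio estimator is unbiased. Returns the combined list and a
    boolean array marking which targets are false.
    """
    if not 0 < pi0 < 1:
        raise ValueError("pi0 must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n_false = int(round(pi0 * n))
    n_true = n - n_false
    ids: list[ScoredId] = []
    is_false = np.zeros(n, dtype=bool)
    is_false[n_true:] = True
    scores = np.concatenate(
        [
            rng.normal(score_params.target_mean, score_params.target_sd, n_true),
            rng.normal(score_params.decoy_mean, score_params.decoy_sd, n_false),
        ]
    )
    for i, s in enumerate(scores):
        ids.append(ScoredId(f"t{i}", float(s), False))
    for i, s in enumerate(rng.normal(score_params.decoy_mean, score_params.decoy_sd, n_false)):
        ids.append(ScoredId(f"d{i}", float(s), True))
    return ids, is_false


def true_fdr(threshold: float, pi0: float, score_params: ScoreParams = ScoreParams()) -> float:
    """Closed-form FDR of the simulated score mixture at ``threshold``."""
    s_null = stats.norm.sf(threshold, score_params.decoy_mean, score_params.decoy_sd)
    s_alt = stats.norm.sf(threshold, score_params.target_mean, score_params.target_sd)
    denom = pi0 * s_null + (1 - pi0) * s_alt
    return float(pi0 * s_null / denom) if denom > 0 else 0.0
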