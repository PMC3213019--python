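"""Peptide identification lists, score thresholds and peptide-to-database mapping.

The central operation partitions identified peptides the way a two-pass
proteogenomic search does: peptides locatable in the annotated protein
database at the annotated-search score cutoff are "pre-existing"; the
rest are searched against a six-frame ORF database at a second (more
permissive) cutoff and, after quality exclusions — contaminant-only
matches, non- or semi-tryptic location, short peptides (<= 5 residues)
and matches touching an ORF terminus — become "new" peptides. New
peptides are the raw evidence for genome re-annotation.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

BOUNDARY = "-"  # flanking marker for a protein terminus

__all__ = [
    "PeptideObservation",
    "PeptideHit",
    "PeptidePartition",
    "read_peptide_tsv",
    "write_peptide_tsv",
    "threshold_hits",
    "locate_peptide",
    "partition_peptides",
]


@dataclass(frozen=True)
class PeptideObservation:
    """One peptide-spectrum match: spectrum, bare peptide, score, sample, decoy label."""

    spectrum_id: str
    peptide: str
    score: float
    sample_id: str
    is_decoy: bool

    def __post_init__(self) -> None:
        if not self.peptide:
            raise ValueError(f"{self.spectrum_id}: empty peptide")
        if not math.isfinite(self.score):
            raise ValueError(f"{self.spectrum_id}: non-finite score")


@dataclass(frozen=True)
class PeptideHit:
    """One occurrence of a peptide inside a database entry.

    ``tryptic_status`` is 'full' when both termini sit at genuine tryptic
    boundaries (protein terminus, or K/R not followed by P), 'partial'
    when exactly one does, 'none' otherwise. ``at_sequence_end`` flags
    hits touching the first or last residue of the entry — in an ORF
    database these are frame-truncation artifacts.
    """

    peptide: str
    target_accession: str
    start: int
    n_term_flanking: str
    c_term_flanking: str
    tryptic_status: str
    at_sequence_end: bool

    @property
    def end(self) -> int:
        return self.start + len(self.peptide)


@dataclass(frozen=True)
class PeptidePartition:
    """Disjoint, exhaustive split of observed target peptides."""

    pre_existing: frozenset[str]
    new: frozenset[str]
    unmatched: frozenset[str]


_TSV_COLUMNS = ("spectrum_id", "peptide", "score", "sample_id", "is_decoy")


def read_peptide_tsv(path) -> list[PeptideObservation]:
    """Read a peptide identification TSV with a strict header.

    Malformed rows raise with their line number. Modified-peptide strings
    are reduced to bare sequence by dropping anything that is not an
    upper-case residue letter (classification here is sequence-level).
    """
    observations: list[PeptideObservation] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            logger.warning("%s: empty peptide TSV", path)
            return []
        missing = set(_TSV_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
        for row in reader:
            line = reader.line_num
            try:
                score = float(row["score"])
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: line {line}: non-numeric score {row['score']!r}"
                ) from None
            flag = (row["is_decoy"] or "").strip().lower()
            if flag not in {"true", "false", "0", "1"}:
                raise ValueError(f"{path}: line {line}: bad is_decoy {row['is_decoy']!r}")
            peptide = "".join(ch for ch in row["peptide"] if ch.isalpha()).upper()
            if not peptide:
                raise ValueError(f"{path}: line {line}: empty peptide")
            observations.append(
                PeptideObservation(
                    spectrum_id=row["spectrum_id"],
                    peptide=peptide,
                    score=score,
                    sample_id=row["sample_id"],
                    is_decoy=flag in {"true", "1"},
                )
            )
    if not observations:
        logger.warning("%s: no observations", path)
    return observations


def write_peptide_tsv(observations: Iterable[PeptideObservation], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_COLUMNS)
        for o in observations:
            writer.writerow(
                [o.spectrum_id, o.peptide, repr(o.score), o.sample_id,
                 "true" if o.is_decoy else "false"]
            )


def threshold_hits(
    observations: Sequence[PeptideObservation], cutoff: float
) -> tuple[list[PeptideObservation], list[PeptideObservation]]:
    """Split observations into (score >= cutoff, score < cutoff)."""
    if math.isnan(cutoff):
        raise ValueError("cutoff must not be NaN")
    passed = [o for o in observations if o.score >= cutoff]
    failed = [o for o in observations if o.score < cutoff]
    return passed, failed


def _tryptic_status(peptide: str, n_flank: str, c_flank: str) -> str:
    n_ok = n_flank == BOUNDARY or (n_flank in "KR" and peptide[0] != "P")
    c_ok = c_flank == BOUNDARY or (peptide[-1] in "KR" and c_flank != "P")
    if n_ok and c_ok:
        return "full"
    if n_ok or c_ok:
        return "partial"
    return "none"


def _canon(sequence: str, il_equivalent: bool) -> str:
    return sequence.replace("I", "L") if il_equivalent else sequence


def locate_peptide(
    peptide: str,
    db: Sequence,
    il_equivalent: bool = False,
) -> list[PeptideHit]:
    """Find every occurrence of ``peptide`` in a protein or ORF database.

    Overlapping occurrences are all reported. Database entries need an
    ``accession``/``sequence`` pair (protein entries) or ``orf_id``/
    ``aa_sequence`` (six-frame ORFs). With ``il_equivalent`` isoleucine
    and leucine are collapsed during matching; reported hits keep the
    database residues.
    """
    if not peptide or not peptide.isalpha():
        raise ValueError(f"invalid peptide {peptide!r}")
    needle = _canon(peptide.upper(), il_equivalent)
    hits: list[PeptideHit] = []
    for entry in db:
        accession = getattr(entry, "accession", None) or getattr(entry, "orf_id")
        target = getattr(entry, "sequence", None) or getattr(entry, "aa_sequence")
        haystack = _canon(target, il_equivalent)
        start = haystack.find(needle)
        while start >= 0:
            end = start + len(needle)
            n_flank = target[start - 1] if start > 0 else BOUNDARY
            c_flank = target[end] if end < len(target) else BOUNDARY
            hits.append(
                PeptideHit(
                    peptide=peptide.upper(),
                    target_accession=accession,
                    start=start,
                    n_term_flanking=n_flank,
                    c_term_flanking=c_flank,
                    tryptic_status=_tryptic_status(target[start:end], n_flank, c_flank),
                    at_sequence_end=start == 0 or end == len(target),
                )
            )
            start = haystack.find(needle, start + 1)
    return hits


def qualifies_as_new(
    hit: PeptideHit,
    min_len: int = 6,
    exclude_sequence_end: bool = True,
) -> bool:
    """Quality filter for an ORF-database hit backing a 'new' peptide."""
    if len(hit.peptide) < min_len:
        return False
    if hit.tryptic_status != "full":
        return False
    if exclude_sequence_end and hit.at_sequence_end:
        return False
    return True


def partition_peptides(
    observations: Sequence[PeptideObservation],
    annotated_db: Sequence,
    orf_db: Sequence,
    contaminants: Sequence = (),
    cutoff_annotated: float = 27.0,
    cutoff_orf: float = 25.0,
    min_new_len: int = 6,
    exclude_sequence_end: bool = True,
    il_equivalent: bool = False,
) -> PeptidePartition:
    """Partition observed target peptides into pre-existing / new / unmatched.

    A peptide is *pre-existing* when its best score reaches
    ``cutoff_annotated`` and it is locatable anywhere in the annotated
    database. A peptide absent from the annotated database is *new* when
    its best score reaches ``cutoff_orf`` and it has at least one ORF hit
    surviving the quality filters. A peptide whose only protein-database
    locations are contaminant entries (keratins, digestion enzymes, ...)
    is contaminant-excluded and can never become new; a peptide also
    present in the annotated proteome is not excluded. Everything else —
    including sub-threshold peptides — is *unmatched*. The three sets are
    disjoint and cover all observed target peptides; decoy observations
    are ignored. The exclusions are per-hit predicates, so their
    application order cannot change the result.
    """
    best: dict[str, float] = {}
    for obs in observations:
        if obs.is_decoy:
            continue
        if obs.peptide not in best or obs.score > best[obs.peptide]:
            best[obs.peptide] = obs.score
    pre_existing: set[str] = set()
    new: set[str] = set()
    unmatched: set[str] = set()
    for peptide, score in best.items():
        ann_hits = locate_peptide(peptide, annotated_db, il_equivalent)
        if ann_hits:
            if score >= cutoff_annotated:
                pre_existing.add(peptide)
            else:
                unmatched.add(peptide)
            continue
        if contaminants and locate_peptide(peptide, contaminants, il_equivalent):
            unmatched.add(peptide)  # contaminant-only: all protein-db locations are contaminants
            continue
        if score >= cutoff_orf:
            good = [
                h for h in locate_peptide(peptide, orf_db, il_equivalent)
                if qualifies_as_new(h, min_new_len, exclude_sequence_end)
            ]
            if good:
                new.add(peptide)
                continue
        unmatched.add(peptide)
    return PeptidePartition(
        pre_existing=frozenset(pre_existing),
        new=frozenset(new),
        unmatched=frozenset(unmatched),
    )
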