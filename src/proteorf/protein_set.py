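"""Comprehensive protein database assembly.

Multiple annotated protein releases (e.g. RefSeq, an official gene set,
GenBank, ab-initio predictions) are merged into one search database by
removing exact full-length sequence duplicates and keeping the entry from
the earliest-listed source. Near-duplicates are deliberately retained:
with unresolved SNPs, sequencing errors and gene duplications it is not
possible to adjudicate which variant is real, so only literal sequence
identity collapses entries. Evidence-derived novel/corrected proteins are
appended afterwards under the ``novel`` source tag.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

__all__ = [
    "ProteinEntry",
    "MergeReport",
    "merge_sources",
    "append_novel",
    "read_protein_fasta",
    "write_protein_fasta",
    "write_merge_report_tsv",
]


@dataclass(frozen=True)
class ProteinEntry:
    """An amino-acid sequence with accession, source tag and decoy flag.

    Sequences are upper-cased and trailing stop characters are stripped
    before any comparison, so duplicate detection is on the translated
    product, not on formatting.
    """

    accession: str
    sequence: str
    source: str = ""
    decoy: bool = False
    description: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper().rstrip("*")
        if not seq:
            raise ValueError(f"{self.accession}: empty protein sequence")
        bad = set(seq) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"{self.accession}: invalid residue(s) {sorted(bad)!r}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MergeReport:
    """Provenance of one dropped exact duplicate."""

    dropped_accession: str
    dropped_source: str
    kept_accession: str
    kept_source: str


def merge_sources(
    sources: Sequence[tuple[str, Sequence[ProteinEntry]]],
) -> tuple[list[ProteinEntry], list[MergeReport]]:
    """Merge priority-ordered sources, collapsing exact sequence duplicates.

    The order of ``sources`` defines priority: for a set of identical
    sequences the entry from the earliest-listed source is kept (first
    occurrence wins within a source). Descriptions of dropped duplicates
    are folded into the kept entry's description, pipe-separated, so
    aliases survive the merge. Returns the merged database and a report
    mapping every dropped accession to its kept representative.
    """
    kept: dict[str, ProteinEntry] = {}  # sequence -> kept entry
    order: list[str] = []
    report: list[MergeReport] = []
    seen_accessions: set[str] = set()
    for source_tag, entries in sources:
        for entry in entries:
            if entry.accession in seen_accessions:
                raise ValueError(f"duplicate accession {entry.accession!r}")
            seen_accessions.add(entry.accession)
            entry = replace(entry, source=source_tag) if entry.source != source_tag else entry
            holder = kept.get(entry.sequence)
            if holder is None:
                kept[entry.sequence] = entry
                order.append(entry.sequence)
            else:
                report.append(
                    MergeReport(entry.accession, source_tag, holder.accession, holder.source)
                )
                if entry.description:
                    merged_desc = (
                        f"{holder.description}|{entry.description}"
                        if holder.description
                        else entry.description
                    )
                    kept[entry.sequence] = replace(holder, description=merged_desc)
    return [kept[seq] for seq in order], report


def append_novel(
    db: Sequence[ProteinEntry], novel: Sequence[ProteinEntry]
) -> tuple[list[ProteinEntry], list[MergeReport]]:
    """Append evidence-derived novel entries, dropping exact duplicates.

    Novel entries must carry the ``novel`` source tag. Accession clashes
    with the existing database are an error.
    """
    existing_acc = {e.accession for e in db}
    by_seq = {e.sequence: e for e in db}
    out = list(db)
    report: list[MergeReport] = []
    for entry in novel:
        if entry.source != "novel":
            raise ValueError(f"{entry.accession}: novel entries must have source 'novel'")
        if entry.accession in existing_acc:
            raise ValueError(f"accession clash: {entry.accession!r}")
        existing_acc.add(entry.accession)
        holder = by_seq.get(entry.sequence)
        if holder is not None:
            report.append(
                MergeReport(entry.accession, entry.source, holder.accession, holder.source)
            )
        else:
            by_seq[entry.sequence] = entry
            out.append(entry)
    return out, report


def read_protein_fasta(path, source: str = "", decoy_prefix: str = "DECOY_") -> list[ProteinEntry]:
    """Read a protein FASTA; entries whose id starts with the decoy prefix are flagged."""
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description[len(rec.id) :].strip() if rec.description else ""
        entries.append(
            ProteinEntry(
                accession=rec.id,
                sequence=str(rec.seq),
                source=source,
                decoy=rec.id.startswith(decoy_prefix),
                description=desc,
            )
        )
    return entries


def write_protein_fasta(entries: Iterable[ProteinEntry], path) -> None:
    records = [
        SeqRecord(Seq(e.sequence), id=e.accession, description=e.description)
        for e in entries
    ]
    SeqIO.write(records, str(path), "fasta")


def write_merge_report_tsv(report: Iterable[MergeReport], path) -> None:
    with open(path, "w") as fh:
        fh.write("dropped_accession\tdropped_source\tkept_accession\tkept_source\n")
        for row in report:
            fh.write(
                f"{row.dropped_accession}\t{row.dropped_source}\t"
                f"{row.kept_accession}\t{row.kept_source}\n"
            )
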