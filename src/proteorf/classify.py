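"""ORF-level aggregation of peptide evidence and Group A / Group B verdicts.

An ORF hit by at least two unique peptides is re-annotation evidence:
if both pre-existing and new peptides land on it, it corrects an
existing gene model (Group A — typically a region falsely called an
intron); if only new peptides do, it is a candidate novel protein
(Group B). ORFs with a single unique peptide are set aside, as are ORFs
carrying only pre-existing peptides. Accepted ORFs are truncated to the
span of their outermost peptide matches before being added to a protein
database, because the peptides are the only evidence available for the
expressed region's boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .peptide_map import PeptideHit, locate_peptide
from .protein_set import ProteinEntry
from .sixframe import SixFrameOrf

VERDICTS = ("group_a", "group_b", "rejected_single_hit", "rejected_no_new")

__all__ = [
    "EvidenceHit",
    "OrfClassification",
    "CorrectionLink",
    "collect_orf_evidence",
    "classify_orfs",
    "truncate_to_span",
    "link_corrections",
    "write_classification_gff3",
    "write_correction_report_tsv",
]


@dataclass(frozen=True)
class EvidenceHit:
    """A located peptide with its partition label ('pre_existing' or 'new')."""

    hit: PeptideHit
    label: str


@dataclass(frozen=True)
class OrfClassification:
    """Evidence summary and verdict for one ORF.

    ``truncated_aa_start``/``truncated_aa_end`` are 0-based half-open
    residue offsets within the ORF spanning the outermost peptide hits.
    """

    orf: SixFrameOrf
    peptides: tuple[EvidenceHit, ...]
    unique_peptide_count: int
    verdict: str
    truncated_aa_start: int
    truncated_aa_end: int
    linked_annotated_accessions: tuple[str, ...] = ()


@dataclass(frozen=True)
class CorrectionLink:
    """Correction-report row for one Group A ORF."""

    orf_id: str
    linked_accessions: tuple[str, ...]
    genomic_overlap: str
    novel_residue_ranges: tuple[tuple[int, int], ...]


def collect_orf_evidence(
    orf_db: Sequence[SixFrameOrf],
    pre_existing: Iterable[str],
    new: Iterable[str],
    il_equivalent: bool = False,
) -> dict[str, list[EvidenceHit]]:
    """Locate every partitioned peptide in every ORF.

    Returns ``orf_id -> labeled hits`` for ORFs with at least one hit.
    Both classes are re-searched against the ORFs: a pre-existing peptide
    landing on an ORF alongside new peptides is what turns that ORF into
    a correction rather than a novel protein.
    """
    evidence: dict[str, list[EvidenceHit]] = {}
    for label, peptides in (("pre_existing", pre_existing), ("new", new)):
        for peptide in sorted(set(peptides)):
            for hit in locate_peptide(peptide, orf_db, il_equivalent):
                evidence.setdefault(hit.target_accession, []).append(
                    EvidenceHit(hit=hit, label=label)
                )
    return evidence


def classify_orfs(
    evidence: Mapping[str, Sequence[EvidenceHit]],
    orf_db: Sequence[SixFrameOrf],
) -> list[OrfClassification]:
    """Assign a verdict to every ORF with evidence.

    The verdict is a total function of (unique peptide count, has new,
    has pre-existing): fewer than two unique peptide sequences rejects
    the ORF outright; two or more with at least one new peptide give
    Group A when a pre-existing peptide co-occurs and Group B otherwise;
    all-pre-existing ORFs carry no re-annotation signal. Uniqueness is by
    distinct bare sequence — nested or repeated hits of one peptide
    within an ORF count once. Output is sorted by genome position.
    """
    orfs_by_id = {o.orf_id: o for o in orf_db}
    out: list[OrfClassification] = []
    for orf_id, hits in evidence.items():
        orf = orfs_by_id.get(orf_id)
        if orf is None:
            raise KeyError(f"evidence references unknown ORF {orf_id!r}")
        unique = {h.hit.peptide for h in hits}
        has_new = any(h.label == "new" for h in hits)
        has_pre = any(h.label == "pre_existing" for h in hits)
        if len(unique) < 2:
            verdict = "rejected_single_hit"
        elif not has_new:
            verdict = "rejected_no_new"
        elif has_pre:
            verdict = "group_a"
        else:
            verdict = "group_b"
        out.append(
            OrfClassification(
                orf=orf,
                peptides=tuple(sorted(hits, key=lambda h: (h.hit.start, h.hit.peptide))),
                unique_peptide_count=len(unique),
                verdict=verdict,
                truncated_aa_start=min(h.hit.start for h in hits),
                truncated_aa_end=max(h.hit.end for h in hits),
            )
        )
    out.sort(key=lambda c: (c.orf.contig_id, c.orf.nt_start, c.orf.orf_id))
    return out


def truncated_genome_coords(c: OrfClassification) -> tuple[int, int]:
    """Forward-strand 0-based half-open genome coordinates of the truncated region."""
    orf = c.orf
    if orf.strand == "+":
        return (
            orf.nt_start + 3 * c.truncated_aa_start,
            orf.nt_start + 3 * c.truncated_aa_end,
        )
    return (
        orf.nt_end - 3 * c.truncated_aa_end,
        orf.nt_end - 3 * c.truncated_aa_start,
    )


def truncate_to_span(c: OrfClassification) -> ProteinEntry:
    """Shorten an accepted ORF to the region spanned by its peptide evidence.

    Returns a ``novel``-source protein entry; the genomic coordinates of
    the truncated region are recorded in the description.
    """
    if c.verdict not in {"group_a", "group_b"}:
        raise ValueError(f"{c.orf.orf_id}: cannot truncate a rejected ORF ({c.verdict})")
    g_start, g_end = truncated_genome_coords(c)
    return ProteinEntry(
        accession=c.orf.orf_id,
        sequence=c.orf.aa_sequence[c.truncated_aa_start : c.truncated_aa_end],
        source="novel",
        decoy=False,
        description=(
            f"{c.verdict} {c.orf.contig_id}:{g_start}-{g_end}({c.orf.strand}) "
            f"unique_peptides={c.unique_peptide_count}"
        ),
    )


def _subtract_intervals(
    spans: list[tuple[int, int]], holes: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Merge ``spans`` then remove ``holes``; both half-open."""
    merged: list[list[int]] = []
    for a, b in sorted(spans):
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    result: list[tuple[int, int]] = []
    for a, b in merged:
        cur = a
        for ha, hb in sorted(holes):
            if hb <= cur or ha >= b:
                continue
            if ha > cur:
                result.append((cur, ha))
            cur = max(cur, hb)
        if cur < b:
            result.append((cur, b))
    return result


def link_corrections(
    group_a: Sequence[OrfClassification],
    annotated_db: Sequence[ProteinEntry],
    annotated_coords: Mapping[str, tuple[str, int, int]] | None = None,
    il_equivalent: bool = False,
) -> list[CorrectionLink]:
    """Tie each Group A ORF back to the gene models it corrects.

    Linking is by shared pre-existing peptides (contigs are unscaffolded,
    so genomic proximity alone is not decisive); when coordinates for
    annotated entries are supplied, overlap of the ORF region with the
    linked entries' contigs is reported as well. The novel residue ranges
    — new-peptide residues lying outside every pre-existing peptide span
    — are the putative missed-exon evidence.
    """
    links: list[CorrectionLink] = []
    for c in group_a:
        if c.verdict != "group_a":
            raise ValueError(f"{c.orf.orf_id}: not a group_a classification")
        pre_peps = {h.hit.peptide for h in c.peptides if h.label == "pre_existing"}
        linked = sorted(
            {
                hit.target_accession
                for pep in pre_peps
                for hit in locate_peptide(pep, annotated_db, il_equivalent)
            }
        )
        overlap = "NA"
        if annotated_coords:
            g_start, g_end = truncated_genome_coords(c)
            notes = []
            for acc in linked:
                if acc not in annotated_coords:
                    continue
                contig, a_start, a_end = annotated_coords[acc]
                if contig != c.orf.contig_id:
                    notes.append(f"{acc}:other_contig")
                elif a_start < g_end and g_start < a_end:
                    notes.append(f"{acc}:overlap")
                else:
                    dist = max(a_start - g_end, g_start - a_end)
                    notes.append(f"{acc}:distance={dist}")
            overlap = ";".join(notes) if notes else "NA"
        new_spans = [
            (h.hit.start, h.hit.end) for h in c.peptides if h.label == "new"
        ]
        pre_spans = [
            (h.hit.start, h.hit.end) for h in c.peptides if h.label == "pre_existing"
        ]
        links.append(
            CorrectionLink(
                orf_id=c.orf.orf_id,
                linked_accessions=tuple(linked),
                genomic_overlap=overlap,
                novel_residue_ranges=tuple(_subtract_intervals(new_spans, pre_spans)),
            )
        )
    return links


def write_classification_gff3(
    classifications: Sequence[OrfClassification], path
) -> None:
    """Write truncated Group A/B regions as GFF3 ``protein_match`` features.

    Coordinates are converted to 1-based closed here and nowhere else.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in classifications:
            if c.verdict not in {"group_a", "group_b"}:
                continue
            g_start, g_end = truncated_genome_coords(c)
            attrs = (
                f"ID={c.orf.orf_id};verdict={c.verdict};"
                f"unique_peptides={c.unique_peptide_count}"
            )
            if c.linked_annotated_accessions:
                attrs += ";linked=" + ",".join(c.linked_annotated_accessions)
            fh.write(
                f"{c.orf.contig_id}\tproteorf\tprotein_match\t"
                f"{g_start + 1}\t{g_end}\t.\t{c.orf.strand}\t.\t{attrs}\n"
            )


def write_correction_report_tsv(links: Sequence[CorrectionLink], path) -> None:
    with open(path, "w") as fh:
        fh.write("orf_id\tlinked_accessions\tgenomic_overlap\tnovel_residue_ranges\n")
        for link in links:
            ranges = ",".join(f"{a}-{b}" for a, b in link.novel_residue_ranges)
            fh.write(
                f"{link.orf_id}\t{','.join(link.linked_accessions)}\t"
                f"{link.genomic_overlap}\t{ranges}\n"
            )
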