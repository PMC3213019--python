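"""Six-frame conceptual translation and stop-to-stop ORF extraction.

A genome contig is translated in three frames on each strand with the
standard (table 1) genetic code. ORFs are maximal stop-free runs of at
least ``min_orf_len`` residues; no start codon is required, which is the
conventional choice for proteogenomic searches where translation starts
are unknown. Every ORF carries forward-strand, 0-based half-open
nucleotide coordinates that round-trip through re-translation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_NUCLEOTIDES = frozenset("ACGTN")
STRANDS = ("+", "-")
FRAMES = (0, 1, 2)

__all__ = [
    "GenomeContig",
    "SixFrameOrf",
    "translate_six_frames",
    "extract_orfs",
    "reverse_complement",
    "read_genome_fasta",
    "write_orf_fasta",
]


@dataclass(frozen=True)
class GenomeContig:
    """A named nucleotide sequence over {A,C,G,T,N}; the coordinate frame for ORFs."""

    contig_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"contig {self.contig_id!r}: sequence is empty")
        seq = self.sequence.upper()
        for pos, base in enumerate(seq):
            if base not in VALID_NUCLEOTIDES:
                raise ValueError(
                    f"contig {self.contig_id!r}: invalid nucleotide {base!r} "
                    f"at position {pos}"
                )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SixFrameOrf:
    """A stop-bounded translated segment with genome coordinates.

    ``nt_start``/``nt_end`` are forward-strand, 0-based half-open and satisfy
    ``nt_end - nt_start == 3 * len(aa_sequence)``. ``frame`` is the phase
    offset (0..2) on the ORF's own strand. ``touches_contig_end`` marks
    segments not bounded by a stop codon on at least one side (the run hits
    the edge of the translated frame), which matter for the downstream
    end-of-sequence peptide filter.
    """

    orf_id: str
    contig_id: str
    strand: str
    frame: int
    nt_start: int
    nt_end: int
    aa_sequence: str
    touches_contig_end: bool = False

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.frame not in FRAMES:
            raise ValueError(f"invalid frame {self.frame!r}")
        if self.nt_end - self.nt_start != 3 * len(self.aa_sequence):
            raise ValueError(
                f"{self.orf_id}: nt span {self.nt_end - self.nt_start} != "
                f"3 * {len(self.aa_sequence)} aa"
            )
        if "*" in self.aa_sequence or "X" in self.aa_sequence:
            raise ValueError(f"{self.orf_id}: aa_sequence contains stop or X")


def reverse_complement(sequence: str) -> str:
    return str(Seq(sequence).reverse_complement())


def _translate_frame(nt: str, frame: int) -> str:
    """Translate one frame; stops as '*', codons containing N as 'X'."""
    sub = nt[frame:]
    sub = sub[: len(sub) - len(sub) % 3]  # drop trailing incomplete codon
    if not sub:
        return ""
    aa = list(str(Seq(sub).translate(table=1)))
    # Biopython resolves degenerate codons where all readings agree
    # (e.g. GGN -> G); mask every N-containing codon to X instead.
    if "N" in sub:
        for i in range(len(aa)):
            if "N" in sub[3 * i : 3 * i + 3]:
                aa[i] = "X"
    return "".join(aa)


def translate_six_frames(contig: GenomeContig) -> dict[tuple[str, int], str]:
    """Translate ``contig`` in all six frames.

    Returns a mapping ``(strand, frame) -> amino-acid string`` where stop
    codons are rendered '*' and any codon containing N is rendered 'X'.
    Frames on the '-' strand are phase offsets on the reverse complement.
    """
    fwd = contig.sequence
    rev = reverse_complement(fwd)
    out: dict[tuple[str, int], str] = {}
    for frame in FRAMES:
        out[("+", frame)] = _translate_frame(fwd, frame)
        out[("-", frame)] = _translate_frame(rev, frame)
    return out


def _runs(aa: str) -> Iterator[tuple[int, int]]:
    """Yield maximal [i, j) runs of residues that are neither '*' nor 'X'."""
    i = None
    for j, ch in enumerate(aa):
        if ch in "*X":
            if i is not None:
                yield i, j
                i = None
        elif i is None:
            i = j
    if i is not None:
        yield i, len(aa)


def extract_orfs(
    contig: GenomeContig,
    min_orf_len: int = 35,
    include_contig_end: bool = True,
    require_met_start: bool = False,
) -> list[SixFrameOrf]:
    """Extract every maximal stop-to-stop ORF of >= ``min_orf_len`` residues.

    Runs are broken at stop codons and at X residues (codons containing N);
    fabricating residues across an ambiguous codon is avoided by treating X
    as a break. Segments touching the edge of a translated frame (no
    bounding stop) are emitted with ``touches_contig_end=True`` unless
    ``include_contig_end`` is False. With ``require_met_start`` each run is
    trimmed to begin at its first methionine (runs without one are dropped).
    """
    if min_orf_len < 1:
        raise ValueError("min_orf_len must be >= 1")
    translations = translate_six_frames(contig)
    length = len(contig)
    orfs: list[SixFrameOrf] = []
    for (strand, frame), aa in translations.items():
        for i, j in _runs(aa):
            if require_met_start:
                m = aa.find("M", i, j)
                if m < 0:
                    continue
                i = m
            if j - i < min_orf_len:
                continue
            at_end = i == 0 or j == len(aa)
            if at_end and not include_contig_end:
                continue
            if strand == "+":
                nt_start = frame + 3 * i
                nt_end = frame + 3 * j
            else:
                nt_start = length - (frame + 3 * j)
                nt_end = length - (frame + 3 * i)
            orfs.append(
                SixFrameOrf(
                    orf_id=f"{contig.contig_id}{strand}{frame}_{nt_start}",
                    contig_id=contig.contig_id,
                    strand=strand,
                    frame=frame,
                    nt_start=nt_start,
                    nt_end=nt_end,
                    aa_sequence=aa[i:j],
                    touches_contig_end=at_end,
                )
            )
    orfs.sort(key=lambda o: (o.contig_id, o.nt_start, o.strand, o.frame))
    return orfs


def orf_nt_sequence(orf: SixFrameOrf, contig: GenomeContig) -> str:
    """Nucleotide sequence of ``orf`` in its own reading orientation."""
    if contig.contig_id != orf.contig_id:
        raise ValueError("contig does not match ORF")
    nt = contig.sequence[orf.nt_start : orf.nt_end]
    return nt if orf.strand == "+" else reverse_complement(nt)


def read_genome_fasta(path) -> list[GenomeContig]:
    """Read a (possibly multi-record, wrapped-line) nucleotide FASTA."""
    contigs = [
        GenomeContig(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not contigs:
        raise ValueError(f"no FASTA records in {path}")
    return contigs


def write_genome_fasta(contigs: Iterable[GenomeContig], path) -> None:
    records = [
        SeqRecord(Seq(c.sequence), id=c.contig_id, description="") for c in contigs
    ]
    SeqIO.write(records, str(path), "fasta")


def write_orf_fasta(orfs: Iterable[SixFrameOrf], path) -> None:
    """Write an ORF amino-acid database keyed by orf_id."""
    records = [
        SeqRecord(
            Seq(o.aa_sequence),
            id=o.orf_id,
            description=f"{o.contig_id}:{o.nt_start}-{o.nt_end}({o.strand}) frame={o.frame}",
        )
        for o in orfs
    ]
    SeqIO.write(records, str(path), "fasta")
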