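"""In-silico tryptic digestion and segment-shuffled decoy databases.

Trypsin cleaves C-terminally to K or R except when the next residue is
proline. Decoy sequences are built by scrambling residues between fixed
tryptic cleavage sites, which preserves each tryptic peptide's length,
amino-acid composition and therefore monoisotopic mass — the property
that makes segment-shuffled decoys a fair null model for peptide-spectrum
matching. K, R and P residues are pinned in place during scrambling so
the cleavage pattern of the decoy is identical to its target; permuting
them could silently create or destroy cleavage sites (a K drifting away
from a shielding proline, or a proline landing at a segment start) and
break the mass equivalence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .protein_set import AA_ALPHABET, ProteinEntry

logger = logging.getLogger(__name__)

DECOY_PREFIX = "DECOY_"

__all__ = [
    "TrypticPeptide",
    "digest",
    "cleavage_sites",
    "shuffle_decoy",
    "build_target_decoy_db",
    "decoy_target_peptide_collisions",
]


@dataclass(frozen=True)
class TrypticPeptide:
    """One tryptic fragment with its position in the parent protein."""

    sequence: str
    parent_accession: str
    start_in_parent: int
    missed_cleavages: int


def cleavage_sites(sequence: str) -> list[int]:
    """0-based positions immediately after which trypsin cleaves (proline rule)."""
    return [
        i + 1
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def digest(
    protein_sequence: str,
    missed_cleavages: int = 0,
    parent_accession: str = "",
) -> list[TrypticPeptide]:
    """Fully tryptic digest with up to ``missed_cleavages`` retained sites.

    Fragments are contiguous and ordered; at 0 missed cleavages they
    concatenate back to the input sequence.
    """
    if not protein_sequence:
        raise ValueError("empty protein sequence")
    seq = protein_sequence.upper()
    bad = set(seq) - AA_ALPHABET
    if bad:
        raise ValueError(f"invalid residue(s) {sorted(bad)!r} in protein sequence")
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    bounds = [0, *cleavage_sites(seq), len(seq)]
    peptides: list[TrypticPeptide] = []
    for mc in range(missed_cleavages + 1):
        for i in range(len(bounds) - 1 - mc):
            start, end = bounds[i], bounds[i + 1 + mc]
            peptides.append(
                TrypticPeptide(
                    sequence=seq[start:end],
                    parent_accession=parent_accession,
                    start_in_parent=start,
                    missed_cleavages=mc,
                )
            )
    peptides.sort(key=lambda p: (p.start_in_parent, p.missed_cleavages))
    return peptides


def _segments(sequence: str) -> list[tuple[int, int]]:
    bounds = [0, *cleavage_sites(sequence), len(sequence)]
    return list(zip(bounds[:-1], bounds[1:]))


def _shuffle_sequence(sequence: str, rng: np.random.Generator) -> str:
    out = list(sequence)
    for start, end in _segments(sequence):
        movable = [i for i in range(start, end) if sequence[i] not in "KRP"]
        if len(movable) < 2:
            continue
        perm = rng.permutation(len(movable))
        residues = [sequence[i] for i in movable]
        for slot, src in zip(movable, perm):
            out[slot] = residues[src]
    return "".join(out)


def shuffle_decoy(
    entry: ProteinEntry,
    seed: int | np.random.Generator,
    prefix: str = DECOY_PREFIX,
) -> ProteinEntry:
    """Scramble a target entry between fixed tryptic cleavage sites.

    Deterministic for a fixed seed. The decoy keeps the target's length,
    its per-segment residue composition and its exact cleavage pattern.
    """
    if entry.decoy:
        raise ValueError(f"{entry.accession}: already a decoy")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return ProteinEntry(
        accession=prefix + entry.accession,
        sequence=_shuffle_sequence(entry.sequence, rng),
        source=entry.source,
        decoy=True,
        description=entry.description,
    )


def build_target_decoy_db(
    entries: Sequence[ProteinEntry],
    seed: int,
    prefix: str = DECOY_PREFIX,
) -> list[ProteinEntry]:
    """Append one shuffled decoy per target: targets first, then decoys.

    A seed is mandatory; the output is a pure function of (entries, seed).
    Decoy peptides colliding with target peptides are kept (re-shuffling
    would break determinism) but counted and logged for FDR interpretation.
    """
    accessions = [e.accession for e in entries]
    if len(set(accessions)) != len(accessions):
        raise ValueError("duplicate accessions in target database")
    if any(e.decoy for e in entries):
        raise ValueError("input to build_target_decoy_db must be all targets")
    rng = np.random.default_rng(seed)
    decoys = [shuffle_decoy(e, rng, prefix=prefix) for e in entries]
    db = [*entries, *decoys]
    collisions = decoy_target_peptide_collisions(db)
    if collisions:
        logger.warning(
            "%d decoy tryptic peptides collide with target peptides", len(collisions)
        )
    return db


def decoy_target_peptide_collisions(db: Iterable[ProteinEntry]) -> set[str]:
    """Decoy 0-missed-cleavage tryptic peptides that also occur in a target."""
    target_peps: set[str] = set()
    decoy_peps: set[str] = set()
    for entry in db:
        peps = {p.sequence for p in digest(entry.sequence, 0, entry.accession)}
        (decoy_peps if entry.decoy else target_peps).update(peps)
    return decoy_peps & target_peps
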