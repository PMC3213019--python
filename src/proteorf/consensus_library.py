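"""Consensus spectra from replicate identifications, and MSP library output.

Replicate fragment spectra of the same peptide ion vary in noise but
agree on genuine fragment peaks. The builder pools peaks across
replicates, clusters them greedily by m/z (highest-intensity peak seeds
each cluster) and keeps clusters observed in at least a configurable
fraction of the replicates — a voting scheme that retains repeated
peaks and discards irreproducible noise. The exact voting weights of
production library builders are not standardized; the support-fraction
vote implemented here is a clearly labeled, deterministic stand-in that
honors the retain-repeated-peaks principle.
"""

from __future__ import annotations

import bisect
import csv
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "Spectrum",
    "ConsensusPeak",
    "ConsensusSpectrum",
    "build_consensus",
    "read_peaklist_tsv",
    "write_msp",
]


@dataclass(frozen=True)
class Spectrum:
    """One fragment spectrum: peptide ion plus (m/z, intensity) peak list."""

    spectrum_id: str
    peptide: str
    charge: int
    peaks: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError(f"{self.spectrum_id}: charge must be >= 1")
        if not self.peaks:
            raise ValueError(f"{self.spectrum_id}: no peaks")
        mzs = [mz for mz, _ in self.peaks]
        if any(b <= a for a, b in zip(mzs, mzs[1:])):
            raise ValueError(f"{self.spectrum_id}: m/z values must be strictly increasing")
        if any(inten < 0 for _, inten in self.peaks):
            raise ValueError(f"{self.spectrum_id}: negative intensity")


@dataclass(frozen=True)
class ConsensusPeak:
    mz: float
    intensity: float
    support: float  # fraction of replicates containing the peak


@dataclass(frozen=True)
class ConsensusSpectrum:
    peptide: str
    charge: int
    peaks: tuple[ConsensusPeak, ...]
    n_replicates: int


def build_consensus(
    replicates: Sequence[Spectrum],
    mz_tol: float = 0.05,
    vote_frac: float = 0.6,
) -> ConsensusSpectrum:
    """Vote a consensus spectrum out of replicate spectra of one peptide ion.

    Peaks from all replicates are pooled and clustered greedily: the
    most intense unassigned peak seeds a cluster that absorbs every
    unassigned peak within ``mz_tol`` Thomson (ties broken by lower m/z,
    making the result independent of replicate order). Clusters present
    in >= ``vote_frac`` of the replicates are retained with
    intensity-weighted mean m/z and mean per-replicate intensity. A
    single replicate is returned as-is with a warning, every peak at
    support 1.
    """
    if not replicates:
        raise ValueError("no replicate spectra")
    peptide, charge = replicates[0].peptide, replicates[0].charge
    for spec in replicates:
        if (spec.peptide, spec.charge) != (peptide, charge):
            raise ValueError(
                f"mixed peptide ions: {spec.peptide}/{spec.charge} vs {peptide}/{charge}"
            )
    n = len(replicates)
    if n == 1:
        logger.warning("single replicate for %s/%d: returned as-is", peptide, charge)
        peaks = tuple(ConsensusPeak(mz, inten, 1.0) for mz, inten in replicates[0].peaks)
        return ConsensusSpectrum(peptide, charge, peaks, 1)

    pool = [
        (mz, inten, rep_idx)
        for rep_idx, spec in enumerate(replicates)
        for mz, inten in spec.peaks
    ]
    # deterministic, permutation-invariant seed order
    pool.sort(key=lambda p: (-p[1], p[0], p[2]))
    assigned = [False] * len(pool)
    by_mz = sorted(range(len(pool)), key=lambda i: pool[i][0])
    mz_sorted = [pool[i][0] for i in by_mz]

    clusters: list[list[int]] = []
    for i in range(len(pool)):
        if assigned[i]:
            continue
        seed_mz = pool[i][0]
        lo = bisect.bisect_left(mz_sorted, seed_mz - mz_tol)
        hi = bisect.bisect_right(mz_sorted, seed_mz + mz_tol)
        members = [by_mz[j] for j in range(lo, hi) if not assigned[by_mz[j]]]
        for m in members:
            assigned[m] = True
        clusters.append(members)

    retained: list[ConsensusPeak] = []
    for members in clusters:
        reps: dict[int, float] = {}
        for m in members:
            mz, inten, rep_idx = pool[m]
            reps[rep_idx] = reps.get(rep_idx, 0.0) + inten  # merge split peaks per replicate
        support = len(reps) / n
        if support < vote_frac:
            continue
        total = sum(pool[m][1] for m in members)
        if total > 0:
            mz = sum(pool[m][0] * pool[m][1] for m in members) / total
        else:
            mz = sum(pool[m][0] for m in members) / len(members)
        intensity = sum(reps.values()) / len(reps)
        retained.append(ConsensusPeak(mz, intensity, support))

    retained.sort(key=lambda p: p.mz)
    merged: list[ConsensusPeak] = []
    for peak in retained:  # weighted means of distinct clusters can coincide
        if merged and peak.mz <= merged[-1].mz:
            prev = merged[-1]
            total = prev.intensity + peak.intensity
            merged[-1] = ConsensusPeak(
                mz=prev.mz,
                intensity=total,
                support=min(1.0, prev.support + peak.support),
            )
        else:
            merged.append(peak)
    return ConsensusSpectrum(peptide, charge, tuple(merged), n)


def read_peaklist_tsv(path) -> list[Spectrum]:
    """Read replicate peak lists from a TSV.

    Columns: spectrum_id, peptide, charge, mz, intensity; one row per
    peak, rows of one spectrum grouped by spectrum_id.
    """
    rows: dict[str, dict] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"spectrum_id", "peptide", "charge", "mz", "intensity"}
        if reader.fieldnames is None or required - set(reader.fieldnames):
            raise ValueError(f"{path}: expected columns {sorted(required)}")
        for row in reader:
            spec = rows.setdefault(
                row["spectrum_id"],
                {"peptide": row["peptide"], "charge": int(row["charge"]), "peaks": []},
            )
            spec["peaks"].append((float(row["mz"]), float(row["intensity"])))
    return [
        Spectrum(
            spectrum_id=sid,
            peptide=spec["peptide"],
            charge=spec["charge"],
            peaks=tuple(sorted(spec["peaks"])),
        )
        for sid, spec in rows.items()
    ]


def write_msp(spectra: Iterable[ConsensusSpectrum], path) -> None:
    """Write consensus spectra as an MSP spectral library."""
    with open(path, "w") as fh:
        for spec in spectra:
            fh.write(f"Name: {spec.peptide}/{spec.charge}\n")
            fh.write(f"Comment: Nreps={spec.n_replicates}\n")
            fh.write(f"NumPeaks: {len(spec.peaks)}\n")
            for peak in spec.peaks:
                fh.write(f"{peak.mz:.4f}\t{peak.intensity:.1f}\t\"support={peak.support:.2f}\"\n")
            fh.write("\n")
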