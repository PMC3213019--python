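"""Decoy-counting FDR estimation at PSM, peptide and protein level.

The estimator is the simple decoy/target ratio: with a shuffled decoy
database of the same size and composition as the target database, the
number of decoy identifications above a score threshold estimates the
number of false target identifications, so FDR ~= decoys / targets.
This reproduces published Mayu-style PSM arithmetic exactly
(110 / 1,339,586 = 8.21e-5); Mayu's hypergeometric protein-level
correction is deliberately not implemented, so peptide- and
protein-level numbers from pipelines applying it are matched only
approximately.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .digest_decoy import DECOY_PREFIX
from .peptide_map import PeptideObservation

logger = logging.getLogger(__name__)

LEVELS = ("psm", "peptide", "protein")

__all__ = [
    "ScoredId",
    "FdrSummary",
    "rollup",
    "estimate_fdr",
    "estimate_fdr_from_counts",
    "threshold_for_fdr",
    "fdr_curve",
]


@dataclass(frozen=True)
class ScoredId:
    """Best-scoring record for one identification unit at one level."""

    id_key: str
    best_score: float
    is_decoy: bool


@dataclass(frozen=True)
class FdrSummary:
    """Target/decoy counts and estimated FDR at one level and threshold.

    ``tp_count`` counts targets above threshold (assumed true positives),
    ``fp_count`` counts decoys (the false-positive estimate).
    """

    level: str
    tp_count: int
    fp_count: int
    fdr: float


def rollup(
    observations: Sequence[PeptideObservation],
    hits: Mapping[str, Sequence[str]] | None,
    level: str,
) -> list[ScoredId]:
    """Aggregate PSMs to one best-scoring record per unit at ``level``.

    psm: one record per spectrum_id. peptide: best score per distinct
    bare peptide; decoy iff every contributing PSM is decoy. protein:
    best score per accession over its peptides (``hits`` maps peptide ->
    accessions); a protein is decoy iff its accession carries the decoy
    prefix. Peptides with no accession are excluded with a warning.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    if level == "psm":
        best: dict[str, ScoredId] = {}
        for o in observations:
            cur = best.get(o.spectrum_id)
            if cur is None or o.score > cur.best_score:
                best[o.spectrum_id] = ScoredId(o.spectrum_id, o.score, o.is_decoy)
        return list(best.values())
    peptide_best: dict[str, float] = {}
    peptide_decoy: dict[str, bool] = {}
    for o in observations:
        if o.peptide not in peptide_best or o.score > peptide_best[o.peptide]:
            peptide_best[o.peptide] = o.score
        peptide_decoy[o.peptide] = peptide_decoy.get(o.peptide, True) and o.is_decoy
    if level == "peptide":
        return [
            ScoredId(pep, score, peptide_decoy[pep])
            for pep, score in peptide_best.items()
        ]
    if hits is None:
        raise ValueError("protein-level rollup requires a peptide->accession map")
    protein_best: dict[str, float] = {}
    skipped = 0
    for pep, score in peptide_best.items():
        accessions = hits.get(pep, ())
        if not accessions:
            skipped += 1
            continue
        for acc in accessions:
            if acc not in protein_best or score > protein_best[acc]:
                protein_best[acc] = score
    if skipped:
        logger.warning("%d peptides had no accession and were excluded", skipped)
    return [
        ScoredId(acc, score, acc.startswith(DECOY_PREFIX))
        for acc, score in protein_best.items()
    ]


def estimate_fdr(ids: Sequence[ScoredId], threshold: float, level: str = "psm") -> FdrSummary:
    """Count targets/decoys with best_score >= threshold; FDR = decoys/targets.

    FDR is 0 when no decoy passes; raising when no target passes, since
    the ratio is then undefined.
    """
    if not ids:
        raise ValueError("empty identification list")
    tp = sum(1 for r in ids if not r.is_decoy and r.best_score >= threshold)
    fp = sum(1 for r in ids if r.is_decoy and r.best_score >= threshold)
    if tp == 0:
        raise ValueError(f"no target identifications at threshold {threshold}")
    return FdrSummary(level=level, tp_count=tp, fp_count=fp, fdr=fp / tp)


def estimate_fdr_from_counts(tp_count: int, fp_count: int, level: str = "psm") -> FdrSummary:
    """Decoy-ratio FDR straight from target/decoy counts above a threshold.

    The counts-level entry point for published summary tables, where only
    the per-level target and decoy totals are printed.
    """
    if tp_count < 0 or fp_count < 0:
        raise ValueError("counts must be non-negative")
    if tp_count == 0:
        raise ValueError("no target identifications: FDR undefined")
    return FdrSummary(level=level, tp_count=tp_count, fp_count=fp_count, fdr=fp_count / tp_count)


def fdr_curve(ids: Sequence[ScoredId]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Raw and monotone-envelope FDR over the sweep of observed scores.

    Returns (thresholds descending, raw decoy/target ratio, q-value-style
    envelope). The envelope at a threshold is the minimum raw ratio over
    all thresholds at or below it, which makes estimated FDR
    non-increasing as the threshold rises.
    """
    if not ids:
        raise ValueError("empty identification list")
    scores = np.array([r.best_score for r in ids])
    decoy = np.array([r.is_decoy for r in ids])
    order = np.argsort(-scores, kind="stable")
    scores, decoy = scores[order], decoy[order]
    thresholds, last_idx = np.unique(-scores, return_index=True)
    thresholds = -thresholds  # ascending unique -> descending scores
    # index of last record with score >= each threshold
    counts_fp = np.cumsum(decoy)
    counts_tp = np.cumsum(~decoy)
    # thresholds ascending in -scores means descending in score; last_idx are
    # first occurrences in the sorted (descending) array
    n_at = np.searchsorted(-scores, -thresholds, side="right")
    fp = counts_fp[n_at - 1]
    tp = counts_tp[n_at - 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(tp > 0, fp / np.maximum(tp, 1), np.inf)
    envelope = np.minimum.accumulate(raw[::-1])[::-1]
    return thresholds, raw, envelope


def threshold_for_fdr(ids: Sequence[ScoredId], target_fdr: float) -> float:
    """Lowest score threshold whose envelope FDR is <= ``target_fdr``.

    The q-value-style monotone envelope avoids non-monotone raw-ratio
    artifacts. When even the strictest threshold exceeds the target (for
    instance an all-decoy list), the strictest threshold is returned
    with a warning.
    """
    if not 0 < target_fdr < 1:
        raise ValueError("target_fdr must be in (0, 1)")
    thresholds, _raw, envelope = fdr_curve(ids)
    ok = np.flatnonzero(envelope <= target_fdr)
    if ok.size == 0:
        logger.warning(
            "FDR %g unattainable; returning strictest threshold %g",
            target_fdr,
            thresholds[0],
        )
        return float(thresholds[0])
    return float(thresholds[ok[-1]])  # lowest qualifying score


def format_summary_block(summaries: Sequence[FdrSummary]) -> str:
    """Mayu-style three-level summary block."""
    lines = []
    for s in summaries:
        tag = {"psm": "PSM", "peptide": "pepID", "protein": "protID"}[s.level]
        lines.append(
            f"{s.level.capitalize():8s} TP_{tag}: {s.tp_count:,} "
            f"FP_{tag}: {s.fp_count:,} FDR: {s.fdr:.3g}"
        )
    return "\n".join(lines)
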