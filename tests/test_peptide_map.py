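"""Peptide TSV handling, score thresholds, location and the two-pass partition."""

import itertools

import pytest

from proteorf.peptide_map import (
    PeptideObservation,
    locate_peptide,
    partition_peptides,
    qualifies_as_new,
    read_peptide_tsv,
    threshold_hits,
    write_peptide_tsv,
)
from proteorf.protein_set import ProteinEntry

AA20 = list("ACDEFGHIKLMNPQRSTVWY")


def obs(peptide, score, spectrum="s1", decoy=False):
    return PeptideObservation(spectrum, peptide, score, "sample", decoy)


class TestTsv:
    def test_well_formed_file(self, tmp_path):
        p = tmp_path / "obs.tsv"
        p.write_text(
            "spectrum_id\tpeptide\tscore\tsample_id\tis_decoy\n"
            "s1\tMKTAYR\t31.5\ta\tfalse\n"
            "s2\tSTLLEK\t12\ta\ttrue\n"
            "s3\tM[+16]KTAYR\t40\tb\tfalse\n"
        )
        rows = read_peptide_tsv(p)
        assert len(rows) == 3
        assert rows[2].peptide == "MKTAYR"  # modification stripped
        assert rows[1].is_decoy

    def test_non_numeric_score_names_line(self, tmp_path):
        p = tmp_path / "obs.tsv"
        p.write_text(
            "spectrum_id\tpeptide\tscore\tsample_id\tis_decoy\n"
            "s1\tMK\tgood\ta\tfalse\n"
        )
        with pytest.raises(ValueError, match="line 2"):
            read_peptide_tsv(p)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "obs.tsv"
        p.write_text("spectrum_id\tpeptide\tscore\tsample_id\ns1\tMK\t3\ta\n")
        with pytest.raises(ValueError, match="is_decoy"):
            read_peptide_tsv(p)

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "obs.tsv"
        p.write_text("")
        assert read_peptide_tsv(p) == []

    def test_write_read_round_trip(self, tmp_path, rng):
        rows = [
            PeptideObservation(
                f"s{i}",
                "".join(rng.choice(AA20, size=8)),
                float(rng.normal(30, 10)),
                f"sample{i % 3}",
                bool(i % 2),
            )
            for i in range(20)
        ]
        p = tmp_path / "obs.tsv"
        write_peptide_tsv(rows, p)
        assert read_peptide_tsv(p) == rows


class TestThreshold:
    def test_cutoff_is_inclusive(self):
        rows = [obs("MKTAYR", s) for s in (26.9, 27.0, 30.0)]
        passed, failed = threshold_hits(rows, 27.0)
        assert len(passed) == 2 and len(failed) == 1

    def test_minus_infinity_passes_all(self):
        rows = [obs("MKTAYR", s) for s in (-100, 0, 100)]
        passed, failed = threshold_hits(rows, float("-inf"))
        assert len(passed) == 3 and failed == []

    def test_partition_is_exhaustive_and_disjoint(self, rng):
        rows = [obs("MKTAYR", float(s)) for s in rng.normal(27, 5, 100)]
        passed, failed = threshold_hits(rows, 27.0)
        assert len(passed) + len(failed) == len(rows)
        assert all(o.score >= 27 for o in passed)
        assert all(o.score < 27 for o in failed)


class TestLocate:
    def test_hit_at_protein_start_is_fully_tryptic(self):
        hits = locate_peptide("MK", [ProteinEntry("P1", "MKTAYR")])
        assert len(hits) == 1
        h = hits[0]
        assert h.start == 0 and h.n_term_flanking == "-"
        assert h.tryptic_status == "full" and h.at_sequence_end

    def test_absent_peptide_gives_empty_list(self):
        assert locate_peptide("WWW", [ProteinEntry("P1", "MKTAYR")]) == []

    def test_overlapping_occurrences_all_reported(self):
        hits = locate_peptide("AA", [ProteinEntry("P1", "KAAAK")])
        assert [h.start for h in hits] == [1, 2]

    def test_proline_rule_demotes_tryptic_status(self):
        # K followed by P is not a genuine site on either side
        db = [ProteinEntry("P1", "AKPEPTKR")]
        assert locate_peptide("PEPTK", db)[0].tryptic_status == "partial"
        db2 = [ProteinEntry("P2", "AKTESTKPR")]
        assert locate_peptide("TESTK", db2)[0].tryptic_status == "partial"

    def test_il_equivalence_switch(self):
        db = [ProteinEntry("P1", "KLLLK")]
        assert locate_peptide("III", db) == []
        hits = locate_peptide("III", db, il_equivalent=True)
        assert len(hits) == 1

    def test_matches_bruteforce_substring_oracle(self, rng):
        proteins = [
            ProteinEntry(f"P{i}", "".join(rng.choice(AA20, size=50)))
            for i in range(1000)
        ]
        for _ in range(30):
            src = proteins[int(rng.integers(len(proteins)))]
            start = int(rng.integers(0, len(src.sequence) - 6))
            peptide = src.sequence[start : start + 6]
            expected = {
                (p.accession, i)
                for p in proteins
                for i in range(len(p.sequence) - 5)
                if p.sequence[i : i + 6] == peptide
            }
            got = {(h.target_accession, h.start) for h in locate_peptide(peptide, proteins)}
            assert got == expected


class TestPartition:
    """Two-pass partition with the quality exclusions on the ORF pass."""

    ANNOTATED = [ProteinEntry("ANN1", "MTESTKVVVAYRLLLK")]
    # ORF contains the annotated protein plus flanking novel sequence
    ORFS = [ProteinEntry("ORF1", "GGGAKMTESTKVVVAYRLLLKWDDDCHHER" + "AEYWK" + "NNN")]

    def test_peptide_in_both_databases_is_pre_existing_only(self):
        part = partition_peptides([obs("TESTK", 40)], self.ANNOTATED, self.ORFS)
        assert part.pre_existing == {"TESTK"} and not part.new

    def test_short_orf_only_peptide_excluded(self):
        part = partition_peptides([obs("AEYWK", 40)], self.ANNOTATED, self.ORFS)
        assert "AEYWK" in part.unmatched  # 5 residues: too short for the new set

    def test_new_peptide_must_be_fully_tryptic(self):
        part = partition_peptides([obs("WDDDCHHER", 40), obs("DDDCHHER", 40)],
                                  self.ANNOTATED, self.ORFS)
        assert part.new == {"WDDDCHHER"}
        assert "DDDCHHER" in part.unmatched  # N-flank W: semi-tryptic

    def test_orf_terminus_hit_excluded(self):
        orfs = [ProteinEntry("ORF2", "WDDDCHHER" + "AAAK")]
        part = partition_peptides([obs("WDDDCHHER", 40)], self.ANNOTATED, orfs)
        assert "WDDDCHHER" in part.unmatched

    def test_scores_gate_each_pass(self):
        part = partition_peptides(
            [obs("TESTK", 26.0), obs("WDDDCHHER", 26.0)], self.ANNOTATED, self.ORFS
        )
        # annotated pass needs 27; ORF pass needs only 25
        assert "TESTK" in part.unmatched
        assert part.new == {"WDDDCHHER"}

    def test_contaminant_only_peptide_never_new(self):
        contaminant = [ProteinEntry("KERATIN", "AKWDDDCHHERLLK")]
        part = partition_peptides(
            [obs("WDDDCHHER", 40)], self.ANNOTATED, self.ORFS, contaminants=contaminant
        )
        assert "WDDDCHHER" in part.unmatched

    def test_decoy_observations_ignored(self):
        part = partition_peptides(
            [obs("TESTK", 40, decoy=True)], self.ANNOTATED, self.ORFS
        )
        assert not (part.pre_existing | part.new | part.unmatched)

    def test_partition_disjoint_and_exhaustive(self, truth, observations):
        from proteorf.sixframe import extract_orfs

        orfs = [o for c in truth.genome for o in extract_orfs(c, 35)]
        part = partition_peptides(observations, truth.annotated_proteins, orfs)
        target_peps = {o.peptide for o in observations if not o.is_decoy}
        sets = [part.pre_existing, part.new, part.unmatched]
        assert set().union(*sets) == target_peps
        for a, b in itertools.combinations(sets, 2):
            assert not a & b

    def test_exclusion_filters_are_order_independent(self):
        """Each exclusion is a pure per-hit predicate: conjunction in any
        order yields the same accepted-hit set."""
        hits = []
        for pep in ("AEYWK", "WDDDCHHER", "DDDCHHER"):
            hits.extend(locate_peptide(pep, self.ORFS))
        predicates = {
            "short": lambda h: len(h.peptide) >= 6,
            "tryptic": lambda h: h.tryptic_status == "full",
            "end": lambda h: not h.at_sequence_end,
        }
        results = set()
        for order in itertools.permutations(predicates.values()):
            kept = hits
            for pred in order:
                kept = [h for h in kept if pred(h)]
            results.add(tuple(sorted((h.peptide, h.start) for h in kept)))
            assert all(qualifies_as_new(h) for h in kept)
        assert len(results) == 1
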