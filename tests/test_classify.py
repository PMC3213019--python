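"""ORF evidence aggregation, Group A/B verdicts and truncation."""

import itertools

import pytest

from proteorf.classify import (
    classify_orfs,
    collect_orf_evidence,
    link_corrections,
    truncate_to_span,
    truncated_genome_coords,
    write_classification_gff3,
)
from proteorf.peptide_map import locate_peptide, partition_peptides
from proteorf.sixframe import GenomeContig, extract_orfs, orf_nt_sequence
from proteorf.synthetic import simulate_observations


def make_orf(aa, contig="ctg", strand="+", nt_start=0):
    from proteorf.sixframe import SixFrameOrf

    return SixFrameOrf(
        orf_id=f"{contig}{strand}0_{nt_start}",
        contig_id=contig,
        strand=strand,
        frame=0,
        nt_start=nt_start,
        nt_end=nt_start + 3 * len(aa),
        aa_sequence=aa,
    )


ORF = make_orf("GGGAKMTESTKVVVAYRLLLKWDDDCHHERAEYWKNNN")


class TestCollectEvidence:
    def test_labels_attached(self):
        ev = collect_orf_evidence([ORF], {"TESTK"}, {"WDDDCHHER"})
        labels = {(h.hit.peptide, h.label) for h in ev[ORF.orf_id]}
        assert labels == {("TESTK", "pre_existing"), ("WDDDCHHER", "new")}

    def test_orf_without_hits_absent(self):
        assert collect_orf_evidence([ORF], {"WWWWW"}, set()) == {}

    def test_equals_bruteforce_scan(self, truth, observations):
        orfs = [o for c in truth.genome for o in extract_orfs(c, 35)]
        part = partition_peptides(observations, truth.annotated_proteins, orfs)
        ev = collect_orf_evidence(orfs, part.pre_existing, part.new)
        got = {
            (orf_id, h.hit.peptide, h.hit.start, h.label)
            for orf_id, hits in ev.items()
            for h in hits
        }
        expected = set()
        for label, peps in (("pre_existing", part.pre_existing), ("new", part.new)):
            for pep in peps:
                for orf in orfs:
                    start = orf.aa_sequence.find(pep)
                    while start >= 0:
                        expected.add((orf.orf_id, pep, start, label))
                        start = orf.aa_sequence.find(pep, start + 1)
        assert got == expected


class TestVerdicts:
    def _classify(self, pre, new):
        ev = collect_orf_evidence([ORF], pre, new)
        return classify_orfs(ev, [ORF])[0].verdict

    def test_two_new_only_is_group_b(self):
        assert self._classify(set(), {"WDDDCHHER", "MTESTK"}) == "group_b"

    def test_new_plus_pre_existing_is_group_a(self):
        assert self._classify({"TESTK"}, {"WDDDCHHER"}) == "group_a"

    def test_single_new_hit_rejected(self):
        assert self._classify(set(), {"WDDDCHHER"}) == "rejected_single_hit"

    def test_all_pre_existing_rejected(self):
        assert self._classify({"TESTK", "VVVAYR"}, set()) == "rejected_no_new"

    def test_nested_duplicate_hits_count_once(self):
        orf = make_orf("AKWEEEDKWEEEDKAK")
        ev = collect_orf_evidence([orf], set(), {"WEEEDK"})
        cls = classify_orfs(ev, [orf])[0]
        assert cls.unique_peptide_count == 1
        assert cls.verdict == "rejected_single_hit"

    def test_verdict_total_over_all_label_combinations(self):
        """The verdict is a total function of (unique count, has_new, has_pre)."""
        peptides = {"pre": ["TESTK", "VVVAYR"], "new": ["WDDDCHHER", "MTESTK"]}
        for n_pre, n_new in itertools.product(range(3), range(3)):
            if n_pre == n_new == 0:
                continue
            pre = set(peptides["pre"][:n_pre])
            new = set(peptides["new"][:n_new])
            verdict = self._classify(pre, new)
            if n_pre + n_new < 2:
                assert verdict == "rejected_single_hit"
            elif n_new == 0:
                assert verdict == "rejected_no_new"
            elif n_pre > 0:
                assert verdict == "group_a"
            else:
                assert verdict == "group_b"


class TestTruncation:
    def test_span_is_min_start_to_max_end(self):
        orf = make_orf("A" * 10 + "WEEEDKWWW" + "A" * 21 + "FEEEDKWWWWWW" + "A" * 8)
        ev = collect_orf_evidence([orf], set(), {"WEEEDKWWW", "FEEEDKWWWWWW"})
        cls = classify_orfs(ev, [orf])[0]
        assert (cls.truncated_aa_start, cls.truncated_aa_end) == (10, 52)
        entry = truncate_to_span(cls)
        assert entry.sequence == orf.aa_sequence[10:52]
        assert entry.source == "novel"

    def test_rejected_orf_cannot_be_truncated(self):
        ev = collect_orf_evidence([ORF], set(), {"WDDDCHHER"})
        cls = classify_orfs(ev, [ORF])[0]
        with pytest.raises(ValueError, match="rejected"):
            truncate_to_span(cls)

    def test_evidence_relocates_inside_truncated_entry(self, truth, observations):
        orfs = [o for c in truth.genome for o in extract_orfs(c, 35)]
        part = partition_peptides(observations, truth.annotated_proteins, orfs)
        ev = collect_orf_evidence(orfs, part.pre_existing, part.new)
        accepted = [
            c for c in classify_orfs(ev, orfs) if c.verdict in ("group_a", "group_b")
        ]
        assert accepted
        for cls in accepted:
            entry = truncate_to_span(cls)
            for h in cls.peptides:
                assert locate_peptide(h.hit.peptide, [entry])

    def test_truncated_genome_coords_translate_back(self, truth, observations):
        """The emitted genome region re-translates to the truncated sequence."""
        contigs = {c.contig_id: c for c in truth.genome}
        orfs = [o for c in truth.genome for o in extract_orfs(c, 35)]
        part = partition_peptides(observations, truth.annotated_proteins, orfs)
        ev = collect_orf_evidence(orfs, part.pre_existing, part.new)
        for cls in classify_orfs(ev, orfs):
            if cls.verdict not in ("group_a", "group_b"):
                continue
            g_start, g_end = truncated_genome_coords(cls)
            trimmed = make_orf(
                cls.orf.aa_sequence[cls.truncated_aa_start : cls.truncated_aa_end],
                contig=cls.orf.contig_id,
                strand=cls.orf.strand,
                nt_start=g_start,
            )
            nt = orf_nt_sequence(trimmed, contigs[cls.orf.contig_id])
            from test_sixframe import oracle_translate

            assert oracle_translate(nt, 0) == trimmed.aa_sequence


class TestLinkCorrections:
    def test_synthetic_intron_report_names_planted_gene(self, truth, observations):
        orfs = [o for c in truth.genome for o in extract_orfs(c, 35)]
        part = partition_peptides(observations, truth.annotated_proteins, orfs)
        ev = collect_orf_evidence(orfs, part.pre_existing, part.new)
        group_a = [c for c in classify_orfs(ev, orfs) if c.verdict == "group_a"]
        links = link_corrections(group_a, truth.annotated_proteins)
        assert len(links) == len(group_a)
        planted = {
            e.gene_id for e in truth.planted_errors if e.type == "missed_intron_exon"
        }
        named = set()
        for link in links:
            assert len(link.linked_accessions) >= 1
            assert link.novel_residue_ranges  # intron-interior evidence exists
            named.update(acc.removeprefix("ANN_") for acc in link.linked_accessions)
        assert planted <= named

    def test_genomic_overlap_reported_with_coords(self, truth, observations):
        orfs = [o for c in truth.genome for o in extract_orfs(c, 35)]
        part = partition_peptides(observations, truth.annotated_proteins, orfs)
        ev = collect_orf_evidence(orfs, part.pre_existing, part.new)
        group_a = [c for c in classify_orfs(ev, orfs) if c.verdict == "group_a"]
        coords = {
            f"ANN_{gid}": (locus.contig_id, locus.nt_start, locus.nt_end)
            for gid, locus in truth.loci.items()
        }
        links = link_corrections(group_a, truth.annotated_proteins, annotated_coords=coords)
        assert all("overlap" in link.genomic_overlap for link in links)


def test_gff3_output_is_one_based_closed(tmp_path):
    ev = collect_orf_evidence([ORF], {"TESTK"}, {"WDDDCHHER"})
    cls = classify_orfs(ev, [ORF])
    out = tmp_path / "out.gff3"
    write_classification_gff3(cls, out)
    lines = out.read_text().splitlines()
    assert lines[0] == "##gff-version 3"
    fields = lines[1].split("\t")
    assert fields[2] == "protein_match"
    g_start, g_end = truncated_genome_coords(cls[0])
    assert int(fields[3]) == g_start + 1 and int(fields[4]) == g_end
    assert "verdict=group_a" in fields[8]
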