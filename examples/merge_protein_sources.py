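"""Merge priority-ordered protein releases into one comprehensive database.

Exact sequence duplicates collapse onto the highest-priority source;
near-duplicates (SNP variants, sequencing errors) are kept. Novel
evidence-derived proteins are appended afterwards.
"""

from proteorf import ProteinEntry, append_novel, merge_sources

refseq = [ProteinEntry("XP_1", "MKTAYIAKQR", description="kinase")]
ogs = [
    ProteinEntry("GB_1", "MKTAYIAKQR", description="kinase-like"),  # exact duplicate
    ProteinEntry("GB_2", "MKTAYIAQQR", description="kinase variant"),  # near-duplicate kept
]
gnomon = [ProteinEntry("GN_1", "MSSPABCDEF".replace("B", "G"), description="prediction")]

merged, report = merge_sources([("refseq", refseq), ("ogs", ogs), ("gnomon", gnomon)])
print(f"kept {len(merged)} of {len(refseq) + len(ogs) + len(gnomon)} entries")
for row in report:
    print(f"  dropped {row.dropped_accession} ({row.dropped_source}) "
          f"-> kept {row.kept_accession} ({row.kept_source})")
print(f"aliases folded into kept entry: {merged[0].description!r}")

novel = [ProteinEntry("ORF_ctg1+0_120", "WDDDCHHER", source="novel")]
final, _ = append_novel(merged, novel)
print(f"after appending novel proteins: {len(final)} entries")
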