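"""Extract a strain's highly-expressed-gene set and print its codon metrics.

Uses a synthetic genome with 40 planted genes so the example is
self-contained; swap in `read_fasta(...)` / `read_ptt(...)` on a real
fna/ptt pair to run it on a genome of your own.
"""

from codonheg import FixtureSpec, build_heg_set, compute_metric_table, generate_fixture

genome, ptt = generate_fixture(FixtureSpec(seed=1, gene_length=100))
heg = build_heg_set(genome, ptt)
print(f"strain {heg.strain_label}: {len(heg)} HEG genes found, "
      f"{len(heg.missing)} catalog genes missing")

table = compute_metric_table(heg)
leucine = table.data[table.data["AA"] == "L"]
print("\nleucine family (counts and metrics):")
print(leucine.round(4).to_string())

# RSCU > 1 marks codons used more often than equal synonymous usage would
# predict; NRSCU is the within-family share; HEG_FB the share of all codons.
print("\nsum of leucine NRSCU (should be 1):", round(leucine["NRSCU"].sum(), 4))
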