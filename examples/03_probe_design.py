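"""Design direct-geneFISH probes against a synthetic phage genome.

Probes are 156-318 bp windows with GC in the 22.0-43.2% band, >= 90%
identity to every reference sequence, no ambiguous off-target similarity,
10-13 per genome, non-overlapping, preferring terminase / polymerase /
structural genes (expected to be conserved).
"""

import zombiescope as z

(gid, genome), genes = z.make_synthetic_phage_genome(length=40_000, seed=7)
probe_set = z.design_probes((gid, genome), references=[(gid, genome)],
                            annotations=genes)

print(probe_set.to_frame()[["start", "end", "length", "gc",
                            "min_identity_to_references", "gene_class"]]
      .to_string(index=False))
print("summary:", {k: round(v, 4) if isinstance(v, float) else v
                   for k, v in probe_set.summary().items()})
# count is capped at 13; every GC sits inside the band and identity is 1.0
# because the reference here is the genome itself.
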