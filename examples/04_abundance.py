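"""RPKM abundance from a mapping count table.

MAGs and 16S genes are normalized by library size and reference length;
phages are normalized to the SAR11 community (sum of reads mapped to all
SAR11 MAGs in the sample) so phage and host dynamics are comparable.
"""

import pandas as pd

import zombiescope as z

counts = pd.DataFrame([
    {"sample": "bloom_d1", "reference": "SAR11_mag1",
     "reference_class": "sar11_mag", "mapped_reads": 1000,
     "length_kb": 1300.0, "total_reads": 1_000_000},
    {"sample": "bloom_d1", "reference": "SAR11_mag2",
     "reference_class": "sar11_mag", "mapped_reads": 250,
     "length_kb": 900.0, "total_reads": 1_000_000},
    {"sample": "bloom_d1", "reference": "HTVC031P",
     "reference_class": "phage", "mapped_reads": 100,
     "length_kb": 50.0, "total_reads": 1_000_000},
])

table = z.compute_table(counts)
print(table.to_string(index=False))
# SAR11_mag1: 1000*1e6 / (1e6 * 1300)   = 0.769  (per-kb, per-million reads)
# HTVC031P : 100*1e6 / ((1000+250)*50)  = 1600   (relative to SAR11 reads)
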