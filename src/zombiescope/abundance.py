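"""RPKM-style relative abundance from read-mapping count tables.

Two normalizations are used in the zombie-cell study and implemented here:

* MAG / 16S-gene abundance::

      RPKM = reads mapped to reference * 1e6
             / (total reads in sample * reference length in kb)

* phage abundance relative to the SAR11 community::

      value = reads mapped to phage genome * 1e6
              / (sum of reads mapped to all SAR11 MAGs in the sample
                 * phage length in kb)

The module consumes count tables (one row per sample x reference); it does
not run a mapper.  A toy exact-substring mapper is provided to feed
end-to-end tests with synthetic reads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

COUNT_COLUMNS = ["sample", "reference", "reference_class",
                 "mapped_reads", "length_kb", "total_reads"]
REFERENCE_CLASSES = ("sar11_mag", "rrna_gene", "phage")


def mag_rpkm(mapped_reads: float, total_reads: float, length_kb: float) -> float:
    """Reads per kilobase of reference per million library reads."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if length_kb <= 0:
        raise ValueError("length_kb must be positive")
    if mapped_reads < 0:
        raise ValueError("mapped_reads must be non-negative")
    return mapped_reads * 1e6 / (total_reads * length_kb)


def phage_relative_rpkm(phage_mapped: float, sum_sar11_mag_mapped: float,
                        phage_length_kb: float) -> float:
    """Phage abundance normalized to the SAR11 community (per-kb, x1e6).

    A zero SAR11 denominator is undefined (raises), never silently 0:
    "no SAR11 detected" is not the same observation as "no phage".
    """
    if phage_length_kb <= 0:
        raise ValueError("phage_length_kb must be positive")
    if phage_mapped < 0:
        raise ValueError("phage_mapped must be non-negative")
    if sum_sar11_mag_mapped <= 0:
        raise ValueError("undefined: no reads mapped to SAR11 MAGs "
                         "in this sample")
    return phage_mapped * 1e6 / (sum_sar11_mag_mapped * phage_length_kb)


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    missing = set(COUNT_COLUMNS) - set(counts.columns)
    if missing:
        raise ValueError(f"count table missing columns {sorted(missing)}")
    if (counts["mapped_reads"] < 0).any():
        raise ValueError("mapped_reads must be non-negative")
    if (counts["length_kb"] <= 0).any():
        raise ValueError("length_kb must be positive")
    bad = set(counts["reference_class"]) - set(REFERENCE_CLASSES)
    if bad:
        raise ValueError(f"unknown reference classes {sorted(bad)}")
    return counts


def compute_table(counts: pd.DataFrame) -> pd.DataFrame:
    """One abundance record per (sample, reference).

    MAGs and 16S genes get library-size RPKM; phages get SAR11-relative
    RPKM with the per-sample sum of SAR11-MAG mapped reads as denominator.
    Phage rows in samples without SAR11-MAG reads are flagged undefined
    (NaN value), not zero.
    """
    if counts.empty:
        return pd.DataFrame(columns=["sample", "reference", "rpkm",
                                     "formula_variant", "undefined"])
    counts = validate_counts(counts)
    sar11_sums = (counts[counts["reference_class"] == "sar11_mag"]
                  .groupby("sample")["mapped_reads"].sum())
    rows = []
    for _, r in counts.iterrows():
        if r["reference_class"] == "phage":
            denom = float(sar11_sums.get(r["sample"], 0.0))
            if denom <= 0:
                value, undef = float("nan"), True
            else:
                value = phage_relative_rpkm(r["mapped_reads"], denom,
                                            r["length_kb"])
                undef = False
            variant = "phage_relative"
        else:
            value = mag_rpkm(r["mapped_reads"], r["total_reads"],
                             r["length_kb"])
            undef = False
            variant = "mag_rpkm"
        rows.append({"sample": r["sample"], "reference": r["reference"],
                     "rpkm": value, "formula_variant": variant,
                     "undefined": undef})
    return pd.DataFrame(rows)


def toy_map_reads(reads, references, sample: str = "s1",
                  reference_classes=None, total_reads: int | None = None
                  ) -> pd.DataFrame:
    """Exact-substring toy mapper producing a count table for tests.

    Each read maps to every reference containing it verbatim (multi-mapping
    allowed, as with real mappers).
    """
    refs = [(rid, str(seq)) for rid, seq in references]
    reference_classes = reference_classes or {}
    counts = {rid: 0 for rid, _ in refs}
    for read in reads:
        for rid, seq in refs:
            if read in seq:
                counts[rid] += 1
    rows = [{"sample": sample, "reference": rid,
             "reference_class": reference_classes.get(rid, "sar11_mag"),
             "mapped_reads": counts[rid],
             "length_kb": len(seq) / 1000.0,
             "total_reads": total_reads if total_reads is not None else len(reads)}
            for rid, seq in refs]
    return pd.DataFrame(rows)
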