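"""Attribute fusion calls from both analytes for a single patient.

Builds a handful of RNA and DNA fusion calls in memory, applies the
cross-analyte positivity rules, and prints the per-driver verdict.
"""

import dualfusion as df

rna = [
    # EML4-ALK seen in RNA with 28 total supporting reads (well above the
    # LOB-derived threshold of 4)
    df.FusionEvidence("PT1", "PT1_S1", df.Analyte.RNA, "EML4", "ALK",
                      df.Breakpoint("chr2", 42_492_091), df.Breakpoint("chr2", 3_300),
                      read_support=28),
    # a second candidate partner with weaker support
    df.FusionEvidence("PT1", "PT1_S1", df.Analyte.RNA, "KIF5B", "ALK",
                      df.Breakpoint("chr10", 32_306_071), df.Breakpoint("chr2", 3_350),
                      read_support=6),
    # NRG1 fusion seen in RNA only, 12 reads
    df.FusionEvidence("PT1", "PT1_S1", df.Analyte.RNA, "CD74", "NRG1",
                      df.Breakpoint("chr5", 149_784_001), df.Breakpoint("chr8", 450),
                      read_support=12),
]
dna = [
    # matching EML4-ALK breakend pair with 18 supporting reads: below the
    # 35-read unconditional cut, but >= 15 with an RNA match, so positive
    df.FusionEvidence("PT1", "PT1_S1", df.Analyte.DNA, "EML4", "ALK",
                      df.Breakpoint("chr2", 42_492_091), df.Breakpoint("chr2", 29_446_394),
                      read_support=18),
]

attributed = df.attribute(rna + dna, drivers=["ALK", "NRG1", "RET"])
for a in attributed:
    print(f"{a.driver}: {a.category.value}  "
          f"RNA partner={a.rna_partner} ({a.rna_support} reads), "
          f"DNA partner={a.dna_partner} ({a.dna_support} reads)")

# ALK is detected by both analytes (the 18-read DNA breakend is unlocked by
# the matching RNA-positive pair); EML4 is chosen over KIF5B because both
# keep the kinase domain intact and EML4 has the higher support. NRG1 has no
# DNA evidence at all, so it is RNA-only. RET has no evidence and is absent.
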