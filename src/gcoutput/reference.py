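"""Packaged synthetic germline and default V/J gene-usage reference.

The germline is a fixed 300-nt, in-frame, stop-free sequence with an
IMGT-like region layout (FWR1, CDR1, FWR2, CDR2, FWR3, CDR3) expressed as
contiguous 0-based half-open nucleotide intervals.  It is a stand-in for a
real IMGT reference: long enough for region-resolved mutation statistics,
short enough to keep simulation cheap.
"""

from __future__ import annotations

import pandas as pd

#: Fixed 300-nt synthetic germline (no stop codons in frame 0).
GERMLINE_300NT = (
    "ATGCCTAGAAGTGTGTCGCATTGCTGCCAAGTATTCGATGCATCTGTTACCCAGAGGTGC"
    "TCCTCACTACAGCCAGGTCATGGACTTCTTCTCAGGATATATTTGCGCTGCGGAAAACGG"
    "CTGATGGGGAGTCGACCTACCTTAATATCTCCGAGGTTGCCCTCACAAATGGCGATGTAC"
    "GCCACACGGGCTACACTCTCGCCTTCTCGTCGCAACTACGAGCTGGACTATCGGCCGAGA"
    "GGATCTAACACGAGAAGTACTTGCCGGCAATCCCTAACCGCCGCTCTCGGTCCACTACGC"
)

REGION_NAMES = ("FWR1", "CDR1", "FWR2", "CDR2", "FWR3", "CDR3")

#: Codon-aligned region boundaries tiling the 300-nt germline.
DEFAULT_REGION_LAYOUT = {
    "FWR1": (0, 75),
    "CDR1": (75, 99),
    "FWR2": (99, 150),
    "CDR2": (150, 174),
    "FWR3": (174, 288),
    "CDR3": (288, 300),
}

# Gene frequencies loosely shaped like public SARS-CoV-2 antibody surveys:
# IGHV1-69 / IGHV3-30 dominant heavy genes, IGKV3-11 / IGKV1-39 / IGKV3-20 /
# IGLV2-14 dominant light genes.  IGHV1-69 and IGHV1-69D are kept distinct.
_DEFAULT_VJ_ROWS = [
    ("IGHV1-69", "heavy", "V", 0.18),
    ("IGHV1-69D", "heavy", "V", 0.06),
    ("IGHV3-30", "heavy", "V", 0.20),
    ("IGHV3-53", "heavy", "V", 0.12),
    ("IGHV4-34", "heavy", "V", 0.10),
    ("IGHV4-59", "heavy", "V", 0.09),
    ("IGHV1-2", "heavy", "V", 0.08),
    ("IGHV5-51", "heavy", "V", 0.07),
    ("IGHV3-23", "heavy", "V", 0.06),
    ("IGHV2-5", "heavy", "V", 0.04),
    ("IGHJ4", "heavy", "J", 0.45),
    ("IGHJ6", "heavy", "J", 0.30),
    ("IGHJ3", "heavy", "J", 0.15),
    ("IGHJ5", "heavy", "J", 0.10),
    ("IGKV3-11", "kappa", "V", 0.22),
    ("IGKV1-39", "kappa", "V", 0.20),
    ("IGKV3-20", "kappa", "V", 0.18),
    ("IGKV1-33", "kappa", "V", 0.12),
    ("IGKV1-5", "kappa", "V", 0.08),
    ("IGKJ1", "kappa", "J", 0.50),
    ("IGKJ2", "kappa", "J", 0.30),
    ("IGKJ4", "kappa", "J", 0.20),
    ("IGLV2-14", "lambda", "V", 0.10),
    ("IGLV1-40", "lambda", "V", 0.06),
    ("IGLV3-21", "lambda", "V", 0.04),
    ("IGLJ2", "lambda", "J", 0.12),
    ("IGLJ3", "lambda", "J", 0.08),
]


def default_vj_usage() -> pd.DataFrame:
    """Default V/J gene-usage reference table.

    Returns a tidy frame with columns ``gene``, ``chain``, ``segment``
    (V or J) and ``frequency``.  Frequencies are normalized within each
    (chain, segment) stratum.
    """
    df = pd.DataFrame(_DEFAULT_VJ_ROWS, columns=["gene", "chain", "segment", "frequency"])
    df["frequency"] = df.groupby(["chain", "segment"])["frequency"].transform(
        lambda s: s / s.sum()
    )
    return df


def reference_gene_frequencies() -> pd.DataFrame:
    """Two-column (gene, frequency) V-gene reference for usage comparisons.

    Frequencies are normalized within each chain so that, per chain, the
    reference is itself a probability distribution over genes.
    """
    df = default_vj_usage()
    df = df[df["segment"] == "V"].copy()
    df["frequency"] = df.groupby("chain")["frequency"].transform(lambda s: s / s.sum())
    return df[["gene", "frequency"]].reset_index(drop=True)
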